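"""Set algebra on signed DEG sets: treatment reversal and cross-tissue overlap.

Given a *disease* contrast (control -> diabetic) and a *treatment*
contrast (diabetic -> treated) from the same tissue, the genes significant
in both are partitioned by the product of their fold-change signs: a
product of -1 means the treatment moved the gene opposite to the disease
("reversed"), +1 means the same direction ("exacerbated").  Reversal is
purely directional; no magnitude-restoration requirement is imposed.

Percentages are reported over the shared set only — genes significant in
just one contrast land in ``disease_only`` / ``treatment_only`` and do not
enter the denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

from .differential import DEGSet
from .exceptions import ConsistencyError

__all__ = [
    "LabeledGeneSet",
    "OverlapClassification",
    "OverlapReport",
    "classify_overlap",
    "cross_tissue_compare",
    "stratify_disease_degs",
]


@dataclass(frozen=True)
class LabeledGeneSet:
    label: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapClassification:
    """Partition of two signed DEG sets from one tissue.

    ``reversed`` and ``exacerbated`` partition the shared genes;
    ``disease_only`` / ``treatment_only`` hold the unshared remainders.
    """

    tissue: str
    reversed: frozenset[str]
    exacerbated: frozenset[str]
    disease_only: frozenset[str]
    treatment_only: frozenset[str]

    @property
    def shared(self) -> frozenset[str]:
        return self.reversed | self.exacerbated

    @property
    def pct_reversed(self) -> float:
        shared = len(self.shared)
        return 100.0 * len(self.reversed) / shared if shared else float("nan")

    @property
    def pct_exacerbated(self) -> float:
        shared = len(self.shared)
        return 100.0 * len(self.exacerbated) / shared if shared else float("nan")

    def summary(self) -> dict:
        return {
            "tissue": self.tissue,
            "n_reversed": len(self.reversed),
            "n_exacerbated": len(self.exacerbated),
            "n_shared": len(self.shared),
            "n_disease_only": len(self.disease_only),
            "n_treatment_only": len(self.treatment_only),
            "pct_reversed": self.pct_reversed,
            "pct_exacerbated": self.pct_exacerbated,
        }


def classify_overlap(disease: DEGSet, treatment: DEGSet) -> OverlapClassification:
    """Split genes shared by a disease and a treatment contrast by sign product.

    Expects the disease contrast oriented control -> diabetic and the
    treatment contrast diabetic -> treated (alt minus ref on the log2
    scale); under that orientation a negative sign product is a reversal.
    """
    if disease.tissue != treatment.tissue:
        raise ConsistencyError(
            f"contrasts come from different tissues: {disease.tissue!r} vs "
            f"{treatment.tissue!r}"
        )
    d_genes = disease.genes
    t_genes = treatment.genes
    shared = d_genes & t_genes
    rev, exa = set(), set()
    for gene in shared:
        product = disease.sign(gene) * treatment.sign(gene)
        if product == -1:
            rev.add(gene)
        elif product == 1:
            exa.add(gene)
        else:  # pragma: no cover - signs are +/-1 by DEGSet construction
            raise ConsistencyError(f"gene {gene!r} has a zero sign")
    return OverlapClassification(
        tissue=disease.tissue,
        reversed=frozenset(rev),
        exacerbated=frozenset(exa),
        disease_only=frozenset(d_genes - t_genes),
        treatment_only=frozenset(t_genes - d_genes),
    )


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise comparison of two labelled gene sets from any strata."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_shared: int
    n_only_a: int
    n_only_b: int
    shared: tuple[str, ...]  # lexicographically sorted

    def summary(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_shared": self.n_shared,
            "n_only_a": self.n_only_a,
            "n_only_b": self.n_only_b,
        }


def cross_tissue_compare(set_a: LabeledGeneSet, set_b: LabeledGeneSet) -> OverlapReport:
    """Overlap counts and the sorted shared gene list for two labelled sets."""
    shared = set_a.genes & set_b.genes
    return OverlapReport(
        label_a=set_a.label,
        label_b=set_b.label,
        n_a=len(set_a.genes),
        n_b=len(set_b.genes),
        n_shared=len(shared),
        n_only_a=len(set_a.genes - set_b.genes),
        n_only_b=len(set_b.genes - set_a.genes),
        shared=tuple(sorted(shared)),
    )


def stratify_disease_degs(
    classification: OverlapClassification, disease: DEGSet
) -> dict[str, LabeledGeneSet]:
    """Partition a disease DEG set by treatment response.

    Returns three labelled strata — ``"{tissue} db/db only"`` (disease
    DEGs untouched by treatment), ``"{tissue} Exacerbated"`` and
    ``"{tissue} Reversed"`` — whose sizes sum to the disease set size.
    """
    if classification.tissue != disease.tissue:
        raise ConsistencyError(
            f"classification tissue {classification.tissue!r} != disease tissue "
            f"{disease.tissue!r}"
        )
    tissue = classification.tissue
    return {
        "db/db only": LabeledGeneSet(
            f"{tissue} db/db only", classification.disease_only
        ),
        "Exacerbated": LabeledGeneSet(
            f"{tissue} Exacerbated", classification.exacerbated
        ),
        "Reversed": LabeledGeneSet(f"{tissue} Reversed", classification.reversed),
    }
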