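"""Per-gene pairwise group contrasts with Benjamini-Hochberg FDR gating.

A contrast compares two groups within one tissue.  The test statistic is a
two-sided Welch t-test on log2(FPKM + 1) replicate values — a deliberately
simple, pluggable stand-in whose downstream consumers need only a p-value,
a q-value and a direction per gene.  Fold changes use a +1 pseudocount on
the FPKM scale so zero expression stays representable:
``log2FC = log2((mean_alt + 1) / (mean_ref + 1))``.

Significance is gated at BH q < alpha (strict), with alpha = 0.05 by
default; the adjustment family is all genes tested in the one contrast.
Genes are tested unfiltered — no expression floor is applied here (the
low-expression filter belongs to the SOM stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DomainError,
    InsufficientReplicationError,
)
from .io import ExpressionMatrix

__all__ = ["ContrastResult", "DEGSet", "benjamini_hochberg", "call_degs", "extract_deg_set"]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjustment, returned in the input order.

    With the p-values sorted ascending, ``q_(i) = min_{j>=i} m * p_(j) / j``
    clipped to 1; ties are handled by a stable sort.  Monotone in the
    inputs and never below them.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DomainError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene statistics for one pairwise group contrast within a tissue.

    ``table`` is indexed by gene with columns ``mean_ref``, ``mean_alt``
    (FPKM), ``log2_fold_change``, ``p_value``, ``q_value``, ``direction``
    (up/down/none) and ``significant``.
    """

    contrast_name: str
    tissue: str
    group_ref: str
    group_alt: str
    alpha: float
    table: pd.DataFrame

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.table.reset_index()
        out = out.rename(columns={out.columns[0]: "gene"})
        out.insert(0, "contrast", self.contrast_name)
        return out


@dataclass(frozen=True)
class DEGSet:
    """The significant, signed subset of a contrast: gene -> +1 (up) or -1 (down)."""

    contrast_name: str
    tissue: str
    members: dict[str, int]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.members)

    def sign(self, gene: str) -> int:
        return self.members[gene]


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Welch p per row, with degenerate rows patched.

    Rows where both groups have zero variance get p = 1 if the means agree
    (no evidence of any kind) and p = 0 if they differ (the difference is
    noise-free at the observed resolution).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    # Welch with one zero-variance group can still yield nan at n=2 edge cases.
    p = np.where(np.isnan(p), 1.0, p)
    return p


def call_degs(
    matrix: ExpressionMatrix,
    tissue: str,
    group_ref: str,
    group_alt: str,
    alpha: float = 0.05,
) -> ContrastResult:
    """Test every gene for differential expression between two groups.

    The contrast is oriented ref -> alt: positive log2 fold change means
    higher expression in ``group_alt``.  Requires at least two replicate
    samples per group in the tissue.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha={alpha} outside (0, 1)")
    meta = matrix.metadata
    if tissue not in set(meta["tissue"]):
        raise ConfigurationError(f"unknown tissue {tissue!r}")
    for group in (group_ref, group_alt):
        if group not in set(meta["group"]):
            raise ConfigurationError(f"unknown group {group!r}")
    samples_ref = matrix.samples_for(tissue, group_ref)
    samples_alt = matrix.samples_for(tissue, group_alt)
    for group, samples in ((group_ref, samples_ref), (group_alt, samples_alt)):
        if len(samples) < 2:
            raise InsufficientReplicationError(
                f"group {group!r} has {len(samples)} replicate(s) in tissue "
                f"{tissue!r}; need >= 2"
            )

    fpkm_ref = matrix.values[samples_ref].to_numpy()
    fpkm_alt = matrix.values[samples_alt].to_numpy()
    log_ref = np.log2(fpkm_ref + 1.0)
    log_alt = np.log2(fpkm_alt + 1.0)

    p = _welch_p(log_ref, log_alt)
    q = benjamini_hochberg(p)
    mean_ref = fpkm_ref.mean(axis=1)
    mean_alt = fpkm_alt.mean(axis=1)
    lfc = np.log2((mean_alt + 1.0) / (mean_ref + 1.0))
    significant = q < alpha
    direction = np.where(
        significant & (lfc > 0), "up", np.where(significant & (lfc < 0), "down", "none")
    )
    table = pd.DataFrame(
        {
            "mean_ref": mean_ref,
            "mean_alt": mean_alt,
            "log2_fold_change": lfc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "significant": significant,
        },
        index=matrix.values.index.copy(),
    )
    name = f"({tissue}) {group_ref} vs {group_alt}"
    return ContrastResult(
        contrast_name=name,
        tissue=tissue,
        group_ref=group_ref,
        group_alt=group_alt,
        alpha=alpha,
        table=table,
    )


def extract_deg_set(result: ContrastResult) -> DEGSet:
    """The significant genes of a contrast with their fold-change signs.

    A significant gene with an exactly zero fold change has no usable
    direction and is excluded (members carry signs +1/-1 only).
    """
    tab = result.table
    sel = tab[tab["significant"] & (tab["log2_fold_change"] != 0)]
    members = {
        gene: (1 if lfc > 0 else -1)
        for gene, lfc in zip(sel.index, sel["log2_fold_change"])
    }
    return DEGSet(
        contrast_name=result.contrast_name, tissue=result.tissue, members=members
    )
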