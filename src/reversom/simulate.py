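"""Synthetic FPKM matrices emulating a 4-tissue, 4-group diabetes/treatment study.

The generator mirrors the design of a db/db mouse pioglitazone experiment:
four tissues (sciatic nerve SCN, dorsal root ganglia DRG, kidney glomeruli
Glom, kidney cortex), four groups (db/+ control, db/db diabetic, and both
with pioglitazone, "PIO"), and n replicates per tissue x group cell.

Expression is simulated on the log2(FPKM + 1) scale: a right-skewed
baseline per gene, plus planted additive effects.  A *disease* effect is
applied to every db/db-containing group and a *treatment* effect to every
PIO-containing group, so a gene whose treatment effect is the exact
negative of its disease effect returns to baseline in db/db PIO — the
"reversed" pattern; equal signs give the "exacerbated" pattern.  Replicate
noise is Gaussian on the log scale and values are mapped back through
FPKM = 2**x - 1, truncated at zero.

A second layer of planted structure is co-expression *module archetypes*:
groups of genes that share a fixed profile over six conditions (by default
db/+, db/db and db/db PIO in SCN and Glom), intended to be recoverable by
the self-organizing map stage.  :func:`generate_gene_sets` turns the
planted modules into a GMT-style collection (plus random decoy sets) so
the enrichment stage has a ground truth.

Everything is driven by a single seeded generator per call; identical
configurations give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "ModuleArchetype",
    "SimulationConfig",
    "SyntheticTruth",
    "generate_dataset",
    "generate_gene_sets",
    "DEFAULT_TISSUES",
    "DEFAULT_GROUPS",
    "DEFAULT_MODULE_CONDITIONS",
    "default_archetypes",
]

DEFAULT_TISSUES = ("SCN", "DRG", "Glom", "cortex")
DEFAULT_GROUPS = ("db/+", "db/db", "db/+ PIO", "db/db PIO")

# The six conditions over which co-expression archetypes are defined:
# control, diabetic and treated diabetic in nerve and glomeruli.
DEFAULT_MODULE_CONDITIONS = (
    ("SCN", "db/+"),
    ("SCN", "db/db"),
    ("SCN", "db/db PIO"),
    ("Glom", "db/+"),
    ("Glom", "db/db"),
    ("Glom", "db/db PIO"),
)

# Per-tissue planted fractions (of all genes carrying a disease effect,
# the share whose treatment effect is opposite / same-signed).  The nerve
# splits its shared genes roughly in half; the glomeruli reverse almost
# everything; DRG and cortex respond weakly to treatment.
DEFAULT_FRAC_REVERSED = {"SCN": 0.21, "DRG": 0.025, "Glom": 0.65, "cortex": 0.16}
DEFAULT_FRAC_EXACERBATED = {"SCN": 0.22, "DRG": 0.025, "Glom": 0.034, "cortex": 0.009}

ROLES = ("null", "reversed", "exacerbated", "disease_only", "treatment_only")


@dataclass(frozen=True)
class ModuleArchetype:
    """A planted co-expression pattern over the module conditions.

    ``profile`` is the centered shape (one entry per condition); member
    genes receive ``baseline + scale * profile`` as their condition means.
    """

    name: str
    profile: tuple[float, ...]
    n_genes: int = 50
    scale: float = 2.0


def default_archetypes() -> tuple[ModuleArchetype, ...]:
    """Three well-separated unit-norm archetypes over the six default conditions."""
    s12 = math.sqrt(12.0)
    return (
        ModuleArchetype(
            "restored_both",  # suppressed in disease, restored by treatment, both tissues
            tuple(v / s12 for v in (1, -2, 1, 1, -2, 1)),
        ),
        ModuleArchetype(
            "mirrored",  # reversed in nerve, opposite directionality in glomeruli
            tuple(v / s12 for v in (1, -2, 1, -1, 2, -1)),
        ),
        ModuleArchetype(
            "treatment_induced",  # flat through disease, induced by treatment
            tuple(v / s12 for v in (-1, -1, 2, -1, -1, 2)),
        ),
    )


def _per_tissue(value, tissues: Sequence[str], what: str) -> dict[str, float]:
    """Broadcast a scalar fraction, or validate a per-tissue mapping."""
    if isinstance(value, Mapping):
        missing = [t for t in tissues if t not in value]
        if missing:
            raise ConfigurationError(f"{what} missing tissues {missing}")
        return {t: float(value[t]) for t in tissues}
    return {t: float(value) for t in tissues}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic dataset.

    Fractions may be scalars (applied to every tissue) or per-tissue
    mappings; the defaults plant ~10% disease-responsive genes per tissue
    with a nearly-all-reversed glomerular response and an evenly split
    nerve response.
    """

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_replicates: int = 6
    n_genes: int = 8000
    frac_disease_deg: float | Mapping[str, float] = 0.10
    frac_reversed: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAC_REVERSED)
    )
    frac_exacerbated: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAC_EXACERBATED)
    )
    frac_treatment_only: float | Mapping[str, float] = 0.05
    effect_size_log2: tuple[float, float] = (2.0, 0.4)  # (mean |effect|, sd)
    min_effect_log2: float = 0.25
    # Planted DE roles go to expressed genes only (baseline log2(FPKM+1) at or
    # above this): a down-effect on a near-zero gene saturates at FPKM = 0 and
    # is unobservable by construction, which would corrupt the ground truth.
    min_de_baseline_log2: float = 3.0
    noise_sd_log2: float = 0.25
    baseline_log2_mean: float = 3.0
    module_archetypes: tuple[ModuleArchetype, ...] = field(
        default_factory=default_archetypes
    )
    module_conditions: tuple[tuple[str, str], ...] = DEFAULT_MODULE_CONDITIONS
    module_baseline_log2_range: tuple[float, float] = (4.0, 8.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.noise_sd_log2 < 0:
            raise ConfigurationError("noise_sd_log2 must be >= 0")
        if len(set(self.tissues)) != len(self.tissues):
            raise ConfigurationError("duplicate tissue labels")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("duplicate group labels")
        for name, frac in (
            ("frac_disease_deg", self.frac_disease_deg),
            ("frac_reversed", self.frac_reversed),
            ("frac_exacerbated", self.frac_exacerbated),
            ("frac_treatment_only", self.frac_treatment_only),
        ):
            for t, v in _per_tissue(frac, self.tissues, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"{name}[{t}]={v} outside [0, 1]")
        rev = _per_tissue(self.frac_reversed, self.tissues, "frac_reversed")
        exa = _per_tissue(self.frac_exacerbated, self.tissues, "frac_exacerbated")
        for t in self.tissues:
            if rev[t] + exa[t] > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"frac_reversed + frac_exacerbated > 1 for tissue {t!r}"
                )
        n_module = sum(a.n_genes for a in self.module_archetypes)
        if n_module > self.n_genes:
            raise ConfigurationError(
                f"archetypes claim {n_module} genes but n_genes={self.n_genes}"
            )
        n_cond = len(self.module_conditions)
        for a in self.module_archetypes:
            if len(a.profile) != n_cond:
                raise ConfigurationError(
                    f"archetype {a.name!r} profile length {len(a.profile)} != "
                    f"{n_cond} module conditions"
                )
        for tissue, group in self.module_conditions:
            if tissue not in self.tissues or group not in self.groups:
                raise ConfigurationError(
                    f"module condition ({tissue!r}, {group!r}) not in design"
                )

    def disease_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if "db/db" in g)

    def treatment_groups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if "PIO" in g)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated dataset.

    ``effects`` has one row per (gene, tissue) with the planted role and
    signed log2 effects; ``module_label`` maps each gene to its archetype
    name ("" for genes outside any planted module).
    """

    effects: pd.DataFrame  # columns: gene, tissue, role, disease_log2, treatment_log2
    module_label: pd.Series  # index: gene, value: archetype name or ""
    seed: int

    def validate(self) -> None:
        eff = self.effects
        d = eff["disease_log2"].to_numpy()
        t = eff["treatment_log2"].to_numpy()
        role = eff["role"].to_numpy()
        ok = (
            ((role == "null") & (d == 0) & (t == 0))
            | ((role == "reversed") & (d != 0) & (t != 0) & (np.sign(d) != np.sign(t)))
            | ((role == "exacerbated") & (d != 0) & (t != 0) & (np.sign(d) == np.sign(t)))
            | ((role == "disease_only") & (d != 0) & (t == 0))
            | ((role == "treatment_only") & (d == 0) & (t != 0))
        )
        if not ok.all():
            bad = eff[~ok].iloc[0]
            raise ConfigurationError(
                f"inconsistent truth row: {bad['gene']}/{bad['tissue']} "
                f"role={bad['role']} d={bad['disease_log2']} t={bad['treatment_log2']}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.module_label.index)

    def genes_with_role(self, tissue: str, role: str) -> list[str]:
        eff = self.effects
        sel = eff[(eff["tissue"] == tissue) & (eff["role"] == role)]
        return list(sel["gene"])

    def role_counts(self, tissue: str) -> dict[str, int]:
        eff = self.effects
        counts = eff[eff["tissue"] == tissue]["role"].value_counts().to_dict()
        return {r: int(counts.get(r, 0)) for r in ROLES}

    def planted_pct_reversed(self, tissue: str) -> float:
        """Planted percentage of shared (reversed + exacerbated) genes reversed."""
        c = self.role_counts(tissue)
        shared = c["reversed"] + c["exacerbated"]
        return 100.0 * c["reversed"] / shared if shared else float("nan")

    @property
    def module_names(self) -> list[str]:
        seen: list[str] = []
        for label in self.module_label:
            if label and label not in seen:
                seen.append(label)
        return seen

    def module_members(self, name: str) -> list[str]:
        return list(self.module_label.index[self.module_label == name])

    def to_frame(self) -> pd.DataFrame:
        """Flat per-(gene, tissue) table including the module label column."""
        out = self.effects.copy()
        out["module"] = out["gene"].map(self.module_label).fillna("")
        return out


def _group_slug(group: str) -> str:
    return group.replace("/", "").replace("+", "p").replace(" ", "_")


def generate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate an FPKM matrix plus ground truth from one seeded configuration.

    See the module docstring for the generative model.  Role counts are
    exact: genes are shuffled once per tissue and partitioned, so the
    number of reversed/exacerbated/disease-only/treatment-only genes equals
    the rounded fraction of ``n_genes``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(5, len(str(n)))
    genes = np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])

    # --- module membership (global, disjoint from per-tissue DE roles)
    order = rng.permutation(n)
    module_label = np.full(n, "", dtype=object)
    cursor = 0
    for arche in config.module_archetypes:
        idx = order[cursor : cursor + arche.n_genes]
        module_label[idx] = arche.name
        cursor += arche.n_genes

    # --- baselines on the log2(FPKM + 1) scale
    baseline = rng.exponential(scale=config.baseline_log2_mean, size=n)
    lo, hi = config.module_baseline_log2_range
    is_module = module_label != ""
    baseline[is_module] = rng.uniform(lo, hi, size=int(is_module.sum()))

    # genes eligible for DE roles: outside modules and expressed
    free = np.flatnonzero(~is_module & (baseline >= config.min_de_baseline_log2))

    frac_deg = _per_tissue(config.frac_disease_deg, config.tissues, "frac_disease_deg")
    frac_rev = _per_tissue(config.frac_reversed, config.tissues, "frac_reversed")
    frac_exa = _per_tissue(config.frac_exacerbated, config.tissues, "frac_exacerbated")
    frac_tonly = _per_tissue(
        config.frac_treatment_only, config.tissues, "frac_treatment_only"
    )
    mean_eff, sd_eff = config.effect_size_log2

    def draw_signed_effects(k: int) -> np.ndarray:
        mags = np.abs(rng.normal(mean_eff, sd_eff, size=k))
        mags = np.maximum(mags, config.min_effect_log2)
        signs = rng.choice([-1.0, 1.0], size=k)
        return signs * mags

    disease_eff: dict[str, np.ndarray] = {}
    treatment_eff: dict[str, np.ndarray] = {}
    roles: dict[str, np.ndarray] = {}
    for tissue in config.tissues:
        d = np.zeros(n)
        t = np.zeros(n)
        role = np.full(n, "null", dtype=object)
        shuffled = rng.permutation(free)
        n_deg = int(round(frac_deg[tissue] * n))
        n_rev = int(round(frac_rev[tissue] * n_deg))
        n_exa = int(round(frac_exa[tissue] * n_deg))
        n_tonly = int(round(frac_tonly[tissue] * n))
        if n_deg + n_tonly > len(shuffled):
            raise ConfigurationError(
                f"tissue {tissue!r}: planted fractions claim {n_deg + n_tonly} genes "
                f"but only {len(shuffled)} expressed genes are outside planted modules"
            )
        i_rev = shuffled[:n_rev]
        i_exa = shuffled[n_rev : n_rev + n_exa]
        i_donly = shuffled[n_rev + n_exa : n_deg]
        i_tonly = shuffled[n_deg : n_deg + n_tonly]

        d[i_rev] = draw_signed_effects(len(i_rev))
        t[i_rev] = -d[i_rev]  # exact return to baseline under treatment
        d[i_exa] = draw_signed_effects(len(i_exa))
        t[i_exa] = np.sign(d[i_exa]) * np.abs(draw_signed_effects(len(i_exa)))
        d[i_donly] = draw_signed_effects(len(i_donly))
        t[i_tonly] = draw_signed_effects(len(i_tonly))
        role[i_rev] = "reversed"
        role[i_exa] = "exacerbated"
        role[i_donly] = "disease_only"
        role[i_tonly] = "treatment_only"
        disease_eff[tissue] = d
        treatment_eff[tissue] = t
        roles[tissue] = role

    # --- condition means on the log2 scale
    disease_groups = set(config.disease_groups())
    treatment_groups = set(config.treatment_groups())
    means: dict[tuple[str, str], np.ndarray] = {}
    for tissue in config.tissues:
        for group in config.groups:
            m = baseline.copy()
            if group in disease_groups:
                m = m + disease_eff[tissue]
            if group in treatment_groups:
                m = m + treatment_eff[tissue]
            means[(tissue, group)] = m
    for j, cond in enumerate(config.module_conditions):
        m = means[cond]
        for arche in config.module_archetypes:
            idx = np.flatnonzero(module_label == arche.name)
            m[idx] = baseline[idx] + arche.scale * arche.profile[j]

    # Module genes realize disease/treatment contrasts through their archetype
    # profile; record the implied per-tissue effects and roles in the truth so
    # downstream recovery is measured against what was actually planted.
    for arche in config.module_archetypes:
        idx = np.flatnonzero(module_label == arche.name)
        profile_by: dict[str, dict[str, list[float]]] = {}
        for j, (tissue, group) in enumerate(config.module_conditions):
            is_dis = group in disease_groups
            is_tr = group in treatment_groups
            kind = "treated" if (is_dis and is_tr) else "disease" if is_dis else (
                "control" if not is_tr else "control_treated"
            )
            profile_by.setdefault(tissue, {}).setdefault(kind, []).append(
                arche.profile[j]
            )
        for tissue, kinds in profile_by.items():
            ctrl = np.mean(kinds["control"]) if "control" in kinds else None
            dis = np.mean(kinds["disease"]) if "disease" in kinds else None
            treat = np.mean(kinds["treated"]) if "treated" in kinds else None
            d_eff = arche.scale * (dis - ctrl) if ctrl is not None and dis is not None else 0.0
            t_eff = arche.scale * (treat - dis) if treat is not None and dis is not None else 0.0
            disease_eff[tissue][idx] = d_eff
            treatment_eff[tissue][idx] = t_eff
            if d_eff != 0 and t_eff != 0:
                roles[tissue][idx] = (
                    "reversed" if np.sign(d_eff) != np.sign(t_eff) else "exacerbated"
                )
            elif d_eff != 0:
                roles[tissue][idx] = "disease_only"
            elif t_eff != 0:
                roles[tissue][idx] = "treatment_only"

    # --- replicates: log-normal noise, back-transform, truncate at zero
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str]] = []
    for tissue in config.tissues:
        for group in config.groups:
            noise = rng.normal(0.0, config.noise_sd_log2, size=(n, config.n_replicates))
            log_vals = means[(tissue, group)][:, None] + noise
            fpkm = np.maximum(np.exp2(log_vals) - 1.0, 0.0)
            slug = _group_slug(group)
            for r in range(config.n_replicates):
                sid = f"{tissue}_{slug}_{r + 1}"
                columns[sid] = fpkm[:, r]
                meta_rows.append((sid, tissue, group))

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "tissue", "group"]
    ).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, metadata=metadata)

    eff_frames = []
    for tissue in config.tissues:
        eff_frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "tissue": tissue,
                    "role": roles[tissue],
                    "disease_log2": disease_eff[tissue],
                    "treatment_log2": treatment_eff[tissue],
                }
            )
        )
    truth = SyntheticTruth(
        effects=pd.concat(eff_frames, ignore_index=True),
        module_label=pd.Series(module_label, index=pd.Index(genes, name="gene"), name="module"),
        seed=config.seed,
    )
    truth.validate()
    return matrix, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    n_decoy_sets: int = 20,
    set_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """One gene set per planted module plus uniform random decoy sets.

    Module sets contain exactly the archetype's member genes; decoys are
    drawn uniformly without replacement from all simulated genes, so they
    carry no planted signal and calibrate the enrichment null.
    """
    modules = truth.module_names
    if not modules:
        raise ConfigurationError("truth contains no planted modules")
    genes = np.array(truth.genes)
    if set_size > len(genes):
        raise ConfigurationError(
            f"set_size={set_size} exceeds the {len(genes)}-gene universe"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, GeneSet] = {}
    for name in modules:
        members = frozenset(truth.module_members(name))
        sets[name] = GeneSet(name=name, description="planted module", members=members)
    for i in range(1, n_decoy_sets + 1):
        name = f"decoy_{i:03d}"
        members = frozenset(rng.choice(genes, size=set_size, replace=False))
        sets[name] = GeneSet(name=name, description="random decoy", members=members)
    return GeneSetCollection(sets=sets)
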