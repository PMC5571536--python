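"""Batch Kohonen self-organizing map over per-gene condition profiles.

The map is a 7x7 (by default) hexagonal lattice of *modules*, each holding
a codebook vector of the same dimension as the input profiles.  Input
profiles are per-gene condition means: mean FPKM per condition, genes with
every condition mean below an expression floor removed, the survivors
transformed to log2(mean + 1) and centred to zero per gene, so only the
shape of the profile matters.

Training is the deterministic batch algorithm: each epoch assigns every
gene to its best-matching unit (BMU, Euclidean nearest codebook, ties to
the lowest module index) and then replaces every codebook vector by the
neighborhood-weighted mean of all profiles, with a Gaussian neighborhood
over hexagonal lattice distance whose radius decays linearly from
max(width, height)/2 to 0.5 across epochs.  Batch training is
order-independent and bit-reproducible given the initialization seed.

Module indices are 1..width*height in row-major order on an offset-row
("odd-r") hexagonal layout; lattice distances are exact integer hex
distances via axial coordinates.  The U-matrix is the Euclidean distance
between codebooks of every adjacent module pair, and adjacent modules can
be merged into clusters either explicitly (a hand-picked connected set)
or wherever neighboring codebooks correlate above a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, DomainError, EmptyInputError
from .io import ExpressionMatrix

__all__ = [
    "SOMInput",
    "SOMGrid",
    "ModuleAssignment",
    "Cluster",
    "preprocess_for_som",
    "train_som",
    "assign_modules",
    "compute_umatrix",
    "merge_modules",
    "merge_by_correlation",
    "hex_lattice_distances",
]


@dataclass(frozen=True)
class SOMInput:
    """Centered log2 condition profiles for the genes surviving the floor."""

    gene_ids: tuple[str, ...]
    condition_labels: tuple[str, ...]
    profiles: np.ndarray  # shape (n_genes, n_conditions)

    def __post_init__(self) -> None:
        prof = self.profiles
        if prof.ndim != 2 or prof.shape != (len(self.gene_ids), len(self.condition_labels)):
            raise ConfigurationError(
                f"profiles shape {prof.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_labels)} conditions"
            )
        if prof.size and not np.isfinite(prof).all():
            raise DomainError("profiles contain non-finite values")
        if prof.size and np.abs(prof.sum(axis=1)).max() > 1e-9:
            raise ConfigurationError("profiles must be centred (rows sum to zero)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def preprocess_for_som(
    matrix: ExpressionMatrix,
    conditions: Sequence[tuple[str, str]],
    min_fpkm: float = 3.0,
) -> SOMInput:
    """Condition means -> expression floor -> log2 -> per-gene centering.

    A gene is kept only if its *maximum* condition-mean FPKM reaches
    ``min_fpkm`` (default 3, i.e. log2 expression of at least log2 3
    somewhere); retained means are transformed to log2(mean + 1) and each
    gene's row mean is subtracted.
    """
    means = matrix.condition_means(conditions)
    keep = means.max(axis=1) >= min_fpkm
    if not bool(keep.any()):
        raise EmptyInputError(
            f"no gene has a condition mean >= {min_fpkm}; nothing to map"
        )
    kept = means[keep]
    log_means = np.log2(kept.to_numpy() + 1.0)
    centered = log_means - log_means.mean(axis=1, keepdims=True)
    return SOMInput(
        gene_ids=tuple(kept.index),
        condition_labels=tuple(means.columns),
        profiles=centered,
    )


def _axial_coords(width: int, height: int) -> np.ndarray:
    """Axial (q, r) coordinates for row-major modules on an odd-r offset layout."""
    rows, cols = np.divmod(np.arange(width * height), width)
    q = cols - (rows - (rows & 1)) // 2
    return np.stack([q, rows], axis=1)


def hex_lattice_distances(width: int, height: int) -> np.ndarray:
    """Integer hexagonal lattice distance between every pair of modules."""
    ax = _axial_coords(width, height)
    dq = ax[:, 0][:, None] - ax[:, 0][None, :]
    dr = ax[:, 1][:, None] - ax[:, 1][None, :]
    return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2


@dataclass(frozen=True)
class SOMGrid:
    """A trained map: lattice geometry plus one codebook vector per module."""

    width: int
    height: int
    condition_labels: tuple[str, ...]
    codebook: np.ndarray  # shape (width*height, n_conditions), module m -> row m-1
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codebook.shape[0] != self.width * self.height:
            raise ConfigurationError(
                f"codebook has {self.codebook.shape[0]} rows for a "
                f"{self.width}x{self.height} lattice"
            )
        if not np.isfinite(self.codebook).all():
            raise DomainError("codebook contains non-finite entries")

    @property
    def n_modules(self) -> int:
        return self.width * self.height

    @property
    def module_ids(self) -> range:
        return range(1, self.n_modules + 1)

    def lattice_distances(self) -> np.ndarray:
        return hex_lattice_distances(self.width, self.height)

    def adjacency(self) -> dict[int, frozenset[int]]:
        """Hexagonal neighbors (lattice distance exactly 1) per module."""
        dist = self.lattice_distances()
        return {
            m: frozenset(int(j) + 1 for j in np.flatnonzero(dist[m - 1] == 1))
            for m in self.module_ids
        }

    def codebook_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codebook,
            index=pd.Index(list(self.module_ids), name="module"),
            columns=list(self.condition_labels),
        )


def train_som(
    input: SOMInput,
    width: int = 7,
    height: int = 7,
    epochs: int = 50,
    seed: int = 0,
    radius_initial: float | None = None,
    radius_final: float = 0.5,
) -> SOMGrid:
    """Train a batch SOM; deterministic given the seed.

    The codebook is initialized by seeded sampling of input profiles
    (without replacement when possible).  Each epoch performs one full
    BMU assignment followed by the neighborhood-weighted batch update;
    modules with zero total neighborhood weight keep their codebook.
    """
    if input.n_genes == 0:
        raise EmptyInputError("cannot train a SOM on zero genes")
    if epochs < 1:
        raise ConfigurationError("epochs must be >= 1")
    if width < 1 or height < 1:
        raise ConfigurationError("lattice dimensions must be >= 1")
    n_modules = width * height
    if input.n_genes < n_modules:
        warnings.warn(
            f"only {input.n_genes} genes for {n_modules} modules; "
            "some modules will start from repeated profiles",
            stacklevel=2,
        )
    profiles = np.asarray(input.profiles, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.choice(
        input.n_genes, size=n_modules, replace=input.n_genes < n_modules
    )
    codebook = profiles[idx].copy()

    if radius_initial is None:
        radius_initial = max(width, height) / 2.0
    lattice_d2 = hex_lattice_distances(width, height).astype(float) ** 2

    for epoch in range(epochs):
        frac = epoch / (epochs - 1) if epochs > 1 else 0.0
        sigma = radius_initial + (radius_final - radius_initial) * frac
        sigma = max(sigma, 1e-12)
        bmu = np.argmin(cdist(profiles, codebook, "sqeuclidean"), axis=1)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, profiles)
        counts = np.bincount(bmu, minlength=n_modules).astype(float)
        weights = np.exp(-lattice_d2 / (2.0 * sigma**2))
        numer = weights @ sums
        denom = weights @ counts
        updatable = denom > 0
        codebook[updatable] = numer[updatable] / denom[updatable, None]

    meta = {
        "seed": int(seed),
        "epochs": int(epochs),
        "radius_initial": float(radius_initial),
        "radius_final": float(radius_final),
        "initialization": "seeded profile sampling",
        "n_genes": int(input.n_genes),
    }
    return SOMGrid(
        width=width,
        height=height,
        condition_labels=input.condition_labels,
        codebook=codebook,
        training_meta=meta,
    )


@dataclass(frozen=True)
class ModuleAssignment:
    """Gene -> best-matching module, plus the map's quantization error."""

    bmu: pd.Series  # index: gene id, value: 1-based module index
    distances: pd.Series  # Euclidean distance of each gene to its BMU codebook
    quantization_error: float

    def genes_in_module(self, module_id: int) -> list[str]:
        return list(self.bmu.index[self.bmu == module_id])

    def module_sizes(self) -> pd.Series:
        return self.bmu.value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.bmu.index, "module": self.bmu.to_numpy(),
             "bmu_distance": self.distances.to_numpy()}
        )


def assign_modules(grid: SOMGrid, input: SOMInput) -> ModuleAssignment:
    """Nearest-codebook assignment; ties break to the lowest module index."""
    if input.profiles.shape[1] != grid.codebook.shape[1]:
        raise ConfigurationError(
            f"input has {input.profiles.shape[1]} conditions but the grid "
            f"codebook has {grid.codebook.shape[1]}"
        )
    dists = cdist(input.profiles, grid.codebook)
    bmu0 = np.argmin(dists, axis=1)  # argmin returns the first (lowest) index
    best = dists[np.arange(len(bmu0)), bmu0]
    genes = pd.Index(input.gene_ids, name="gene")
    return ModuleAssignment(
        bmu=pd.Series(bmu0 + 1, index=genes, name="module"),
        distances=pd.Series(best, index=genes, name="bmu_distance"),
        quantization_error=float(best.mean()),
    )


def compute_umatrix(grid: SOMGrid) -> pd.DataFrame:
    """Codebook distances across every hexagonal edge of the lattice.

    One row per unordered adjacent pair (module_a < module_b); the
    distance is symmetric by construction.
    """
    lattice = grid.lattice_distances()
    rows = []
    for a in grid.module_ids:
        for b in grid.module_ids:
            if a < b and lattice[a - 1, b - 1] == 1:
                d = float(np.linalg.norm(grid.codebook[a - 1] - grid.codebook[b - 1]))
                rows.append((a, b, d))
    return pd.DataFrame(rows, columns=["module_a", "module_b", "distance"])


@dataclass(frozen=True)
class Cluster:
    """A lattice-connected set of modules and the union of their genes."""

    module_ids: frozenset[int]
    member_genes: frozenset[str]
    label: str

    def __len__(self) -> int:
        return len(self.member_genes)


def _is_connected(module_ids: frozenset[int], adjacency: dict[int, frozenset[int]]) -> bool:
    if not module_ids:
        return False
    seen = {next(iter(sorted(module_ids)))}
    frontier = list(seen)
    while frontier:
        node = frontier.pop()
        for nb in adjacency[node] & module_ids:
            if nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    return seen == set(module_ids)


def merge_modules(
    grid: SOMGrid,
    assignment: ModuleAssignment,
    module_ids: Iterable[int],
    label: str | None = None,
) -> Cluster:
    """Merge an explicit, lattice-connected set of modules into one cluster."""
    ids = frozenset(int(m) for m in module_ids)
    if not ids:
        raise ConfigurationError("module_ids is empty")
    bad = [m for m in ids if not 1 <= m <= grid.n_modules]
    if bad:
        raise ConfigurationError(f"module indices out of range: {sorted(bad)}")
    if not _is_connected(ids, grid.adjacency()):
        raise ConfigurationError(
            f"modules {sorted(ids)} are not connected on the hexagonal lattice"
        )
    genes = frozenset(
        g for m in ids for g in assignment.genes_in_module(m)
    )
    if label is None:
        label = "modules " + "+".join(str(m) for m in sorted(ids))
    return Cluster(module_ids=ids, member_genes=genes, label=label)


def _codebook_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson correlation of two codebook vectors (cosine after centering)."""
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu == 0 and nv == 0:
        return 1.0  # two flat profiles have identical shape
    if nu == 0 or nv == 0:
        return 0.0
    return float(uc @ vc / (nu * nv))


def merge_by_correlation(
    grid: SOMGrid,
    assignment: ModuleAssignment,
    threshold: float = 0.8,
) -> list[Cluster]:
    """Merge adjacent modules whose codebooks correlate at or above a threshold.

    Only modules that contain genes are merged: empty modules hold
    interpolated codebooks that sit between data regimes, and letting them
    participate would chain distinct expression patterns into one cluster.
    Returns the full partition of the lattice into clusters (connected
    components of the thresholded adjacency graph over gene-bearing
    modules), ordered and labelled by their smallest module index; unmerged
    and empty modules appear as singletons.
    """
    parent = {m: m for m in grid.module_ids}
    occupied = set(assignment.bmu.unique())

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adjacency = grid.adjacency()
    for a in grid.module_ids:
        for b in adjacency[a]:
            if a < b and a in occupied and b in occupied:
                corr = _codebook_correlation(grid.codebook[a - 1], grid.codebook[b - 1])
                if corr >= threshold:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)

    components: dict[int, set[int]] = {}
    for m in grid.module_ids:
        components.setdefault(find(m), set()).add(m)
    clusters = []
    for i, root in enumerate(sorted(components), start=1):
        ids = frozenset(components[root])
        genes = frozenset(g for m in ids for g in assignment.genes_in_module(m))
        clusters.append(
            Cluster(module_ids=ids, member_genes=genes, label=f"cluster_{i:02d}")
        )
    return clusters
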