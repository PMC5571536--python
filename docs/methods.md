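# Methods

## The analysis chain

The pipeline starts from a genes × samples FPKM matrix with each sample
labelled by tissue and experimental group, and proceeds in four stages:
pairwise differential expression within tissues, directional
classification of the disease/treatment DEG overlap, self-organizing-map
(SOM) co-expression module discovery across conditions, and gene-set
over-representation of any resulting gene list. Each stage is usable on
its own; the orchestrator wires them together under one master seed.

### Differential expression

The caller is a deliberately simple, pluggable stand-in for a full
count-model pipeline: a two-sided Welch *t*-test per gene on
log₂(FPKM + 1) replicate values. The +1 pseudocount keeps zero expression
representable on the log scale and is used consistently in both the test
and the fold change, log₂((x̄_alt + 1)/(x̄_ref + 1)). The assumptions are
therefore approximate log-normality of FPKM within groups and independent
replicates; no dispersion shrinkage, covariates or isoform structure.
Degenerate genes (zero variance in both groups) get p = 1 when the means
agree and p = 0 otherwise. Multiple testing uses the Benjamini–Hochberg
step-up, applied within each contrast (per tissue), and significance is
the strict gate q < α with α = 0.05. Genes are tested without any
expression floor — the low-expression filter belongs to the SOM stage
only, so DEG counts and SOM inputs remain independent choices.

### Reversal / exacerbation classification

With the disease contrast oriented control → diseased and the treatment
contrast diseased → treated, a gene significant in both is *reversed*
when the two fold-change signs differ and *exacerbated* when they agree.
The definition is purely directional: no magnitude-restoration criterion
is imposed, and no conjunction p-value is computed for the intersection —
the inputs are hard-thresholded sets. Percentages are always over the
shared set; genes significant in only one contrast are reported as
`disease_only` / `treatment_only` but stay out of the denominators.
Unshared, exacerbated and reversed genes partition the disease DEG set
exactly, which the pipeline asserts.

### Self-organizing map

Preprocessing computes mean FPKM per (tissue, group) condition, drops
genes whose **maximum** condition mean is below 3 FPKM (i.e. genes that
never reach log₂ 3 anywhere), transforms survivors to log₂(mean + 1) and
centres every gene's profile to zero. Only profile shape matters after
centring, so Euclidean distance is the single metric used for training,
assignment and the U-matrix. The floor rule is a single documented switch
(`min_fpkm`); "below the floor in every condition" was chosen over
per-sample readings because it removes uniformly low genes without
discarding condition-specific expression.

Training is batch Kohonen on a width × height (default 7×7) hexagonal
lattice, modules numbered 1..49 row-major on an offset-row layout with
exact integer hex distances. Each epoch assigns every gene to its nearest
codebook (ties to the lowest module index) and replaces each codebook by
the Gaussian-neighborhood-weighted mean of all profiles; the radius decays
linearly from max(width, height)/2 to 0.5 over the epochs (50 by
default). Batch updates are order-independent, and the only randomness is
the seeded sampling of input profiles for initialization, so training is
bit-reproducible. Modules receiving zero total neighborhood weight keep
their codebook. In the radius → 0 limit one epoch reduces to one Lloyd
k-means step, which the tests verify against an independent
implementation.

Because codebooks are convex combinations of centred profiles they remain
centred, so Pearson correlation between codebooks equals their cosine.
Cluster formation merges lattice-adjacent modules either explicitly (a
hand-picked connected set) or wherever two **gene-bearing** neighbors
correlate at ≥ 0.8. Empty modules are excluded from similarity merging by
design: their codebooks are interpolations between data regimes, and
letting them participate chains distinct expression patterns into one
cluster (observed directly on the three-archetype benchmark, where a
boundary codebook halfway between two patterns correlates ≈ 0.87 with
both ends). Empty and unmerged modules appear as singleton clusters.

One caveat on fit statistics: with sampled initialization the initial
codebooks are actual data points, so on *tightly pre-clustered* data the
initial quantization error can already be near the noise floor and the
final smoothed map may sit slightly above it; on spread-out data training
reliably improves on the initialization, which is what the test asserts.
The positive final radius trades a little quantization error for the
topological ordering that makes lattice adjacency meaningful.

### Over-representation

Enrichment of a gene list is the one-sided Fisher exact test: the
upper-tail hypergeometric probability P(X ≥ k) for overlap k between an
n-gene list and a K-member set inside an N-gene universe, computed via
scipy's hypergeometric survival function (log-space internally, so
p ≈ 10⁻²⁰ does not underflow). Over-representation only — depletion is
not tested, matching how pathway tools report results. The universe is
explicit and configurable: all matrix genes for DEG strata, all
floor-surviving genes for SOM clusters. BH correction is applied across
all sets tested for one list (one family per list). Sets with no members
in the universe report p = 1. The multi-list significance matrix holds
−log₁₀ p and orders both axes by average-linkage hierarchical clustering
on Euclidean distance, with inputs label-sorted first so leaf orders are
deterministic.

## The synthetic-data generator

The generator emulates a 4-tissue × 4-group × 6-replicate design: tissues
SCN, DRG, Glom, cortex; groups db/+, db/db, db/+ PIO, db/db PIO.
Expression is built on the log₂(FPKM + 1) scale: per-gene baselines drawn
from an exponential with mean 3 (right-skewed, so the SOM floor removes a
realistic fraction — roughly half at the default settings), additive
planted effects, Gaussian replicate noise (sd 0.25), and the
back-transform FPKM = 2ˣ − 1 truncated at zero. The disease effect is
added to every db/db-containing group and the treatment effect to every
PIO-containing group, so a treatment effect equal to minus the disease
effect returns the gene to baseline in db/db PIO — the reversed pattern.
Effect magnitudes are |N(2.0, 0.4)| log₂ units with a 0.25 floor, signs
random.

Per-tissue role fractions are exact by construction (deterministic
partition after a seeded shuffle). The defaults plant 10% disease DEGs
per tissue and split them so the realized shared-DEG reversal matches the
motivating biology: a glomerulus-like tissue where nearly all shared
genes reverse (frac_reversed 0.65, frac_exacerbated 0.034 of disease
DEGs → ≈95% of shared), a nerve-like tissue split roughly in half (0.21 /
0.22 → ≈49%), and weakly treatment-responsive DRG/cortex. An additional
5% of genes per tissue are treatment-only responders.

Two bookkeeping rules keep the recorded truth equal to what the data
actually contain:

- **DE roles go to expressed genes only** (baseline ≥ 3 log₂ units,
  `min_de_baseline_log2`). A −2 log₂ effect on a near-zero gene saturates
  at FPKM = 0 and is unobservable in principle; planting it would make
  the "planted" reversal percentage unrecoverable by any method (down-
  regulated exacerbated genes would silently vanish from the treatment
  contrast).
- **Module genes carry profile-implied roles.** Planted co-expression
  archetypes are fixed profiles over six conditions (db/+, db/db,
  db/db PIO in SCN and Glom by default), scaled by 2 log₂ units, on
  elevated baselines (uniform 4–8 log₂) so they survive the SOM floor.
  Those profiles realize real disease/treatment contrasts, so the truth
  derives each module gene's per-tissue effects and role from its profile
  rather than recording "null". The three default archetypes (50 genes
  each, mutually separated unit-norm shapes) are: restored in both
  tissues, restored in nerve but mirrored in glomeruli, and
  treatment-induced.

What the generator does **not** model: counts or library-size/length
biases (noise is Gaussian on log FPKM, not negative binomial), dropout,
batch effects, gene–gene correlation outside the planted modules, and
per-gene dispersion trends. Passing tests therefore demonstrate that the
pipeline's logic and statistics recover planted structure under
idealized, independent log-normal noise — not that the Welch stand-in
matches a count-model caller on real sequencing data.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with one named
  generator per call; the pipeline derives per-stage seeds from a single
  master seed via CRC32 of the stage name (kept below 2³¹).
- BH is hand-written (the step-up definition directly) and cross-checked
  against statsmodels in the tests; the SOM is hand-written end to end;
  the Welch test, hypergeometric tail and hierarchical clustering come
  from scipy.
- TSV everywhere, floats at 8 significant digits (round-trips preserve 6);
  gene identifiers are opaque case-sensitive strings; missing values are
  not representable in the matrix (encode absence as 0.0).
- Ties: BMU ties break to the lowest module index; BH ties rely on a
  stable sort; heat-map leaf orders label-sort their inputs first.
- Explicit cluster merging validates lattice connectivity by BFS and
  rejects disconnected sets.

## Problem sizes

Default simulations use 8,000 genes (the acceptance script) down to
1,500–2,000 genes in tests; calibration experiments use 200 simulated
datasets of 1,000–5,000 genes. These sizes give binomial/normal error
bars comfortably inside the asserted tolerances while keeping the whole
suite fast on a single CPU.

## Known limitations

- The DEG stage is a stand-in; absolute DEG counts on real data will
  differ from any count-model pipeline even though downstream logic only
  consumes (p, q, sign).
- Reversal is directional only; a gene overshooting baseline under
  treatment still counts as reversed.
- The SOM's module numbering and exact territories depend on the seed and
  the neighborhood schedule; only the topology-level statements (cluster
  recovery, territory separation) are stable claims.
- Enrichment p-values depend strongly on the universe choice; the
  defaults are explicit but not a substitute for a curated background on
  real data.
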