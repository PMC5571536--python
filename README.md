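# reversom

Cross-tissue transcriptome comparison for disease/treatment studies:
pairwise differential-expression contrasts on an FPKM matrix, directional
classification of treatment effects (**reversed** vs. **exacerbated**),
batch self-organizing-map (SOM) discovery of co-expression modules, and
gene-set over-representation with Benjamini–Hochberg FDR control — plus a
seeded synthetic-data generator that emulates the underlying study design
with planted ground truth for every stage.

The motivating setting is a type 2 diabetes mouse experiment: four tissues
(sciatic nerve SCN, dorsal root ganglia DRG, kidney glomeruli Glom, kidney
cortex) by four groups (db/+ control, db/db diabetic, and both under
pioglitazone, "PIO"), with ~6 replicates per cell. The scientific question
the pipeline answers is *where* a treatment pushes disease-altered genes
back toward control ("reversed") and where it pushes them further
("exacerbated") — a pattern that can differ sharply between tissues.

## Model and statistics

- **Contrast.** For tissue *t* and groups *a* → *b*, each gene is tested
  with a two-sided Welch *t*-test on log₂(FPKM + 1) replicate values; fold
  change is log₂((x̄_b + 1)/(x̄_a + 1)). Genes with BH-adjusted *q* < 0.05
  (step-up: q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j) form the signed DEG set.
- **Reversal.** For genes significant in both the disease contrast
  (control → diabetic) and the treatment contrast (diabetic → treated),
  sign(log₂FC_disease) · sign(log₂FC_treatment) = −1 ⇒ reversed,
  +1 ⇒ exacerbated. Percentages are reported over this shared set.
- **SOM.** Per-gene condition-mean profiles (genes with every condition
  mean below FPKM 3 removed; log₂(mean+1), centred per gene) are mapped
  onto a 7×7 hexagonal lattice by deterministic batch Kohonen training
  (Gaussian neighborhood over hex lattice distance, radius decaying
  linearly from max(w,h)/2 to 0.5). Adjacent modules merge into clusters
  either explicitly or where gene-bearing neighbors' codebooks correlate
  ≥ 0.8; the U-matrix gives per-edge codebook distances.
- **Enrichment.** One-sided Fisher exact test: P(X ≥ k) with
  X ~ Hypergeom(N, K, n) for a list of n genes from an N-gene universe
  against a set with K members, BH-corrected per list; −log₁₀ p matrices
  across several lists are ordered by average-linkage clustering.

## Worked example

```python
import reversom as rv

config = rv.SimulationConfig(n_genes=2000, seed=1)
matrix, truth = rv.generate_dataset(config)

disease = rv.call_degs(matrix, "Glom", "db/+", "db/db")
treatment = rv.call_degs(matrix, "Glom", "db/db", "db/db PIO")
cls = rv.classify_overlap(rv.extract_deg_set(disease), rv.extract_deg_set(treatment))
print(f"{disease.n_significant} / {treatment.n_significant} DEGs, "
      f"{len(cls.shared)} shared, {cls.pct_reversed:.1f}% reversed "
      f"(planted: {truth.planted_pct_reversed('Glom'):.1f}%)")

som_input = rv.preprocess_for_som(matrix, rv.simulate.DEFAULT_MODULE_CONDITIONS)
grid = rv.train_som(som_input, epochs=50, seed=1)
assignment = rv.assign_modules(grid, som_input)
clusters = rv.merge_by_correlation(grid, assignment, threshold=0.8)
planted = set(truth.module_members("restored_both"))
best = max(clusters, key=lambda c: len(c.member_genes & planted))
sets = rv.generate_gene_sets(truth, seed=1)
table = rv.fisher_enrichment(best.member_genes, set(som_input.gene_ids), sets)
print(table.sort_values("p_value").head(3)[["set", "k", "K", "p_value", "q_value"]])
```

prints

```
310 / 394 DEGs, 238 shared, 97.1% reversed (planted: 97.0%)
          set   k   K      p_value      q_value
restored_both  50  50 7.076535e-77 1.627603e-75
    decoy_014   4  27 5.246604e-02 6.033594e-01
    decoy_015   4  31 8.020076e-02 6.148725e-01
```

The glomerular treatment response is almost entirely a reversal of the
disease signature (97.1% estimated vs. 97.0% planted), and the SOM cluster
built from two lattice-adjacent modules recovers the planted
"suppressed-by-disease, restored-by-treatment" co-expression module
intact (all 50 members, p ≈ 10⁻⁷⁷) while random decoy sets stay at
chance.

The same chain runs from the shell:

```sh
reversom run --outdir out/ --seed 7        # full default simulated study
reversom simulate --seed 5 --outdir sim/   # just the synthetic dataset
reversom deg --matrix sim/matrix.tsv --metadata sim/metadata.tsv \
    --tissue Glom --ref 'db/+' --alt 'db/db' --out glom_disease.tsv
```

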