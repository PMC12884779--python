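# scper

Cell-type deconvolution of bulk RNA-seq against single-cell references that
come from different studies, platforms or tissues.

Bulk tumor or tissue RNA-seq measures a mixture: the expression of malignant,
immune and stromal cells summed in unknown proportions. Single-cell atlases
tell us what each cell type's transcriptome looks like — but stitching
references together across studies drags in batch and tissue effects that
swamp the biology. `scper` addresses both problems at once:

1. **Adversarial deconfounding autoencoder.** An encoder f maps each cell's
   log-normalized expression x to a 100-dimensional latent code z = f(x); a
   decoder reconstructs x from z while an adversary network tries to predict
   the nuisance label c (study, platform or tissue) from z. The joint
   objective

       min  E ||x − g(f(x))||²  −  λ · L(h(z), c)        (λ = 1)

   is optimized by alternating updates, leaving a latent space that keeps
   cell identity but not the confounder. Training also enforces
   *mixture consistency*: a convex combination of cells in linear (CP10K)
   expression space must embed at the same convex combination of their
   latent codes — the property that makes bulk samples interpretable in
   this space.
2. **Latent-space regression.** Each cell type's representation is the
   coordinate-wise median of its cells' latents (the reference panel R,
   cell types × 100). A bulk sample is normalized like the cells, embedded
   with the same encoder into T, and its composition P solved from

       T = P · R,    P ≥ 0,  Σ P = 1,

   per sample, with a gradient-boosted linear regressor (negative
   coefficients clipped to zero, remainder renormalized). A non-negative
   least-squares solver is included as an independent oracle.
3. **Phenotype association.** Estimated proportions feed mutual-information
   feature ranking (averaged over 20 estimator runs), a boosted classifier
   scored by cross-validated AUROC, and per-type Wilcoxon rank-sum
   comparisons between clinical groups.

A negative-binomial synthetic-data generator with known cell types, marker
genes, batch effects and library-size variation makes the whole chain
testable without external data, including pseudobulk simulators (random
uniform proportions, or patient-wise aggregation) that carry ground-truth
compositions.

## Worked example

```python
import scper
from scper import aae, bulksim, deconv
from scper.preprocess import PreprocessConfig

# two-batch, five-type synthetic reference (3,000 cells x 2,000 genes)
spec = scper.SyntheticSpec(cell_types={f"type{c}": 600 for c in "ABCDE"}, seed=11)
sc = scper.generate_sc(spec)

# 50 pseudobulks with random ground-truth proportions, 500 cells each
bulks = bulksim.simulate_bulk_random(sc, n_samples=50, n_total=500, seed=12)
bulk, truth = bulksim.bulks_to_matrix(bulks)

result = scper.deconvolve_dataset(
    sc, bulk,
    pre_cfg=PreprocessConfig(n_cells_subsample=3000, n_hvg=1000, seed=13),
    train_cfg=aae.TrainingConfig(hidden=(256, 128), ae_pretrain_epochs=80,
                                 adv_pretrain_epochs=20, joint_rounds=60, seed=14),
)
m = deconv.score_predictions(result.proportions.P, truth,
                             cell_types=result.proportions.cell_types)
print(f"mean per-type r = {m.mean_per_type_pearson:.3f}, mAD = {m.mad:.4f}")
```

```
mean per-type r = 0.950, mAD = 0.0667
```

Each of the 50 estimated composition vectors is non-negative and sums to 1;
the per-type Pearson r of ~0.95 says the ranking of samples by each type's
abundance is recovered almost perfectly, and a mean absolute deviation of
~0.07 means the typical proportion is off by about six percentage points.
Across generator seeds the same experiment lands at r ≈ 0.92–0.98 and
mAD ≈ 0.03–0.07.

The same stages are scriptable from the shell:

```bash
scper synth --seed 1 --out ref/                      # synthetic reference
scper simulate-bulk --sc ref/ --n 50 --out sim/      # pseudobulks + truth
scper run --config run.yaml                          # preprocess→train→embed→deconvolve
scper evaluate --pred out/proportions.tsv --truth sim/true_proportions.tsv --out metrics.tsv
scper phenotype --proportions out/proportions.tsv --labels labels.tsv --mode compare --out pheno/
```

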