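# screendep

Gene-dependency estimation from pooled shRNA (RNAi) loss-of-function screens.

Pooled RNAi screens measure, for tens of thousands of shRNA reagents across
many cancer cell lines, how strongly each reagent depletes during growth.
Turning those depletion measurements into *per-gene, per-cell-line dependency
scores* is confounded by three well-known problems:

1. **seed-sequence off-target effects** — an shRNA silences not only its
   intended transcript but every transcript complementary to its 7-nt seed;
2. **variable reagent efficacy** — shRNAs targeting the same gene achieve
   very different knockdown;
3. **screen-quality differences between cell lines** — lines with more
   efficient RNAi machinery show globally stronger depletion, so naive
   scores make common-essential genes look like selective dependencies of
   high-quality screens.

`screendep` implements a hierarchical linear model that deconvolves all
three at once and returns absolute dependency scores (0 = no effect,
−1 = median common-essential knockout effect) with per-entry uncertainties.

## The model

The observed log fold change of shRNA *i* in cell line *j*, dataset/batch
*k* is modeled as

```
D_ijk = a_jk + θ_ik + γ_jk ( q_j α_i Σ_l G_il (ḡ_l + g_lj)
                             + β_i Σ_s B_is (b̄_s + b_sj) + c_i ) + ε_ijk
```

with `ε_ijk ~ N(0, σ²_jk)` and

| term | meaning |
| --- | --- |
| `ḡ_l`, `g_lj` | across-line average and line-specific knockdown effect of gene *l* |
| `b̄_s`, `b_sj` | the same decomposition for seed sequence *s* |
| `G`, `B` | fixed binary shRNA→gene and shRNA→seed incidence maps |
| `α_i`, `β_i ∈ [0,1]` | on-/off-target efficacy of shRNA *i* |
| `q_j > 0` | per-line *screen signal* (RNAi efficiency), mean 1 |
| `γ_jk > 0`, `a_jk` | per-screen scale and offset, mean(γ) = 1 |
| `θ_ik`, `c_i` | per-(shRNA, batch) and per-shRNA offsets (reference-measurement error, unmodeled off-targets) |

Gene, seed and offset terms carry zero-mean Gaussian priors and receive a
fully factorized Gaussian posterior; the scale/efficacy/noise parameters are
point-estimated. Fitting alternates exact conditional updates (analytic
gradients with L-BFGS-B for the Gaussian block; closed-form EM-style normal
equations for efficacies, scales and noise variances; a control-gene based
update for `q_j`) and finishes with a deterministic variational-EM stage
that returns marginal posterior means and variances for every gene effect.
Released scores are the posterior means of `ḡ_l + g_lj`, anchored by one
affine map so that the median positive-control (common-essential) gene sits
at −1 and the median negative control at 0, with reliability filters on
reagent number and efficacy.

Because ground truth is unknowable in real screens, the package ships a
first-class simulator that draws screens from the generative model above,
plus recovery/calibration evaluators and the gene-averaging (GA) baseline
with SSMD-based screen-quality metrics.

## Worked example

```python
import screendep as sd

truth = sd.simulate(sd.SimConfig(seed=1))          # 40 lines x 400 genes x 5 shRNAs
fit = sd.fit_model(truth.data, truth.maps, truth.controls)
report = sd.evaluate_recovery(truth, fit)
print(report.to_frame().round(3))
print(f"calibration z-SD: {report.calibration_z_sd:.3f}")
```

prints

```
                bias   rmse  pearson_r
gene_avg       0.085  0.146      0.983
gene_total     0.086  0.268      0.931
screen_scale  -0.000  0.122      0.810
screen_signal -0.000  0.179      0.849
seed_total    -0.028  0.169      0.912
calibration z-SD: 1.105
```

`gene_total` rows compare the fitted total gene effects `ḡ_l + g_lj`
(16,000 gene × line entries) against the simulated truth: correlation 0.93
with RMSE 0.27 LFC units. The screen-signal recovery (r = 0.85 over 40
lines) is the hardest quantity at this compact scale — with a single
dataset, `q_j` and `γ_jk` are separated only through the seed/offset
channel (see `docs/methods.md`). The calibration value near 1 says the
posterior SDs are honest about the size of the actual errors. On the same
simulation the model's control-gene separation (SSMD) beats the
gene-averaging baseline in 40/40 cell lines, and the baseline's essential
gene scores correlate with the true screen signal at |r| ≈ 0.86 (the
screen-quality bias) versus |r| ≈ 0.32 for the model.

The same pipeline is available from the shell:

```bash
screendep simulate --config cfg.yaml --out data/
screendep fit --lfc data/lfc.tsv --screens data/screens.tsv \
    --gene-map data/gene_map.tsv --seed-map data/seed_map.tsv \
    --pos-controls data/pos_controls.txt --neg-controls data/neg_controls.txt \
    --out fit/
screendep qc --scores fit/gene_dependency.tsv \
    --pos-controls data/pos_controls.txt --neg-controls data/neg_controls.txt --out qc/
```

`screendep preprocess` turns raw read-count TSVs into replicate-collapsed
LFC matrices (logCPM with a library-size scaled pseudocount, plasmid
representation filter, median collapse), `screendep baseline` produces the
GA baseline, and `screendep run` drives the full simulate → fit → QC round
trip from one YAML file.

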