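# scshape

Single-cell RNA structure probing analysis: from per-cell per-base
mutation/coverage counts to SHAPE reactivities, structural-heterogeneity
statistics, structure-accuracy benchmarking, and feature/RBP enrichment —
plus a ground-truth simulator so the whole pipeline can be exercised and
validated without sequencing data.

## The problem

Chemical probes such as NAI-N3 acylate the 2′-OH of flexible (unpaired)
RNA nucleotides; during reverse transcription the adducts appear as
mutations (mutational profiling, MaP). In single cells this yields, per
cell *c* and transcript position *i*, a coverage count and a mutated-read
count in a reagent-treated channel and a mock (DMSO) control channel. The
per-base **reactivity** is

> r(i) = m_treated(i)/d_treated(i) − m_control(i)/d_control(i)

high where the base is accessible/single-stranded, low where it is paired
or protected. The package answers two questions downstream of these
counts: *how accurate are single-cell reactivities* (benchmarked against
reference secondary structures), and *does the same RNA fold differently
in different cells* (structural heterogeneity).

## The statistics at the core

**Window-level heterogeneity (adjusted R²).** The transcriptome is tiled
into 10-nt windows; a window is detected when its total coverage exceeds
600 reads and it is covered in ≥ 50 % of cells. Within a detected window
*s*, summed counts per cell follow

> mutant(c, s) = mod(s) · depth(c, s) + ε

if every cell shares one modification rate mod(s). The fit of this linear
model across cells (OLS, R² = squared Pearson correlation;
adj R² = 1 − (1 − R²)(n − 1)/(n − 2)) measures homogeneity: near 1 = one
conformation shared by all cells, near 0 = cell-to-cell variation.

**Gene-level heterogeneity (cosine dispersion).** After quantile
normalization across cells, each cell's reactivity profile R_i is compared
to the pooled (pseudobulk) profile by cosine distance
D_i = 1 − cos(R_i, R_pseudo), and the transcript's heterogeneity is the
RMS dispersion √(Σ D_i²/n).

**Benchmarking.** Unpaired bases in a reference structure are labeled
True (truly modifiable), paired bases False; accuracy is the AUC-ROC of
reactivity against these labels (rank/Mann–Whitney formulation, ½ credit
per tie), optionally restricted to bases with 2′-OH solvent accessibility
≥ 3 Å².

**Enrichment.** Windows of interest (e.g. the most heterogeneous
quartile) are tested for overlap with feature/RBP binding intervals by an
upper-tail hypergeometric test, Bonferroni-corrected, significant at
adjusted P ≤ 0.05. Expression-stratified contrasts split cells into
quartiles of a regulator's abundance and compare per-cell window
reactivities between the extreme quartiles (Welch t-test, log2 fold
change).

## Worked example

```python
import scshape as scs

# simulate 40 cells probing a transcript that mixes two conformations:
# 5 windows identical between conformations, 5 differing by 0.1
config, _ = scs.make_two_conformation_panel(
    n_windows_homogeneous=5, n_windows_heterogeneous=5,
    rate_gap=0.1, n_cells=40, mean_depth=1000, seed=0,
)
treated, control, truth = scs.simulate_counts(config)

windows = scs.tile_windows(treated, "panel_tx", config.transcripts[0].length)
scs.filter_windows(windows, total_cells=40)
for w in windows:
    rec = scs.window_heterogeneity(w)
    label = truth.window_labels[("panel_tx", w.window_start)]
    print(f"window {w.window_start:3d}-{w.window_end:<3d}  "
          f"adj R2 = {rec.adj_r_squared:.3f}  "
          f"slope = {rec.fitted_modification_rate:.4f}  truth = {label}")
```

prints

```
window   0-10   adj R2 = 0.781  slope = 0.0323  truth = homogeneous
window  10-20   adj R2 = 0.064  slope = 0.0845  truth = heterogeneous
window  20-30   adj R2 = 0.841  slope = 0.0351  truth = homogeneous
window  30-40   adj R2 = 0.058  slope = 0.0684  truth = heterogeneous
window  40-50   adj R2 = 0.730  slope = 0.0280  truth = homogeneous
window  50-60   adj R2 = 0.053  slope = 0.0769  truth = heterogeneous
window  60-70   adj R2 = -0.017  slope = 0.0294  truth = heterogeneous
window  70-80   adj R2 = 0.817  slope = 0.0348  truth = homogeneous
window  80-90   adj R2 = 0.008  slope = 0.0455  truth = heterogeneous
window  90-100  adj R2 = 0.771  slope = 0.0314  truth = homogeneous
```

Windows generated from one shared conformation score adj R² ≈ 0.7–0.85;
windows whose modification profile differs between the two mixed
conformations collapse toward 0. The fitted slope is the window's pooled
modification rate (here around the simulated 3 % base rate, higher where
one conformation adds the 0.1 rate gap).

## Command line

`scshape simulate` writes a self-contained demo dataset (counts for both
channels, reference structure, expression table, annotation, feature
intervals, ground truth and a digest manifest). `scshape run` executes
QC → reactivity → heterogeneity → enrichment → benchmark end to end;
`scshape qc`, `heterogeneity`, `benchmark`, `enrich` run single stages,
and `scshape verify` checks a dataset against its manifest.

```
scshape simulate --output-dir demo --seed 1
scshape run --config demo/config.yaml --output-dir results
```

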