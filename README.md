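# gcmab

Integrative single-cell analysis of germinal-center (GC) B cells: from
plate-based 5'-end scRNA-seq UMI counts, index-sort flow cytometry and
reconstructed B-cell-receptor (BCR) contigs to annotated GC subsets,
clonotypes, somatic-hypermutation profiles, ELISA binding thresholds of
recombinant monoclonal antibodies (mAbs), and the statistics that tie them
together. A synthetic-data generator with full ground truth makes every
stage testable without access to a sequencing run.

It is aimed at immunologists and computational biologists analyzing
antigen-specific B-cell responses where phenotype (index-sort MFI),
transcriptome (UMI counts), repertoire (paired IGH + IGK/IGL sequences) and
antibody function (ELISA) are measured on the *same* single cells.

## What it computes

- **QC & normalization** — per-cell total UMI, genes detected, %
  mitochondrial reads and ERCC spike-in quantification accuracy
  (Pearson r of log1p counts vs log10 input concentration); cells passing
  all four gates are log-normalized, `ln(1 + 10^4 · x_gc / Σ_g x_gc)`.
- **BCR consolidation** — contigs of one V(D)J rearrangement (same
  `v_call`, `j_call`, junction) are merged keeping the largest sequence;
  contigs without an in-frame constant region are discarded; the
  highest-expressed survivor per chain class gives one heavy + one light
  chain per cell.
- **Clonotypes** — heavy chains blocked by (V gene, junction length) and
  single-linkage clustered at ≥ 80 % junction nucleotide identity.
- **Somatic hypermutation** — end-free global alignment of each chain to
  its inferred germline V; substitutions split by region (CDR vs FW) and
  coding effect (silent vs non-silent), indels flagged.
- **Subset gating** — module scores (signature mean minus bin-matched
  control-gene mean) for LZ, DZ, LZtoDZ, preMem, prePC and PC signatures,
  with cell-cycle genes removed from LZ/DZ before scoring; sequential
  empirical gates assign one label per cell; S/G2M module scores give the
  cell-cycle phase.
- **Index sorting** — `asinh(MFI / 100)` transform; a cell is
  antigen-positive when the transformed OVA-AF647 signal exceeds 1.
- **ELISA Binding Threshold** — the minimum antibody amount (ng) at which
  mean OD of a 4-fold dilution series reaches the detection threshold
  (mean + 3 sd of no-primary-antibody controls, or a fixed override),
  interpolated between dilution points on log-log scale and censored as
  `">1000"` when never detectable.
- **Integration** — Kruskal–Wallis with tie-corrected, Bonferroni-adjusted
  Dunn post hoc; the semi-log least-squares fit
  `asinh binding = a + b·log10(threshold)` with R²; clonotype selection
  (size ≥ 5, ≥ 1 member above background); and the FACS-vs-ELISA outlier
  rule (no surface binding yet threshold strictly inside 10–100 ng).

## Worked example: the bundled mAb panel

The package ships the published panel of 37 recombinant mAbs (32 derived
from single GC B cells of clonotypes c179, c248, c127, c87 and c184 after
ovalbumin immunization, plus 5 germline revertants):

```python
from gcmab.panel import load_cell_mabs
from gcmab.stats import semilog_fit, detect_outliers

panel = load_cell_mabs()
fit = semilog_fit(panel["threshold_ng"], panel["asinh_OVA-AF647"],
                  panel["censored"], censor_policy="cap")
print(f"R^2 = {fit['r_squared']:.4f}  slope = {fit['slope']:.3f}  n = {fit['n']}")
out = detect_outliers(panel)
print(len(out), "outliers,", (out["clonotype_id"] == "c184").sum(), "from c184")
```

prints

```
R^2 = 0.4659  slope = -0.421  n = 32
5 outliers, 3 from c184
```

i.e. surface antigen binding falls by ~0.4 asinh units per 10-fold increase
in the ELISA Binding Threshold, log-threshold explains ~47 % of the binding
variance, and five cells (three of clonotype c184) produce well-binding
mAbs despite undetectable surface binding — the FACS assay misses them.

## Synthetic pipeline from the command line

```bash
gcmab --outdir out --seed 1 run      # simulate -> qc -> ... -> integrate
gcmab --outdir out --seed 1 report
```

prints, for the default simulated cohort (747 cells, seed 1):

```
mutations_by_sample: Kruskal-Wallis H=253.305 p=1.26e-54
binding_by_subset: Kruskal-Wallis H=4.520 p=0.477
semilog fit (cap): R^2=0.4867 slope=-0.385 n=31
semilog fit (exclude): R^2=0.3995 slope=-0.338 n=23
selected clonotypes: c1, c11, c13, ...
outlier cells: 0
```

The mutation load rises sharply across immunization time points (planted
by the generator), and the simulated mAbs reproduce a semi-log
binding–threshold relation of the same strength as the real panel.

## Layout

| module | contents |
| --- | --- |
| `gcmab.simulate` | synthetic dataset generator + ground truth |
| `gcmab.qc` | QC metrics, filtering, log-normalization |
| `gcmab.repertoire` | contig consolidation, clonotypes, mutation counting |
| `gcmab.germline` | bundled synthetic germline V references |
| `gcmab.annotate` | module scores, subset gating, cell-cycle phase |
| `gcmab.cytometry` | asinh transform, index-sort attachment |
| `gcmab.elisa` | dilution series, binding-threshold statistic |
| `gcmab.stats` | integrated table, Kruskal–Wallis/Dunn, semi-log fit, outliers |
| `gcmab.panel` | bundled published mAb panel |
| `gcmab.io`, `gcmab.pipeline`, `gcmab.cli` | formats, stage driver, CLI |

See `docs/methods.md` for the modeling assumptions and numerical choices.
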