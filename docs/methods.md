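# Methods

This note records the models, parameter choices and numerical conventions
behind `gcmab`, and what the synthetic-data tests do and do not establish
about real data.

## Quality control and normalization

Four per-cell criteria gate cells into the analysis: total UMI count
(endogenous genes only), number of genes detected, percentage of
mitochondrial transcripts, and ERCC spike-in quantification accuracy —
the Pearson correlation of `log1p(observed spike-in count)` against
`log10(input concentration)` across spike-in species with positive input.
Accuracy is undefined (and the cell fails) when fewer than 3 species are
detected. The default cut-offs (`min_total_umi=2000`, `min_genes=500`,
`max_pct_mito=20`, `min_ercc_accuracy=0.8`) are typical for plate-based
scRNA-seq with spike-ins; they are configuration, not constants, and
should be tuned per dataset. Mitochondrial genes default to the mouse
`mt-` prefix.

Normalization is `ln(1 + s · x_gc / Σ_g x_gc)` with scale factor
`s = 10,000`, natural log, ERCC rows excluded from totals and output.
Cells with zero totals must be removed by QC first; the normalizer refuses
them.

## BCR consolidation, clonotypes, mutation counting

Reconstructed contigs are reduced to one heavy and one light chain per
cell in three ordered steps: (1) contigs with identical
(`locus`, `v_call`, `j_call`, `junction`) are treated as one rearrangement
and merged keeping the largest sequence; (2) contigs lacking an in-frame
constant region are discarded (the annotator's flag when present, else the
`productive` flag, else permissive); (3) per chain class (IGH; IGK and IGL
jointly) the highest-expressed survivor is kept. Ties break
deterministically by length, expression, then sequence id.

Clonotypes use heavy-chain evidence only: cells are blocked by
(V gene, junction nucleotide length) and single-linkage clustered, linking
pairs with junction identity ≥ 0.8 (configurable). Identity is the
fraction of matching positions between the equal-length junctions. Ids
`c1..cN` are assigned by decreasing size then smallest member id, so the
partition and its naming are independent of input order. Light-chain-aware
clonotyping and lineage trees are out of scope.

Mutations are counted against the inferred germline V (allele lookup, with
a documented `*01` default when the allele suffix is missing) by global
alignment with free end gaps: match +1, mismatch −1, gap open −4, gap
extend −1. Each aligned substitution is attributed to the CDR or FW region
of its germline position (region maps are 0-based half-open and supply the
reading-frame offset) and classified silent/non-silent by translating the
germline codon against the codon with that single substitution applied.
Indels set a flag but are never counted as mutations — reported counts are
substitution counts, and V-region only (the junction is not included).
Alignments covering < 80 % of the germline are rejected as
sequence/germline mismatches.

## Signature scoring and gating

A module score is the mean normalized expression of the signature genes
minus the mean of control genes drawn from the same average-expression
bins: all genes are ranked by mean expression across cells, cut into
`n_bins = 24` equal-size bins, and `n_ctrl = 100` controls per signature
gene are sampled (seeded, excluding signature genes; with replacement,
with a warning, when a bin is smaller than `n_ctrl`). Scores are therefore
location-free: adding a constant to the whole matrix changes nothing.

The bundled signatures are the top-5 marker genes of each GC state (LZ,
DZ, LZtoDZ, preMem, prePC, PC) in murine OVA-responding lymph nodes; the
full signature lists of the original annotation live in a companion
resource, so the bundled lists are a faithful stand-in, not a
reproduction. Because proliferation is entangled with DZ identity,
cell-cycle genes (an input list; the default covers the bundled S/G2M
genes plus the cycling DZ markers Ccnb2 and Stmn1) are removed from LZ and
DZ signatures before scoring.

Gating is sequential with empirical thresholds (default 0, the natural
signal-above-control boundary): PC, then prePC, then preMem on their own
scores; then LZtoDZ where both LZ and DZ scores exceed their thresholds;
remaining cells go to whichever of LZ/DZ scores higher, exact ties
`unassigned`. Cell-cycle phase is the argmax of the S and G2M module
scores when either is positive, else G1/quiescent.

## Index sorting

Compensated fluorescence is transformed as `asinh(value / cofactor)` with
cofactor 100 (per-channel overridable); the transform is odd and strictly
increasing, so compensated negatives are handled and MFI rank order is
preserved. A cell counts as antigen-positive (above background) when the
transformed OVA-AF647 value exceeds 1; the cutoff is configuration.
Attachment of (plate, well)-keyed values to cells is lossless and reports
unmapped wells; 96-well geometry (A1–H12) is enforced at parse time.

## ELISA Binding Threshold

Each mAb is titrated in a geometric dilution series (default 4-fold from
1000 ng) with replicate wells; the curve is the per-amount mean OD.  The
detection threshold defaults to mean + 3 sd of the no-primary-antibody
negative controls, with a fixed override for assays where the threshold
line is set by eye. Scanning amounts upward, the Binding Threshold is the
smallest amount whose mean OD reaches the detection threshold, refined by
interpolation in (log10 amount, log10 OD) between the bracketing
dilutions. Log-log interpolation is used because below saturation the OD
of a binding curve is proportional to amount, making the interpolated
crossing essentially exact there (measured ≤ 0.7 % deviation from the
analytic crossing of saturation curves across four orders of magnitude of
K), whereas OD-linear interpolation on the log-amount axis is biased low
by 15–20 % on a 4-fold grid; the fallback is OD-linear when the lower
bracket OD is 0. Results censor as `">max"` when even the largest amount
stays below threshold and `"<min"` when the smallest amount is already
above; censored values serialize both as display strings and as
(bound, flag) pairs. Non-monotone curves use the crossing at the lowest
amount, with a warning. 4PL/EC50 fitting is deliberately out of scope —
the threshold statistic is the endpoint.

## Integrated statistics

Group comparisons use Kruskal–Wallis (tie-corrected, via scipy) with
Dunn's post hoc: z-statistics on pooled mean ranks with the tie correction
`Σ(t³−t)/(12(N−1))`, two-sided normal p-values, Bonferroni-adjusted over
all pairs by default (Holm and unadjusted available). Pairwise results are
only reported together with the omnibus p. The degenerate all-identical
case returns H = 0, p = 1.

The binding–threshold relation is a least-squares fit of
`y = a + b·log10(x)` (the closed-form optimum of the semi-log model, hence
identical to an iterative fit of the same model), with
R² = 1 − SSres/SStot = squared Pearson r(y, log10 x). Censored `">1000"`
thresholds are handled by two first-class policies: `cap` (keep at the
bound) and `exclude` (drop); on the bundled 32-mAb panel the cap policy
reproduces the published R² (0.4659 computed vs 0.4638 printed) while
exclusion gives 0.347, so cap is the documented default and both are
reported side by side by the pipeline. Germline constructs have no
index-sort value and never enter the fit.

Clonotype selection takes clonotypes of size ≥ 5 with ≥ 1 member above
background, optionally subsampled with a seed; the outlier rule returns
cells with transformed binding < 1 whose mAb threshold is uncensored and
strictly inside (10, 100) ng.

## Synthetic-data generator

The generator emulates the full study design with known ground truth. Its
defaults are the study conditions where those are stated: subset sizes
LZ 331 / DZ 300 / LZtoDZ 55 / preMem 29 / prePC 27 / PC 5 (747 cells),
sample proportions d10p:d20p:d10s:d20s = 145:205:295:124 with per-sample
mutation-load multipliers rising from primary to secondary response,
4-fold ELISA dilutions from 1000 ng in duplicate, 92 spike-in species, 13
mitochondrial genes, asinh cofactor 100. Everything is drawn from one
seeded generator; identical configs give byte-identical bundles.

Choices where the design was open:

- **Counts.** Negative binomial per gene (gamma–Poisson, dispersion 2)
  with lognormal(ln 3, 1) baseline means over ~950 background genes,
  ~4.5 % mitochondrial fraction, 10 % per-gene dropout; spike-ins are
  Poisson (technical noise only, no dropout) on a 6-level 2-fold
  concentration ladder. Marker genes are modeled as subset-exclusive:
  mean `marker_fold` (default 8) in their elevating subsets and 0
  elsewhere, with LZtoDZ cells also expressing LZ and DZ markers and
  preMem cells LZ markers, mirroring the described biology. This on/off
  idealization is what makes noise-free recovery exact; real markers are
  graded, so passing round-trip tests demonstrates correctness of the
  gating logic, not expected accuracy on real data.
- **Repertoire.** Each clonotype owns a heavy/light germline allele pair
  from the bundled synthetic reference set (294-nt in-frame V segments,
  IMGT-style `-sim` names, shared CDR/FW layout) and a founder junction;
  members carry ≤ 5 % junction substitutions while distinct clones in the
  same (V gene, length) block are rejection-sampled below 70 % identity,
  so the planted partition is unambiguous at the 80 % linkage threshold.
  Per-cell mutation counts are Poisson(shm_rate × sample multiplier),
  planted in distinct codons so per-substitution silent flags are
  well-defined. Decoy contigs (truncated duplicates, constant-region-less
  contigs, lower-expressed competing rearrangements) exercise each
  consolidation step; exactly one true contig per chain is recorded.
- **Affinity and assays.** log10 affinity = −0.35 + 0.33 × (non-silent
  CDR substitutions, both chains) + N(0, 0.2), with a 35 % background of
  non-binders at affinity 10⁻³. MFI = 50 × affinity × lognormal(0, 0.4)
  + autofluorescence 5, giving the observed asinh-scale separation around
  1. ELISA curves are OD(a) = od_max·a/(a+K), K = 50/affinity, od_max 3,
  replicate noise sd 0.05, 8 dilutions — germline and background
  constructs then censor at ">1000" as in the published panel.
- **QC violators.** 10 % of cells violate one criterion each (total UMI
  × 0.08; only a quarter of background genes expressed; mitochondrial
  means × 15; spike-in means permuted), with margins that keep clean and
  violating cells many standard deviations from the default thresholds.
- **Noise-free mode** (`SimConfig.noise_free()`) zeroes dropout, count
  noise (counts become rounded expectations), FACS/ELISA noise and
  affinity scatter while keeping all planted structure; it is the regime
  where every stage must recover ground truth exactly and is what the
  end-to-end acceptance tests run.

Not modeled: read-level data, sequencing errors, doublets, graded marker
expression, subset-dependent antigen affinity, batch effects.

## Problem sizes in the test suite

The end-to-end round trip runs the full 747-cell cohort in noise-free
mode; the brute-force clonotype oracle uses 50 cells; mutation-counter
bookkeeping covers 1000 random chains over all bundled alleles;
Kruskal–Wallis is checked against a 10,000-permutation oracle on 3 × 8
values; ELISA interpolation against a 2000-point grid search. These sizes
keep the whole suite around ten seconds on one CPU while leaving the
statistical checks well-powered.
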