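# Methods

## Scope and data model

The package operates on a complete probe-set × condition matrix of linear
hybridization signals (RMA-style output; background around 9, ceiling
around 33,500) with per-condition metadata: organ, treatment, optional
timepoint (dpi for the nodulation kinetics, dap for seed development,
hours for short treatments) and a sample class separating whole organs
from hand-dissected nodule zones (I, II, II–III, III, IV) and LCM cell
types (M, dIZ, pIZ, IC, UC). Normalization is upstream of the package:
inputs are assumed normalized and no log transform is applied at I/O
time. Missing cells are a hard error — the compendia this targets are
complete exports — and NaN appears only in derived outputs (undefined
entropy, undefined ratios), serialized as `NA`. Reals are written with 12
significant digits and a `.` decimal separator.

## Entropy-based tissue specificity

Conditions are pooled into `N ≥ 2` tissue classes by arithmetic mean; the
reference panel pools 19 experiments into 10 tissues (nodule = the
4/10/14/28 dpi stages; seed = six dap stages; root = the nodulation 0 dpi
control plus one independent experiment; seven single-experiment
tissues). Per gene, relative expression is `P_t = W_t / Σ W_t` and the
Shannon entropy is `E = −Σ P_t log2 P_t` with the standard convention
`0·log2(0) = 0`. Properties the test suite enforces: `0 ≤ E ≤ log2(N)`,
zero exactly for single-tissue genes, invariance to tissue permutation
and to positive rescaling of a gene's row.

Choices where the procedure was genuinely open:

* **All-zero genes** carry no specificity information and are excluded
  from the ranking rather than assigned maximal entropy.
* **Ties** in entropy break lexicographically on gene id, so ranks and
  top-`k` selections are bit-reproducible.
* **No background subtraction** is applied before entropy (a configurable
  floor could be added by callers at aggregation time); entropy is
  computed on the compendium values directly.
* **Root pooling**: the two root experiments are averaged into one tissue
  before normalization (pooling first, then normalizing).
* The default selection size is a fraction (20%) of the ranked genes
  rather than an absolute count, so synthetic compendia of any size
  exercise the same selection pressure as a fixed-count cut on a
  50,900-probe-set atlas.

Alternative specificity indices (tau, TSI, gini) are deliberately not
implemented; entropy is the package's single specificity currency.

## Temporal waves

The inoculation time course is taken from whole-organ, untreated
conditions with dpi timepoints — nodules from 4 dpi on, plus the 0/3 dpi
samples, which are root material (uninoculated control and primordia
still embedded in the root). Replicates are averaged per dpi before any
ratio. A gene is *activated* at dpi `d` when its signal is at least
`activation_fraction` (default 0.5) of its 14 dpi reference level **and**
above an absolute floor of `floor_factor × background` (default 5 × 9).
The first activating dpi maps to the wave: 4 → wave 1, 6 → wave 2,
10 or 14 → wave 3; never → unassigned. The wave count is fixed at three
by this rule — a testable rule rather than a clustering outcome. A gene
is *declining* when its latest-stage signal (28 dpi by default) is below
`decline_fraction` (default 0.5) of its temporal maximum. Increasing
`activation_fraction` can only move genes to later waves (a monotonicity
property under test). The activation rule applied to broadly expressed
housekeeping-like genes labels them wave 1 (they trivially track their
own reference level); wave assignment is therefore meaningful for, and
reported over, the nodule-induced family.

Timepoint correlation matrices are Pearson correlations between
replicate-averaged expression vectors over a gene subset, with
zero-variance vectors yielding NA pairs.

## Zone profiles and clustering

Each of the five zone classes is replicate-averaged; a gene's profile is
`log2(zone / mean over the five zones)`, undefined when the five-zone
mean is zero. The back-transform `mean_zones(2^profile) = 1` holds
exactly and is asserted as an invariant.

Clustering is agglomerative average linkage (UPGMA), implemented
in-package because the analysis contract pins behaviour generic libraries
leave open: equal-distance merge candidates resolve to the pair whose
smallest original row index is lowest (then the smaller partner), and
leaf order places the subtree containing the smaller minimum index on the
left. Distances are Euclidean or correlation distance `1 − r` — signed,
not `1 − |r|`, because co-activation of expression profiles is
directional; zero-variance rows are rejected under the correlation
metric. Merge heights are validated against two independent routes: an
exhaustive brute-force average-linkage recomputation from the original
pairwise matrix, and `scipy.cluster.hierarchy.linkage`. Distance matrices
are symmetrized before agglomeration (`corrcoef` is asymmetric at 1 ulp).
Dendrograms export to Newick with height differences as branch lengths.
Heat-map export offers `none`, `row_max` (rows scaled to their maximum;
zero rows flagged and zeroed) and `log2_ratio` (identical to the zone
transform) scalings; rendering itself is cosmetic and out of scope.

## Screens

All screens are Welch (unequal-variance) two-sample t-tests on linear
signals over replicate conditions, with fold changes computed on group
means (not means of per-replicate ratios). Flagging uses an uncorrected
p < 0.05 in the stated direction, replicating compendium-era practice;
directional claims ("higher in the uninfected cells", "higher in zone
IV") use one-sided alternatives. Because family-wide screens at a raw
alpha are anticonservative, an optional Benjamini–Hochberg mode reports
adjusted q-values alongside (flags remain raw-alpha; off by default).
Degenerate zero-variance-in-both-groups cases take p = 1 when the means
are equal, p = 0 otherwise. Welch at n = 3 per group is conservative on
log-normal noise: its true two-sided size is ≈0.034 at nominal 0.05
(measured by direct simulation), which the negative-control test band
[0.02, 0.055] reflects.

The senescence screen reports per-gene treated/control ratios and, per
family, the fractions of genes below and above unity (genes with zero
control signal excluded). Expression strength is summarized by per-gene
maxima over all conditions: cohort mean, median, and fractions above
5,000 / 10,000 / 15,000.

## Quality control

*Relaxed specificity*: the cohort background is the median signal of all
non-family genes over non-nodule conditions — an aggregate expression
floor, robust to the minority of highly expressed genes. A family gene is
relaxed when at least one non-nodule condition (contamination-flagged
conditions excluded — such columns carry genuine nodule signal) exceeds
`max(floor_factor × background, ratio_cut × own nodule maximum)`, with
defaults `floor_factor = 5` and `ratio_cut = 0.01`; the ratio cut captures
expression down to 100-fold below a gene's nodule level.

*Contamination*: for every non-nodule condition the bacterial-marker set
is summarized by its log2 mean (the geometric mean — the natural scale
for multiplicative hybridization noise; the arithmetic mean is
right-skewed enough to false-flag at robust thresholds). A condition is
flagged when its log2 marker mean exceeds the median plus
`z_cut × 1.4826 × MAD` of the log2 means over the non-nodule conditions;
the 1.4826 factor makes the MAD a consistent normal-scale estimate, so
`z_cut` (default 5) reads as a robust z-score. A planted 20% admixture of
a nodule column sits ≈65 robust standard deviations above background.

## The synthetic compendium

The generator emulates the statistical anatomy of the real compendium at
a desk scale chosen so the full pipeline and the multi-seed property
tests run in seconds: 500 genes × 84 conditions by default (the original
is 50,900 × 267), with 60 strictly nodule-specific family genes, 5
relaxed members, 8 senescence markers, 10 bacterial markers, and 3
replicates per contrast (replicate counts are not published for the
original; 3 is the usual microarray design).

Signal model, per gene and condition, on the linear scale:

* **Baselines** (probe affinity): log-normal around 9, log-sd 0.8 for
  plant probes; bacterial markers use log-sd 0.3 since cross-hybridization
  of bacterial probes on a plant chip is uniformly low.
* **Noise**: mean-preserving multiplicative log-normal noise, CV 0.2 per
  cell — microarray-like heteroscedasticity (variance grows with signal).
* **Family genes**: background everywhere outside nodules; in the time
  course, logistic activation in dpi with wave midpoints 3.5 / 5.5 / 9.0
  and scales 0.2 / 0.6 / 0.8, clamped to zero at ≤ 3 dpi (primordia are
  not yet transcriptionally active). Midpoints sit half a step before
  each wave's nominal activation day (4 / 6 / 10 dpi) so that a wave's
  genes are clearly past the 50%-of-14-dpi activation rule *at* that day
  rather than straddling it. Peaks are log-uniform over 5,000–33,500.
  A configurable fraction (30%) of wave-1/2 genes decline to 25% of peak
  at 28 dpi. Zone and LCM weights encode the wave-to-space
  correspondence (wave 1 apical, wave 3 proximal; meristem and uninfected
  cells near-silent), and every wave's zone IV weight is well below its
  zone III weight — the generator plants no senescence-upregulated family
  gene.
* **Relaxed genes**: family-like plus root/stem expression at 25–50% of
  their nodule peak. The two uninfected-cell-biased genes (planted UC/IC
  mean folds 9.6 and 3.2, pinned exactly at the mean level) double as
  relaxed genes with modest peaks (1,500–3,500) and near-parity root
  levels, mirroring genes expressed "to similar levels" in roots and
  nodules; a 9.6-fold UC excess on a ceiling-level peak would leave the
  array's dynamic range.
* **Markers**: senescence markers are zone-IV-biased and rise 5-fold
  under nitrate induction while family genes drop to 20% of their induced
  component; bacterial markers track infection (logistic in dpi, zone and
  cell-type weighted) and are absent from all non-nodule material.
* **Ordinary genes**: a broad cohort (log-normal levels, mild per-organ
  modulation) plus a 6% minority with single-organ specific expression
  outside nodules and a 2% basal leak in other organs — real
  tissue-specific genes are rarely absolutely silenced elsewhere, which
  is exactly what makes the hard nodule exclusivity of the family
  cohort stand out in the entropy ranking.
* **Contamination**: one mycorrhiza column is replaced by
  `0.8 × itself + 0.2 × a 14 dpi nodule column`.

Everything is a deterministic function of the seed; identical configs and
seeds give bit-identical matrices.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: probe-level effects and
cross-hybridization between family members, array batch effects,
genotype mixtures, RNA-amplification bias in LCM samples, and the
long-tailed condition diversity (biotic/abiotic stress series) of the
real compendium. Recovery rates on synthetic data measure the internal
consistency of the pipeline's rules against a known truth, not the
accuracy of the original biological conclusions.

Correlation structure under the noise model: two replicate-averaged
vectors of the same expression state cannot correlate above
`1/(1 + CV_e²) ≈ 0.987` (CV_e = 0.2/√3 ≈ 0.115), and the family peak
spread puts the 10-vs-14 dpi correlation near 0.94; the tests therefore
assert the block structure (adjacent stages > 0.95 / > 0.90, early-vs-
mature < 0.5) rather than a literal "≈ 1".

## Pipeline and reproducibility

`run_pipeline` executes QC → entropy → waves → zones → screens on either
a synthetic or a loaded compendium, writes every stage's TSV, and emits a
JSON summary (schema_version 1) that is a pure function of configuration
and seed — reruns are byte-identical. Thresholds actually used are echoed
into the summary; the resolved tissue map and group assignments are
logged. Exit codes at the CLI: 0 ok, 1 validation error, 2 runtime
failure.

## Known limitations

* Entropy depends on the tissue-map granularity; `E` values are only
  comparable within one panel (the `log2(N)` ceiling moves with `N`).
* The wave rule is threshold-based; genes hovering at the activation
  fraction can swap between adjacent waves under replicate noise (the
  synthetic recovery rate of ≈98% reflects exactly this).
* Welch screens at raw alpha are anticonservative over a family; the BH
  mode is provided but the defaults replicate the uncorrected historical
  analysis.
* The UPGMA tie-break is a package convention; other tools (e.g. MeV)
  order equal-height merges differently, so leaf orders are comparable
  only between runs of this package.
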