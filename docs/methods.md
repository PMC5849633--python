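# Methods

`caftools` implements a rule-based analysis of stromal heterogeneity in
carcinoma: classification of carcinoma-associated fibroblast (CAF) subsets
from multi-marker intensities, tile-level spatial maps of tumor sections,
a min-p log-rank cutoff search for biomarker prognosis, and the scalar
scores used around those analyses. Every stage is exercised on synthetic
data whose generating parameters are known, so the tests measure recovery
of a ground truth rather than agreement with another implementation.

## Subset classification

Fibroblasts are identified among dissociated-tumor events by sequential
lineage gating: events at or above a threshold on the viability dye,
EPCAM, CD45 or CD31 channel are removed, in that order, and the gating
report attributes each exclusion to the first failing channel. Thresholds
can be supplied directly or derived as the 99th percentile of
negative-control events; the fallback constant (100 a.u.) sits between the
autofluorescence and positive-population locations of the synthetic data.

Each of the five classification markers (CD29, FAP, SMA, FSP1, PDGFRB) is
discretised into Neg / Low / Med / Hi at the quartiles (Q1, median, Q3) of
a pooled reference distribution — all reference cells or all tumors of a
cohort, not per subset. Percentiles use linear interpolation between order
statistics (the numpy default). The level rule is half-open and closed on
the right: `< Q1 -> Neg`, `[Q1, Mdn) -> Low`, `[Mdn, Q3) -> Med`,
`>= Q3 -> Hi`, so a degenerate marker (Q1 = Mdn = Q3) maps every value to
Hi and the assignment stays total. CAV1 is carried in the tables but not
consulted: its dynamic range does not separate the subsets.

The decision list applies ordered rules to the level vector:

1. FAP = Hi -> **CAF-S1** (the broadly positive, FAP-high subset);
2. else CD29 = Hi and SMA = Hi -> **CAF-S4** (FAP-negative myofibroblasts);
3. else all five markers in {Neg, Low} -> **CAF-S2** (negative for all);
4. else -> **CAF-S3** (intermediate CD29/SMA, typically FSP1-high).

The order is the discriminating structure of the published subset
profiles: FAP-Hi is unique to CAF-S1, CD29-Hi with SMA-Hi is unique to
CAF-S4 among FAP-non-Hi cells. Rules are data (`ThresholdSet.rules`), so
an alternative tree can be loaded from JSON and versioned. The same
`ThresholdSet` object classifies FACS events, image tiles and whole-tumor
histological scores; when moving between modalities the quartiles are
re-derived on the target modality's own score distribution rather than
transported, since no principled intensity-to-H-score mapping exists.

**Known limitation (quartile-band saturation).** If one profile holds more
than a quartile of the reference mass, the corresponding cut point falls
*inside* that profile's intensity cluster and any spread splits the
cluster across a band boundary: in a cohort with 60% CAF-S1-profile
tumors, Q3 of FAP sits near the middle of the S1 cluster and only about
half of those tumors reach Hi once scores carry noise. At zero noise the
tied values keep the whole cluster at the cut point, and the closed-right
rule assigns them all Hi. Quartile gating therefore recovers dominant
profiles exactly only when within-profile spread is small relative to the
between-profile separation. The practical consequence: derive thresholds
from a *balanced* reference — a gated cytometry cohort or a learning set
containing all subsets in comparable amounts — and then apply the saved
`ThresholdSet` to maps and cohorts, rather than re-deriving quartiles from
each map's own (possibly skewed) label distribution. On synthetic tissue
with 40% CAF-S1 tiles, map-derived thresholds recover only ~74% of tile
labels at any noise level (the quantile cut always slices the dominant
clusters at a fixed fraction), while thresholds from a balanced reference
recover 100%.

## Synthetic data

*FACS events.* Intensities are log-normal around per-subset location
anchors Neg = 10, Low = 40, Med = 100, Hi = 300 a.u. (fluorescence is
right-skewed; anchors are chosen once so adjacent bands differ by a factor
2.5–4, large against the default log-scale dispersion of 0.3). With zero
dispersion every event equals its profile exactly and the full
gate -> quartiles -> tree chain recovers 100% of labels; at dispersion 0.3
recovery is ~98%. Contaminant events (one hot lineage channel at 1000
a.u.) are added on top of the configured subset counts so that the
configured fraction is the fraction of all events.

*Tissue.* Epithelial regions are unions of random discs on the tile grid;
stromal tiles receive subset labels by a largest-remainder split of the
configured proportions. CAF-S1 tiles are placed with sampling weight
`exp(-bias * d)` where `d` is the (unwindowed) distance to the nearest
epithelial tile; at bias 0 labels are independent of position. The
enrichment condition used in the power study is bias = 0.2 — an e-fold
decay of placement odds per five tiles — chosen so the enrichment is
pronounced while every subset keeps enough tiles inside the distance
window for a two-sample comparison (stronger bias lets CAF-S1 saturate the
near-epithelium zone and starves the comparison group). Rasters expand
each tile into a block of pixels (default 3x3, i.e. 5 um pixels) with
additive Gaussian pixel noise; CD3+ points are per-tile Poisson draws with
label-dependent rates, placed uniformly within the tile. The generator
does not emulate stain variation across serial sections, segmentation
error, or alignment error — real maps inherit all three — so passing
recovery tests show correctness of the tiling/classification machinery,
not robustness to histology artifacts.

*Survival.* Biomarker values are normal (location 8, scale 1, a log2
probe-intensity scale); event times are exponential with a step hazard:
0.04/month below the true cutoff (median survival ~17 months) times a
hazard ratio of 3 above it; censoring is independent exponential at
0.01/month (~15–20% censored). These are realistic advanced
ovarian-cancer follow-up conditions in months; the step hazard is the
simplest model under which a true cutoff exists.

## Spatial maps

Tiles are 15 um squares (225 um^2, roughly one cell). Per-tile intensity
is the mean pixel value of the pre-aligned single-channel raster; a tile
is epithelial when more than 50% of its pixels fall in the epithelial
mask; partial edge tiles are dropped rather than padded. When the pixel
size does not divide the tile side, rasters are resampled (bilinear for
intensities, nearest for the mask) to the closest grid that does.
Elastic alignment of serial sections and stain deconvolution are upstream
of this package: inputs are already-aligned grayscale intensity rasters.

The distance from a stromal tile to the epithelium is the minimum
Euclidean distance, in tile units, over epithelial tiles within a Chebyshev
window of 5 tiles (configurable); tile centers are used, which for integer
offsets equals the coordinate formula `sqrt((xe-x)^2 + (ye-y)^2)`. Tiles
with no epithelial tile in the window carry an *undefined* distance — they
are excluded from summaries and counted, never clamped to the window edge.
Defined distances therefore lie in (0, 5*sqrt(2)] at the default radius.
The implementation shifts the epithelial mask over the 11x11 offset grid;
an exhaustive per-tile scan serves as the independent oracle in the tests.
Heatmaps map the defined range linearly onto a red-to-yellow ramp
(undefined tiles gray, epithelial tiles black), and the green channel
round-trips the distance up to 8-bit quantization.

Immune points are assigned to the tile containing them under half-open
tile intervals `[k*15, (k+1)*15)`, so shared edges belong to the
right/bottom tile and counts always sum to the number of points.
Densities divide counts by compartment areas (n_tiles x 2.25e-4 mm^2).
Per-subset distance summaries report mean +/- SEM of defined distances and
compare each label against the pooled others with the test-selection
cascade below.

## Survival analysis

The Kaplan-Meier estimator and the two-group log-rank test are computed
directly from risk-set tables (and are cross-checked against an
independent survival library in the test suite); the variance term uses
the standard hypergeometric form with the `(n-d)/(n-1)` correction, and a
zero-variance configuration (e.g. duplicated groups with simultaneous
deaths) returns statistic 0, p = 1.

`iterative_cutoff` scans candidate cutoffs at midpoints between
consecutive *distinct* sorted biomarker values; a candidate is admissible
when both the Low (`biomarker <= cutoff`) and High groups hold at least
`min_group_fraction` (default 15%) of the cohort, which excludes
degenerate splits the search would otherwise favor. The returned cutoff
minimizes the log-rank p. The median split — the admissible candidate
dividing the cohort most evenly — is preferred whenever its p ties the
minimum within a relative tolerance of 1e-9, and the result records that
fallback; among other exact ties the smallest cutoff wins. The search is
invariant under strictly increasing biomarker transforms (group
memberships and p-values unchanged, cutoff mapped through).

**Caveat: min-p inflation and rank wander.** No multiple-testing
correction is applied, matching common practice for this procedure. Two
consequences are quantified by the simulation studies and should temper
interpretation. First, under the null (hazard ratio 1) the minimal p over
~140 correlated candidate splits falls below 0.05 in roughly 35–40% of
cohorts — the p at the chosen cutoff is an optimistic screening statistic,
not a calibrated test. Second, even under a strong signal (hazard ratio 3,
n = 200) the argmin wanders: the chosen split lands within +/-2
order-statistic positions of the true threshold in only ~60–70% of
replicates, because adjacent splits differ by a single patient and the p
profile near the optimum is nearly flat, occasionally handing the minimum
to a distant local optimum. Recovery within +/-2 ranks at a 90% rate
would require implausibly strong effects (hazard ratio ~10 in the same
design). The package reports both rates honestly rather than presenting
the cutoff as precisely located.

## Statistical utilities

The gene-set overlap test is the exact hypergeometric upper tail
P(X >= k); Fisher's exact test uses the conventional two-sided rule (total
probability of tables no more likely than the observed one). Both agree
with exhaustive enumeration oracles for all configurations with universe
size up to 12. The two-sample selector follows the cascade: Shapiro-Wilk
on both samples at alpha = 0.05; both normal -> Bartlett; variances equal
-> Student's t, otherwise Welch; any normality failure -> Mann-Whitney
(unpaired) or Wilcoxon signed-rank (paired); constant samples are treated
as non-normal, and identical paired samples report "no-difference" with
p = 1 rather than a degenerate test. Percentage tables round
half-away-from-zero with an optional truncation mode, because published
cohort tables mix the two conventions. The remaining formulas are pure
arithmetic with bounds enforced: H-score = pct x intensity in [0, 400];
suppression % = (log2(y_alone) - log2(y_with)) / log2(y_alone) x 100
(undefined at y_alone = 1); caliper volume V = a*b^2/2 with a >= b and
RTV = V_n/V_0; transwell migration normalizes each chamber's count by its
bead recovery (reference = mean of the two bead counts) before taking the
lower-chamber fraction and dividing by the live fraction.

## Problem sizes and determinism

The simulation studies use 10,000 events for classifier recovery, 100
random 30x30 maps for the distance oracle, 100 tissue replicates on 40x40
grids for the proximity power and null rates, and 100 (recovery) plus 200
(null) cohorts of n = 200 for the cutoff studies — sizes at which the
binomial error of a reported rate is 2–4 percentage points and the full
evaluation completes in about a minute. Every generator and study takes a
seed; replicate seeds are spawned from it, so identical seeds give
identical tables, maps, cohorts and rates.
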