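# caftools

Analysis of stromal heterogeneity in carcinoma for researchers quantifying
carcinoma-associated fibroblasts (CAF) in cytometry and histology data.
High-grade serous ovarian cancers harbor four CAF subpopulations —
CAF-S1 (broadly positive, FAP-high, immunosuppressive), CAF-S2 (negative
for all markers), CAF-S3 (intermediate, FSP1-high) and CAF-S4
(FAP-negative CD29/SMA-high myofibroblasts) — and their abundance and
spatial arrangement carry prognostic information. `caftools` provides the
computational side of that analysis as a tested, reusable pipeline:

- **Subset classification** (`caftools.classifier`): lineage gating
  (viability, EPCAM, CD45, CD31), quartile discretisation of CD29, FAP,
  SMA, FSP1 and PDGFRB into Neg/Low/Med/Hi at the Q1/Mdn/Q3 of a reference
  distribution, and an ordered decision list (FAP^Hi -> CAF-S1; CD29^Hi &
  SMA^Hi -> CAF-S4; all Neg/Low -> CAF-S2; else CAF-S3) applied uniformly
  to cells, tiles or whole-tumor histological scores.
- **Spatial maps** (`caftools.spatial`): 225 um^2 tiles (15 um side,
  ~one cell) built from pre-aligned marker rasters and an epithelial mask;
  per-tile subset labels; windowed distance-to-epithelium
  d(x, y) = min sqrt((x_e - x)^2 + (y_e - y)^2) over epithelial tiles
  within 5 tiles in x and y (undefined beyond the window); red-to-yellow
  distance heatmaps; immune-cell colocalization counts and densities per
  mm^2.
- **Survival analysis** (`caftools.survival`): Kaplan-Meier estimation,
  the two-group log-rank test, and an iterative min-p cutoff search that
  dichotomizes a continuous biomarker at the split maximally separating
  the survival curves, with a median-split fallback on ties and a
  minimum-group-size constraint.
- **Cohort statistics** (`caftools.stats`): H-scores, exact hypergeometric
  overlap and Fisher tests, the Shapiro -> Bartlett -> Student/Welch or
  rank-test selection cascade, percentage tables, expression ratios, CFSE
  suppression percentages, caliper tumor volumes (V = a·b²/2, RTV =
  V_n/V_0) and bead-normalized transwell migration fractions.
- **Synthetic data** (`caftools.synthetic`): generators for FACS-like
  event tables, tissue tile maps with rasters and CD3+ point patterns, and
  biomarker-survival cohorts, all with recoverable ground truth and full
  seed determinism.

## Worked example

```python
import caftools as ct

# simulate a cytometry run: 4 x 2500 events plus 10% lineage contaminants
cfg = ct.FacsSimConfig(lineage_contamination_fraction=0.1, seed=1)
events = ct.gen_facs_events(cfg)

gated, report = ct.gate_fibroblasts(events)
thresholds = ct.derive_thresholds(gated[list(ct.MARKERS)])
labels = ct.classify_frame(gated[list(ct.MARKERS)], thresholds)

truth = gated["true_label"]
acc = (labels[truth != "contaminant"] == truth[truth != "contaminant"]).mean()
print(f"retained {report.n_retained}/{report.n_input} events")
print(f"excluded per channel: {dict(report.excluded_per_channel)}")
print(f"subset recovery: {100 * acc:.1f}%")
```

prints

```
retained 10000/11111 events
excluded per channel: {'viability': 262, 'EPCAM': 292, 'CD45': 278, 'CD31': 279}
subset recovery: 98.0%
```

The gate removed exactly the 1111 simulated contaminants (10% of all
events, attributed to the first lineage channel each failed) and none of
the fibroblasts; quartile thresholds derived from the retained events then
reproduce 98.0% of the hidden subset labels at the default noise level.

The same thresholds object — derived from a balanced reference cohort —
then drives tissue maps (re-deriving quartiles from a map whose subset
proportions are skewed would place cut points inside the dominant subset's
intensity cluster, see `docs/methods.md`):

```python
sample = ct.gen_tissue(ct.TissueSimConfig(s1_proximity_bias=0.2, seed=2))
tiles = ct.build_tile_map(sample.rasters, sample.epithelial_mask, sample.pixel_size_um)
tiles = ct.assign_subsets(tiles, thresholds)
dmap = ct.distance_to_epithelium(tiles, window_radius=5)
res = ct.summarize_distance_by_subset(tiles, dmap)
print(res.summary[["n_defined", "mean", "sem"]].round(2))
print(res.comparisons[("CAF-S1", "rest")])
```

```
        n_defined  mean   sem
label
CAF-S1        492  3.18  0.07
CAF-S2          9  4.29  0.19
CAF-S3         12  5.13  0.31
CAF-S4         14  4.83  0.36
TestSelection(test='mann-whitney', p_value=2.99500715380804e-08, stages={'shapiro_a': 6.141261648092432e-13, 'shapiro_b': 0.22723164317798117})
```

CAF-S1 tiles sit measurably closer to the epithelium than the other
subsets (distances in tile units; multiply by 15 for um), recovering the
simulated proximity enrichment; the map's tile labels agree 100% with the
generator's hidden truth here.

A cohort-level survival cutoff:

```python
cohort = ct.gen_survival(ct.SurvivalSimConfig(seed=4))
result = ct.iterative_cutoff(cohort, min_group_fraction=0.15)
print(result.cutoff, result.n_low, result.n_high, f"{result.chosen_p:.2e}")
```

```
8.0016 101 99 1.99e-12
```

The search recovers the simulated threshold (8.0) almost exactly, splitting
the 200 patients 101/99. The p at the chosen split is a screening
statistic: min-p searches are anti-conservative without correction (see
`docs/methods.md`).

A command-line interface mirrors these steps
(`caftools simulate|classify|map|survival|stats --help`).

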