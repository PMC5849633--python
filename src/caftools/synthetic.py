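"""Synthetic FACS events, tissue tile maps and survival cohorts with known truth.

Every downstream stage of the package (gating, quartile classification,
spatial mapping, cutoff search) is exercised on data from these generators,
whose hidden parameters are recoverable:

* :func:`gen_facs_events` emulates a dissociated-tumor cytometry run: four
  fibroblast subpopulations with log-normal marker intensities around
  subset-specific locations, plus an optional fraction of lineage-positive
  contaminant events (dead cells, epithelial, hematopoietic, endothelial).
* :func:`gen_tissue` emulates a stained tumor section summarised on a grid
  of 15 um tiles: epithelial regions are unions of random discs, stromal
  tiles carry a true CAF subset, per-marker rasters reconstruct the tile
  intensities up to pixel noise, and CD3+ T cells are placed by a per-tile
  Poisson process whose rate depends on the tile label.  A nonnegative
  ``s1_proximity_bias`` concentrates CAF-S1 tiles near the epithelium.
* :func:`gen_survival` emulates a biomarker-dichotomised patient cohort:
  exponential event times whose hazard steps up by ``hazard_ratio`` above a
  hidden biomarker threshold, with independent exponential censoring.

All three are deterministic given their ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .classifier import ALL_MARKERS, LINEAGE_CHANNELS, MARKERS, SUBSETS
from .spatial import TileMap

#: Intensity anchors for the four discretisation bands (arbitrary
#: fluorescence/densitometry units, log-normal scale).  Ratios between
#: adjacent anchors are large relative to the default noise so bands stay
#: separable at realistic dispersion.
LEVEL_ANCHORS: dict[str, float] = {"Neg": 10.0, "Low": 40.0, "Med": 100.0, "Hi": 300.0}

_A = LEVEL_ANCHORS

#: Canonical per-subset marker locations implementing the published subset
#: profiles (CAF-S1: FAP-high and broadly positive; CAF-S2: negative for
#: everything; CAF-S3: FSP1-high with intermediate CD29; CAF-S4: CD29/SMA
#: high myofibroblasts without FAP).
DEFAULT_SUBSET_PROFILES: dict[str, dict[str, float]] = {
    "CAF-S1": {"CD29": _A["Med"], "FAP": _A["Hi"], "SMA": _A["Med"], "FSP1": _A["Hi"],
               "PDGFRB": _A["Hi"], "CAV1": _A["Low"]},
    "CAF-S2": {"CD29": _A["Low"], "FAP": _A["Neg"], "SMA": _A["Neg"], "FSP1": _A["Neg"],
               "PDGFRB": _A["Neg"], "CAV1": _A["Neg"]},
    "CAF-S3": {"CD29": _A["Med"], "FAP": _A["Low"], "SMA": _A["Low"], "FSP1": _A["Hi"],
               "PDGFRB": _A["Med"], "CAV1": _A["Neg"]},
    "CAF-S4": {"CD29": _A["Hi"], "FAP": _A["Low"], "SMA": _A["Hi"], "FSP1": _A["Med"],
               "PDGFRB": _A["Hi"], "CAV1": _A["Neg"]},
}

#: Lineage-channel locations for clean fibroblasts and for the positive
#: channel of a contaminant event.
LINEAGE_NEGATIVE_LEVEL = 10.0
LINEAGE_POSITIVE_LEVEL = 1000.0

#: true_label value carried by contaminant (non-fibroblast) events.
CONTAMINANT_LABEL = "contaminant"


def _check_fraction(name: str, value: float, *, open_top: bool = False) -> None:
    top_ok = value < 1 if open_top else value <= 1
    if not (0 <= value and top_ok):
        raise ValueError(f"{name} must lie in [0, 1{')' if open_top else ']'}; got {value}")


# ---------------------------------------------------------------------------
# FACS events
# ---------------------------------------------------------------------------

@dataclass
class FacsSimConfig:
    """Study conditions for the simulated cytometry run.

    ``subset_marker_means`` are log-normal location parameters: with zero
    ``noise_sd`` every event's intensity equals its subset's mean exactly,
    and for any noise the per-subset median converges to the mean parameter.
    ``lineage_contamination_fraction`` is the fraction of *all* events that
    are lineage-positive; contaminants are generated on top of the
    configured per-subset counts.
    """

    n_events_per_subset: Mapping[str, int] = field(
        default_factory=lambda: {s: 2500 for s in SUBSETS}
    )
    subset_marker_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(p) for s, p in DEFAULT_SUBSET_PROFILES.items()}
    )
    noise_sd: float = 0.3
    lineage_contamination_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.n_events_per_subset:
            raise ValueError("n_events_per_subset is empty")
        for subset, n in self.n_events_per_subset.items():
            if int(n) <= 0:
                raise ValueError(f"event count for {subset} must be positive; got {n}")
        marker_sets = {frozenset(m) for m in map(dict, self.subset_marker_means.values())}
        if len(marker_sets) != 1:
            raise ValueError("all subsets must share the same marker list")
        for subset in self.n_events_per_subset:
            if subset not in self.subset_marker_means:
                raise ValueError(f"no marker means configured for subset {subset!r}")
            for marker, mean in self.subset_marker_means[subset].items():
                if mean <= 0:
                    raise ValueError(f"mean for {subset}/{marker} must be positive; got {mean}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        _check_fraction(
            "lineage_contamination_fraction", self.lineage_contamination_fraction, open_top=True
        )


def gen_facs_events(config: FacsSimConfig) -> pd.DataFrame:
    """Simulate a per-event marker-intensity table with hidden true labels.

    Returns a DataFrame with the four lineage channels, the six fibroblast
    markers and a ``true_label`` column (subset name, or ``"contaminant"``
    for lineage-positive events).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = sorted(next(iter(config.subset_marker_means.values())).keys())

    blocks = []
    for subset in sorted(config.n_events_per_subset):
        n = int(config.n_events_per_subset[subset])
        block = {"true_label": np.full(n, subset, dtype=object)}
        for channel in LINEAGE_CHANNELS:
            block[channel] = LINEAGE_NEGATIVE_LEVEL * np.exp(
                rng.normal(0.0, config.noise_sd, size=n)
            )
        for marker in markers:
            mean = config.subset_marker_means[subset][marker]
            block[marker] = mean * np.exp(rng.normal(0.0, config.noise_sd, size=n))
        blocks.append(pd.DataFrame(block))

    n_clean = sum(int(n) for n in config.n_events_per_subset.values())
    f = config.lineage_contamination_fraction
    n_cont = int(round(f / (1.0 - f) * n_clean)) if f > 0 else 0
    if n_cont:
        subsets = sorted(config.n_events_per_subset)
        pick = rng.choice(len(subsets), size=n_cont)
        block = {"true_label": np.full(n_cont, CONTAMINANT_LABEL, dtype=object)}
        hot = rng.choice(len(LINEAGE_CHANNELS), size=n_cont)
        for i, channel in enumerate(LINEAGE_CHANNELS):
            base = np.where(hot == i, LINEAGE_POSITIVE_LEVEL, LINEAGE_NEGATIVE_LEVEL)
            block[channel] = base * np.exp(rng.normal(0.0, config.noise_sd, size=n_cont))
        for marker in markers:
            means = np.array(
                [config.subset_marker_means[subsets[j]][marker] for j in pick]
            )
            block[marker] = means * np.exp(rng.normal(0.0, config.noise_sd, size=n_cont))
        blocks.append(pd.DataFrame(block))

    events = pd.concat(blocks, ignore_index=True)
    order = [c for c in LINEAGE_CHANNELS] + markers + ["true_label"]
    return events[order]


# ---------------------------------------------------------------------------
# Tissue tile maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpithelialGeometry:
    """Epithelial regions as a union of random discs on the tile grid."""

    n_blobs: int = 3
    radius_range: tuple[float, float] = (3.0, 6.0)

    def validate(self, grid_shape: tuple[int, int]) -> None:
        if self.n_blobs < 1:
            raise ValueError("need at least one epithelial blob")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError("radius_range must satisfy 0 < lo <= hi")
        if min(grid_shape) < int(np.ceil(2 * lo)) + 2:
            raise ValueError(
                f"grid {grid_shape} too small to place epithelial discs of radius >= {lo}"
            )


@dataclass
class TissueSimConfig:
    """Study conditions for the simulated tissue section.

    ``subset_proportions`` is a simplex over the four subsets among stromal
    tiles.  ``s1_proximity_bias`` >= 0 weights CAF-S1 placement by
    exp(-bias * distance-to-epithelium); at 0, labels are independent of
    position.  ``cd3_rate_per_subset`` gives the expected CD3+ points per
    tile keyed by subset label (plus optionally ``"epithelial"``).
    """

    grid_shape: tuple[int, int] = (50, 50)
    epithelial_geometry: EpithelialGeometry = field(default_factory=EpithelialGeometry)
    subset_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"CAF-S1": 0.4, "CAF-S2": 0.1, "CAF-S3": 0.2, "CAF-S4": 0.3}
    )
    s1_proximity_bias: float = 0.0
    cd3_rate_per_subset: Mapping[str, float] = field(
        default_factory=lambda: {"CAF-S1": 2.0, "CAF-S2": 0.3, "CAF-S3": 0.3,
                                 "CAF-S4": 0.3, "epithelial": 0.3}
    )
    marker_noise_sd: float = 5.0
    pixels_per_tile: int = 3
    epithelial_marker_level: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ValueError("grid must be at least 2x2 tiles")
        self.epithelial_geometry.validate((rows, cols))
        props = dict(self.subset_proportions)
        if set(props) != set(SUBSETS):
            raise ValueError(f"subset_proportions must be keyed by {SUBSETS}")
        total = sum(props.values())
        if any(p < 0 for p in props.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("subset_proportions must be nonnegative and sum to 1")
        if self.s1_proximity_bias < 0:
            raise ValueError("s1_proximity_bias must be nonnegative")
        if any(r < 0 for r in self.cd3_rate_per_subset.values()):
            raise ValueError("CD3 rates must be nonnegative")
        if self.marker_noise_sd < 0:
            raise ValueError("marker_noise_sd must be nonnegative")
        if self.pixels_per_tile < 1:
            raise ValueError("pixels_per_tile must be >= 1")


@dataclass
class TissueSample:
    """Generated tissue: ground truth plus the rasters a pipeline would read."""

    truth: TileMap
    rasters: dict[str, np.ndarray]
    epithelial_mask: np.ndarray
    cd3_points: pd.DataFrame
    pixel_size_um: float
    cd3_counts: np.ndarray  # per-tile truth of the Poisson draws


def _largest_remainder_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Split n items into integer counts matching proportions exactly."""
    keys = sorted(proportions)
    raw = np.array([proportions[k] * n for k in keys])
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))  # largest fractional parts first
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(keys, counts))


def gen_tissue(config: TissueSimConfig) -> TissueSample:
    """Simulate a tissue section: truth tile map, marker rasters, mask, CD3 points."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape

    # epithelial discs on the tile grid
    geom = config.epithelial_geometry
    epithelial = np.zeros((rows, cols), dtype=bool)
    yy, xx = np.mgrid[0:rows, 0:cols]
    for _ in range(geom.n_blobs):
        cy = rng.uniform(0, rows - 1)
        cx = rng.uniform(0, cols - 1)
        r = rng.uniform(*geom.radius_range)
        epithelial |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if epithelial.all():
        raise ValueError("epithelial discs cover the whole grid; no stromal tiles remain")
    if not epithelial.any():  # pragma: no cover - centers are inside the grid
        raise ValueError("no epithelial tile was placed")

    # label assignment among stromal tiles
    stromal_idx = np.flatnonzero(~epithelial.ravel())
    n_stromal = stromal_idx.size
    counts = _largest_remainder_counts(n_stromal, dict(config.subset_proportions))
    labels_flat = np.full(rows * cols, None, dtype=object)

    # distance of each stromal tile to the nearest epithelial tile (unbounded)
    dist_full = ndimage.distance_transform_edt(~epithelial).ravel()

    remaining = stromal_idx.copy()
    n_s1 = counts["CAF-S1"]
    if n_s1 > 0:
        weights = np.exp(-config.s1_proximity_bias * dist_full[remaining])
        weights /= weights.sum()
        chosen = rng.choice(remaining, size=n_s1, replace=False, p=weights)
        labels_flat[chosen] = "CAF-S1"
        remaining = np.setdiff1d(remaining, chosen)
    rng.shuffle(remaining)
    start = 0
    for subset in ("CAF-S2", "CAF-S3", "CAF-S4"):
        k = counts[subset]
        labels_flat[remaining[start : start + k]] = subset
        start += k
    labels = labels_flat.reshape(rows, cols)

    # ground-truth tile intensities for the five IHC markers
    intensities = {}
    for marker in MARKERS:
        grid = np.full((rows, cols), config.epithelial_marker_level, dtype=float)
        for subset in SUBSETS:
            grid[labels == subset] = DEFAULT_SUBSET_PROFILES[subset][marker]
        intensities[marker] = grid
    truth = TileMap(intensities=intensities, epithelial=epithelial, labels=labels)

    # pixel rasters: each tile becomes a pixels_per_tile^2 block plus noise
    ppt = config.pixels_per_tile
    rasters = {}
    for marker in MARKERS:
        px = np.kron(intensities[marker], np.ones((ppt, ppt)))
        if config.marker_noise_sd > 0:
            px = px + rng.normal(0.0, config.marker_noise_sd, size=px.shape)
        rasters[marker] = np.clip(px, 0.0, None)
    mask_px = np.kron(epithelial.astype(np.uint8), np.ones((ppt, ppt), dtype=np.uint8)) > 0

    # CD3+ point pattern: per-tile Poisson conditioned on the tile label
    rates = np.zeros((rows, cols))
    rates[epithelial] = config.cd3_rate_per_subset.get("epithelial", 0.0)
    for subset in SUBSETS:
        rates[labels == subset] = config.cd3_rate_per_subset.get(subset, 0.0)
    cd3_counts = rng.poisson(rates)
    side = truth.tile_side_um
    pts_x, pts_y = [], []
    for (r, c), k in np.ndenumerate(cd3_counts):
        if k:
            pts_x.append(c * side + rng.uniform(0, side, size=k))
            pts_y.append(r * side + rng.uniform(0, side, size=k))
    cd3_points = pd.DataFrame(
        {
            "x_um": np.concatenate(pts_x) if pts_x else np.array([]),
            "y_um": np.concatenate(pts_y) if pts_y else np.array([]),
        }
    )
    cd3_points["phenotype"] = "CD3"

    return TissueSample(
        truth=truth,
        rasters=rasters,
        epithelial_mask=mask_px,
        cd3_points=cd3_points,
        pixel_size_um=side / ppt,
        cd3_counts=cd3_counts,
    )


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

@dataclass
class SurvivalSimConfig:
    """Study conditions for the simulated biomarker-survival cohort.

    Event times are exponential with hazard ``baseline_hazard`` below the
    hidden ``true_cutoff`` and ``baseline_hazard * hazard_ratio`` above it
    (a step hazard, the simplest model under which a true cutoff exists).
    Censoring is independent exponential with rate ``censoring_rate``; the
    observed time is the earlier of the two.  Defaults emulate an advanced
    ovarian-cancer cohort followed in months: a median overall survival
    under 2 years in the low-risk group and roughly 20% censoring.
    """

    n_patients: int = 200
    true_cutoff: float = 8.0
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.04  # events per month
    censoring_rate: float = 0.01  # censorings per month
    biomarker_loc: float = 8.0  # e.g. log2 probe intensity
    biomarker_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be nonnegative")
        if self.biomarker_scale <= 0:
            raise ValueError("biomarker_scale must be positive")


def gen_survival(config: SurvivalSimConfig) -> pd.DataFrame:
    """Simulate a cohort table with columns time, event, biomarker."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_patients)
    biomarker = rng.normal(config.biomarker_loc, config.biomarker_scale, size=n)
    hazard = np.where(
        biomarker > config.true_cutoff,
        config.baseline_hazard * config.hazard_ratio,
        config.baseline_hazard,
    )
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"time": time, "event": event, "biomarker": biomarker})
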