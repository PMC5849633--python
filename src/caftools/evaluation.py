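"""Simulation studies quantifying how well the pipeline recovers known truth.

Each routine here runs the package end-to-end on synthetic data with a
recoverable ground truth and reports a scalar quality metric: exact
agreement of the windowed distance with a brute-force scan, label-recovery
accuracy of the gate -> quartiles -> decision-tree chain, statistical power
to detect the CAF-S1 proximity enrichment (and the matching false-positive
rate under the null), rank accuracy of the min-p survival cutoff search
(and the type-I inflation the uncorrected search incurs), and agreement of
the exact tests with enumeration oracles.

All routines are deterministic given their ``seed`` (replicate seeds are
spawned from it) and are sized to run in minutes on one CPU.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from . import classifier, spatial, stats, survival, synthetic


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# distance oracle
# ---------------------------------------------------------------------------

def brute_force_distance(tiles: spatial.TileMap, window_radius: int = 5) -> np.ndarray:
    """Reference windowed distance: scan every epithelial tile per stromal tile."""
    rows, cols = tiles.shape
    epith_coords = np.argwhere(tiles.epithelial)
    out = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            if tiles.epithelial[r, c]:
                continue
            dr = np.abs(epith_coords[:, 0] - r)
            dc = np.abs(epith_coords[:, 1] - c)
            in_window = (dr <= window_radius) & (dc <= window_radius)
            if in_window.any():
                out[r, c] = float(np.hypot(dr[in_window], dc[in_window]).min())
    return out


def distance_oracle_agreement(
    n_maps: int = 100, shape: tuple[int, int] = (30, 30), seed: int = 0,
    window_radius: int = 5,
) -> float:
    """Percent of random tile maps where the fast distance equals brute force."""
    seeds = _spawn_seeds(seed, n_maps)
    agree = 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        epith = rng.random(shape) < rng.uniform(0.05, 0.4)
        tiles = spatial.TileMap(intensities={}, epithelial=epith)
        fast = spatial.distance_to_epithelium(tiles, window_radius).distances
        slow = brute_force_distance(tiles, window_radius)
        same_nan = np.isnan(fast) == np.isnan(slow)
        same_val = np.isclose(fast, slow, equal_nan=True)
        agree += bool((same_nan & same_val).all())
    return 100.0 * agree / n_maps


# ---------------------------------------------------------------------------
# classifier recovery
# ---------------------------------------------------------------------------

def classifier_recovery(
    noise_sd: float,
    seed: int = 0,
    n_per_subset: int = 2500,
    contamination: float = 0.1,
) -> float:
    """End-to-end label recovery (%) on synthetic FACS events.

    Runs lineage gating, quartile threshold derivation on the retained
    events, and the decision tree; accuracy is scored on retained events
    with a true subset label.
    """
    cfg = synthetic.FacsSimConfig(
        n_events_per_subset={s: n_per_subset for s in classifier.SUBSETS},
        noise_sd=noise_sd,
        lineage_contamination_fraction=contamination,
        seed=int(seed),
    )
    events = synthetic.gen_facs_events(cfg)
    gated, _ = classifier.gate_fibroblasts(events)
    thresholds = classifier.derive_thresholds(gated[list(classifier.MARKERS)])
    predicted = classifier.classify_frame(gated[list(classifier.MARKERS)], thresholds)
    truth = gated["true_label"]
    is_fibro = truth.isin(classifier.SUBSETS)
    return 100.0 * float((predicted[is_fibro] == truth[is_fibro]).mean())


# ---------------------------------------------------------------------------
# proximity enrichment
# ---------------------------------------------------------------------------

def proximity_detection_rate(
    bias: float,
    n_reps: int = 100,
    seed: int = 0,
    grid_shape: tuple[int, int] = (40, 40),
    alpha: float = 0.05,
    require_direction: bool = True,
) -> float:
    """Percent of replicate tissues where CAF-S1 proximity enrichment is called.

    A replicate counts as a detection when the CAF-S1-versus-rest distance
    comparison is significant at ``alpha`` and (when ``require_direction``)
    the CAF-S1 mean distance is the smaller one.  With ``bias`` = 0 and
    ``require_direction`` = False this measures the false-positive rate of
    the comparison.
    """
    seeds = _spawn_seeds(seed, n_reps)
    hits = 0
    for s in seeds:
        cfg = synthetic.TissueSimConfig(
            grid_shape=grid_shape, s1_proximity_bias=bias, seed=int(s)
        )
        sample = synthetic.gen_tissue(cfg)
        dmap = spatial.distance_to_epithelium(sample.truth)
        res = spatial.summarize_distance_by_subset(sample.truth, dmap)
        test = res.comparisons.get(("CAF-S1", "rest"))
        if test is None:
            continue
        significant = test.p_value < alpha
        if require_direction:
            others = res.summary.drop(index="CAF-S1")
            direction = res.summary.loc["CAF-S1", "mean"] < others["mean"].min()
            significant = significant and bool(direction)
        hits += bool(significant)
    return 100.0 * hits / n_reps


# ---------------------------------------------------------------------------
# survival cutoff search
# ---------------------------------------------------------------------------

def cutoff_recovery_rate(
    n_reps: int = 100,
    seed: int = 0,
    rank_tolerance: int = 2,
    config: synthetic.SurvivalSimConfig | None = None,
) -> float:
    """Percent of replicates where the min-p cutoff lands within
    ``rank_tolerance`` order-statistic positions of the true threshold."""
    base = config or synthetic.SurvivalSimConfig()
    seeds = _spawn_seeds(seed, n_reps)
    hits = 0
    for s in seeds:
        cfg = synthetic.SurvivalSimConfig(**{**base.__dict__, "seed": int(s)})
        cohort = synthetic.gen_survival(cfg)
        result = survival.iterative_cutoff(cohort)
        true_rank = int((cohort["biomarker"] <= cfg.true_cutoff).sum())
        hits += abs(result.n_low - true_rank) <= rank_tolerance
    return 100.0 * hits / n_reps


def cutoff_null_minp_rate(
    n_reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    config: synthetic.SurvivalSimConfig | None = None,
) -> float:
    """Type-I rate (%) of the uncorrected min-p search under hazard_ratio = 1.

    The minimal log-rank p over all candidate splits is compared with
    ``alpha``; because the search optimizes over many correlated tests the
    rate exceeds the nominal level — the expected inflation of min-p
    threshold selection.
    """
    base = config or synthetic.SurvivalSimConfig()
    seeds = _spawn_seeds(seed, n_reps)
    hits = 0
    for s in seeds:
        cfg = synthetic.SurvivalSimConfig(
            **{**base.__dict__, "hazard_ratio": 1.0, "seed": int(s)}
        )
        cohort = synthetic.gen_survival(cfg)
        result = survival.iterative_cutoff(cohort)
        hits += result.chosen_p < alpha
    return 100.0 * hits / n_reps


# ---------------------------------------------------------------------------
# exact-test enumeration oracles
# ---------------------------------------------------------------------------

def hypergeom_tail_enumerated(n_universe: int, k_a: int, k_b: int, k: int) -> Fraction:
    """P(X >= k) for the overlap of a random k_b-subset with a fixed k_a-set,
    summed exactly over the hypergeometric support with integer arithmetic."""
    total = comb(n_universe, k_b)
    acc = 0
    for j in range(k, min(k_a, k_b) + 1):
        if k_b - j <= n_universe - k_a:
            acc += comb(k_a, j) * comb(n_universe - k_a, k_b - j)
    return Fraction(acc, total)


def fisher_two_sided_enumerated(table) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = comb(n, c1)

    def mass(x: int) -> int:
        return comb(r1, x) * comb(r2, c1 - x)

    observed = mass(a)
    acc = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if mass(x) <= observed:
            acc += mass(x)
    return Fraction(acc, total)


def exact_test_agreement(max_universe: int = 12, rel_tol: float = 1e-9) -> dict:
    """Check the scipy-backed exact tests against enumeration for small problems.

    Covers every hypergeometric configuration and every 2x2 table with a
    universe/total of at most ``max_universe``.  Returns the number of
    configurations checked and the percent agreeing within ``rel_tol``.
    """
    n_checked = n_agree = 0
    for n in range(1, max_universe + 1):
        for k_a in range(0, n + 1):
            for k_b in range(0, n + 1):
                lo = max(0, k_a + k_b - n)
                for k in range(lo, min(k_a, k_b) + 1):
                    spec = stats.OverlapSpec(n, k_a, k_b, k)
                    got = stats.hypergeom_overlap(spec)
                    want = float(hypergeom_tail_enumerated(n, k_a, k_b, k))
                    n_checked += 1
                    n_agree += bool(abs(got - want) <= rel_tol * max(1.0, want))
    for n in range(1, max_universe + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    got = stats.fisher_exact([[a, b], [c, d]])
                    want = float(fisher_two_sided_enumerated([[a, b], [c, d]]))
                    n_checked += 1
                    n_agree += bool(abs(got - want) <= max(rel_tol, 1e-7 * max(1.0, want)))
    return {"n_checked": n_checked, "agreement_pct": 100.0 * n_agree / n_checked}
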