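"""Scalar assay scores and statistical utilities for cohort analyses.

Small pure functions used across the histology and functional-assay
workflows: the H-score (percent positive cells times staining grade),
hypergeometric gene-set overlap and Fisher exact tests, a normality-driven
two-sample test selector (Shapiro-Wilk, then Bartlett, then Student/Welch t
or the rank-based alternatives), cohort percentage tables, expression
ratios, the CFSE suppression percentage, caliper tumor volumes with
relative tumor volume (RTV), and transwell migration fractions with bead
normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HScore",
    "OverlapSpec",
    "SuppressionAssay",
    "TumorMeasurement",
    "TestSelection",
    "hscore",
    "hypergeom_overlap",
    "fisher_exact",
    "select_and_test",
    "percentage_table",
    "expression_ratio",
    "delog2",
    "suppression_percent",
    "tumor_volume_rtv",
    "migration_fraction",
]


@dataclass(frozen=True)
class HScore:
    """Histological score: percentage of stained cells x intensity grade (0-4)."""

    pct_positive: float
    intensity: float

    @property
    def score(self) -> float:
        return self.pct_positive * self.intensity


@dataclass(frozen=True)
class OverlapSpec:
    """Overlap of two gene sets drawn from a universe of ``universe_size`` genes."""

    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int

    def validate(self) -> None:
        n, k_a, k_b, k = self.universe_size, self.set_a_size, self.set_b_size, self.overlap
        if min(n, k_a, k_b, k) < 0:
            raise ValueError("set sizes must be nonnegative")
        if max(k_a, k_b) > n:
            raise ValueError("a set cannot exceed the universe")
        if k > min(k_a, k_b):
            raise ValueError("overlap cannot exceed the smaller set")
        if k < max(0, k_a + k_b - n):
            raise ValueError("overlap below the minimum forced by the set sizes")


@dataclass(frozen=True)
class SuppressionAssay:
    """CFSE dilution readouts for a regulatory T-cell suppression assay.

    Each ``y`` is the CFSE mean fluorescence intensity of the whole effector
    population divided by the MFI of the non-proliferating cells; stronger
    proliferation gives smaller y.
    """

    y_teff_alone: float
    y_teff_plus_treg: float


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement: V = a*b^2/2 from two perpendicular diameters (mm)."""

    a: float
    b: float
    v0: float

    @property
    def volume(self) -> float:
        return self.a * self.b**2 / 2.0

    @property
    def rtv(self) -> float:
        return self.volume / self.v0


@dataclass(frozen=True)
class TestSelection:
    """Record of the test-selection cascade and its final p-value."""

    test: str
    p_value: float
    stages: Mapping[str, float]  # p-values of the selection stages actually run


def hscore(pct_positive: float, intensity: float) -> HScore:
    """H-score with bounds enforced: pct in [0, 100], intensity in [0, 4]."""
    if not (0 <= pct_positive <= 100):
        raise ValueError(f"pct_positive must be in [0, 100]; got {pct_positive}")
    if not (0 <= intensity <= 4):
        raise ValueError(f"intensity must be in [0, 4]; got {intensity}")
    return HScore(float(pct_positive), float(intensity))


def hypergeom_overlap(spec: OverlapSpec) -> float:
    """Upper-tail hypergeometric probability P(X >= observed overlap).

    X counts the intersection of a random ``set_b_size``-subset of the
    universe with a fixed set of ``set_a_size`` genes.
    """
    spec.validate()
    return float(
        sps.hypergeom.sf(
            spec.overlap - 1, spec.universe_size, spec.set_a_size, spec.set_b_size
        )
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p: total mass of tables no more probable than observed."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test needs a 2x2 table")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table entries must be nonnegative integers")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def select_and_test(
    sample_a,
    sample_b,
    paired: bool = False,
    alpha: float = 0.05,
) -> TestSelection:
    """Two-sample comparison with the normality-driven selection cascade.

    Shapiro-Wilk checks normality of both samples at ``alpha``.  If both
    pass: for unpaired data Bartlett's test decides between Student's t
    (equal variances) and Welch's t; for paired data a paired t-test is
    used.  Any normality failure switches to Mann-Whitney (unpaired) or the
    Wilcoxon signed-rank test (paired).  All tests are two-tailed.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("normality check (Shapiro-Wilk) needs n >= 3 per sample")
    if paired and a.size != b.size:
        raise ValueError("paired samples must have equal length")

    stages: dict[str, float] = {}
    degenerate_a = np.ptp(a) == 0
    degenerate_b = np.ptp(b) == 0
    # Shapiro-Wilk is undefined for constant samples; treat them as non-normal
    p_sh_a = float(sps.shapiro(a).pvalue) if not degenerate_a else 0.0
    p_sh_b = float(sps.shapiro(b).pvalue) if not degenerate_b else 0.0
    stages["shapiro_a"] = p_sh_a
    stages["shapiro_b"] = p_sh_b
    normal = p_sh_a > alpha and p_sh_b > alpha

    if paired:
        diff = a - b
        if np.ptp(diff) == 0 and diff[0] == 0:
            # identical paired samples: no difference to test
            return TestSelection(test="no-difference", p_value=1.0, stages=stages)
        if normal:
            res = sps.ttest_rel(a, b)
            return TestSelection("paired-t", float(res.pvalue), stages)
        res = sps.wilcoxon(a, b, zero_method="wilcox")
        return TestSelection("wilcoxon-signed-rank", float(res.pvalue), stages)

    if normal:
        p_bart = float(sps.bartlett(a, b).pvalue)
        stages["bartlett"] = p_bart
        if p_bart > alpha:
            res = sps.ttest_ind(a, b, equal_var=True)
            return TestSelection("student-t", float(res.pvalue), stages)
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestSelection("welch-t", float(res.pvalue), stages)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestSelection("mann-whitney", float(res.pvalue), stages)


def _round_half_away(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percentage_table(
    counts: Mapping[str, int] | Sequence[int],
    total: int,
    decimals: int = 1,
    truncate: bool = False,
) -> pd.Series:
    """Category counts as percentages of ``total``.

    Rounds half-away-from-zero to ``decimals`` places, or truncates when
    ``truncate`` is set (published cohort tables mix both conventions).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not isinstance(counts, Mapping):
        counts = {str(i): c for i, c in enumerate(counts)}
    out = {}
    for key, count in counts.items():
        if count < 0 or count > total:
            raise ValueError(f"count for {key!r} must lie in [0, total]")
        pct = 100.0 * count / total
        if truncate:
            factor = 10.0**decimals
            out[key] = math.floor(pct * factor) / factor
        else:
            out[key] = _round_half_away(pct, decimals)
    return pd.Series(out, name="percent")


def delog2(value: float) -> float:
    """Convert a log2-scale expression value back to the linear scale."""
    return float(2.0**value)


def expression_ratio(value_b: float, value_a: float) -> float:
    """Ratio of two linear-scale expression values (b over a).

    Log2 microarray intensities must be exponentiated first (:func:`delog2`).
    """
    if value_a <= 0:
        raise ValueError("denominator expression must be positive")
    return float(value_b) / float(value_a)


def suppression_percent(assay: SuppressionAssay) -> float:
    """Percentage suppression of effector proliferation by regulatory T cells.

    ((log2(y_alone) - log2(y_with_treg)) / log2(y_alone)) * 100, where y is
    the whole-population CFSE MFI over the non-proliferating-cell CFSE MFI.
    """
    y0, y1 = assay.y_teff_alone, assay.y_teff_plus_treg
    if y0 <= 0 or y1 <= 0:
        raise ValueError("y ratios must be positive")
    denom = math.log2(y0)
    if denom == 0:
        raise ValueError("y_teff_alone = 1 makes the suppression denominator zero")
    return (denom - math.log2(y1)) / denom * 100.0


def tumor_volume_rtv(a: float, b: float, v0: float) -> TumorMeasurement:
    """Tumor volume V = a*b^2/2 (mm^3) and RTV = V/V0 from caliper diameters."""
    if b <= 0:
        raise ValueError("diameters must be positive")
    if b > a:
        raise ValueError("a must be the major diameter (a >= b)")
    if v0 <= 0:
        raise ValueError("inclusion volume V0 must be positive")
    return TumorMeasurement(float(a), float(b), float(v0))


def migration_fraction(
    lower_count: float,
    upper_count: float,
    lower_beads: float,
    upper_beads: float,
    live_fraction: float = 1.0,
) -> float:
    """Percentage of cells that migrated to the lower transwell chamber.

    Raw counts are rescaled by counting beads (reference = mean of the two
    bead counts) to correct per-well collection efficiency, then the lower
    fraction of the total is normalized by the live-cell fraction.
    """
    if lower_beads <= 0 or upper_beads <= 0:
        raise ValueError("bead counts must be positive")
    if not (0 < live_fraction <= 1):
        raise ValueError("live_fraction must lie in (0, 1]")
    reference = (lower_beads + upper_beads) / 2.0
    lower_norm = lower_count * reference / lower_beads
    upper_norm = upper_count * reference / upper_beads
    total = lower_norm + upper_norm
    if total <= 0:
        raise ValueError("no cells counted in either chamber")
    return 100.0 * lower_norm / total / live_fraction
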