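"""Quartile decision-tree classification of carcinoma-associated fibroblast (CAF) subsets.

Fibroblasts isolated from high-grade serous ovarian cancer fall into four
subpopulations (CAF-S1 to CAF-S4) with distinct combinations of six marker
levels (CD29, FAP, SMA, FSP1, PDGFRB, CAV1).  This module implements the
rule-based pipeline that recovers those identities from raw intensities:

1. ``gate_fibroblasts`` removes dead cells and non-fibroblast lineages
   (viability dye, EPCAM, CD45, CD31) by sequential thresholding, the way a
   cytometrist draws lineage gates.
2. ``derive_thresholds`` discretises each marker into Neg/Low/Med/Hi bands
   at the quartiles (Q1, median, Q3) of a reference intensity distribution.
3. ``classify`` walks an ordered rule list over the level vector:
   FAP-high cells are CAF-S1; among the rest, CD29-high SMA-high
   myofibroblasts are CAF-S4; cells low for everything are CAF-S2; the
   remainder (typically FSP1-high with intermediate CD29/SMA) are CAF-S3.

The same thresholds-plus-rules object (:class:`ThresholdSet`) applies
unchanged to single cells, image tiles, or whole-tumor histological scores,
so FACS events and IHC maps share one classification code path.  CAV1 is
carried through the tables but not used by the default rules: its dynamic
range does not separate the subsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Markers used by the decision rules, in conventional panel order.
MARKERS: tuple[str, ...] = ("CD29", "FAP", "SMA", "FSP1", "PDGFRB")

#: Full fibroblast panel (CAV1 is measured but not consulted by the rules).
ALL_MARKERS: tuple[str, ...] = MARKERS + ("CAV1",)

#: Channels used for lineage exclusion, in gating order.
LINEAGE_CHANNELS: tuple[str, ...] = ("viability", "EPCAM", "CD45", "CD31")

#: Discrete intensity bands, ordered.
LEVELS: tuple[str, ...] = ("Neg", "Low", "Med", "Hi")

#: The closed set of subset labels.
SUBSETS: tuple[str, ...] = ("CAF-S1", "CAF-S2", "CAF-S3", "CAF-S4")

#: Fallback lineage gate when no negative controls are supplied (arbitrary
#: fluorescence units; sits between typical autofluorescence and a genuine
#: positive population in the synthetic data).
DEFAULT_LINEAGE_THRESHOLD = 100.0


@dataclass(frozen=True)
class DecisionRule:
    """One node of the ordered decision list.

    ``conditions`` maps marker name to the set of levels that satisfy the
    rule; a rule fires when every listed marker's level is in its allowed
    set.  Rules are evaluated in order and the first match wins.
    """

    label: str
    conditions: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "conditions",
            {m: frozenset(v) for m, v in dict(self.conditions).items()},
        )
        for marker, allowed in self.conditions.items():
            bad = allowed - set(LEVELS)
            if bad:
                raise ValueError(f"unknown level(s) {sorted(bad)} for marker {marker!r}")

    def matches(self, levels: Mapping[str, str]) -> bool:
        try:
            return all(levels[m] in allowed for m, allowed in self.conditions.items())
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"level vector is missing marker {exc.args[0]!r}") from exc


#: Default rule order, reconstructed from the published subset profiles:
#: FAP-Hi is unique to CAF-S1; CD29-Hi plus SMA-Hi is unique to CAF-S4 among
#: FAP-non-Hi cells; all-Neg/Low cells are CAF-S2; everything else is CAF-S3.
DEFAULT_RULES: tuple[DecisionRule, ...] = (
    DecisionRule("CAF-S1", {"FAP": frozenset({"Hi"})}),
    DecisionRule("CAF-S4", {"CD29": frozenset({"Hi"}), "SMA": frozenset({"Hi"})}),
    DecisionRule("CAF-S2", {m: frozenset({"Neg", "Low"}) for m in MARKERS}),
)

DEFAULT_FALLBACK_LABEL = "CAF-S3"


@dataclass
class ThresholdSet:
    """Per-marker quartile cut points plus the ordered decision rules.

    ``quartiles`` is a DataFrame indexed by marker with columns
    ``["Q1", "Mdn", "Q3"]``.  Values below Q1 are Neg, values in [Q1, Mdn)
    are Low, [Mdn, Q3) are Med and values >= Q3 are Hi.  A degenerate marker
    (Q1 == Mdn == Q3) therefore maps every value to Hi, keeping the level
    assignment total.
    """

    quartiles: pd.DataFrame
    rules: tuple[DecisionRule, ...] = DEFAULT_RULES
    fallback_label: str = DEFAULT_FALLBACK_LABEL

    def __post_init__(self) -> None:
        self.quartiles = pd.DataFrame(self.quartiles).astype(float)
        missing = [c for c in ("Q1", "Mdn", "Q3") if c not in self.quartiles.columns]
        if missing:
            raise ValueError(f"quartile table lacks column(s) {missing}")
        self.quartiles = self.quartiles[["Q1", "Mdn", "Q3"]]
        if not np.isfinite(self.quartiles.to_numpy()).all():
            raise ValueError("quartile cut points must be finite")
        q = self.quartiles
        if not ((q["Q1"] <= q["Mdn"]) & (q["Mdn"] <= q["Q3"])).all():
            raise ValueError("expected Q1 <= Mdn <= Q3 for every marker")
        self.rules = tuple(self.rules)

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.quartiles.index)

    def level_of(self, marker: str, value: float) -> str:
        """Discretise one intensity into Neg/Low/Med/Hi."""
        if marker not in self.quartiles.index:
            raise ValueError(f"no thresholds for marker {marker!r}")
        q1, mdn, q3 = self.quartiles.loc[marker]
        if value < q1:
            return "Neg"
        if value < mdn:
            return "Low"
        if value < q3:
            return "Med"
        return "Hi"

    def levels_frame(self, values: pd.DataFrame) -> pd.DataFrame:
        """Vectorised level assignment for a table of intensities."""
        out = {}
        for marker in self.markers:
            if marker not in values.columns:
                raise ValueError(f"input table lacks marker column {marker!r}")
            v = values[marker].to_numpy(dtype=float)
            q1, mdn, q3 = self.quartiles.loc[marker]
            out[marker] = np.select([v < q1, v < mdn, v < q3], ["Neg", "Low", "Med"], "Hi")
        return pd.DataFrame(out, index=values.index)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "quartiles": {m: list(map(float, self.quartiles.loc[m])) for m in self.markers},
            "rules": [
                {"label": r.label, "conditions": {m: sorted(v) for m, v in r.conditions.items()}}
                for r in self.rules
            ],
            "fallback_label": self.fallback_label,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ThresholdSet":
        quart = pd.DataFrame.from_dict(
            payload["quartiles"], orient="index", columns=["Q1", "Mdn", "Q3"]
        )
        rules = tuple(
            DecisionRule(r["label"], {m: frozenset(v) for m, v in r["conditions"].items()})
            for r in payload["rules"]
        )
        return cls(quart, rules, payload.get("fallback_label", DEFAULT_FALLBACK_LABEL))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SpecificMFI:
    """Background-corrected median fluorescence intensity.

    ``specific_value`` is the marker median minus the matched isotype-control
    median; it may legitimately be negative and is reported as-is.
    """

    marker_median: float
    isotype_median: float

    @property
    def specific_value(self) -> float:
        return self.marker_median - self.isotype_median


@dataclass(frozen=True)
class GatingReport:
    """Bookkeeping for lineage gating: which channel removed each event."""

    n_input: int
    n_retained: int
    excluded_per_channel: Mapping[str, int]
    thresholds: Mapping[str, float]

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained


def lineage_thresholds_from_controls(
    controls: pd.DataFrame, percentile: float = 99.0
) -> dict[str, float]:
    """Derive lineage gates as a high percentile of negative-control events."""
    thresholds = {}
    for channel in LINEAGE_CHANNELS:
        if channel not in controls.columns:
            raise ValueError(f"control table lacks lineage channel {channel!r}")
        thresholds[channel] = float(np.percentile(controls[channel].to_numpy(float), percentile))
    return thresholds


def gate_fibroblasts(
    events: pd.DataFrame,
    lineage_thresholds: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, GatingReport]:
    """Sequentially exclude dead, epithelial, hematopoietic and endothelial events.

    Retained events are strictly below the threshold on all four lineage
    channels.  Exclusion is attributed to the first failing channel in the
    order viability -> EPCAM -> CD45 -> CD31, mirroring the usual gating
    hierarchy.
    """
    if lineage_thresholds is None:
        lineage_thresholds = {c: DEFAULT_LINEAGE_THRESHOLD for c in LINEAGE_CHANNELS}
    missing = [c for c in LINEAGE_CHANNELS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks lineage channel(s) {missing}")
    missing_thr = [c for c in LINEAGE_CHANNELS if c not in lineage_thresholds]
    if missing_thr:
        raise ValueError(f"no threshold supplied for lineage channel(s) {missing_thr}")

    keep = np.ones(len(events), dtype=bool)
    excluded: dict[str, int] = {}
    for channel in LINEAGE_CHANNELS:
        positive = events[channel].to_numpy(float) >= lineage_thresholds[channel]
        newly = keep & positive
        excluded[channel] = int(newly.sum())
        keep &= ~positive
    retained = events.loc[keep].copy()
    report = GatingReport(
        n_input=len(events),
        n_retained=len(retained),
        excluded_per_channel=excluded,
        thresholds=dict(lineage_thresholds),
    )
    return retained, report


def derive_thresholds(
    reference: pd.DataFrame | Mapping[str, Sequence[float]],
    rules: tuple[DecisionRule, ...] = DEFAULT_RULES,
    fallback_label: str = DEFAULT_FALLBACK_LABEL,
) -> ThresholdSet:
    """Quartile cut points from pooled reference intensities, one row per marker.

    Quartiles use linear interpolation between order statistics (the numpy
    default), computed on the pooled distribution of each marker across all
    reference cells or tumors.
    """
    if isinstance(reference, pd.DataFrame):
        reference = {m: reference[m].to_numpy(float) for m in reference.columns}
    rows = {}
    for marker, values in reference.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 4:
            raise ValueError(
                f"marker {marker!r} has {arr.size} reference values; quartiles need >= 4"
            )
        if not np.isfinite(arr).all():
            raise ValueError(f"marker {marker!r} has non-finite reference values")
        rows[marker] = np.percentile(arr, [25, 50, 75])
    quart = pd.DataFrame.from_dict(rows, orient="index", columns=["Q1", "Mdn", "Q3"])
    return ThresholdSet(quart, rules, fallback_label)


def classify(marker_vector: Mapping[str, float], thresholds: ThresholdSet) -> str:
    """Assign a CAF subset to one marker-intensity vector."""
    levels = {}
    for rule in thresholds.rules:
        for marker in rule.conditions:
            if marker not in levels:
                if marker not in marker_vector:
                    raise ValueError(f"marker vector lacks {marker!r}")
                levels[marker] = thresholds.level_of(marker, float(marker_vector[marker]))
        if rule.matches(levels):
            return rule.label
    return thresholds.fallback_label


def classify_frame(values: pd.DataFrame, thresholds: ThresholdSet) -> pd.Series:
    """Vectorised :func:`classify` over a table with one row per cell/tile/tumor."""
    needed = sorted({m for r in thresholds.rules for m in r.conditions})
    missing = [m for m in needed if m not in values.columns]
    if missing:
        raise ValueError(f"input table lacks marker column(s) {missing}")
    levels = thresholds.levels_frame(values[[m for m in thresholds.markers if m in values.columns]])
    labels = np.full(len(values), thresholds.fallback_label, dtype=object)
    unassigned = np.ones(len(values), dtype=bool)
    for rule in thresholds.rules:
        mask = unassigned.copy()
        for marker, allowed in rule.conditions.items():
            mask &= np.isin(levels[marker].to_numpy(), list(allowed))
        labels[mask] = rule.label
        unassigned &= ~mask
    return pd.Series(labels, index=values.index, name="label")


def predominant_subset(
    tumor_marker_scores: Mapping[str, float], thresholds: ThresholdSet
) -> str:
    """Predominant CAF subset of one tumor from its per-marker scores.

    Identical to :func:`classify`; the thresholds are expected to come from
    the cohort-wide distribution of the same score type (H-scores or mean
    tile intensities), see :func:`predominant_subsets`.
    """
    return classify(tumor_marker_scores, thresholds)


def predominant_subsets(
    cohort_scores: pd.DataFrame,
    rules: tuple[DecisionRule, ...] = DEFAULT_RULES,
    fallback_label: str = DEFAULT_FALLBACK_LABEL,
) -> tuple[pd.Series, ThresholdSet]:
    """Predominant subset per tumor for a whole cohort of marker scores.

    Thresholds are re-derived from the cohort's own score distribution, so a
    cohort needs at least 4 tumors for the quartiles to exist.
    """
    if len(cohort_scores) < 4:
        raise ValueError("cohort has fewer than 4 tumors; quartiles are undefined")
    thresholds = derive_thresholds(cohort_scores, rules, fallback_label)
    return classify_frame(cohort_scores, thresholds), thresholds


def specific_mfi(
    marker_values: Iterable[float], isotype_values: Iterable[float]
) -> SpecificMFI:
    """Median marker intensity corrected by the matched isotype-control median."""
    marker_arr = np.asarray(list(marker_values), dtype=float)
    isotype_arr = np.asarray(list(isotype_values), dtype=float)
    if marker_arr.size == 0 or isotype_arr.size == 0:
        raise ValueError("specific MFI needs non-empty marker and isotype collections")
    return SpecificMFI(float(np.median(marker_arr)), float(np.median(isotype_arr)))
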