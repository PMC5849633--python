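import numpy as np
import pandas as pd
import pytest

from caftools import (
    EpithelialGeometry,
    FacsSimConfig,
    SurvivalSimConfig,
    TissueSimConfig,
    MARKERS,
    SUBSETS,
    derive_thresholds,
    gen_facs_events,
    gen_tissue,
)


@pytest.fixture(scope="session")
def small_facs_events():
    """Noiseless 4x100-event table: every event sits exactly on its profile."""
    cfg = FacsSimConfig(
        n_events_per_subset={s: 100 for s in SUBSETS}, noise_sd=0.0, seed=11
    )
    return gen_facs_events(cfg)


@pytest.fixture(scope="session")
def noiseless_thresholds(small_facs_events):
    return derive_thresholds(small_facs_events[list(MARKERS)])


@pytest.fixture(scope="session")
def tissue_sample():
    """Noise-free 30x30 tissue with all four subsets and CD3 points."""
    cfg = TissueSimConfig(
        grid_shape=(30, 30),
        epithelial_geometry=EpithelialGeometry(n_blobs=2, radius_range=(3.0, 5.0)),
        marker_noise_sd=0.0,
        seed=7,
    )
    return gen_tissue(cfg)


@pytest.fixture()
def survival_cohort():
    from caftools import gen_survival

    return gen_survival(SurvivalSimConfig(seed=42))


@pytest.fixture()
def level_vector():
    """Helper building a marker->value vector that lands on requested levels."""

    def _make(thresholds, **levels):
        vec = {}
        for marker, level in levels.items():
            q1, mdn, q3 = thresholds.quartiles.loc[marker]
            vec[marker] = {
                "Neg": q1 - max(1.0, abs(q1)),
                "Low": (q1 + mdn) / 2 if mdn > q1 else q1,
                "Med": (mdn + q3) / 2 if q3 > mdn else mdn,
                "Hi": q3 + 1.0,
            }[level]
        return vec

    return _make
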