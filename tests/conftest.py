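"""Shared fixtures: small synthetic cohorts with ground truth.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitfatigue.bout_detection import detect_bouts
from gaitfatigue.synthetic_data import SimConfig, simulate_cohort
from gaitfatigue.windowing import compute_bout_features


@pytest.fixture(scope="session")
def recovery_cohort():
    """Noise-light cohort (5 subjects x 1 day) for detector-recovery checks.

    Bout gaps are floored well above the 2-s merge window so every true
    bout is separable; a four-hour wear window keeps the run short.
    """
    cfg = SimConfig(
        n_subjects=5,
        days=1,
        day_start_h=9.0,
        day_end_h=13.0,
        noise_sd_g=0.005,
        cadence_jitter=0.015,
        missing_frac=0.0,
        flip_probability=0.0,
        seed=42,
    )
    recordings, pro, truth = simulate_cohort(cfg)
    return cfg, recordings, pro, truth


@pytest.fixture(scope="session")
def recovery_products(recovery_cohort):
    """Detected bouts and per-bout gait features for the recovery cohort."""
    _, recordings, _, truth = recovery_cohort
    out = {}
    for rec in recordings:
        bouts = detect_bouts(rec)
        feats = compute_bout_features(rec, bouts)
        out[rec.subject_id] = (rec, bouts, feats)
    return out, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
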