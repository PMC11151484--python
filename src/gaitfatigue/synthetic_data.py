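"""Synthetic cohorts of accelerometer recordings and fatigue diaries.

The study data this package targets (continuous lower-back accelerometry
with momentary physical/mental fatigue diaries) are not publicly
deposited, so every downstream stage is exercised against a generator
with known ground truth: bout boundaries, initial-contact times, step
lengths and the latent gait-fatigue coupling are all recorded.

Signal model (an artifact of this package, chosen so published detector
thresholds are exercised and parameters are recoverable, not a
biomechanical simulation):

* Rest: VV = -1 g plus white noise, ML/AP noise only.
* Walking bouts alternate with rest gaps.  Bout lengths follow a Pareto
  power law with exponent ``bout_length_alpha`` above ``bout_length_xmin``
  (capped at ``bout_length_max`` for realism); gap lengths are lognormal
  with a floor that keeps distinct bouts separable by the detector.
* Within a bout, each step k of duration T_k carries a vertical
  acceleration ``(h_k/2) * omega_k^2 * (cos(theta) - 0.2 cos(2 theta))``
  (theta the step phase, omega_k = 2 pi / T_k), whose double integral has
  a peak-to-trough excursion of exactly h_k; h_k is chosen by inverting
  the inverted-pendulum relation so the injected step length is
  recoverable.  The waveform is symmetric in theta, so the zero-phase
  event-detection chain marks the initial contact exactly at theta = 0
  (the vertical-displacement minimum), where the true IC times are
  placed.  AP and ML carry phase-shifted copies (ML at stride frequency).
* Alternating steps differ in length by ``asymmetry_frac`` (amplitude
  asymmetry); step durations jitter with CV ``cadence_jitter``.
* Whole days are sign-flipped with probability ``flip_probability``;
  ``missing_frac`` of samples are blanked in contiguous blocks placed
  inside rest gaps (device off-body at rest), so bout ground truth stays
  valid and walking + non-walking + missing durations add to the total.
* Diary scores: per bin a response occurs with ``pro_response_prob``; the
  physical-fatigue score is Binomial(6, p) with
  logit p = intercept + subject effect + coupling_beta * z(feature),
  where the feature is the windowed true gait measure (standardised over
  the cohort) for the two hours before the entry.  Mental fatigue uses
  the same form with its own coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .micro_features import PENDULUM_HEIGHT_FRAC
from .recording_io import (
    AccelRecording,
    G_MPS2,
    PRO_BINS,
    SECONDS_PER_DAY,
    Segment,
)

STEP_HARMONIC = -0.2  # relative cos(2 theta) amplitude on VV
AP_REL, ML_REL = 0.4, 0.25


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults follow the protocol the package models: 100 Hz sampling, up
    to four diary bins per day, a heavy-tailed bout-length distribution
    (alpha 1.8 above 5 s) and Likert 0-6 scores from a subject-level
    latent logistic model.
    """

    n_subjects: int = 10
    days: int = 1
    sampling_rate: float = 100.0
    cadence_mean_hz: float = 1.9       # steps per second, across subjects
    cadence_sd_hz: float = 0.12
    cadence_jitter: float = 0.02       # within-subject CV of step duration
    step_length_mean_m: float = 0.65
    step_length_sd_m: float = 0.06
    asymmetry_frac: float = 0.05
    bout_length_alpha: float = 1.8
    bout_length_xmin_s: float = 5.0
    bout_length_max_s: float = 600.0
    nonwalk_lognorm_mu: float = 4.0    # log-seconds
    nonwalk_lognorm_sigma: float = 0.9
    nonwalk_min_s: float = 6.0
    noise_sd_g: float = 0.01
    flip_probability: float = 0.0
    missing_frac: float = 0.0
    pro_bins: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PRO_BINS)
    )
    pro_response_prob: float = 0.9
    coupling_feature: str = "step_velocity"
    coupling_beta: float = 0.0
    mf_coupling_beta: float | None = None
    pro_intercept: float = 0.0
    subject_intercept_sd: float = 0.8
    height_mean_m: float = 1.70
    height_sd_m: float = 0.09
    day_start_h: float = 8.0
    day_end_h: float = 22.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.bout_length_alpha <= 1:
            raise ValueError(
                "bout_length_alpha must exceed 1 (power-law normalisation)"
            )
        if not 0 <= self.flip_probability <= 1:
            raise ValueError("flip_probability must be in [0, 1]")
        if not 0 <= self.missing_frac <= 1:
            raise ValueError("missing_frac must be in [0, 1]")
        for name in ("cadence_sd_hz", "step_length_sd_m", "noise_sd_g",
                     "subject_intercept_sd", "height_sd_m", "cadence_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.day_end_h <= self.day_start_h:
            raise ValueError("day_end_h must exceed day_start_h")


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    height_m: float
    cadence_hz: float
    step_length_m: float
    pro_intercept: float
    bouts: list[tuple[float, float]] = field(default_factory=list)
    ic_times: list[list[float]] = field(default_factory=list)       # per bout
    step_lengths: list[list[float]] = field(default_factory=list)   # per bout
    step_times: list[list[float]] = field(default_factory=list)     # per bout
    flipped_days: list[int] = field(default_factory=list)
    missing_s: float = 0.0

    def all_steps(self) -> pd.DataFrame:
        rows = []
        for b, (ics, lens, times) in enumerate(
            zip(self.ic_times, self.step_lengths, self.step_times)
        ):
            for ic, ln, t in zip(ics[:-1], lens, times):
                rows.append({"bout": b, "ic_s": ic, "length_m": ln, "time_s": t})
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    subjects: dict[str, SubjectTruth] = field(default_factory=dict)
    pro_latent: pd.DataFrame | None = None


def sample_powerlaw(n: int, alpha: float, xmin: float, rng: np.random.Generator,
                    xmax: float | None = None) -> np.ndarray:
    """Continuous Pareto draws: density ∝ x^-alpha above xmin.

    ``xmax`` truncates by redrawing (None for the exact distribution, as
    used by the estimator-consistency checks).
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    out = xmin * rng.uniform(size=n) ** (-1.0 / (alpha - 1.0))
    if xmax is not None:
        for _ in range(100):
            bad = out > xmax
            if not bad.any():
                break
            out[bad] = xmin * rng.uniform(size=int(bad.sum())) ** (-1.0 / (alpha - 1.0))
        out = np.minimum(out, xmax)
    return out


def sample_nonwalk(n: int, mu: float, sigma: float, min_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    return np.maximum(rng.lognormal(mu, sigma, size=n), min_s)


def excursion_for_step_length(step_length_m: np.ndarray, height_m: float) -> np.ndarray:
    """Invert the pendulum relation: h with 2*sqrt(2*l*h - h^2) = length."""
    l = PENDULUM_HEIGHT_FRAC * height_m
    s = np.asarray(step_length_m, dtype=float)
    if np.any(s >= 2 * l):
        raise ValueError("step length exceeds pendulum diameter")
    return l - np.sqrt(l * l - s * s / 4.0)


def _synth_bout(t0: float, length_s: float, cadence: float, jitter: float,
                step_len: float, asym: float, height: float, fs: float,
                rng: np.random.Generator):
    """Per-step waveform of one bout; returns (acc block, ics, lens, times)."""
    n_steps = max(3, int(round(length_s * cadence)))
    mean_T = 1.0 / cadence
    T = mean_T * (1.0 + jitter * rng.standard_normal(n_steps))
    T = np.clip(T, 0.5 * mean_T, 1.5 * mean_T)
    ic = t0 + np.concatenate([[0.0], np.cumsum(T)])
    lens = step_len * (1.0 + np.where(np.arange(n_steps) % 2 == 0, 1, -1) * asym / 2.0)
    h = excursion_for_step_length(lens, height)

    i0 = int(np.ceil(t0 * fs))
    i1 = int(np.floor(ic[-1] * fs))
    t = np.arange(i0, i1) / fs
    k = np.clip(np.searchsorted(ic, t, side="right") - 1, 0, n_steps - 1)
    theta = 2 * np.pi * (t - ic[k]) / T[k]
    omega = 2 * np.pi / T[k]
    amp = (h[k] / 2.0) * omega ** 2 / G_MPS2  # g
    vv = amp * (np.cos(theta) + STEP_HARMONIC * np.cos(2 * theta))
    ap = -AP_REL * amp * np.sin(theta)
    ml = ML_REL * amp * np.cos(theta / 2.0 + k * np.pi)
    acc = np.column_stack([vv, ml, ap]).astype(np.float32)
    return i0, acc, ic.tolist(), lens.tolist(), T.tolist()


def simulate_subject(cfg: SimConfig, subject_id: str, rng: np.random.Generator
                     ) -> tuple[AccelRecording, SubjectTruth]:
    fs = cfg.sampling_rate
    height = max(1.4, cfg.height_mean_m + cfg.height_sd_m * rng.standard_normal())
    cadence = float(np.clip(
        cfg.cadence_mean_hz + cfg.cadence_sd_hz * rng.standard_normal(), 1.2, 2.6))
    step_len = float(np.clip(
        cfg.step_length_mean_m + cfg.step_length_sd_m * rng.standard_normal(),
        0.35, 0.9))
    truth = SubjectTruth(
        subject_id=subject_id,
        height_m=height,
        cadence_hz=cadence,
        step_length_m=step_len,
        pro_intercept=float(cfg.subject_intercept_sd * rng.standard_normal()),
    )
    segments = []
    for day in range(cfg.days):
        day0 = day * SECONDS_PER_DAY
        start = day0 + cfg.day_start_h * 3600.0
        end = day0 + cfg.day_end_h * 3600.0
        n = int(round((end - start) * fs))
        acc = np.zeros((n, 3), dtype=np.float32)
        acc[:, 0] = -1.0

        cursor = start + float(sample_nonwalk(
            1, cfg.nonwalk_lognorm_mu, cfg.nonwalk_lognorm_sigma,
            cfg.nonwalk_min_s, rng)[0])
        while True:
            length = float(sample_powerlaw(
                1, cfg.bout_length_alpha, cfg.bout_length_xmin_s, rng,
                cfg.bout_length_max_s)[0])
            if cursor + length + cfg.nonwalk_min_s > end:
                break
            i0, block, ic, lens, times = _synth_bout(
                cursor, length, cadence, cfg.cadence_jitter, step_len,
                cfg.asymmetry_frac, height, fs, rng)
            j0 = i0 - int(round(start * fs))
            block = block[: max(n - j0, 0)]
            acc[j0:j0 + len(block)] += block
            truth.bouts.append((float(ic[0]), float(ic[-1])))
            truth.ic_times.append(ic)
            truth.step_lengths.append(lens)
            truth.step_times.append(times)
            gap = float(sample_nonwalk(
                1, cfg.nonwalk_lognorm_mu, cfg.nonwalk_lognorm_sigma,
                cfg.nonwalk_min_s, rng)[0])
            cursor = ic[-1] + gap
        if cfg.noise_sd_g > 0:
            acc += rng.normal(0.0, cfg.noise_sd_g, size=acc.shape).astype(np.float32)
        if rng.uniform() < cfg.flip_probability:
            acc = -acc
            truth.flipped_days.append(day)
        segments.append(Segment(start, acc))

    if cfg.missing_frac > 0:
        truth.missing_s = _blank_missing(cfg, segments, truth, rng)
    rec = AccelRecording(subject_id, fs, segments, height_m=height)
    return rec, truth


def _blank_missing(cfg: SimConfig, segments: list[Segment], truth: SubjectTruth,
                   rng: np.random.Generator) -> float:
    """Blank contiguous blocks inside rest gaps until missing_frac is met."""
    fs = cfg.sampling_rate
    total = sum(s.n_samples for s in segments)
    target = int(cfg.missing_frac * total)
    blanked = 0
    margin = int(1.0 * fs)  # keep 1 s of rest on either side of a block
    for seg in segments:
        if blanked >= target:
            break
        end_s = seg.start_s + seg.n_samples / fs
        edges = [seg.start_s] + [t for b in truth.bouts for t in b
                                 if seg.start_s <= t <= end_s] + [end_s]
        gaps = [(edges[i], edges[i + 1]) for i in range(0, len(edges) - 1, 2)]
        for lo, hi in sorted(gaps, key=lambda g: g[0] - g[1]):
            i0 = int((lo - seg.start_s) * fs) + margin
            i1 = int((hi - seg.start_s) * fs) - margin
            if i1 - i0 < fs:
                continue
            take = min(i1 - i0, target - blanked)
            seg.acc[i0:i0 + take] = np.nan
            blanked += take
            if blanked >= target:
                break
    return blanked / fs


def true_window_feature(truth: SubjectTruth, pro_timestamp: float,
                        feature: str = "step_velocity",
                        window_s: float = 7200.0) -> float:
    """Mean true gait measure over steps whose IC lies in the pre-entry window."""
    values = []
    for ics, lens, times in zip(truth.ic_times, truth.step_lengths, truth.step_times):
        ic = np.asarray(ics[:-1])
        sel = (ic >= pro_timestamp - window_s) & (ic < pro_timestamp)
        if not sel.any():
            continue
        lens_a, times_a = np.asarray(lens)[sel], np.asarray(times)[sel]
        if feature == "step_velocity":
            values.append(lens_a / times_a)
        elif feature == "step_length":
            values.append(lens_a)
        elif feature == "step_time":
            values.append(times_a)
        else:
            raise KeyError(feature)
    if not values:
        return np.nan
    return float(np.concatenate(values).mean())


def simulate_cohort(cfg: SimConfig
                    ) -> tuple[list[AccelRecording], pd.DataFrame, GroundTruth]:
    """Generate recordings, a diary table and the ground truth for a cohort.

    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    recordings, truths = [], {}
    for s in range(cfg.n_subjects):
        sid = f"S{s:03d}"
        rec, truth = simulate_subject(cfg, sid, rng)
        recordings.append(rec)
        truths[sid] = truth

    # diary entries with latent coupling to the windowed true gait feature
    rows = []
    for rec in recordings:
        truth = truths[rec.subject_id]
        for day in range(cfg.days):
            day0 = day * SECONDS_PER_DAY
            for name, (lo, hi) in cfg.pro_bins.items():
                lo_c = max(lo, cfg.day_start_h)
                hi_c = min(hi, cfg.day_end_h)
                if hi_c <= lo_c or rng.uniform() >= cfg.pro_response_prob:
                    continue
                ts = day0 + rng.uniform(lo_c, hi_c) * 3600.0
                rows.append({
                    "subject_id": rec.subject_id,
                    "timestamp": ts,
                    "bin": name,
                    "x_true": true_window_feature(truth, ts, cfg.coupling_feature),
                })
    pro = pd.DataFrame(rows)
    if pro.empty:
        return recordings, pd.DataFrame(
            columns=["subject_id", "timestamp", "bin", "pf_score", "mf_score"]
        ), GroundTruth(truths, pro)

    x = pro["x_true"].to_numpy()
    mu, sd = np.nanmean(x), np.nanstd(x)
    z = np.where(np.isfinite(x), (x - mu) / sd if sd > 0 else 0.0, 0.0)
    intercepts = pro["subject_id"].map(
        {sid: t.pro_intercept for sid, t in truths.items()}).to_numpy()
    beta_mf = cfg.coupling_beta if cfg.mf_coupling_beta is None else cfg.mf_coupling_beta
    p_pf = expit(cfg.pro_intercept + intercepts + cfg.coupling_beta * z)
    p_mf = expit(cfg.pro_intercept + intercepts + beta_mf * z)
    pro["pf_score"] = rng.binomial(6, p_pf)
    pro["mf_score"] = rng.binomial(6, p_mf)
    pro["latent_z"] = z
    table = pro[["subject_id", "timestamp", "bin", "pf_score", "mf_score"]].copy()
    truth_all = GroundTruth(truths, pro)
    return recordings, table, truth_all


def simulate_association_table(
    n_subjects: int,
    n_per_subject: int,
    coupling_beta: float,
    subject_intercept_sd: float,
    rng: np.random.Generator | int,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Feature/score table straight from the latent diary model.

    Bypasses signal synthesis for calibration studies of the association
    stage: x ~ N(0,1) per entry, score ~ Binomial(6, logit^-1(intercept +
    subject effect + beta * x)).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    subj = np.repeat(np.arange(n_subjects), n_per_subject)
    a = subject_intercept_sd * rng.standard_normal(n_subjects)
    x = rng.standard_normal(subj.size)
    p = expit(intercept + a[subj] + coupling_beta * x)
    y = rng.binomial(6, p)
    return pd.DataFrame({
        "subject_id": [f"S{s:03d}" for s in subj],
        "x": x,
        "score": y,
    })


def write_cohort(out_dir, recordings, pro_table, truth: GroundTruth) -> None:
    """Write cohort CSVs plus a ground-truth JSON sidecar per subject."""
    from .recording_io import write_pro_table, write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, out / f"{rec.subject_id}_acc.csv")
        st = truth.subjects[rec.subject_id]
        with open(out / f"{rec.subject_id}_truth.json", "w") as fh:
            json.dump(asdict(st), fh)
    write_pro_table(pro_table, out / "pro.csv")
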