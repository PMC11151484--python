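"""Step-level spatiotemporal gait measures and their per-bout summaries.

Temporal measures come straight from the IC/FC sequence:

    stance_i = FC_{i+1} - IC_i
    stride_i = IC_{i+2} - IC_i
    swing_i  = stride_i - stance_i
    step_i   = IC_{i+1} - IC_i

Step length uses the inverted-pendulum model: the vertical excursion h of
the centre of mass between consecutive ICs, together with a pendulum
length l of 53% of the subject's height, gives

    step length = 2 * sqrt(2*l*h - h^2)

with h obtained by double integration of the vertical acceleration,
highpass filtered at 0.1 Hz after each stage to suppress integration
drift.  Step velocity is step length over step time.

Per bout, the measures are grouped into pace, rhythm, variability (SD over
valid steps), asymmetry (absolute difference of left- and right-foot
means) and postural control (step-length asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .gait_events import GaitEventSeries
from .recording_io import G_MPS2

PENDULUM_HEIGHT_FRAC = 0.53
DRIFT_HIGHPASS_ORDER = 4
DRIFT_HIGHPASS_CUTOFF_HZ = 0.1

#: per-bout micro measures by gait-model group
MICRO_GROUPS = {
    "pace": ["step_velocity_mps", "step_length_m", "swing_sd_s"],
    "rhythm": ["stance_s", "swing_s", "step_s", "stride_s"],
    "variability": [
        "step_sd_s",
        "stance_sd_s",
        "step_velocity_sd_mps",
        "step_length_sd_m",
        "stride_sd_s",
    ],
    "asymmetry": ["step_asym_s", "swing_asym_s", "stance_asym_s"],
    "postural_control": ["step_length_asym_m"],
}


@dataclass
class StepMeasures:
    """Per-step quantities of one bout, aligned to consecutive IC pairs."""

    table: pd.DataFrame  # columns step_s, stride_s, stance_s, swing_s,
    #                      step_length_m, step_velocity_mps, foot, valid

    def valid(self) -> pd.DataFrame:
        return self.table[self.table["valid"]]


def temporal_params(events: GaitEventSeries) -> pd.DataFrame:
    """Step, stride, stance and swing times from an IC/FC sequence.

    One row per step (consecutive IC pair).  The last step has no stride
    (needs IC_{i+2}); strides with a missing FC have NaN stance/swing.
    Fewer than 3 ICs yield an empty frame.
    """
    ic, fc = events.ic_times, events.fc_times
    n = len(ic) - 1
    if n < 2:
        return pd.DataFrame(
            columns=["step_s", "stride_s", "stance_s", "swing_s", "foot"]
        )
    step = np.diff(ic)
    stride = np.full(n, np.nan)
    stride[: n - 1] = ic[2:] - ic[:-2]
    stance = np.full(n, np.nan)
    stance[:] = fc[1:] - ic[:-1]
    swing = stride - stance
    return pd.DataFrame(
        {
            "step_s": step,
            "stride_s": stride,
            "stance_s": stance,
            "swing_s": swing,
            "foot": events.foot[:-1],
        }
    )


def vertical_displacement(acc_vv_g: np.ndarray, fs: float) -> np.ndarray:
    """Vertical position (m) by double integration of VV acceleration.

    The gravity-free acceleration (mean removed) is integrated twice with
    a zero-phase 0.1 Hz Butterworth highpass after each stage.
    """
    a = (np.asarray(acc_vv_g, dtype=float) - np.nanmean(acc_vv_g)) * G_MPS2
    b, coef_a = butter(DRIFT_HIGHPASS_ORDER, DRIFT_HIGHPASS_CUTOFF_HZ / (fs / 2.0), "high")
    padlen = 3 * max(len(b), len(coef_a))
    v = cumulative_trapezoid(a, dx=1.0 / fs, initial=0.0)
    if v.size > padlen:
        v = filtfilt(b, coef_a, v)
    z = cumulative_trapezoid(v, dx=1.0 / fs, initial=0.0)
    if z.size > padlen:
        z = filtfilt(b, coef_a, z)
    return z


def step_length_from_excursion(h: np.ndarray, height_m: float) -> np.ndarray:
    """Inverted-pendulum step length 2*sqrt(2*l*h - h^2), l = 0.53*height.

    h beyond the model's range (h >= l) is flagged invalid (NaN); the
    radicand stays positive up to h < 2l but h >= l already means the
    pendulum geometry is violated.
    """
    l = PENDULUM_HEIGHT_FRAC * height_m
    h = np.asarray(h, dtype=float)
    out = np.full(h.shape, np.nan)
    ok = (h >= 0) & (h < l)
    out[ok] = 2.0 * np.sqrt(2.0 * l * h[ok] - h[ok] ** 2)
    return out


def step_length_and_velocity(
    acc_vv_g: np.ndarray,
    fs: float,
    events: GaitEventSeries,
    height_m: float,
) -> pd.DataFrame:
    """Per-step length and velocity for one bout.

    ``acc_vv_g`` are the bout's VV samples; IC times in ``events`` are
    absolute, so they are shifted by the bout start before indexing.
    """
    ic_rel = events.ic_times - events.bout.start_s
    n = len(ic_rel) - 1
    if n < 1:
        return pd.DataFrame(columns=["step_length_m", "step_velocity_mps", "h_m"])
    z = vertical_displacement(acc_vv_g, fs)
    idx = np.clip(np.round(ic_rel * fs).astype(int), 0, len(z) - 1)
    h = np.full(n, np.nan)
    for i in range(n):
        chunk = z[idx[i]: idx[i + 1] + 1]
        if chunk.size >= 2:
            h[i] = chunk.max() - chunk.min()
    length = step_length_from_excursion(h, height_m)
    step_t = np.diff(events.ic_times)
    with np.errstate(invalid="ignore", divide="ignore"):
        velocity = length / step_t
    return pd.DataFrame({"step_length_m": length, "step_velocity_mps": velocity, "h_m": h})


def combine_step_measures(temporal: pd.DataFrame, spatial: pd.DataFrame,
                          valid_mask: np.ndarray) -> StepMeasures:
    table = temporal.copy()
    for col in ("step_length_m", "step_velocity_mps"):
        table[col] = spatial[col].to_numpy() if col in spatial else np.nan
    table["valid"] = np.asarray(valid_mask, dtype=bool)[: len(table)]
    return StepMeasures(table)


def _sd(x: pd.Series | np.ndarray) -> float:
    x = pd.Series(x).dropna()
    return float(x.std(ddof=1)) if len(x) >= 2 else np.nan


def _asym(values: pd.Series, foot: pd.Series) -> float:
    left = values[foot == "L"].dropna()
    right = values[foot == "R"].dropna()
    if left.empty or right.empty:
        return np.nan
    return float(abs(left.mean() - right.mean()))


def variability_and_asymmetry(steps: StepMeasures) -> dict[str, float]:
    """The 16 per-bout micro measures over the bout's valid steps.

    Variability is the SD of a measure over the valid steps (missing when
    fewer than two contribute); asymmetry is |mean(left) - mean(right)|
    (missing when either foot is absent), making it invariant to a global
    swap of the foot labels.
    """
    v = steps.valid()
    foot = v["foot"] if "foot" in v else pd.Series(dtype="U1")
    out = {
        "step_velocity_mps": float(v["step_velocity_mps"].mean()) if len(v) else np.nan,
        "step_length_m": float(v["step_length_m"].mean()) if len(v) else np.nan,
        "swing_sd_s": _sd(v["swing_s"]) if len(v) else np.nan,
        "stance_s": float(v["stance_s"].mean()) if len(v) else np.nan,
        "swing_s": float(v["swing_s"].mean()) if len(v) else np.nan,
        "step_s": float(v["step_s"].mean()) if len(v) else np.nan,
        "stride_s": float(v["stride_s"].mean()) if len(v) else np.nan,
        "step_sd_s": _sd(v["step_s"]) if len(v) else np.nan,
        "stance_sd_s": _sd(v["stance_s"]) if len(v) else np.nan,
        "step_velocity_sd_mps": _sd(v["step_velocity_mps"]) if len(v) else np.nan,
        "step_length_sd_m": _sd(v["step_length_m"]) if len(v) else np.nan,
        "stride_sd_s": _sd(v["stride_s"]) if len(v) else np.nan,
        "step_asym_s": _asym(v["step_s"], foot) if len(v) else np.nan,
        "swing_asym_s": _asym(v["swing_s"], foot) if len(v) else np.nan,
        "stance_asym_s": _asym(v["stance_s"], foot) if len(v) else np.nan,
        "step_length_asym_m": _asym(v["step_length_m"], foot) if len(v) else np.nan,
    }
    return out


def micro_group_of(measure: str) -> str:
    for group, members in MICRO_GROUPS.items():
        if measure in members:
            return group
    raise KeyError(measure)
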