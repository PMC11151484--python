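"""Activity-level (macro) gait measures over a pre-diary window.

Volumes count walking and non-walking bouts and their lengths; the
pattern group holds the power-law alpha parameter of the walking bout
lengths and the mean walking/non-walking times; variability is the
lognormal maximum-likelihood shape of the bout lengths (S2W walking,
S2S non-walking); vector magnitude is the per-sample Euclidean norm of
the three axes.

The alpha parameter is the maximum-likelihood exponent of a power law
fitted to the bout lengths x_i above x_min = min(x_i):

    alpha = 1 + n / sum(ln(x_i / x_min))

Bout-length variability S2 is the maximum-likelihood estimate of the
lognormal shape parameter, sqrt(mean((ln x - mean ln x)^2)) (population
form), which is invariant to rescaling the lengths.
"""

from __future__ import annotations

import logging

import numpy as np

from .bout_detection import Bout
from .recording_io import AccelRecording, G_MPS2

logger = logging.getLogger(__name__)

WALK_LONG_BOUT_MIN_S = 10 * 60.0
NONWALK_LONG_BOUT_MIN_S = (20 * 60.0, 30 * 60.0, 50 * 60.0)


def alpha_parameter(bout_lengths_s) -> float:
    """Power-law MLE exponent of a bout-length sample; NaN if undefined."""
    x = np.asarray(bout_lengths_s, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or (x <= 0).any():
        return np.nan
    xmin = x.min()
    total = np.log(x / xmin).sum()
    if total <= 0:
        logger.info("alpha undefined: all %d bout lengths equal", x.size)
        return np.nan
    return 1.0 + x.size / total


def bout_length_variability(bout_lengths_s) -> float:
    """Lognormal MLE shape parameter (S2) of a bout-length sample."""
    x = np.asarray(bout_lengths_s, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2 or (x <= 0).any():
        return np.nan
    logs = np.log(x)
    return float(np.sqrt(np.mean((logs - logs.mean()) ** 2)))


def vector_magnitude(acc: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(VV^2 + ML^2 + AP^2)."""
    acc = np.asarray(acc, dtype=float)
    return np.sqrt((acc ** 2).sum(axis=-1))


def window_vector_magnitude(rec: AccelRecording, start_s: float, end_s: float,
                            in_mps2: bool = True) -> np.ndarray:
    """Vector-magnitude series over [start_s, end_s), skipping gaps.

    Computed over all samples in the window (walking and non-walking),
    reported in m/s² by default to match the conventional unit.
    """
    fs = rec.sampling_rate
    parts = []
    for seg in rec.segments:
        lo = max(start_s, seg.start_s)
        hi = min(end_s, seg.end_s(fs))
        if hi <= lo:
            continue
        i0 = int(np.ceil((lo - seg.start_s) * fs - 1e-9))
        i1 = int(np.ceil((hi - seg.start_s) * fs - 1e-9))
        chunk = seg.acc[i0:i1]
        chunk = chunk[np.isfinite(chunk).all(axis=1)]
        if chunk.size:
            parts.append(vector_magnitude(chunk))
    if not parts:
        return np.array([])
    vm = np.concatenate(parts)
    return vm * G_MPS2 if in_mps2 else vm


def volume_and_pattern(bouts: list[Bout], steps_per_bout: dict[int, int] | None = None
                       ) -> dict[str, object]:
    """Scalar macro measures and pooled series for one window's bouts.

    ``steps_per_bout`` maps the index of each walking bout (position in
    ``bouts``) to its detected step count.  Returns scalars plus the raw
    bout-length series (pooled by the windowing stage, mean excluded there
    because the means already live in the pattern group).
    """
    walking = [b for b in bouts if b.kind == "walking"]
    nonwalk = [b for b in bouts if b.kind == "non_walking"]
    w_len = np.array([b.length_s for b in walking])
    n_len = np.array([b.length_s for b in nonwalk])
    steps = []
    if steps_per_bout is not None:
        steps = [steps_per_bout[i] for i, b in enumerate(bouts)
                 if b.kind == "walking" and i in steps_per_bout]
    out: dict[str, object] = {
        "walking_volume__steps_in_bouts": np.asarray(steps, dtype=float),
        "walking_volume__bout_length_s": w_len,
        "walking_volume__n_walking_bouts": float(len(walking)),
        "walking_volume__n_bouts_ge_10min": float((w_len >= WALK_LONG_BOUT_MIN_S).sum()),
        "nonwalking_volume__bout_length_s": n_len,
        "pattern__alpha": alpha_parameter(w_len),
        "pattern__mean_walking_time_s": float(w_len.mean()) if w_len.size else np.nan,
        "pattern__mean_nonwalking_time_s": float(n_len.mean()) if n_len.size else np.nan,
        "variability__s2w": bout_length_variability(w_len),
        "variability__s2s": bout_length_variability(n_len),
    }
    for thresh, label in zip(NONWALK_LONG_BOUT_MIN_S, ("20", "30", "50")):
        out[f"nonwalking_volume__n_bouts_ge_{label}min"] = float((n_len >= thresh).sum())
    return out
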