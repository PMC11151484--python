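"""Initial- and final-contact detection within walking bouts.

The vertical (VV) acceleration of a bout is linearly detrended, mean
normalised, lowpass filtered (4th-order Butterworth, 20 Hz, zero phase),
integrated (cumulative trapezoid) and then differentiated with a Gaussian
first-derivative continuous wavelet transform, which acts as a smoothed
differentiator at step-frequency scale.  Initial contacts (IC, heel
strike) are the retained local minima of this signal; final contacts (FC,
toe off) are the retained local maxima of a further CWT differentiation.

Peaks are thresholded against the mean of their own kind: minima must
reach 0.4x the mean minimum depth, maxima 0.25x the mean maximum height,
both measured relative to the mean of the transformed signal.

Feet alternate from the first IC of each bout, which is labelled right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, detrend, filtfilt, find_peaks

from .bout_detection import Bout

logger = logging.getLogger(__name__)

EVENT_LOWPASS_ORDER = 4
EVENT_LOWPASS_CUTOFF_HZ = 20.0
IC_DEPTH_FACTOR = 0.4
FC_HEIGHT_FACTOR = 0.25
PEAK_NOISE_FLOOR = 1e-8  # discard float-precision dust on flat signals
MIN_STEPS_PER_BOUT = 3
INITIATION_HEAD = 3  # steps masked at bout start
INITIATION_TAIL = 5  # steps masked at bout end
STEP_TIME_BOUNDS_S = (0.25, 1.25)
STEP_LENGTH_BOUNDS_M = (0.23, 0.95)
SWING_TIME_BOUNDS_S = (0.23, 0.95)


@dataclass
class GaitEventSeries:
    """Ordered IC/FC times of one bout with foot labels and a step mask.

    ``fc_times`` is aligned so that ``fc_times[i+1]`` is the first detected
    FC inside (IC_i, IC_{i+1}); stance time of step i is then
    ``fc_times[i+1] - ic_times[i]``.  ``fc_times[0]`` is NaN unless an FC
    precedes the first IC.  ``valid_step_mask`` has one entry per step
    (consecutive IC pair) and is refined by :func:`apply_step_exclusions`.
    """

    bout: Bout
    ic_times: np.ndarray
    fc_times: np.ndarray
    foot: np.ndarray = field(default_factory=lambda: np.array([], dtype="U1"))
    valid_step_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_steps(self) -> int:
        return max(len(self.ic_times) - 1, 0)


def _cwt_diff(x: np.ndarray, scale: float, fs: float) -> np.ndarray:
    coef, _ = pywt.cwt(x, [scale], "gaus1", sampling_period=1.0 / fs)
    return coef[0]


def detect_ic_fc(acc_vv: np.ndarray, fs: float, bout: Bout,
                 scale: float | None = None) -> GaitEventSeries:
    """Detect IC/FC events in a walking bout's VV acceleration.

    ``acc_vv`` are the bout's vertical-axis samples in g; times in the
    returned series are absolute (``bout.start_s`` + offset).  ``scale`` is
    the CWT scale in samples (default ``fs / 10``).  A bout too short for a
    stable filter response yields an empty series.
    """
    if scale is None:
        scale = fs / 10.0
    b, a = butter(EVENT_LOWPASS_ORDER, EVENT_LOWPASS_CUTOFF_HZ / (fs / 2.0))
    padlen = 3 * max(len(a), len(b))
    if acc_vv.size <= padlen or not np.isfinite(acc_vv).all():
        logger.info("bout at %.1f s too short or invalid for event detection", bout.start_s)
        return GaitEventSeries(bout, np.array([]), np.array([]))
    y = detrend(acc_vv.astype(float))
    y -= y.mean()
    y = filtfilt(b, a, y)
    v = cumulative_trapezoid(y, dx=1.0 / fs, initial=0.0)
    c1 = _cwt_diff(v, scale, fs)
    m1 = c1 - c1.mean()
    ic_idx, _ = find_peaks(-m1)
    depths = -m1[ic_idx]
    ic_idx = ic_idx[depths > PEAK_NOISE_FLOOR]
    depths = depths[depths > PEAK_NOISE_FLOOR]
    if depths.size:
        ic_idx = ic_idx[depths >= IC_DEPTH_FACTOR * depths.mean()]
    c2 = _cwt_diff(c1, scale, fs)
    m2 = c2 - c2.mean()
    fc_idx, _ = find_peaks(m2)
    heights = m2[fc_idx]
    fc_idx = fc_idx[heights > PEAK_NOISE_FLOOR]
    heights = heights[heights > PEAK_NOISE_FLOOR]
    if heights.size:
        fc_idx = fc_idx[heights >= FC_HEIGHT_FACTOR * heights.mean()]

    ic = bout.start_s + ic_idx / fs
    fc_raw = bout.start_s + fc_idx / fs
    fc = _align_fc(ic, fc_raw)
    events = GaitEventSeries(
        bout,
        ic,
        fc,
        valid_step_mask=np.ones(max(len(ic) - 1, 0), dtype=bool),
    )
    return assign_feet(events)


def _align_fc(ic: np.ndarray, fc_raw: np.ndarray) -> np.ndarray:
    """Index FCs so that fc[i+1] is the first raw FC in (IC_i, IC_{i+1})."""
    fc = np.full(len(ic), np.nan)
    if len(ic) == 0:
        return fc
    before = fc_raw[fc_raw < ic[0]]
    if before.size:
        fc[0] = before[-1]
    for i in range(len(ic) - 1):
        cand = fc_raw[(fc_raw > ic[i]) & (fc_raw < ic[i + 1])]
        if cand.size:
            fc[i + 1] = cand[0]
    return fc


def assign_feet(events: GaitEventSeries) -> GaitEventSeries:
    """Label ICs right, left, right, ... from the first IC of the bout."""
    n = len(events.ic_times)
    events.foot = np.array(["R" if i % 2 == 0 else "L" for i in range(n)], dtype="U1")
    return events


def apply_step_exclusions(
    events: GaitEventSeries,
    step_times: np.ndarray,
    step_lengths: np.ndarray | None = None,
    swing_times: np.ndarray | None = None,
) -> GaitEventSeries | None:
    """Apply bout-level and step-level exclusions, in the published order.

    1. bouts with fewer than three detected steps are removed (None);
    2. gait initiation: the first three and last five steps are masked;
    3. outliers: steps with step time outside (0.25, 1.25) s, step length
       outside (0.23, 0.95) m, or stride swing time outside (0.23, 0.95) s
       are masked (bounds inclusive).

    ``step_lengths``/``swing_times`` may be None when unavailable; NaN
    entries do not trigger the outlier mask (they are handled downstream as
    missing measures).
    """
    n_steps = events.n_steps
    if n_steps < MIN_STEPS_PER_BOUT:
        return None
    mask = np.ones(n_steps, dtype=bool)
    mask[:INITIATION_HEAD] = False
    mask[n_steps - INITIATION_TAIL:] = False

    def _outliers(values: np.ndarray | None, lo: float, hi: float) -> None:
        if values is None:
            return
        v = np.asarray(values, dtype=float)[:n_steps]
        with np.errstate(invalid="ignore"):
            bad = (v <= lo) | (v >= hi)  # NaN compares False: stays unmasked
        mask[: len(v)] &= ~bad

    _outliers(step_times, *STEP_TIME_BOUNDS_S)
    _outliers(step_lengths, *STEP_LENGTH_BOUNDS_M)
    _outliers(swing_times, *SWING_TIME_BOUNDS_S)
    events.valid_step_mask = mask
    return events
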