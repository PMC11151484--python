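"""Walking-bout identification from windowed threshold conditions.

The recording is lowpass filtered (2nd-order Butterworth, 17 Hz, zero
phase) and cut into non-overlapping 0.1-s windows.  A window is *active*
(upright and moving) iff

    sigma_VV + sigma_ML + sigma_AP >= 0.05 g          (movement)
    mean(Acc_VV) <= -0.77 g                            (upright)

where the SDs are taken per window on the filtered signal and the VV mean
on the filtered, gravity-retaining signal.  Runs of active windows
separated by fewer than 20 inactive windows (2 s) are merged; merged runs
shorter than 20 windows are excluded.  The complement of the retained
walking bouts within valid (non-missing) data forms the non-walking bouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .recording_io import AccelRecording, Segment

WINDOW_S = 0.1
SD_SUM_MIN_G = 0.05
VV_MEAN_MAX_G = -0.77
MIN_BOUT_WINDOWS = 20
MERGE_GAP_WINDOWS = 20
LOWPASS_ORDER = 2
LOWPASS_CUTOFF_HZ = 17.0


@dataclass
class Bout:
    """A half-open interval of windows labelled walking or non-walking."""

    start_s: float
    end_s: float
    kind: str  # "walking" | "non_walking"
    start_window: int | None = None
    end_window: int | None = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("bout must have positive length")
        if self.kind not in ("walking", "non_walking"):
            raise ValueError(f"unknown bout kind {self.kind!r}")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


def lowpass(acc: np.ndarray, fs: float, cutoff: float = LOWPASS_CUTOFF_HZ,
            order: int = LOWPASS_ORDER) -> np.ndarray:
    """Zero-phase Butterworth lowpass, NaN runs left untouched."""
    b, a = butter(order, cutoff / (fs / 2.0))
    out = np.array(acc, dtype=float, copy=True)
    finite = np.isfinite(acc).all(axis=1) if acc.ndim == 2 else np.isfinite(acc)
    padlen = 3 * max(len(a), len(b))
    for start, stop in _runs(finite):
        if stop - start > padlen:
            out[start:stop] = filtfilt(b, a, acc[start:stop], axis=0)
    return out


def _runs(mask: np.ndarray):
    """(start, stop) pairs of the True runs of a boolean mask."""
    idx = np.flatnonzero(np.diff(np.r_[False, mask, False].astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def flag_active_windows(acc: np.ndarray, fs: float) -> np.ndarray:
    """Boolean activity flag per 0.1-s window of one contiguous segment.

    Windows that contain any non-finite sample are inactive by definition.
    A segment shorter than one window yields an empty result.
    """
    w = int(round(WINDOW_S * fs))
    n_win = acc.shape[0] // w
    if n_win == 0:
        return np.zeros(0, dtype=bool)
    filt = lowpass(acc, fs)
    blocks = filt[: n_win * w].reshape(n_win, w, 3)
    with np.errstate(invalid="ignore"):
        sd_sum = blocks.std(axis=1, ddof=0).sum(axis=1)
        vv_mean = blocks[:, :, 0].mean(axis=1)
    active = (sd_sum >= SD_SUM_MIN_G) & (vv_mean <= VV_MEAN_MAX_G)
    active &= np.isfinite(blocks).all(axis=(1, 2))
    return active


def assemble_bouts(active: np.ndarray, fs: float, segment_start_s: float = 0.0,
                   valid: np.ndarray | None = None) -> list[Bout]:
    """Merge active runs into walking bouts and label the complement.

    Runs separated by an inactive gap of fewer than ``MERGE_GAP_WINDOWS``
    windows are merged left-to-right (iterated to a fixpoint; a single pass
    reaches it since merging never widens the remaining gaps).  Gaps of
    exactly 20 windows are not merged and bouts of exactly 20 windows are
    retained.  Merged runs shorter than ``MIN_BOUT_WINDOWS`` are dropped.
    ``valid`` marks windows with usable data (defaults to all); non-walking
    bouts are emitted only over valid windows.
    """
    if valid is None:
        valid = np.ones_like(active, dtype=bool)
    runs = _runs(active)
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < MERGE_GAP_WINDOWS:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    walking = [(s, e) for s, e in merged if e - s >= MIN_BOUT_WINDOWS]

    bouts = [
        Bout(
            start_s=segment_start_s + s * WINDOW_S,
            end_s=segment_start_s + e * WINDOW_S,
            kind="walking",
            start_window=s,
            end_window=e,
        )
        for s, e in walking
    ]
    # complement within valid windows
    in_walk = np.zeros_like(active, dtype=bool)
    for s, e in walking:
        in_walk[s:e] = True
    for s, e in _runs(valid & ~in_walk):
        bouts.append(
            Bout(
                start_s=segment_start_s + s * WINDOW_S,
                end_s=segment_start_s + e * WINDOW_S,
                kind="non_walking",
                start_window=int(s),
                end_window=int(e),
            )
        )
    bouts.sort(key=lambda b: b.start_s)
    return bouts


def detect_bouts(rec: AccelRecording) -> list[Bout]:
    """Walking/non-walking bouts for every segment of a recording.

    Bouts never span the gaps between segments.
    """
    w = int(round(WINDOW_S * rec.sampling_rate))
    out: list[Bout] = []
    for seg in rec.segments:
        active = flag_active_windows(seg.acc, rec.sampling_rate)
        n_win = active.size
        if n_win == 0:
            continue
        finite = np.isfinite(seg.acc[: n_win * w]).all(axis=1)
        valid = finite.reshape(n_win, w).all(axis=1)
        out.extend(assemble_bouts(active, rec.sampling_rate, seg.start_s, valid))
    return out


def bouts_before_pro(bouts: list[Bout], pro_timestamp: float,
                     window_s: float = 7200.0) -> list[Bout]:
    """Bouts that *began* in the window before a diary entry.

    Selection is by bout start within [pro_timestamp - window_s,
    pro_timestamp); a bout that starts inside the window but ends after the
    entry is included in full.
    """
    lo = pro_timestamp - window_s
    return [b for b in bouts if lo <= b.start_s < pro_timestamp]


def slice_bout(rec: AccelRecording, bout: Bout) -> tuple[np.ndarray, float] | None:
    """The samples of a bout and their start time, from its segment."""
    fs = rec.sampling_rate
    for seg in rec.segments:
        if seg.start_s - 1e-9 <= bout.start_s and bout.end_s <= seg.end_s(fs) + 1e-9:
            i0 = int(round((bout.start_s - seg.start_s) * fs))
            i1 = int(round((bout.end_s - seg.start_s) * fs))
            return seg.acc[i0:i1], seg.start_s + i0 / fs
    return None
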