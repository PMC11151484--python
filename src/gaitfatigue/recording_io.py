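"""Reading, writing and orienting lower-back accelerometer recordings.

A recording is a set of contiguous segments of triaxial acceleration in g,
sampled on a regular grid, with axes relabelled to the body frame:
vertical (VV), medial-lateral (ML) and anterior-posterior (AP).  Gaps in
the data (device off, transmission loss) are represented as boundaries
between segments and are never interpolated across.

The upright-wear convention is a vertical-axis mean of about -1 g; a day
whose VV mean is positive indicates the device was worn upside down and is
corrected by flipping the sign of all three axes for that day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AXES = ("VV", "ML", "AP")
SECONDS_PER_DAY = 86400.0
DEVICE_RANGE_G = 8.0
G_MPS2 = 9.81

#: columns of the PRO (patient-reported outcome) diary table
PRO_COLUMNS = ["subject_id", "timestamp", "bin", "pf_score", "mf_score"]

#: daily diary bins, hours of day (start inclusive, end exclusive)
PRO_BINS = {
    "morning": (9.0, 12.0),
    "early_afternoon": (13.0, 16.0),
    "late_afternoon": (17.0, 20.0),
    "evening": (21.0, 24.0),
}


@dataclass
class Segment:
    """A gap-free stretch of samples. ``acc`` has columns VV, ML, AP in g."""

    start_s: float
    acc: np.ndarray  # (n, 3) float32

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    def end_s(self, fs: float) -> float:
        return self.start_s + self.n_samples / fs

    def times(self, fs: float) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / fs


@dataclass
class AccelRecording:
    """One subject's multi-day triaxial acceleration at a fixed rate."""

    subject_id: str
    sampling_rate: float
    segments: list[Segment] = field(default_factory=list)
    height_m: float | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        last_end = -np.inf
        for seg in self.segments:
            if seg.start_s < last_end - 0.5 / self.sampling_rate:
                raise ValueError("segments must be sorted and non-overlapping")
            last_end = seg.end_s(self.sampling_rate)
            finite = seg.acc[np.isfinite(seg.acc)]
            if finite.size and np.abs(finite).max() > DEVICE_RANGE_G + 1e-6:
                raise ValueError(
                    f"acceleration exceeds device range of ±{DEVICE_RANGE_G} g"
                )

    @property
    def total_duration_s(self) -> float:
        return sum(s.n_samples for s in self.segments) / self.sampling_rate

    def day_indices(self) -> np.ndarray:
        days = set()
        for seg in self.segments:
            d0 = int(seg.start_s // SECONDS_PER_DAY)
            d1 = int(max(seg.start_s, seg.end_s(self.sampling_rate) - 1e-9) // SECONDS_PER_DAY)
            days.update(range(d0, d1 + 1))
        return np.array(sorted(days))

    def day_mean_vv(self, day: int) -> float:
        """Mean of the VV axis over one day, NaN if the day holds no data."""
        acc = [
            seg.acc[self._day_slice(seg, day), 0]
            for seg in self.segments
            if self._day_slice(seg, day) is not None
        ]
        if not acc:
            return np.nan
        return float(np.nanmean(np.concatenate(acc)))

    def _day_slice(self, seg: Segment, day: int) -> slice | None:
        fs = self.sampling_rate
        lo = day * SECONDS_PER_DAY
        hi = (day + 1) * SECONDS_PER_DAY
        i0 = int(np.ceil((lo - seg.start_s) * fs - 1e-9))
        i1 = int(np.ceil((hi - seg.start_s) * fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, seg.n_samples)
        return slice(i0, i1) if i1 > i0 else None


def correct_orientation(rec: AccelRecording) -> AccelRecording:
    """Flip days worn upside down so the VV mean is negative (≈ -1 g).

    For every day whose VV mean is positive, the sign of all three axes is
    flipped for that day (an inverted sensor reverses VV and AP together, and
    the consistent operation is a whole-body-frame flip).  Idempotent; days
    without data are skipped.  Each flip is recorded in the module log.
    """
    flipped_days = [d for d in rec.day_indices() if rec.day_mean_vv(int(d)) > 0]
    if not flipped_days:
        return rec
    new_segments = []
    for seg in rec.segments:
        acc = seg.acc.copy()
        for day in flipped_days:
            sl = rec._day_slice(seg, int(day))
            if sl is not None:
                acc[sl] = -acc[sl]
        new_segments.append(Segment(seg.start_s, acc))
    for day in flipped_days:
        logger.info("subject %s: flipped orientation of day %d", rec.subject_id, day)
    return replace(rec, segments=new_segments)


def load_recording(
    path,
    axis_map: dict[str, str],
    sampling_rate: float,
    subject_id: str | None = None,
    units: str = "g",
    gap_tolerance_s: float | None = None,
    height_m: float | None = None,
) -> AccelRecording:
    """Read an accelerometer CSV into an :class:`AccelRecording`.

    The file must have a header with a ``timestamp`` column (seconds) and the
    acceleration columns named in ``axis_map``, which maps file column names
    to the body-frame roles ``VV``/``ML``/``AP``.  Any additional columns
    (e.g. gyroscope channels) are ignored.  Timestamps with jumps beyond
    ``gap_tolerance_s`` (default: half a sample period beyond nominal) start a
    new segment; irregular timestamps inside a segment raise an error.
    ``units="mps2"`` converts from m/s² to g on load.
    """
    if set(axis_map.values()) != set(AXES):
        raise ValueError(f"axis_map must cover exactly {AXES}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty recording file")
    needed = ["timestamp", *axis_map.keys()]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    numeric = df[needed].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~df[needed].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    t = numeric["timestamp"].to_numpy(float)
    cols = {axis_map[c]: numeric[c].to_numpy(np.float32) for c in axis_map}
    acc = np.column_stack([cols[a] for a in AXES])
    if units == "mps2":
        acc = acc / np.float32(G_MPS2)
    elif units != "g":
        raise ValueError(f"unknown units {units!r}")

    dt = 1.0 / sampling_rate
    if gap_tolerance_s is None:
        gap_tolerance_s = 0.5 * dt
    # rows that are entirely NaN act as explicit gap markers
    keep = np.isfinite(acc).all(axis=1) | ~np.isfinite(t)
    keep &= np.isfinite(t)
    t, acc = t[keep], acc[keep]
    if t.size == 0:
        raise ValueError(f"{path}: no valid samples")
    steps = np.diff(t)
    if (steps <= 0).any():
        raise ValueError(f"{path}: timestamps not strictly increasing")
    breaks = np.flatnonzero(np.abs(steps - dt) > gap_tolerance_s)
    segments = []
    start = 0
    for b in np.append(breaks, t.size - 1):
        stop = int(b) + 1
        seg_t = t[start:stop]
        if seg_t.size > 1:
            irregular = np.abs(np.diff(seg_t) - dt).max()
            if irregular > gap_tolerance_s:
                raise ValueError(f"{path}: irregular timestamps beyond tolerance")
        segments.append(Segment(float(seg_t[0]), np.ascontiguousarray(acc[start:stop])))
        start = stop
    sid = subject_id if subject_id is not None else str(path)
    return AccelRecording(sid, sampling_rate, segments, height_m=height_m)


def write_recording(rec: AccelRecording, path, axis_map: dict[str, str] | None = None) -> None:
    """Write a recording to the CSV dialect read by :func:`load_recording`."""
    if axis_map is None:
        axis_map = {"ax": "VV", "ay": "ML", "az": "AP"}
    inverse = {v: k for k, v in axis_map.items()}
    frames = []
    for seg in rec.segments:
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": seg.times(rec.sampling_rate),
                    inverse["VV"]: seg.acc[:, 0],
                    inverse["ML"]: seg.acc[:, 1],
                    inverse["AP"]: seg.acc[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def load_pro_table(path) -> pd.DataFrame:
    """Read a PRO diary CSV (subject_id, timestamp, pf, mf [, bin]).

    Scores outside 0–6 raise; missing scores are allowed (NaN).  The bin name
    is derived from the timestamp's hour of day when not supplied.
    """
    df = pd.read_csv(path)
    rename = {"pf": "pf_score", "mf": "mf_score"}
    df = df.rename(columns=rename)
    for col in ("pf_score", "mf_score"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 6)).any():
            raise ValueError(f"{path}: {col} outside the 0-6 scale")
    if "bin" not in df.columns:
        df["bin"] = [bin_for_timestamp(t) for t in df["timestamp"]]
    df["subject_id"] = df["subject_id"].astype(str)
    return df[PRO_COLUMNS]


def write_pro_table(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"pf_score": "pf", "mf_score": "mf"})
    out.to_csv(path, index=False)


def bin_for_timestamp(timestamp_s: float) -> str | None:
    """Name of the diary bin a completion time falls into, else None."""
    hour = (timestamp_s % SECONDS_PER_DAY) / 3600.0
    for name, (lo, hi) in PRO_BINS.items():
        if lo <= hour < hi:
            return name
    return None
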