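"""Pooling gait measures over the two-hour window before each diary entry.

Every multi-valued measure (per-bout micro measures, bout lengths, step
counts, the vector-magnitude series) is summarised by nine statistics —
mean, SD, variance, sum, min, max, median and the 25th/75th percentiles —
while single-valued measures (bout counts, alpha, S2, mean walking and
non-walking times) pass through tagged ``single``.  A sample exists only
when at least one walking bout began in the window *and* at least one
fatigue label is present; subjects whose every window is excluded drop
out of the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bout_detection, gait_events, macro_features, micro_features
from .bout_detection import Bout, bouts_before_pro, detect_bouts, slice_bout
from .recording_io import AccelRecording, correct_orientation

logger = logging.getLogger(__name__)

STATISTICS = (
    "mean", "sd", "variance", "sum", "min", "max", "median", "p25", "p75",
)
WINDOW_S = 7200.0


@dataclass
class FeatureWindow:
    """Pooled feature vector for the window before one diary entry."""

    subject_id: str
    pro_timestamp: float
    bin: str | None
    pf_score: float
    mf_score: float
    features: dict[str, float] = field(default_factory=dict)


def pool_statistics(values, ddof: int = 1, include_count: bool = False
                    ) -> dict[str, float]:
    """The nine pooled statistics of a value series.

    SD and variance use the sample (n-1) form; a single value has SD and
    variance 0 and every location statistic equal to itself.  Percentiles
    interpolate linearly between order statistics.  An empty (or all-NaN)
    input yields all statistics missing.  ``include_count`` optionally adds
    the number of pooled values as a tenth statistic (off by default).
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size == 0:
        out = {s: np.nan for s in STATISTICS}
    else:
        sd = float(np.std(x, ddof=ddof)) if x.size > ddof else 0.0
        out = {
            "mean": float(x.mean()),
            "sd": sd,
            "variance": sd ** 2,
            "sum": float(x.sum()),
            "min": float(x.min()),
            "max": float(x.max()),
            "median": float(np.median(x)),
            "p25": float(np.percentile(x, 25)),
            "p75": float(np.percentile(x, 75)),
        }
    if include_count:
        out["count"] = float(x.size)
    return out


def _expand(prefix: str, values, stats_excl: tuple[str, ...] = (),
            include_count: bool = False) -> dict[str, float]:
    pooled = pool_statistics(values, include_count=include_count)
    return {f"{prefix}__{s}": v for s, v in pooled.items() if s not in stats_excl}


@dataclass
class BoutFeatures:
    """Per-bout gait-event products cached for reuse across windows."""

    bout: Bout
    n_steps_detected: int
    micro: dict[str, float] | None  # None when the bout was removed


def compute_bout_features(rec: AccelRecording, bouts: list[Bout],
                          cwt_scale: float | None = None) -> list[BoutFeatures]:
    """Run event detection and micro measures once per walking bout."""
    out = []
    for bout in bouts:
        if bout.kind != "walking":
            continue
        sliced = slice_bout(rec, bout)
        if sliced is None:
            continue
        acc, _ = sliced
        events = gait_events.detect_ic_fc(acc[:, 0], rec.sampling_rate, bout,
                                          scale=cwt_scale)
        n_det = events.n_steps
        temporal = micro_features.temporal_params(events)
        if temporal.empty:
            out.append(BoutFeatures(bout, n_det, None))
            continue
        height = rec.height_m if rec.height_m else 1.70
        spatial = micro_features.step_length_and_velocity(
            acc[:, 0], rec.sampling_rate, events, height)
        kept = gait_events.apply_step_exclusions(
            events,
            temporal["step_s"].to_numpy(),
            spatial["step_length_m"].to_numpy(),
            temporal["swing_s"].to_numpy(),
        )
        if kept is None:
            out.append(BoutFeatures(bout, n_det, None))
            continue
        steps = micro_features.combine_step_measures(
            temporal, spatial, kept.valid_step_mask)
        out.append(BoutFeatures(bout, n_det,
                                micro_features.variability_and_asymmetry(steps)))
    return out


def window_features(rec: AccelRecording, bouts: list[Bout],
                    bout_feats: list[BoutFeatures], pro_timestamp: float,
                    window_s: float = WINDOW_S,
                    vm_in_mps2: bool = True) -> dict[str, float] | None:
    """Macro + micro feature map for one diary entry, None if no bout began."""
    in_window = bouts_before_pro(bouts, pro_timestamp, window_s)
    if not any(b.kind == "walking" for b in in_window):
        return None
    keys = {(b.start_s, b.end_s) for b in in_window}
    feats_in = [bf for bf in bout_feats if (bf.bout.start_s, bf.bout.end_s) in keys]

    steps_per_bout = {i: bf.n_steps_detected
                      for i, bf in enumerate(feats_in)}
    walking = [bf.bout for bf in feats_in]
    nonwalk = [b for b in in_window if b.kind == "non_walking"]
    scalars = macro_features.volume_and_pattern(
        walking + nonwalk,
        {i: n for i, n in steps_per_bout.items()},
    )
    row: dict[str, float] = {}
    for key, value in scalars.items():
        if isinstance(value, np.ndarray):
            excl = ("mean",) if key.endswith("bout_length_s") else ()
            row.update(_expand(f"macro__{key}", value, stats_excl=excl))
        else:
            row[f"macro__{key}__single"] = value
    vm = macro_features.window_vector_magnitude(
        rec, pro_timestamp - window_s, pro_timestamp, in_mps2=vm_in_mps2)
    row.update(_expand("macro__vector_magnitude__vm_mps2", vm))

    per_bout = [bf.micro for bf in feats_in if bf.micro is not None]
    for group, measures in micro_features.MICRO_GROUPS.items():
        for m in measures:
            series = [d[m] for d in per_bout]
            row.update(_expand(f"micro__{group}__{m}", series))
    return row


def build_dataset(recordings: list[AccelRecording], pro_table: pd.DataFrame,
                  window_s: float = WINDOW_S, cwt_scale: float | None = None,
                  orient: bool = True) -> pd.DataFrame:
    """Assemble the modelling table: one row per retained diary entry.

    Entries without any fatigue label or without a walking bout starting in
    the preceding window are excluded; subjects left with no rows are
    dropped entirely.  Duplicate timestamps per subject keep the first
    occurrence.  Feature columns are constant across rows (missing measures
    are NaN).
    """
    rows = []
    for rec in recordings:
        sub = pro_table[pro_table["subject_id"] == rec.subject_id]
        if sub.empty:
            continue
        dup = sub.duplicated(subset="timestamp")
        if dup.any():
            logger.warning("subject %s: dropping %d duplicate diary timestamps",
                           rec.subject_id, int(dup.sum()))
            sub = sub[~dup]
        if orient:
            rec = correct_orientation(rec)
        bouts = detect_bouts(rec)
        bout_feats = compute_bout_features(rec, bouts, cwt_scale=cwt_scale)
        for _, entry in sub.iterrows():
            pf, mf = entry.get("pf_score", np.nan), entry.get("mf_score", np.nan)
            if pd.isna(pf) and pd.isna(mf):
                continue
            feats = window_features(rec, bouts, bout_feats,
                                    float(entry["timestamp"]), window_s)
            if feats is None:
                continue
            rows.append({
                "subject_id": rec.subject_id,
                "pro_timestamp": float(entry["timestamp"]),
                "bin": entry.get("bin"),
                "pf_score": pf,
                "mf_score": mf,
                **feats,
            })
    df = pd.DataFrame(rows)
    return df


def feature_columns(dataset: pd.DataFrame, domain: str | None = None,
                    group: str | None = None) -> list[str]:
    """Names of feature columns, optionally filtered by domain or group."""
    cols = [c for c in dataset.columns if c.startswith(("macro__", "micro__"))]
    if domain:
        cols = [c for c in cols if c.startswith(f"{domain}__")]
    if group:
        cols = [c for c in cols if c.split("__")[1] == group]
    return cols
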