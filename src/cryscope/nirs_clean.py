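"""NIRS artifact filter cascade and condition segmentation.

The recording carries three variables sampled every 2 s: regional
cerebral oxygen saturation (rSO2, %), peripheral arterial saturation
(SpO2, %) and pulse rate (PR, beats/min).  Cleaning removes
acquisition errors in two stages applied per variable until a fixed
point is reached (which makes the cascade idempotent by
construction): (1) samples inside a 60-s sliding window whose
standard deviation falls below 0.5 native units are flat-line
dropouts; (2) samples outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] of the
whole cleaned recording are outliers.  Surviving samples are assigned
to annotated condition intervals after trimming 15 s from both ends,
and a segment's variable is excluded when its mean violates the
plausibility floor (SpO2 < 80%, rSO2 < 50%, PR < 70 bpm).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NIRSConfig

VARIABLES = ("rSO2", "SpO2", "PR")


@dataclass
class NirsSegment:
    condition: str
    start_s: float
    end_s: float
    samples: dict = field(default_factory=dict)   # variable -> np.ndarray
    means: dict = field(default_factory=dict)     # variable -> float or nan
    keep: dict = field(default_factory=dict)      # variable -> bool


def clean(series: pd.DataFrame, cfg: NIRSConfig | None = None) -> pd.DataFrame:
    """Apply the flat-line and IQR rules per variable to a fixed point.

    Removed samples become NaN (timestamps are preserved).  Iterating
    the two rules until nothing more is removed guarantees
    ``clean(clean(x)) == clean(x)``.
    """
    cfg = cfg or NIRSConfig()
    df = series.copy()
    if not np.all(np.diff(df["t_s"].to_numpy()) > 0):
        raise ValueError("timestamps must be strictly increasing")
    win = max(3, int(round(cfg.sd_window_s / cfg.sample_period_s)) | 1)
    for _ in range(20):
        removed = 0
        for var in VARIABLES:
            x = df[var]
            # flat-line dropout: a sample is bad when *any* window
            # containing it has SD below threshold, i.e. the centred
            # low-SD mask dilated by the window half-width — this
            # removes whole dropout runs, edges included, rather than
            # leaving a point mass of repeated values behind
            sd = x.rolling(win, center=True, min_periods=3).std()
            low = (sd.notna() & (sd < cfg.sd_min)).astype(float)
            flat = (low.rolling(win, center=True, min_periods=1).max() > 0) & x.notna()
            # Tukey fences over the whole SD-cleaned recording (the
            # cascade is sequential: dropout runs must not poison the
            # quantiles); skipped when the spread is degenerate
            x2 = x.mask(flat)
            q1, q3 = x2.quantile(0.25), x2.quantile(0.75)
            iqr = q3 - q1
            if np.isfinite(iqr) and iqr > 0:
                lo, hi = q1 - cfg.iqr_factor * iqr, q3 + cfg.iqr_factor * iqr
                out = x2.notna() & ((x2 < lo) | (x2 > hi))
            else:
                out = pd.Series(False, index=x.index)
            mask = flat | out
            removed += int(mask.sum())
            df.loc[mask, var] = np.nan
        if removed == 0:
            break
    return df


def segment(
    series: pd.DataFrame,
    annotations: list[tuple[float, float, str]],
    cfg: NIRSConfig | None = None,
) -> list[NirsSegment]:
    """Assign cleaned samples to trimmed condition intervals.

    A sample whose 2-s acquisition window [t, t+dt) lies strictly
    inside (start + 15 s, end - 15 s) belongs to the interval;
    intervals of 30 s or less therefore yield empty segments, and
    samples in annotation gaps are dropped.
    """
    cfg = cfg or NIRSConfig()
    t = series["t_s"].to_numpy()
    out = []
    for start, end, label in annotations:
        lo = start + cfg.trim_s
        hi = end - cfg.trim_s
        m = (t > lo) & (t + cfg.sample_period_s < hi)
        seg = NirsSegment(condition=label, start_s=start, end_s=end)
        for var in VARIABLES:
            vals = series.loc[m, var].dropna().to_numpy()
            seg.samples[var] = vals
            seg.means[var] = float(vals.mean()) if len(vals) else np.nan
        out.append(seg)
    return out


def threshold_filter(seg: NirsSegment, cfg: NIRSConfig | None = None) -> dict[str, bool]:
    """Per-variable keep flags from the segment-mean plausibility floors.

    Comparisons are strict: a mean exactly at its floor is retained.
    Variables with no samples are excluded.
    """
    cfg = cfg or NIRSConfig()
    keep = {}
    for var in VARIABLES:
        mean = seg.means.get(var, np.nan)
        keep[var] = bool(np.isfinite(mean) and not (mean < cfg.floors[var]))
    seg.keep = keep
    return keep


def segment_table(segments: list[NirsSegment], cfg: NIRSConfig | None = None) -> pd.DataFrame:
    """Long-format summary with means, sample counts and keep flags."""
    cfg = cfg or NIRSConfig()
    rows = []
    for i, seg in enumerate(segments):
        keep = seg.keep or threshold_filter(seg, cfg)
        for var in VARIABLES:
            rows.append({
                "segment": i, "condition": seg.condition,
                "start_s": seg.start_s, "end_s": seg.end_s, "variable": var,
                "n": len(seg.samples.get(var, ())),
                "mean": seg.means.get(var, np.nan), "keep": keep[var],
            })
    return pd.DataFrame(rows)
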