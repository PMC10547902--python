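"""EEG preprocessing, epoching and relative band power analysis.

The pipeline mirrors standard neonatal resting-EEG practice: zero-phase
1-45 Hz band-pass, bad-channel detection (flat, extreme-variance or
decorrelated channels), spherical-spline interpolation of at most one
bad channel (more rejects the recording's epochs), average reference
over good channels, non-overlapping 4-s epochs tiled within each
annotated condition interval, amplitude-based epoch rejection
(channel-mean peak |x| >= 200 uV), Welch relative power in the delta
(1-4), theta (4-8) and alpha (8-12 Hz) bands normalised by total
1-45 Hz power, and percent change of each condition against the
resting baseline (resting == 100%).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import eval_legendre

from .config import EEGConfig, EEG_CHANNELS

#: idealised unit-sphere positions of the 8 recorded 10-20 electrodes
#: (x = right, y = anterior, z = superior)
ELECTRODE_POSITIONS = {
    "F3": (-0.5952, 0.6292, 0.4998),
    "F4": (0.6066, 0.6355, 0.4776),
    "C3": (-0.7069, -0.1258, 0.6961),
    "C4": (0.7210, -0.1171, 0.6830),
    "T7": (-0.9766, -0.1859, -0.1084),
    "T8": (0.9789, -0.1728, -0.1092),
    "P3": (-0.4810, -0.7149, 0.5076),
    "P4": (0.4985, -0.7035, 0.5065),
}


@dataclass
class EEGRecording:
    """8-channel EEG in microvolts at a fixed sampling rate."""

    data: np.ndarray                    # (8, n_samples), uV
    fs: int = 512
    channels: tuple = EEG_CHANNELS
    bad_channels: set = field(default_factory=set)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if tuple(self.channels) != tuple(EEG_CHANNELS):
            raise ValueError(f"expected channels {EEG_CHANNELS}")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")

    @property
    def good_channels(self) -> list[str]:
        return [c for c in self.channels if c not in self.bad_channels]


@dataclass
class EEGEpoch:
    data: np.ndarray                    # (8, epoch_samples), uV
    condition: str
    start_s: float
    quality: str = "good"               # good | rejected | interpolated-1


def preprocess(rec: EEGRecording, cfg: EEGConfig | None = None) -> EEGRecording:
    """Zero-phase 1-45 Hz band-pass, then average reference.

    The average reference is computed over good channels only and
    subtracted from every channel, so the channel-mean of good
    channels is exactly zero at every sample.
    """
    cfg = cfg or EEGConfig()
    sos = signal.butter(cfg.filter_order, cfg.bandpass_hz, btype="bandpass",
                        fs=rec.fs, output="sos")
    filt = signal.sosfiltfilt(sos, rec.data, axis=1)
    good_idx = [i for i, c in enumerate(rec.channels) if c not in rec.bad_channels]
    ref = filt[good_idx].mean(axis=0)
    return EEGRecording(filt - ref, rec.fs, rec.channels, set(rec.bad_channels))


def detect_bad_channels(rec: EEGRecording, cfg: EEGConfig | None = None) -> set[str]:
    """Flag flat, extreme-variance or decorrelated channels."""
    cfg = cfg or EEGConfig()
    var = rec.data.var(axis=1)
    bad = set()
    for i, c in enumerate(rec.channels):
        if var[i] < cfg.flat_variance_uv2:
            bad.add(c)
    live = [i for i, c in enumerate(rec.channels) if c not in bad]
    if live:
        med = np.median(var[live])
        if med > 0:
            for i in live:
                if var[i] > cfg.variance_ratio_max * med:
                    bad.add(rec.channels[i])
    live = [i for i, c in enumerate(rec.channels) if c not in bad]
    if len(live) >= 3:
        cc = np.corrcoef(rec.data[live])
        np.fill_diagonal(cc, np.nan)
        # the decorrelation rule is only meaningful when the montage
        # itself shows volume-conducted correlation; otherwise every
        # channel of an uncorrelated recording would be flagged
        if np.nanmedian(np.abs(cc)) >= cfg.min_channel_correlation:
            for k, i in enumerate(live):
                if np.nanmax(np.abs(cc[k])) < cfg.min_channel_correlation:
                    bad.add(rec.channels[i])
    return bad


def _spline_g(cosang: np.ndarray, m: int, n_terms: int) -> np.ndarray:
    """Legendre-series g function of spherical-spline interpolation."""
    out = np.zeros_like(np.asarray(cosang, dtype=np.float64))
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n**m * (n + 1) ** m) * eval_legendre(n, cosang)
    return out / (4 * np.pi)


def interpolate_spherical_spline(
    rec: EEGRecording, bad: str, cfg: EEGConfig | None = None,
) -> EEGRecording:
    """Rebuild one bad channel from the seven good ones.

    Spherical-spline interpolation on the unit sphere (Legendre g
    function of order m with a truncated series and a small
    regularisation ridge).  Only a single channel may be interpolated;
    recordings with more bad channels are rejected upstream rather
    than repaired.
    """
    cfg = cfg or EEGConfig()
    if bad not in rec.channels:
        raise ValueError(f"unknown channel {bad!r}")
    others = set(rec.bad_channels) - {bad}
    if others:
        raise ValueError("at most one bad channel may be interpolated")
    good = [c for c in rec.channels if c != bad]
    pos = np.asarray([ELECTRODE_POSITIONS[c] for c in good])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    target = np.asarray(ELECTRODE_POSITIONS[bad])
    target /= np.linalg.norm(target)

    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    g = _spline_g(cosang, cfg.spline_order_m, cfg.spline_n_terms)
    n = len(good)
    lhs = np.zeros((n + 1, n + 1))
    lhs[:n, :n] = g + cfg.spline_regularization * np.eye(n)
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    gi = [i for i, c in enumerate(rec.channels) if c != bad]
    v = rec.data[gi]
    rhs = np.vstack([v, np.zeros((1, v.shape[1]))])
    sol = np.linalg.solve(lhs, rhs)
    w, c0 = sol[:n], sol[n]
    g_t = _spline_g(np.clip(pos @ target, -1.0, 1.0), cfg.spline_order_m, cfg.spline_n_terms)
    interp = g_t @ w + c0

    data = rec.data.copy()
    data[rec.channels.index(bad)] = interp
    return EEGRecording(data, rec.fs, rec.channels, set())


def epoch_and_reject(
    rec: EEGRecording,
    annotations: list[tuple[float, float, str]],
    cfg: EEGConfig | None = None,
) -> list[EEGEpoch]:
    """Tile non-overlapping 4-s epochs inside each condition interval.

    An epoch is good iff the mean across channels of the per-channel
    peak absolute amplitude stays below the 200 uV limit.  Epochs
    never straddle annotation boundaries.
    """
    cfg = cfg or EEGConfig()
    n_ep = int(round(cfg.epoch_s * rec.fs))
    epochs = []
    for start, end, label in annotations:
        i0 = int(round(start * rec.fs))
        count = int(np.floor((end - start) / cfg.epoch_s))
        for k in range(count):
            a = i0 + k * n_ep
            b = a + n_ep
            if b > rec.data.shape[1]:
                break
            seg = rec.data[:, a:b]
            peak = np.abs(seg).max(axis=1).mean()
            quality = "good" if peak < cfg.amplitude_reject_uv else "rejected"
            epochs.append(EEGEpoch(seg, label, a / rec.fs, quality))
    return epochs


def relative_power(epoch: EEGEpoch | np.ndarray, fs: int = 512,
                   cfg: EEGConfig | None = None) -> pd.DataFrame:
    """Welch relative band power per channel for one epoch.

    Welch uses 1-s Hamming windows with 50% overlap (1 Hz bin width,
    so band edges fall exactly on bin centres).  Relative power of a
    band is the sum of its half-open [lo, hi) bins divided by the sum
    over the total 1-45 Hz range.
    """
    cfg = cfg or EEGConfig()
    data = epoch.data if isinstance(epoch, EEGEpoch) else np.asarray(epoch)
    nper = int(round(cfg.welch_window_s * fs))
    nov = int(round(nper * cfg.welch_overlap))
    # detrend=False: mean-detrending each segment suppresses the 1 Hz
    # bin through the window mainlobe and biases delta power low; the
    # preprocessing band-pass already removes DC
    freqs, psd = signal.welch(data, fs=fs, window="hamming", nperseg=nper,
                              noverlap=nov, axis=1, detrend=False)
    lo_t, hi_t = cfg.total_band_hz
    total_mask = (freqs >= lo_t) & (freqs < hi_t)
    total = psd[:, total_mask].sum(axis=1)
    total[total <= 0] = np.inf
    rows = []
    for band, (lo, hi) in cfg.bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        rel = psd[:, mask].sum(axis=1) / total
        for ch, r in zip(EEG_CHANNELS, rel):
            rows.append({"channel": ch, "band": band, "relative_power": float(r)})
    return pd.DataFrame(rows)


def band_power_table(
    epochs: list[EEGEpoch], fs: int = 512, cfg: EEGConfig | None = None,
    good_only: bool = True,
) -> pd.DataFrame:
    """Long-format relative power for every (epoch, channel, band)."""
    cfg = cfg or EEGConfig()
    frames = []
    for i, ep in enumerate(epochs):
        if good_only and ep.quality == "rejected":
            continue
        df = relative_power(ep, fs, cfg)
        df["epoch"] = i
        df["condition"] = ep.condition
        df["start_s"] = ep.start_s
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["channel", "band", "relative_power",
                                     "epoch", "condition", "start_s"])
    return pd.concat(frames, ignore_index=True)


def percent_change(cond_table: pd.DataFrame, resting_table: pd.DataFrame) -> pd.DataFrame:
    """Percent change of mean relative power vs the resting baseline.

    For each (channel, band): 100 * (mean_cond - mean_rest) / mean_rest,
    i.e. resting is the 100% reference.
    """
    mc = cond_table.groupby(["channel", "band"])["relative_power"].mean()
    mr = resting_table.groupby(["channel", "band"])["relative_power"].mean()
    pc = 100.0 * (mc - mr) / mr
    out = pc.rename("percent_change").reset_index()
    return out
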