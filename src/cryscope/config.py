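"""Run configuration: every fixed analysis constant lives here.

All thresholds that define the analysis (filter bands, epoch length,
rejection limits, NIRS floors, split fraction, bootstrap repetitions)
are declared once in these dataclasses so that the rest of the package
never hard-codes them.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

EEG_CHANNELS = ("F3", "F4", "C3", "C4", "T7", "T8", "P3", "P4")

#: Frequency bands analysed (Hz, half-open [lo, hi) bins).
EEG_BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0)}


@dataclass
class AcousticsConfig:
    """Parameters of cry segmentation and per-unit feature extraction."""

    fs_expected: int = 48_000
    # F0 / voicing
    f0_band_hz: tuple[float, float] = (200.0, 1200.0)  # band-pass before pitch search
    f0_frame_s: float = 0.040
    f0_hop_s: float = 0.010
    voicing_threshold: float = 0.45      # normalised autocorrelation, band-passed
    voicing_threshold_full: float = 0.30  # secondary check on the unfiltered frame
    octave_margin: float = 0.15          # prefer shortest lag within this of the max
    high_pitch_hz: float = 800.0
    hyperphonation_hz: float = 1000.0
    # segmentation
    energy_threshold_db: float = -40.0   # relative to recording peak frame energy
    min_gap_s: float = 0.06              # shorter silent dips are kept inside a unit
    min_unit_s: float = 0.2              # shorter voiced runs are segmentation noise
    episode_break_s: float = 5.0         # longer gaps end the cry episode
    # jitter / shimmer / HNR (cycle-synchronous measures)
    cycle_window_frac: float = 0.95      # window length as fraction of median period
    hnr_clip_db: tuple[float, float] = (-10.0, 40.0)
    # formants
    formant_lowpass_hz: float = 10_000.0
    formant_fs: int = 20_000
    formant_fit_fmax_hz: float = 9500.0
    # physiologically plausible newborn search bands for F1/F2/F3 (Hz)
    formant_search_f1_hz: tuple[float, float] = (900.0, 2199.0)
    formant_search_f2_hz: tuple[float, float] = (2200.0, 4299.0)
    formant_search_f3_hz: tuple[float, float] = (4300.0, 9000.0)
    formant_bw_range_hz: tuple[float, float] = (150.0, 800.0)
    # MFCC / spectrogram
    n_mfcc: int = 13
    mfcc_n_mels: int = 40
    mfcc_frame_s: float = 0.025
    mfcc_hop_s: float = 0.010
    spec_n_mels: int = 64
    spec_frame_s: float = 0.050
    spec_hop_s: float = 0.025
    spec_canvas_s: float = 1.5


@dataclass
class EEGConfig:
    """EEG preprocessing, epoching and spectral-analysis parameters."""

    fs: int = 512
    channels: tuple[str, ...] = EEG_CHANNELS
    bandpass_hz: tuple[float, float] = (1.0, 45.0)
    filter_order: int = 12               # steep enough to put 50 Hz mains >20 dB down
    epoch_s: float = 4.0
    amplitude_reject_uv: float = 200.0   # channel-mean of per-channel peak |x|
    flat_variance_uv2: float = 0.1
    variance_ratio_max: float = 10.0
    min_channel_correlation: float = 0.2
    bands: dict = field(default_factory=lambda: dict(EEG_BANDS))
    total_band_hz: tuple[float, float] = (1.0, 45.0)
    welch_window_s: float = 1.0
    welch_overlap: float = 0.5
    # spherical-spline interpolation
    spline_order_m: int = 4
    spline_n_terms: int = 7
    spline_regularization: float = 1e-5
    max_interpolated_channels: int = 1


@dataclass
class NIRSConfig:
    """NIRS filter-cascade and segmentation parameters."""

    sample_period_s: float = 2.0
    sd_window_s: float = 60.0
    sd_min: float = 0.5                  # native units of each variable
    iqr_factor: float = 1.5
    trim_s: float = 15.0                 # discarded before/after each segment
    floors: dict = field(default_factory=lambda: {"SpO2": 80.0, "rSO2": 50.0, "PR": 70.0})


@dataclass
class StatsConfig:
    bootstrap_reps: int = 10_000
    alpha: float = 0.05
    strong_agreement_w: float = 0.5
    framed_agreement_w: float = 0.7


@dataclass
class ClassifierConfig:
    frac_train: float = 0.8
    rf_n_estimators: int = 500
    cnn_filters: tuple[int, int, int] = (16, 32, 64)
    cnn_dense_units: int = 64
    cnn_epochs: int = 10
    cnn_batch_size: int = 32
    cnn_learning_rate: float = 1e-3
    cnn_patience: int = 2


@dataclass
class SimulateConfig:
    """Shape of the default synthetic session."""

    n_cry_episodes: int = 3
    n_distress_episodes: int = 2
    resting_block_s: float = 60.0
    units_per_episode: int = 30          # ~40-50 s episodes, like real cry bouts
    eeg_artifact_rate: float = 0.0       # bursts per minute, 0 = clean
    nirs_dropout: bool = False


@dataclass
class RunConfig:
    """Top-level configuration for the end-to-end pipeline."""

    seed: int = 7
    out_dir: str = "cryscope_out"
    classifier: str = "rf"               # "rf", "cnn" or "both"
    classifier_n_units: int = 400        # units synthesised for the classifier stage
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    acoustics: AcousticsConfig = field(default_factory=AcousticsConfig)
    eeg: EEGConfig = field(default_factory=EEGConfig)
    nirs: NIRSConfig = field(default_factory=NIRSConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classify: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                "simulate", "acoustics", "eeg", "nirs", "stats", "classify",
            ):
                sub = {
                    "simulate": SimulateConfig, "acoustics": AcousticsConfig,
                    "eeg": EEGConfig, "nirs": NIRSConfig,
                    "stats": StatsConfig, "classify": ClassifierConfig,
                }[f.name]
                v = _restore(sub, v)
            kwargs[f.name] = v
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _restore(dc_cls, d):
    """Rebuild a config dataclass from a YAML dict, restoring tuples."""
    kwargs = {}
    for f in dataclasses.fields(dc_cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list):
            v = tuple(v)
        elif isinstance(v, dict):
            v = {k: tuple(x) if isinstance(x, list) else x for k, x in v.items()}
        kwargs[f.name] = v
    return dc_cls(**kwargs)
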