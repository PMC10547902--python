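"""Synthetic multimodal newborn sessions with known ground truth.

The generator produces one "session" per call: a 48 kHz audio track in
which resting blocks alternate with cry and distress episodes, an
8-channel 512 Hz EEG, a NIRS time series sampled every 2 s, and one
COMFORT assessment per cry episode — all on a shared clock, together
with the exact parameters used to create them.

Cry units are produced by source–filter synthesis: a glottal pulse
train whose cycle periods and amplitudes are perturbed to realise a
requested local jitter and shimmer, shaped by a one-pole glottal
spectral tilt and three second-order formant resonators, plus white
noise scaled analytically to a requested harmonics-to-noise ratio.
The analytic harmonic/noise power ratio fixed at synthesis time is the
oracle against which the HNR estimator is validated.

Default condition profiles follow the published group statistics of
cry vs distress vocalisations (F0 ~478 vs ~413 Hz, jitter 0.016 vs
0.022, shimmer 0.113 vs 0.143, HNR 11.9 vs 6.7 dB, rising formants),
the sign pattern of EEG relative-power changes (delta down, theta and
alpha up relative to resting), NIRS directions (SpO2/rSO2 down and
pulse rate up while crying) and COMFORT scores increasing with
distress.  EEG/NIRS magnitudes are free parameters calibrated to
reproduce orderings only.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .config import EEG_CHANNELS, SimulateConfig
from . import io as _io

AUDIO_FS = 48_000
EEG_FS = 512
NIRS_DT = 2.0

# Gaussian period/amplitude perturbations: E|N(0,1)_{i+1} - N(0,1)_i| =
# 2/sqrt(pi), so a perturbation SD of sqrt(pi)/2 * target makes the
# *expected measured* local jitter/shimmer equal the requested value.
_GAUSS_LOCAL = np.sqrt(np.pi) / 2.0

_CONTOUR_DEPTH = {"flat": 0.0, "rise-fall": 0.18, "falling": 0.15}

# ---------------------------------------------------------------------------
# domain types


@dataclass
class CryParams:
    """Ground-truth acoustic parameters of one cry unit generator."""

    f0_mean: float = 477.563          # Hz
    f0_sd: float = 109.396            # Hz, across-unit spread of the unit mean F0
    f0_contour_shape: str = "rise-fall"
    jitter_frac: float = 0.016
    shimmer_frac: float = 0.113
    hnr_db: float = 11.880
    formants: tuple[float, float, float] = (1428.963, 3557.709, 5897.238)
    formant_bw: tuple[float, float, float] = (450.0, 500.0, 550.0)
    unit_dur_range: tuple[float, float] = (0.6, 1.1)   # s
    gap_dur_range: tuple[float, float] = (0.3, 0.8)    # s
    n_units: int = 6

    def validate(self) -> None:
        if not (200.0 <= self.f0_mean <= 1200.0):
            raise ValueError("f0_mean must lie in [200, 1200] Hz")
        for name in ("jitter_frac", "shimmer_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.2):
                raise ValueError(f"{name} must lie in [0, 0.2]")
        if not (self.formants[0] < self.formants[1] < self.formants[2]):
            raise ValueError("formants must be strictly increasing")
        if self.f0_contour_shape not in _CONTOUR_DEPTH:
            raise ValueError(f"unknown contour shape {self.f0_contour_shape!r}")
        if min(self.unit_dur_range + self.gap_dur_range) <= 0:
            raise ValueError("durations must be positive")
        if not (-10.0 <= self.hnr_db <= 40.0):
            raise ValueError("hnr_db must lie in [-10, 40] dB")


#: published group means used as generator defaults for the two cry conditions
CRY_DEFAULTS = CryParams()
DISTRESS_DEFAULTS = CryParams(
    f0_mean=412.587, f0_sd=109.124, jitter_frac=0.022, shimmer_frac=0.143,
    hnr_db=6.662, formants=(1630.672, 3739.816, 6094.533),
    unit_dur_range=(0.9, 1.5), gap_dur_range=(0.3, 0.7),
)


@dataclass
class ConditionProfile:
    """Generative targets for one condition across all modalities."""

    condition: str                                   # resting | cry | distress
    cry_params: CryParams | None = None
    eeg_band_gains: dict = field(default_factory=dict)  # oscillator SD in uV
    nirs_levels: dict = field(default_factory=dict)     # mean rSO2 %, SpO2 %, PR bpm
    comfort_item_means: tuple = (1.5,) * 6

    def validate(self) -> None:
        if self.condition not in ("resting", "cry", "distress"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if any(g <= 0 for g in self.eeg_band_gains.values()):
            raise ValueError("eeg_band_gains must be positive")
        if not (0.0 <= self.nirs_levels.get("SpO2", 50.0) <= 100.0):
            raise ValueError("SpO2 must lie in [0, 100]")
        if any(not (1.0 <= m <= 5.0) for m in self.comfort_item_means):
            raise ValueError("comfort means must lie in [1, 5]")
        if self.cry_params is not None:
            self.cry_params.validate()


def default_profiles() -> dict[str, ConditionProfile]:
    """The study conditions: resting baseline, cry, and distress."""
    return {
        "resting": ConditionProfile(
            condition="resting",
            eeg_band_gains={"delta": 22.0, "theta": 6.0, "alpha": 4.0},
            nirs_levels={"rSO2": 78.0, "SpO2": 97.0, "PR": 120.0},
            comfort_item_means=(1.5,) * 6,
        ),
        "cry": ConditionProfile(
            condition="cry",
            cry_params=CryParams(**asdict(CRY_DEFAULTS)),
            eeg_band_gains={"delta": 20.0, "theta": 9.5, "alpha": 8.5},
            nirs_levels={"rSO2": 75.0, "SpO2": 94.0, "PR": 145.0},
            comfort_item_means=(3.0,) * 6,
        ),
        "distress": ConditionProfile(
            condition="distress",
            cry_params=CryParams(**asdict(DISTRESS_DEFAULTS)),
            eeg_band_gains={"delta": 18.5, "theta": 11.5, "alpha": 11.0},
            nirs_levels={"rSO2": 73.0, "SpO2": 92.0, "PR": 160.0},
            comfort_item_means=(4.5,) * 6,
        ),
    }


@dataclass
class SessionBundle:
    """One synthetic session: all modalities on a shared clock."""

    audio: np.ndarray
    fs: int
    annotations: list                     # (start_s, end_s, condition)
    eeg: np.ndarray                       # 8 x n_samples, uV
    eeg_fs: int
    eeg_channels: tuple
    nirs: pd.DataFrame                    # t_s, rSO2, SpO2, PR
    comfort: pd.DataFrame                 # one row per cry/distress episode
    truth: dict                           # generator ground truth

    @property
    def duration_s(self) -> float:
        return len(self.audio) / self.fs

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        _io.write_wav(path / "audio.wav", self.audio, self.fs)
        _io.write_annotations(path / "annotations.tsv", self.annotations)
        _io.write_eeg_csv(path / "eeg.csv", self.eeg, self.eeg_channels)
        _io.write_nirs_csv(path / "nirs.csv", self.nirs)
        _io.write_comfort_csv(path / "comfort.csv", self.comfort)
        with open(path / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# audio synthesis


def _resonator_sos(freqs, bws, fs) -> np.ndarray:
    """Cascade of two-pole resonators (unit gain at the pole frequency)."""
    sections = []
    for f, bw in zip(freqs, bws):
        r = np.exp(-np.pi * bw / fs)
        theta = 2 * np.pi * f / fs
        a = [1.0, -2 * r * np.cos(theta), r * r]
        # normalise gain at the resonance frequency
        w = theta
        h = 1.0 / abs(np.polyval(a, np.exp(1j * w)) / np.exp(2j * w))
        sections.append([1.0 / h, 0.0, 0.0, *a])
    return np.asarray(sections)


def synth_cry_unit(
    params: CryParams,
    dur: float,
    seed: int | np.random.Generator,
    fs: int = AUDIO_FS,
    f0_mean: float | None = None,
) -> np.ndarray:
    """Synthesise a single cry unit (expiratory vocalisation).

    Source–filter model: glottal pulses placed at per-cycle perturbed
    periods (jitter), scaled by per-cycle perturbed amplitudes
    (shimmer), spectrally tilted by a one-pole glottal low-pass,
    filtered through three formant resonators, and mixed with white
    Gaussian noise whose power is set from the clean harmonic power to
    realise ``params.hnr_db`` exactly in expectation.

    ``f0_mean`` overrides the profile mean (used by :func:`synth_episode`
    to draw per-unit F0).  The returned waveform is peak-normalised to
    |x| <= 0.99.
    """
    params.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f0 = float(f0_mean if f0_mean is not None else params.f0_mean)
    if dur <= 2.0 / f0:
        raise ValueError("unit duration must exceed two pitch periods")
    if fs < 16_000:
        raise ValueError("sample rate must be >= 16 kHz")
    if max(params.formants) >= fs / 2:
        raise ValueError("formants must lie below the Nyquist frequency")

    n = int(round(dur * fs))
    depth = _CONTOUR_DEPTH[params.f0_contour_shape]

    def f0_at(t: np.ndarray) -> np.ndarray:
        ph = t / dur
        if params.f0_contour_shape == "rise-fall":
            # zero-mean raised-sine excursion: mean F0 stays at f0
            return f0 * (1.0 + depth * (np.sin(np.pi * ph) - 2.0 / np.pi))
        if params.f0_contour_shape == "falling":
            return f0 * (1.0 + depth * (1.0 - 2.0 * ph) * 0.5)
        return np.full_like(ph, f0)

    # place glottal pulses: per-cycle multiplicative period perturbation
    sig_j = _GAUSS_LOCAL * params.jitter_frac
    sig_s = _GAUSS_LOCAL * params.shimmer_frac
    times, amps = [], []
    t = 1.0 / f0_at(np.array([0.0]))[0]  # first pulse after one period
    while t < dur - 0.5 / f0:
        times.append(t)
        amps.append(max(0.05, 1.0 + sig_s * rng.standard_normal()))
        period = 1.0 / f0_at(np.array([t]))[0]
        period *= float(np.clip(1.0 + sig_j * rng.standard_normal(), 0.6, 1.4))
        t += period
    # band-limited pulses at fractional-sample positions (windowed sinc),
    # so the programmed periods are exact rather than quantised to 1/fs
    src = np.zeros(n)
    half = 16
    kspan = np.arange(-half, half + 1)
    hann = 0.5 + 0.5 * np.cos(np.pi * kspan / (half + 1))
    for tt, aa in zip(times, amps):
        fi = tt * fs
        i0 = int(np.floor(fi))
        frac = fi - i0
        kernel = aa * hann * np.sinc(kspan - frac)
        j0, j1 = i0 - half, i0 + half + 1
        k0 = max(0, -j0)
        k1 = len(kernel) - max(0, j1 - n)
        if k1 > k0:
            src[max(0, j0) : min(n, j1)] += kernel[k0:k1]

    sos = _resonator_sos(params.formants, params.formant_bw, fs)
    clean = signal.sosfilt(sos, src)

    p_harm = float(np.mean(clean**2))
    p_noise = p_harm * 10.0 ** (-params.hnr_db / 10.0)
    x = clean + np.sqrt(p_noise) * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    return (0.99 / peak) * x if peak > 0 else x


def synth_episode(
    profile: ConditionProfile,
    seed: int | np.random.Generator,
    fs: int = AUDIO_FS,
    arousal: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Synthesise one cry episode: alternating cry units and silent gaps.

    ``arousal`` is a per-episode latent (z-score) that lengthens units
    and shortens gaps, so that the fraction of vocalised time covaries
    with the physiological offsets applied to NIRS and COMFORT for the
    same episode.  Returns the waveform and a ground-truth record with
    unit boundaries, per-unit F0 means and cryCE / unvoicedCE totals.
    """
    if profile.cry_params is None or profile.condition == "resting":
        raise ValueError("episodes can only be synthesised for cry/distress conditions")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = profile.cry_params
    u_lo, u_hi = p.unit_dur_range
    g_lo, g_hi = p.gap_dur_range
    u_scale = float(np.clip(1.0 + 0.15 * arousal, 0.6, 1.4))
    g_scale = float(np.clip(1.0 - 0.15 * arousal, 0.6, 1.4))

    pieces, units, gaps = [], [], []
    f0_units = []
    t = 0.0
    for k in range(p.n_units):
        dur = float(rng.uniform(u_lo, u_hi)) * u_scale
        f0_u = float(np.clip(rng.normal(p.f0_mean, p.f0_sd), 250.0, 1100.0))
        x = synth_cry_unit(p, dur, rng, fs=fs, f0_mean=f0_u)
        # short raised-cosine fades avoid segmentation edge clicks
        x = _fade(x, fs)
        pieces.append(x)
        units.append((t, t + len(x) / fs))
        f0_units.append(f0_u)
        t += len(x) / fs
        if k < p.n_units - 1:
            gdur = float(rng.uniform(g_lo, g_hi)) * g_scale
            gn = int(round(gdur * fs))
            pieces.append(_breath_noise(gn, rng))
            gaps.append((t, t + gn / fs))
            t += gn / fs
    wav = np.concatenate(pieces)
    cry_s = sum(e - s for s, e in units)
    unv_s = sum(e - s for s, e in gaps)
    truth = {
        "condition": profile.condition,
        "units": units,
        "gaps": gaps,
        "f0_units": f0_units,
        "cryCE": cry_s,
        "unvoicedCE": unv_s,
        "params": asdict(p),
        "arousal": arousal,
    }
    return wav, truth


def _fade(x: np.ndarray, fs: int, fade_s: float = 0.01) -> np.ndarray:
    nf = min(int(fade_s * fs), len(x) // 4)
    if nf > 0:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(nf) / nf)
        x = x.copy()
        x[:nf] *= ramp
        x[-nf:] *= ramp[::-1]
    return x


def _breath_noise(n: int, rng: np.random.Generator, level: float = 5e-4) -> np.ndarray:
    """Very low-level pink noise standing in for room tone / breathing."""
    if n == 0:
        return np.zeros(0)
    return level * _pink_noise(n, rng)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# EEG synthesis


def synth_eeg(
    timeline: list[tuple[float, float, str]],
    profiles: dict[str, ConditionProfile],
    seed: int | np.random.Generator,
    fs: int = EEG_FS,
    artifact_rate_per_min: float = 0.0,
    flat_channel: str | None = None,
) -> np.ndarray:
    """Synthesise the 8-channel EEG (uV) covering the whole timeline.

    Per channel and condition interval: 1/f background plus
    band-limited delta/theta/alpha oscillators whose SDs follow the
    condition profile, plus a small broadband residual.  Optionally
    injects >200 uV amplitude bursts (for rejection tests) and one flat
    channel (for bad-channel tests).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    _check_timeline(timeline)
    total = timeline[-1][1]
    n_total = int(round(total * fs))
    n_ch = len(EEG_CHANNELS)
    data = np.zeros((n_ch, n_total))

    sos_bands = {
        name: signal.butter(4, lohi, btype="bandpass", fs=fs, output="sos")
        for name, lohi in (("delta", (1.0, 4.0)), ("theta", (4.0, 8.0)), ("alpha", (8.0, 12.0)))
    }
    for start, end, label in timeline:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        nseg = i1 - i0
        if nseg <= 0:
            continue
        gains = profiles[label].eeg_band_gains
        # volume conduction: every channel mixes a shared source with a
        # channel-specific one, giving realistic inter-channel correlation
        mix = 0.6
        shared = {name: signal.sosfilt(sos, rng.standard_normal(nseg))
                  for name, sos in sos_bands.items()}
        shared_pink = _pink_noise(nseg, rng)
        for c in range(n_ch):
            x = 6.0 * (np.sqrt(mix) * shared_pink
                       + np.sqrt(1 - mix) * _pink_noise(nseg, rng))
            for name, sos in sos_bands.items():
                osc = (np.sqrt(mix) * shared[name]
                       + np.sqrt(1 - mix) * signal.sosfilt(sos, rng.standard_normal(nseg)))
                sd = osc.std()
                if sd > 0:
                    x += gains[name] * osc / sd
            data[c, i0:i1] = x

    if artifact_rate_per_min > 0:
        n_art = rng.poisson(artifact_rate_per_min * total / 60.0)
        for _ in range(n_art):
            t0 = rng.uniform(0, total - 0.5)
            j0 = int(t0 * fs)
            burst = 500.0 * np.hanning(int(0.4 * fs))
            j1 = min(j0 + len(burst), n_total)
            data[:, j0:j1] += burst[: j1 - j0]
    if flat_channel is not None:
        data[EEG_CHANNELS.index(flat_channel)] = 0.0
    return data


def _check_timeline(timeline) -> None:
    if not timeline:
        raise ValueError("empty timeline")
    prev_end = 0.0
    for start, end, _ in timeline:
        if abs(start - prev_end) > 1e-6:
            raise ValueError("timeline has gaps or overlaps")
        if end <= start:
            raise ValueError("empty timeline interval")
        prev_end = end


# ---------------------------------------------------------------------------
# NIRS and COMFORT synthesis


def synth_nirs(
    timeline: list[tuple[float, float, str]],
    profiles: dict[str, ConditionProfile],
    seed: int | np.random.Generator,
    dt: float = NIRS_DT,
    noise_sd: dict | None = None,
    episode_offsets: dict | None = None,
    dropout_runs: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """NIRS time series sampled every ``dt`` seconds over the timeline.

    Values are Gaussian around the condition means, with optional
    per-episode offsets (keyed by interval start time) that couple the
    physiology to episode arousal, and optional flat dropout runs that
    exercise the SD < 0.5 acquisition-error rule.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    _check_timeline(timeline)
    noise_sd = noise_sd or {"rSO2": 1.5, "SpO2": 1.0, "PR": 4.0}
    total = timeline[-1][1]
    t = np.arange(0.0, total, dt)
    cols = {"rSO2": np.empty(len(t)), "SpO2": np.empty(len(t)), "PR": np.empty(len(t))}
    for start, end, label in timeline:
        m = (t >= start) & (t < end)
        levels = dict(profiles[label].nirs_levels)
        if episode_offsets and start in episode_offsets:
            for k, v in episode_offsets[start].items():
                levels[k] = levels[k] + v
        for k in cols:
            cols[k][m] = levels[k] + noise_sd[k] * rng.standard_normal(int(m.sum()))
    cols["SpO2"] = np.clip(cols["SpO2"], 0.0, 100.0)
    df = pd.DataFrame({"t_s": t, **cols})
    if dropout_runs:
        for start, end in dropout_runs:
            m = (df["t_s"] >= start) & (df["t_s"] < end)
            for k in ("rSO2", "SpO2", "PR"):
                df.loc[m, k] = float(df.loc[m, k].iloc[0]) if m.any() else np.nan
    return df


def synth_comfort(
    profile: ConditionProfile,
    seed: int | np.random.Generator,
    shift: float = 0.0,
    item_sd: float = 0.7,
) -> tuple[int, ...]:
    """Draw one six-item COMFORT assessment on the 1-5 integer scale."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    items = rng.normal(np.asarray(profile.comfort_item_means) + shift, item_sd)
    return tuple(int(v) for v in np.clip(np.round(items), 1, 5))


def synth_unit_dataset(
    n_units: int,
    seed: int,
    profiles: dict[str, ConditionProfile] | None = None,
    fs: int = AUDIO_FS,
    balance: float = 0.5,
) -> tuple[list[np.ndarray], list[str]]:
    """Synthesise a labelled set of isolated cry/distress units.

    Unit durations and per-unit F0 are drawn from each condition's
    profile; ``balance`` is the fraction of cry (non-distress) units.
    Used to build classifier datasets without assembling sessions.
    """
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    n_cry = int(round(balance * n_units))
    labels = ["cry"] * n_cry + ["distress"] * (n_units - n_cry)
    waves = []
    for lab in labels:
        p = profiles[lab].cry_params
        dur = float(rng.uniform(*p.unit_dur_range))
        f0_u = float(np.clip(rng.normal(p.f0_mean, p.f0_sd), 250.0, 1100.0))
        waves.append(synth_cry_unit(p, dur, rng, fs=fs, f0_mean=f0_u))
    return waves, labels


# ---------------------------------------------------------------------------
# whole sessions


def synth_session(
    seed: int,
    profiles: dict[str, ConditionProfile] | None = None,
    sim: SimulateConfig | None = None,
    fs: int = AUDIO_FS,
) -> SessionBundle:
    """Generate a full synthetic session.

    Resting blocks alternate with cry and distress episodes.  Each
    episode carries a latent arousal z-score that jointly drives its
    vocalised-time fraction, its NIRS offsets (PR up, rSO2/SpO2 down)
    and its COMFORT shift, reproducing the qualitative cross-modal
    correlation structure of real sessions.
    """
    sim = sim or SimulateConfig()
    profiles = profiles or default_profiles()
    for pr in profiles.values():
        pr.validate()
    rng = np.random.default_rng(seed)

    order = ["cry", "distress"] * max(sim.n_cry_episodes, sim.n_distress_episodes)
    counts = {"cry": 0, "distress": 0}
    episode_plan = []
    for cond in order:
        limit = sim.n_cry_episodes if cond == "cry" else sim.n_distress_episodes
        if counts[cond] < limit:
            episode_plan.append(cond)
            counts[cond] += 1

    pieces, annotations = [], []
    episode_truth, episode_offsets = [], {}
    comfort_rows = []
    t = 0.0

    def add_resting(dur: float) -> None:
        nonlocal t
        n = int(round(dur * fs))
        pieces.append(_breath_noise(n, rng))
        annotations.append((t, t + n / fs, "resting"))
        t += n / fs

    add_resting(sim.resting_block_s)
    for ep_id, cond in enumerate(episode_plan):
        arousal = float(rng.standard_normal())
        prof = profiles[cond]
        prof.cry_params.n_units = sim.units_per_episode
        wav, truth = synth_episode(prof, rng, fs=fs, arousal=arousal)
        start = t
        pieces.append(wav)
        annotations.append((start, start + len(wav) / fs, cond))
        t += len(wav) / fs
        truth["start_s"] = start
        truth["episode_id"] = ep_id
        episode_truth.append(truth)
        episode_offsets[start] = {
            "PR": 8.0 * arousal, "rSO2": -1.5 * arousal, "SpO2": -0.8 * arousal,
        }
        items = synth_comfort(prof, rng, shift=0.6 * arousal)
        comfort_rows.append(
            {"episode_id": ep_id, "condition": cond,
             "alertness": items[0], "agitation": items[1], "crying": items[2],
             "body_movements": items[3], "muscular_tone": items[4],
             "facial_tension": items[5], "total": sum(items)}
        )
        add_resting(sim.resting_block_s)

    audio = np.concatenate(pieces)
    # snap the timeline end to an integer number of NIRS samples
    timeline = [(round(s, 6), round(e, 6), lab) for s, e, lab in annotations]
    timeline = _contiguous(timeline)

    eeg = synth_eeg(
        timeline, profiles, rng,
        artifact_rate_per_min=sim.eeg_artifact_rate,
    )
    offsets = {round(k, 6): v for k, v in episode_offsets.items()}
    dropout = [(30.0, 90.0)] if sim.nirs_dropout else None
    nirs = synth_nirs(timeline, profiles, rng, episode_offsets=offsets, dropout_runs=dropout)
    comfort = pd.DataFrame(comfort_rows)

    truth = {
        "seed": seed,
        "episodes": episode_truth,
        "profiles": {k: _profile_dict(v) for k, v in profiles.items()},
    }
    return SessionBundle(
        audio=audio, fs=fs, annotations=timeline,
        eeg=eeg, eeg_fs=EEG_FS, eeg_channels=EEG_CHANNELS,
        nirs=nirs, comfort=comfort, truth=truth,
    )


def _contiguous(timeline):
    """Force exact start/end continuity after rounding."""
    out = []
    t = 0.0
    for start, end, lab in timeline:
        dur = end - start
        out.append((t, t + dur, lab))
        t += dur
    return out


def _profile_dict(p: ConditionProfile) -> dict:
    d = {
        "condition": p.condition,
        "eeg_band_gains": dict(p.eeg_band_gains),
        "nirs_levels": dict(p.nirs_levels),
        "comfort_item_means": list(p.comfort_item_means),
    }
    if p.cry_params is not None:
        d["cry_params"] = asdict(p.cry_params)
    return d
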