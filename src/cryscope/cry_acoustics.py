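"""Cry segmentation and per-unit acoustic feature extraction.

Implements the audio side of the analysis: energy+voicing segmentation
of a recording into cry episodes (CEs) and cry units (CUs), time-domain
bookkeeping (cryCE / unvoicedCE and their fractions), the pitch
contour restricted to 200-1200 Hz with its descriptive statistics and
the high-pitch (F0 >= 800 Hz) / hyper-phonation (F0 >= 1000 Hz)
fractions, voice-quality measures (local jitter, local shimmer, HNR),
LPC formants (F1-F3) after a 10 kHz low-pass, and the MFCC / mel
spectrogram representations used by the distress classifier.

Jitter, shimmer and HNR are measured cycle-synchronously: glottal
cycle marks are picked on the 200-1200 Hz band-passed signal and
refined to sub-sample precision by cross-correlating consecutive
cycles of the full-band waveform.  Periods come from the refined
inter-mark lags, amplitudes from an aligned projection onto the mean
cycle template, and HNR from the mean normalised correlation r between
consecutive cycles via HNR = 10*log10(r / (1-r)).  A frame-wise
autocorrelation at a fixed lag would be biased low whenever the period
itself fluctuates (which is exactly what jitter means), whereas the
cycle-aligned correlation isolates the additive-noise component.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.fft import dct, rfft

from .config import AcousticsConfig

_EPS = 1e-12


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CryUnit:
    start: float
    end: float
    condition: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("cry unit must have end > start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class CryEpisode:
    """A crying bout: cry units separated by unvoiced gaps."""

    units: list[CryUnit]
    unvoiced_intervals: list[tuple[float, float]]
    condition: str | None = None

    @property
    def start(self) -> float:
        return self.units[0].start

    @property
    def end(self) -> float:
        return self.units[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TimeFeatures:
    cryCE: float
    unvoicedCE: float
    cryCE_pct: float
    unvoicedCE_pct: float


@dataclass
class AcousticFeatureVector:
    f0_mean: float = np.nan
    f0_min: float = np.nan
    f0_max: float = np.nan
    f0_sd: float = np.nan
    f1: float = np.nan
    f2: float = np.nan
    f3: float = np.nan
    high_pitch_pct: float = np.nan
    hyperphonation_pct: float = np.nan
    jitter_local: float = np.nan
    shimmer_local: float = np.nan
    hnr: float = np.nan
    valid: bool = True


# ---------------------------------------------------------------------------
# framing helpers


def _frame(x: np.ndarray, flen: int, hop: int) -> np.ndarray:
    if len(x) < flen:
        return np.empty((0, flen))
    n = 1 + (len(x) - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _norm_autocorr(frames: np.ndarray, max_lag: int) -> np.ndarray:
    """Unbiased normalised autocorrelation per frame up to ``max_lag``."""
    n = frames.shape[1]
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : max_lag + 1]
    lag = np.arange(max_lag + 1)
    unbias = n / np.maximum(n - lag, 1)
    acn = ac * unbias[None, :]
    r0 = acn[:, 0].copy()
    r0[r0 <= 0] = np.inf
    return acn / r0[:, None]


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


# ---------------------------------------------------------------------------
# segmentation


def detect_voiced_regions(
    x: np.ndarray,
    fs: float,
    cfg: AcousticsConfig | None = None,
    condition: str | None = None,
) -> list[CryEpisode]:
    """Segment a mono recording into cry episodes of voiced cry units.

    Frames are classified as cry when their short-time energy exceeds
    ``energy_threshold_db`` (relative to the loudest frame) *and* the
    band-passed normalised autocorrelation shows periodicity in the
    200-1200 Hz pitch range.  Contiguous voiced runs become cry units;
    gaps shorter than ``episode_break_s`` stay inside the episode as
    unvoiced intervals, longer gaps split episodes.  Runs shorter than
    ``min_unit_s`` are discarded as segmentation noise.
    """
    cfg = cfg or AcousticsConfig()
    x = np.asarray(x, dtype=np.float64)
    if len(x) == 0 or np.all(x == x[0]):
        return []
    flen = int(round(cfg.f0_frame_s * fs))
    hop = int(round(cfg.f0_hop_s * fs))
    frames = _frame(x, flen, hop)
    if len(frames) == 0:
        return []
    energy = np.mean(frames**2, axis=1)
    peak = energy.max()
    if peak <= 0:
        return []
    edb = 10.0 * np.log10(np.maximum(energy / peak, _EPS))
    energetic = edb > cfg.energy_threshold_db

    xb = _bandpass(x, fs, *cfg.f0_band_hz)
    fb = _frame(xb, flen, hop)
    lag_lo = int(np.floor(fs / cfg.f0_band_hz[1]))
    lag_hi = int(np.ceil(fs / cfg.f0_band_hz[0]))
    r = _norm_autocorr(fb, lag_hi)
    rmax = r[:, lag_lo : lag_hi + 1].max(axis=1)
    voiced = energetic & (rmax >= cfg.voicing_threshold)

    # close sub-min_gap dips, then extract runs
    voiced = _close_gaps(voiced, int(np.ceil(cfg.min_gap_s / cfg.f0_hop_s)))
    runs = _runs(voiced)
    hop_s = cfg.f0_hop_s
    frame_s = cfg.f0_frame_s
    units = []
    for i0, i1 in runs:
        start = i0 * hop_s
        end = (i1 - 1) * hop_s + frame_s
        if end - start >= cfg.min_unit_s:
            units.append(CryUnit(start, min(end, len(x) / fs), condition))
    if not units:
        return []

    episodes: list[CryEpisode] = []
    cur_units = [units[0]]
    cur_gaps: list[tuple[float, float]] = []
    for u in units[1:]:
        gap = u.start - cur_units[-1].end
        if gap > cfg.episode_break_s:
            episodes.append(CryEpisode(cur_units, cur_gaps, condition))
            cur_units, cur_gaps = [u], []
        else:
            if gap > 0:
                cur_gaps.append((cur_units[-1].end, u.start))
            cur_units.append(u)
    episodes.append(CryEpisode(cur_units, cur_gaps, condition))
    return episodes


def _close_gaps(mask: np.ndarray, max_len: int) -> np.ndarray:
    out = mask.copy()
    for i0, i1 in _runs(~mask):
        if i1 - i0 <= max_len and i0 > 0 and i1 < len(mask):
            out[i0:i1] = True
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if len(mask) == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask)]
    return list(zip(starts, ends))


def time_features(episode: CryEpisode) -> TimeFeatures:
    """cryCE / unvoicedCE durations and their fractions of the episode."""
    cry = sum(u.duration for u in episode.units)
    unv = sum(e - s for s, e in episode.unvoiced_intervals)
    total = cry + unv
    if total <= 0:
        raise ValueError("episode has zero duration")
    return TimeFeatures(cry, unv, cry / total, unv / total)


# ---------------------------------------------------------------------------
# pitch


@dataclass
class F0Contour:
    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray
    strength: np.ndarray = field(default=None)  # band-passed autocorr at the pick


def f0_contour(x: np.ndarray, fs: float, cfg: AcousticsConfig | None = None) -> F0Contour:
    """Frame-wise F0 in the 200-1200 Hz search range with voicing flags.

    The waveform is band-passed to 200-1200 Hz before the normalised
    autocorrelation pitch search.  A frame is voiced when the
    band-passed autocorrelation at the picked lag reaches
    ``voicing_threshold`` *and* the raw-waveform autocorrelation at the
    same lag reaches ``voicing_threshold_full`` (band-limited noise
    alone can be locally self-similar, the full-band check rejects
    it).  Among autocorrelation peaks within ``octave_margin`` of the
    maximum the shortest lag wins, which suppresses octave errors.
    """
    cfg = cfg or AcousticsConfig()
    x = np.asarray(x, dtype=np.float64)
    flen = int(round(cfg.f0_frame_s * fs))
    hop = int(round(cfg.f0_hop_s * fs))
    lag_lo = int(np.floor(fs / cfg.f0_band_hz[1]))
    lag_hi = int(np.ceil(fs / cfg.f0_band_hz[0]))
    if len(x) < max(flen, 3 * lag_hi // 2):
        return F0Contour(np.empty(0), np.empty(0), np.empty(0, bool), np.empty(0))

    xb = _bandpass(x, fs, *cfg.f0_band_hz)
    fb = _frame(xb, flen, hop)
    fr = _frame(x, flen, hop)
    nfr = len(fb)
    r_bp = _norm_autocorr(fb, lag_hi + 1)
    r_full = _norm_autocorr(fr, lag_hi + 1)

    times = (np.arange(nfr) * hop + flen / 2) / fs
    f0 = np.full(nfr, np.nan)
    voiced = np.zeros(nfr, dtype=bool)
    strength = np.zeros(nfr)
    energy = np.mean(fr**2, axis=1)
    floor = max(energy.max() * 1e-6, _EPS)

    for i in range(nfr):
        seg = r_bp[i, lag_lo : lag_hi + 1]
        peaks, _ = signal.find_peaks(seg)
        if len(peaks) == 0:
            continue
        best = seg[peaks].max()
        cands = peaks[seg[peaks] >= best - cfg.octave_margin]
        k = int(cands.min()) + lag_lo
        # parabolic refinement of the lag
        if 0 < k < r_bp.shape[1] - 1:
            a, b, c = r_bp[i, k - 1], r_bp[i, k], r_bp[i, k + 1]
            denom = a - 2 * b + c
            delta = 0.5 * (a - c) / denom if abs(denom) > _EPS else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        k_ref = k + delta
        strength[i] = r_bp[i, k]
        if (
            r_bp[i, k] >= cfg.voicing_threshold
            and r_full[i, min(k, r_full.shape[1] - 1)] >= cfg.voicing_threshold_full
            and energy[i] > floor
        ):
            voiced[i] = True
            f0[i] = fs / k_ref
    return F0Contour(times, f0, voiced, strength)


def f0_statistics(contour: F0Contour, cfg: AcousticsConfig | None = None) -> dict:
    """Descriptive F0 statistics over voiced frames only."""
    cfg = cfg or AcousticsConfig()
    v = contour.f0[contour.voiced]
    if len(v) == 0:
        return {k: np.nan for k in
                ("f0_mean", "f0_min", "f0_max", "f0_sd", "high_pitch_pct", "hyperphonation_pct")}
    return {
        "f0_mean": float(np.mean(v)),
        "f0_min": float(np.min(v)),
        "f0_max": float(np.max(v)),
        "f0_sd": float(np.std(v)),
        "high_pitch_pct": float(np.mean(v >= cfg.high_pitch_hz)),
        "hyperphonation_pct": float(np.mean(v >= cfg.hyperphonation_hz)),
    }


# ---------------------------------------------------------------------------
# voice quality: jitter, shimmer, HNR


def jitter_local(periods) -> float:
    """Local jitter: mean |T_{i+1} - T_i| / mean T_i."""
    periods = np.asarray(periods, dtype=np.float64)
    if len(periods) < 2:
        return np.nan
    return float(np.mean(np.abs(np.diff(periods))) / np.mean(periods))


def shimmer_local(amplitudes) -> float:
    """Local shimmer: mean |A_{i+1} - A_i| / mean A_i."""
    amps = np.asarray(amplitudes, dtype=np.float64)
    if len(amps) < 2:
        return np.nan
    return float(np.mean(np.abs(np.diff(amps))) / np.mean(amps))


@dataclass
class CycleMeasures:
    periods: np.ndarray        # s, refined consecutive-cycle lags
    amplitudes: np.ndarray     # aligned template projections, arbitrary units
    pair_correlation: np.ndarray
    jitter_noise_floor: float = 0.0  # expected measured jitter at zero true jitter


def cycle_measures(
    x: np.ndarray, fs: float, cfg: AcousticsConfig | None = None,
    contour: F0Contour | None = None,
) -> CycleMeasures | None:
    """Pitch-synchronous periods, amplitudes and pair correlations.

    Marks are peaks of the 200-1200 Hz band-passed waveform spaced by
    roughly one median pitch period; each consecutive pair of
    cycle windows of the raw waveform is then aligned by maximising
    their normalised cross-correlation over a small lag range with
    parabolic interpolation, yielding sub-sample periods and the
    noise-limited correlation used for HNR.
    """
    cfg = cfg or AcousticsConfig()
    x = np.asarray(x, dtype=np.float64)
    if contour is None:
        contour = f0_contour(x, fs, cfg)
    v = contour.f0[contour.voiced]
    if len(v) < 2:
        return None
    f0_med = float(np.median(v))
    period = fs / f0_med
    xb = _bandpass(x, fs, *cfg.f0_band_hz)
    marks, _ = signal.find_peaks(xb, distance=max(2, int(0.7 * period)))
    if len(marks) < 3:
        return None
    heights = xb[marks]
    marks = marks[heights > 0.25 * np.median(heights)]
    if len(marks) < 3:
        return None

    L = max(8, int(round(cfg.cycle_window_frac * period)))
    a = int(round(0.1 * L))  # window starts just before the pulse attack
    search = max(3, int(round(0.004 * period)) + 5)

    # timing runs on a low-passed copy: the glottal signal carries almost
    # no energy above ~8 kHz while the additive noise is broadband, so
    # discarding the top octaves sharpens the matched-filter lag estimate
    lp = signal.butter(6, min(8000.0, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    xt = signal.sosfiltfilt(lp, x)

    wins = []
    valid_marks = []
    for m in marks:
        i0 = m - a
        if i0 < 0 or i0 + L > len(x):
            continue
        wins.append(x[i0 : i0 + L])
        valid_marks.append(m)
    if len(wins) < 3:
        return None
    W = np.asarray(wins)
    valid_marks = np.asarray(valid_marks)

    # per-cycle event times: align each low-passed cycle window to the
    # mean cycle template (the pulse response is shape-invariant across
    # the unit, so a single template applies to every cycle); two
    # alignment passes sharpen the template against initial mark noise
    offsets = np.zeros(len(valid_marks))
    alphas = np.zeros(len(valid_marks))
    tmpl_t = None
    for _ in range(2):
        Wt = np.asarray([
            xt[i0 : i0 + L]
            for m, o in zip(valid_marks, offsets)
            for i0 in (int(np.clip(m - a + int(round(o)), 0, len(xt) - L)),)
        ])
        nt = np.linalg.norm(Wt, axis=1)
        nt[nt <= 0] = _EPS
        tmpl_t = (Wt / nt[:, None]).mean(axis=0)
        tmpl_t /= max(np.linalg.norm(tmpl_t), _EPS)
        fits = [_template_offset(xt, m - a, L, tmpl_t, search) for m in valid_marks]
        offsets = np.asarray([f[0] for f in fits])
        alphas = np.asarray([f[1] for f in fits])
    event_t = (valid_marks + offsets) / fs

    periods, rhos = [], []
    for i in range(len(valid_marks) - 1):
        gap = valid_marks[i + 1] - valid_marks[i]
        if not (0.6 * period <= gap <= 1.6 * period):
            periods.append(np.nan)
            rhos.append(np.nan)
            continue
        tau = (event_t[i + 1] - event_t[i]) * fs
        periods.append(event_t[i + 1] - event_t[i])
        rhos.append(_pair_rho(x, valid_marks[i] - a, tau, L))
    periods = np.asarray(periods)
    rhos = np.asarray(rhos)
    good = np.isfinite(periods)
    # mark artifacts: genuine cycle-to-cycle jitter stays within a few
    # percent of the slowly varying contour period, so periods deviating
    # >20% from a running median are mis-picked marks, not phonation
    if good.sum() >= 5:
        filled = np.where(good, periods, np.nanmedian(periods[good]))
        run_med = signal.medfilt(filled, kernel_size=15)
        good &= np.abs(periods / np.maximum(run_med, _EPS) - 1.0) <= 0.20

    # expected contribution of timing noise to the measured jitter: the
    # per-event matched-filter timing error is sigma_n / (alpha * |u'|)
    # (alpha = template correlation peak, u = unit-norm template); a
    # second difference of event times has variance 6 sigma_t^2, so at
    # zero true jitter E|dT| = sqrt(2/pi * 6) sigma_t.  The template
    # derivative lies inside the timing low-pass band, so the full
    # broadband noise density applies (low-passing the copy does not
    # reduce the noise the matched filter actually sees).
    r_mean = float(np.clip(np.nanmean(rhos), 0.0, 1.0 - 1e-9)) if good.any() else 0.0
    p_win = float(np.mean(W**2))
    sigma_nt = np.sqrt(max((1.0 - r_mean) * p_win, 0.0))
    du_norm = float(np.linalg.norm(np.diff(tmpl_t)))
    alpha_med = float(np.median(alphas[alphas > 0])) if (alphas > 0).any() else 0.0
    if alpha_med > 0 and du_norm > 0 and good.any():
        sigma_t = sigma_nt / (alpha_med * du_norm)
        floor = np.sqrt(2.0 / np.pi * 6.0) * sigma_t / (float(np.nanmean(periods)) * fs)
    else:
        floor = 0.0

    # aligned template projection for amplitudes
    norms = np.linalg.norm(W, axis=1)
    norms[norms <= 0] = _EPS
    template = (W / norms[:, None]).mean(axis=0)
    template /= max(np.linalg.norm(template), _EPS)
    amps = np.empty(len(W))
    for i, m in enumerate(valid_marks):
        amps[i] = _aligned_projection(x, m - a, L, template, 3)

    return CycleMeasures(periods[good], amps, rhos[good], jitter_noise_floor=float(floor))


def _sinc_peak(lags: np.ndarray, scores: np.ndarray, d_int: int) -> tuple[float, float]:
    """Continuous peak of a band-limited score sequence near ``d_int``.

    Cross-correlations of sampled signals are band-limited to the
    Nyquist frequency, so their integer-lag samples determine the
    continuous function exactly; a three-point parabola, by contrast,
    is visibly biased when the peak is only a couple of samples wide.
    The sinc series is evaluated on a fine grid one sample either side
    of the integer maximum.
    """
    tau = np.arange(d_int - 1.0, d_int + 1.0001, 0.05)
    vals = np.sinc(tau[:, None] - lags[None, :]) @ scores
    i = int(np.argmax(vals))
    # final parabolic touch-up on the fine grid
    if 0 < i < len(tau) - 1:
        a_, b_, c_ = vals[i - 1], vals[i], vals[i + 1]
        denom = a_ - 2 * b_ + c_
        delta = 0.5 * (a_ - c_) / denom if abs(denom) > _EPS else 0.0
        return float(tau[i] + np.clip(delta, -0.5, 0.5) * 0.05), float(b_)
    return float(tau[i]), float(vals[i])


def _template_offset(xt, i0, L, template, search):
    """Sub-sample offset aligning one cycle window to the template.

    Matched-filter timing: the template is nearly noise-free, so only
    the window contributes noise; the continuous peak of the
    cross-correlation is located by sinc interpolation.
    """
    d0, d1 = -search - 6, search + 6
    j_lo = max(0, i0 + d0)
    j_hi = min(len(xt), i0 + d1 + L)
    if j_hi - j_lo < L:
        return 0.0, 0.0
    wins = np.lib.stride_tricks.sliding_window_view(xt[j_lo:j_hi], L)
    scores = wins @ template
    lags = np.arange(j_lo - i0, j_lo - i0 + len(scores), dtype=float)
    inner = np.abs(lags) <= search
    if not inner.any():
        return 0.0, 0.0
    d_int = int(lags[inner][np.argmax(scores[inner])])
    d, peak = _sinc_peak(lags, scores, d_int)
    return float(np.clip(d, -search, search)), float(peak)


def _pair_rho(x, i0, tau, L):
    """Normalised correlation between consecutive raw-waveform cycles.

    Evaluated *at* the independently estimated cycle lag ``tau``
    (sinc-interpolated numerator, linearly interpolated window
    energy).  Maximising rho over lags instead would pick the upper
    tail of its sampling noise and bias HNR high at low HNR.  The
    full-band noise power is what limits the value, which is what the
    HNR statistic needs.
    """
    w0 = x[i0 : i0 + L]
    n0 = np.linalg.norm(w0)
    d_int = int(round(tau))
    j_lo = max(0, i0 + d_int - 8)
    j_hi = min(len(x), i0 + d_int + 8 + L)
    if j_hi - j_lo < L:
        return np.nan
    wins = np.lib.stride_tricks.sliding_window_view(x[j_lo:j_hi], L)
    nums = wins @ w0
    energies = np.einsum("ij,ij->i", wins, wins)
    lags = np.arange(j_lo - i0, j_lo - i0 + len(nums), dtype=float)
    if not (lags[0] <= tau <= lags[-1]):
        return np.nan
    num_tau = float(np.sinc(tau - lags) @ nums)
    e_tau = float(np.interp(tau, lags, energies))
    rho = num_tau / max(n0 * np.sqrt(max(e_tau, _EPS)), _EPS)
    return min(rho, 1.0)


def _aligned_projection(x, i0, L, template, search):
    best = 0.0
    for d in range(-search, search + 1):
        j0 = i0 + d
        if j0 < 0 or j0 + L > len(x):
            continue
        p = float(x[j0 : j0 + L] @ template)
        if abs(p) > abs(best):
            best = p
    return abs(best)


def hnr(
    x: np.ndarray, fs: float, cfg: AcousticsConfig | None = None,
    measures: CycleMeasures | None = None,
) -> float:
    """Harmonics-to-noise ratio in dB, clipped to [-10, 40].

    r is the mean normalised correlation between consecutive aligned
    glottal cycles; HNR = 10*log10(r / (1 - r)).  For a periodic
    signal plus independent additive noise E[r] = P_h / (P_h + P_n),
    so the statistic recovers the harmonic/noise power ratio.
    """
    cfg = cfg or AcousticsConfig()
    if measures is None:
        measures = cycle_measures(x, fs, cfg)
    if measures is None or len(measures.pair_correlation) == 0:
        return np.nan
    r = float(np.clip(np.mean(measures.pair_correlation), 1e-6, 1 - 1e-6))
    val = 10.0 * np.log10(r / (1.0 - r))
    return float(np.clip(val, *cfg.hnr_clip_db))


# ---------------------------------------------------------------------------
# formants


def formants(
    x: np.ndarray, fs: float, cfg: AcousticsConfig | None = None,
    contour: F0Contour | None = None,
) -> tuple[float, float, float]:
    """(F1, F2, F3) in Hz by harmonic-domain resonance fitting, or NaNs.

    Conventional frame-wise linear prediction is unreliable at infant
    fundamental frequencies (350-700 Hz): the envelope is sampled only
    at widely spaced harmonics and all-pole fits lock onto individual
    harmonic lines.  Instead the unit is low-passed at 10 kHz,
    resampled to 20 kHz, and its Welch-averaged power spectrum is
    reduced to one *integrated* energy per harmonic of the median F0
    (integration over +-0.45 F0 makes the sample invariant to
    jitter/contour line-broadening).  A three-resonance source-filter
    magnitude model — gain, spectral-tilt and noise-floor terms plus
    three Lorentzian resonance pairs with bounded half-widths — is fit
    to the log harmonic energies by robust least squares from several
    starting layouts; the best fit's resonance centres, sorted
    ascending, are F1-F3.  Units with no voiced frames or too few
    harmonics return NaNs.
    """
    cfg = cfg or AcousticsConfig()
    x = np.asarray(x, dtype=np.float64)
    if contour is None:
        contour = f0_contour(x, fs, cfg)
    v = contour.f0[contour.voiced]
    if len(v) == 0:
        return (np.nan,) * 3
    f0_med = float(np.median(v))
    hf, ha = _harmonic_energies(x, fs, f0_med, cfg)
    if len(hf) < 6:
        return (np.nan,) * 3
    est = _fit_resonances(hf, ha, cfg)
    if len(est) < 3:
        return (np.nan,) * 3
    return tuple(float(f) for f in est)


def _harmonic_energies(x, fs, f0, cfg):
    """Integrated spectral energy around each harmonic of ``f0``."""
    sos = signal.butter(8, cfg.formant_lowpass_hz, btype="lowpass", fs=fs, output="sos")
    xl = signal.sosfiltfilt(sos, x)
    g = np.gcd(int(fs), cfg.formant_fs)
    xr = signal.resample_poly(xl, cfg.formant_fs // g, int(fs) // g)
    fsa = cfg.formant_fs
    nper = min(2048, len(xr))
    f, P = signal.welch(xr, fs=fsa, nperseg=nper, noverlap=nper // 2,
                        nfft=max(8192, nper), window="hann")
    df = f[1] - f[0]
    fmax = cfg.formant_fit_fmax_hz
    hf, ha = [], []
    for k in range(1, int(fmax / f0) + 1):
        lo = int((k * f0 - 0.45 * f0) / df)
        hi = int((k * f0 + 0.45 * f0) / df)
        if lo < 1 or hi >= len(f) - 1:
            continue
        hf.append(k * f0)
        ha.append(np.log(max(float(P[lo:hi].sum() * df), 1e-30)))
    return np.asarray(hf), np.asarray(ha)


def _resonance_log(fx, F, g):
    return -np.log(((fx - F) ** 2 + g**2) * ((fx + F) ** 2 + g**2))


def _fit_resonances(hf, ha, cfg):
    from scipy.optimize import least_squares

    lo1, hi1 = cfg.formant_search_f1_hz
    lo2, hi2 = cfg.formant_search_f2_hz
    lo3, hi3 = cfg.formant_search_f3_hz
    g_lo, g_hi = (cfg.formant_bw_range_hz[0] / 2, cfg.formant_bw_range_hz[1] / 2)
    starts = [
        (1400.0, 3500.0, 5900.0), (1630.0, 3740.0, 6100.0),
        (1200.0, 3100.0, 5200.0), (1800.0, 4100.0, 6800.0),
    ]

    def shape(fx, s, F1, F2, F3, g1, g2, g3):
        return (s * fx / 1000.0 + _resonance_log(fx, F1, g1)
                + _resonance_log(fx, F2, g2) + _resonance_log(fx, F3, g3))

    def model(p):
        c, s, floor, F1, F2, F3, g1, g2, g3 = p
        return np.logaddexp(c + shape(hf, s, F1, F2, F3, g1, g2, g3), floor)

    best, best_cost = None, np.inf
    for F1, F2, F3 in starts:
        c0 = float(np.median(ha - shape(hf, 0.0, F1, F2, F3, 220.0, 250.0, 280.0)))
        p0 = [c0, 0.0, float(ha.min()) - 1.0, F1, F2, F3, 220.0, 250.0, 280.0]
        try:
            res = least_squares(
                lambda p: model(p) - ha, p0, loss="soft_l1", f_scale=1.0,
                bounds=([-400.0, -0.4, -800.0, lo1, lo2, lo3, g_lo, g_lo, g_lo],
                        [400.0, 0.4, 100.0, hi1, hi2, hi3, g_hi, g_hi, g_hi]),
                max_nfev=4000,
            )
        except Exception:
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
    if best is None:
        return []
    return sorted(best.x[3:6])


# ---------------------------------------------------------------------------
# MFCC and spectrogram


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(fs: float, nfft: int, n_mels: int, fmin: float, fmax: float) -> np.ndarray:
    mels = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz = _mel_to_hz(mels)
    bins = np.fft.rfftfreq(nfft, 1.0 / fs)
    fb = np.zeros((n_mels, len(bins)))
    for i in range(n_mels):
        lo, cen, hi = hz[i], hz[i + 1], hz[i + 2]
        up = (bins - lo) / max(cen - lo, _EPS)
        down = (hi - bins) / max(hi - cen, _EPS)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _mel_power(x, fs, frame_s, hop_s, n_mels, fmax):
    flen = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    frames = _frame(np.asarray(x, dtype=np.float64), flen, hop)
    if len(frames) == 0:
        frames = np.zeros((1, flen))
    win = np.hanning(flen)
    spec = np.abs(rfft(frames * win, axis=1)) ** 2
    fb = _mel_filterbank(fs, flen, n_mels, 50.0, fmax)
    return spec @ fb.T  # (n_frames, n_mels)


def mfcc(x: np.ndarray, fs: float, cfg: AcousticsConfig | None = None) -> np.ndarray:
    """26-value MFCC summary: frame-wise mean and SD of 13 coefficients."""
    cfg = cfg or AcousticsConfig()
    mel = _mel_power(x, fs, cfg.mfcc_frame_s, cfg.mfcc_hop_s, cfg.mfcc_n_mels, fs / 2)
    logmel = np.log(np.maximum(mel, _EPS))
    cc = dct(logmel, type=2, norm="ortho", axis=1)[:, : cfg.n_mfcc]
    return np.concatenate([cc.mean(axis=0), cc.std(axis=0)])


def spectrogram(x: np.ndarray, fs: float, cfg: AcousticsConfig | None = None) -> np.ndarray:
    """Fixed-size log-mel image for the CNN (pad/crop to the canvas).

    The unit is centre-padded or cropped to ``spec_canvas_s`` seconds,
    converted to a log mel power image and standardised per image
    (zero mean, unit variance), which makes the representation
    invariant to overall gain.
    """
    cfg = cfg or AcousticsConfig()
    n = int(round(cfg.spec_canvas_s * fs))
    x = np.asarray(x, dtype=np.float64)
    if len(x) >= n:
        i0 = (len(x) - n) // 2
        xc = x[i0 : i0 + n]
    else:
        xc = np.zeros(n)
        i0 = (n - len(x)) // 2
        xc[i0 : i0 + len(x)] = x
    mel = _mel_power(xc, fs, cfg.spec_frame_s, cfg.spec_hop_s, cfg.spec_n_mels, fs / 2)
    img = np.log(np.maximum(mel, _EPS)).T  # (n_mels, n_frames)
    img = img - img.mean()
    sd = img.std()
    if sd > 0:
        img = img / sd
    return img.astype(np.float32)


# ---------------------------------------------------------------------------
# per-unit driver


def analyze_unit(x: np.ndarray, fs: float, cfg: AcousticsConfig | None = None) -> AcousticFeatureVector:
    """Compute the full per-unit acoustic feature vector.

    A unit whose contour contains no voiced frames is returned with
    ``valid=False`` and NaN features, mirroring the exclusion of
    unusable vocalisations from downstream statistics.
    """
    cfg = cfg or AcousticsConfig()
    contour = f0_contour(x, fs, cfg)
    if contour.voiced.sum() == 0:
        return AcousticFeatureVector(valid=False)
    stats = f0_statistics(contour, cfg)
    cm = cycle_measures(x, fs, cfg, contour=contour)
    jit = shm = np.nan
    if cm is not None:
        jit = jitter_local(cm.periods)
        # timing-noise compensation: measured and noise-induced jitter
        # add in quadrature for Gaussian perturbations
        if np.isfinite(jit):
            jit = float(np.sqrt(max(jit**2 - cm.jitter_noise_floor**2, 0.0)))
        shm = shimmer_local(cm.amplitudes)
    h = hnr(x, fs, cfg, measures=cm)
    f1, f2, f3 = formants(x, fs, cfg, contour=contour)
    return AcousticFeatureVector(
        f0_mean=stats["f0_mean"], f0_min=stats["f0_min"], f0_max=stats["f0_max"],
        f0_sd=stats["f0_sd"], f1=f1, f2=f2, f3=f3,
        high_pitch_pct=stats["high_pitch_pct"],
        hyperphonation_pct=stats["hyperphonation_pct"],
        jitter_local=jit, shimmer_local=shm, hnr=h, valid=True,
    )
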