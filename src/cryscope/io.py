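"""File-format glue: WAV, annotation TSV, EEG/NIRS/COMFORT CSV.

Audio is stored as 24-bit PCM WAV (the acquisition resolution).  The
standard-library ``wave`` module handles the container; sample packing
to/from 3-byte little-endian integers is done here because neither
``scipy.io.wavfile`` nor ``wave`` converts 24-bit frames on its own.
"""
from __future__ import annotations

import wave
from pathlib import Path

import numpy as np
import pandas as pd

_FULL_SCALE_24 = float(2**23 - 1)


def write_wav(path, x: np.ndarray, fs: int) -> None:
    """Write a mono float waveform in [-1, 1] as 24-bit PCM WAV."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("write_wav expects a mono waveform")
    ints = np.clip(np.round(x * _FULL_SCALE_24), -(2**23), 2**23 - 1).astype(np.int32)
    b = ints.astype("<i4").tobytes()
    frames = np.frombuffer(b, dtype=np.uint8).reshape(-1, 4)[:, :3]  # drop MSB
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(3)
        wf.setframerate(fs)
        wf.writeframes(frames.tobytes())


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV (16/24/32-bit PCM) into float in [-1, 1]."""
    with wave.open(str(path), "rb") as wf:
        n, width, fs = wf.getnframes(), wf.getsampwidth(), wf.getframerate()
        if wf.getnchannels() != 1:
            raise ValueError("only mono WAV files are supported")
        raw = wf.readframes(n)
    if width == 2:
        x = np.frombuffer(raw, dtype="<i2").astype(np.float64) / float(2**15 - 1)
    elif width == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        padded = np.zeros((b.shape[0], 4), dtype=np.uint8)
        padded[:, 1:] = b  # sign-extend via the int32 shift below
        ints = padded.view("<i4").ravel() >> 8
        x = ints.astype(np.float64) / _FULL_SCALE_24
    elif width == 4:
        x = np.frombuffer(raw, dtype="<i4").astype(np.float64) / float(2**31 - 1)
    else:
        raise ValueError(f"unsupported sample width {width}")
    return x, fs


def write_annotations(path, annotations) -> None:
    """Write condition annotations as ``start_s<TAB>end_s<TAB>label`` lines."""
    with open(path, "w") as fh:
        for start, end, label in annotations:
            fh.write(f"{start:.6f}\t{end:.6f}\t{label}\n")


def read_annotations(path) -> list[tuple[float, float, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            s, e, lab = line.split("\t")
            out.append((float(s), float(e), lab))
    return out


def write_eeg_csv(path, data: np.ndarray, channels) -> None:
    """Channel-matrix CSV: one column per channel, one row per sample (uV)."""
    pd.DataFrame(data.T, columns=list(channels)).to_csv(path, index=False)


def read_eeg_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy().T.astype(np.float64), list(df.columns)


def read_eeg(path, fs: int | None = None):
    """Read an EEG recording from CSV (channel matrix) or EDF.

    EDF reading requires the optional ``mne`` dependency.
    Returns ``(data_uv, channel_names, fs)``; for CSV the caller must
    supply the sampling rate.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        return raw.get_data() * 1e6, list(raw.ch_names), int(raw.info["sfreq"])
    data, channels = read_eeg_csv(path)
    if fs is None:
        raise ValueError("fs is required when reading EEG from CSV")
    return data, channels, fs


def write_nirs_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, columns=["t_s", "rSO2", "SpO2", "PR"])


def read_nirs_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_comfort_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_comfort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
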