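"""Frame-level standard speech measures: loudness, cepstra, spectral entropy.

Loudness is plain RMS amplitude.  Cepstral coefficients default to MFCCs (13
coefficients from 26 mel filters after pre-emphasis and Hamming windowing)
with regression first- and second-order time derivatives.  Spectral entropy
is the Shannon entropy of the min-shifted, normalized log power spectrum,
mirroring perceptual (log) magnitude weighting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft

__all__ = [
    "loudness_rms",
    "mel_filterbank",
    "cepstral_coeffs",
    "delta_coeffs",
    "spectral_entropy",
    "assemble_frame_features",
]

N_CEPSTRA = 13
N_MEL_FILTERS = 26
PREEMPHASIS = 0.97
DELTA_WINDOW = 2
LOG_FLOOR = 1e-10


def loudness_rms(frame: np.ndarray) -> float:
    """Root-mean-square amplitude of the frame."""
    x = np.asarray(frame, dtype=float)
    return float(np.sqrt(np.mean(x**2))) if len(x) else 0.0


def _hz_to_mel(f: np.ndarray) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_fft: int, sample_rate_hz: float
) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, n_fft//2 + 1)."""
    nyq = sample_rate_hz / 2.0
    mel_edges = np.linspace(0.0, _hz_to_mel(nyq), n_filters + 2)
    hz_edges = _mel_to_hz(mel_edges)
    bins = np.floor((n_fft + 1) * hz_edges / sample_rate_hz).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        for b in range(lo, mid):
            if mid > lo:
                fb[i, b] = (b - lo) / (mid - lo)
        for b in range(mid, hi):
            if hi > mid:
                fb[i, b] = (hi - b) / (hi - mid)
    return fb


def cepstral_coeffs(
    frame: np.ndarray,
    sample_rate_hz: float,
    n_coeffs: int = N_CEPSTRA,
    n_filters: int = N_MEL_FILTERS,
    preemphasis: float = PREEMPHASIS,
    cepstrum: str = "mel",
) -> np.ndarray:
    """Mel-frequency cepstral coefficients c0..c12 of one frame.

    The frame is pre-emphasized, Hamming-windowed, and its power spectrum is
    pooled by a 26-filter mel bank; coefficients are the orthonormal DCT-II of
    the log filter energies (floored to keep all-zero frames finite).  With
    ``cepstrum='linear'`` the filterbank step is skipped and the DCT is taken
    over the log power spectrum directly, truncated to ``n_coeffs``.
    """
    x = np.asarray(frame, dtype=float)
    x = np.append(x[0] * (1.0 - preemphasis), x[1:] - preemphasis * x[:-1])
    x = x * np.hamming(len(x))
    n_fft = int(2 ** np.ceil(np.log2(len(x))))
    spectrum = np.abs(rfft(x, n=n_fft)) ** 2
    if cepstrum == "mel":
        fb = mel_filterbank(n_filters, n_fft, sample_rate_hz)
        energies = fb @ spectrum
    elif cepstrum == "linear":
        energies = spectrum
    else:
        raise ValueError("cepstrum must be 'mel' or 'linear'")
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    return dct(log_e, type=2, norm="ortho")[:n_coeffs]


def delta_coeffs(coeff_seq: np.ndarray, window: int = DELTA_WINDOW) -> np.ndarray:
    """Regression deltas of a (n_frames, n_coeffs) coefficient sequence.

    ``delta_t = sum_w w * (c_{t+w} - c_{t-w}) / (2 * sum_w w^2)`` with edge
    frames replicated; apply twice for delta-deltas.
    """
    C = np.atleast_2d(np.asarray(coeff_seq, dtype=float))
    W = int(window)
    padded = np.pad(C, ((W, W), (0, 0)), mode="edge")
    denom = 2.0 * sum(w * w for w in range(1, W + 1))
    out = np.zeros_like(C)
    for w in range(1, W + 1):
        out += w * (padded[W + w : W + w + len(C)] - padded[W - w : W - w + len(C)])
    return out / denom


def spectral_entropy(frame: np.ndarray) -> float:
    """Shannon entropy (nats) of the normalized log power spectrum.

    The log power spectrum is shifted to be non-negative (its minimum maps to
    zero) and normalized to a probability vector; a degenerate flat spectrum
    yields the maximum ln(K).
    """
    x = np.asarray(frame, dtype=float) * np.hamming(len(frame))
    p = np.abs(rfft(x)) ** 2
    k = len(p)
    log_p = np.log(np.maximum(p, LOG_FLOOR))
    shifted = log_p - log_p.min()
    total = shifted.sum()
    if total <= 0:
        return float(np.log(k))
    q = shifted / total
    nz = q[q > 0]
    return float(-np.sum(nz * np.log(nz)))


VOICED_ONLY_FIELDS = ("f0_hz", "jitter_pct", "shimmer_pct", "hnr_db")


def assemble_frame_features(
    frame_times: np.ndarray,
    silent: np.ndarray,
    voiced: np.ndarray,
    pitch_hz: np.ndarray,
    jitter_pct: np.ndarray,
    shimmer_pct: np.ndarray,
    hnr_db: np.ndarray,
    loudness: np.ndarray,
    cepstra: np.ndarray,
    delta: np.ndarray,
    delta2: np.ndarray,
    entropy: np.ndarray,
) -> pd.DataFrame:
    """Join per-frame measures into one table of non-silent frames.

    All inputs are aligned on the full frame index; voiced-only fields are
    masked to NaN on unvoiced frames.  Raises on length mismatch.
    """
    n = len(frame_times)
    arrays = {
        "silent": silent, "voiced": voiced, "f0_hz": pitch_hz,
        "jitter_pct": jitter_pct, "shimmer_pct": shimmer_pct,
        "hnr_db": hnr_db, "loudness": loudness, "spectral_entropy": entropy,
    }
    for name, arr in arrays.items():
        if len(arr) != n:
            raise ValueError(f"{name} has {len(arr)} rows, expected {n}")
    for name, mat in (("cepstra", cepstra), ("delta", delta), ("delta2", delta2)):
        if len(mat) != n:
            raise ValueError(f"{name} has {len(mat)} rows, expected {n}")

    df = pd.DataFrame({"time_s": frame_times, "silent": silent, "voiced": voiced})
    df["f0_hz"] = pitch_hz
    df["jitter_pct"] = jitter_pct
    df["shimmer_pct"] = shimmer_pct
    df["hnr_db"] = hnr_db
    df["loudness"] = loudness
    for i in range(cepstra.shape[1]):
        df[f"mfcc_{i:02d}"] = cepstra[:, i]
    for i in range(delta.shape[1]):
        df[f"mfcc_{i:02d}_d"] = delta[:, i]
    for i in range(delta2.shape[1]):
        df[f"mfcc_{i:02d}_dd"] = delta2[:, i]
    df["spectral_entropy"] = entropy

    unvoiced = ~df["voiced"].to_numpy(dtype=bool)
    df.loc[unvoiced, list(VOICED_ONLY_FIELDS)] = np.nan
    return df[~df["silent"].to_numpy(dtype=bool)].reset_index(drop=True)
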