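"""Harmonic model (HM) fitting and voice-quality measures.

A voiced frame ``y(t)`` is modeled as a DC offset plus ``H`` harmonics of a
fundamental ``f0`` with additive zero-mean Gaussian noise:

    s(t) = a0 + sum_h [ a_h cos(2 pi f0 h t) + b_h sin(2 pi f0 h t) ]
    y(t) = s(t) + n(t),    n ~ N(0, sigma_n^2)

Coefficients are estimated by maximum a posteriori (MAP) inference with a
zero-mean Gaussian prior on the harmonic coefficients, i.e. ridge-regularized
least squares; the reported fit score is the penalized log-likelihood with a
model-order term so that pitch candidates of different harmonic counts are
comparable.

The time-varying extension (TV-HM) replaces each harmonic's coefficient pair
with a smooth polynomial trajectory over the frame, which lets the
reconstruction follow cycle-to-cycle frequency and amplitude perturbations;
cycle marks extracted from the reconstructed fundamental yield jitter and
shimmer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy.signal import find_peaks

__all__ = [
    "HarmonicFit",
    "TVHarmonicFit",
    "n_harmonics_for",
    "design_matrix",
    "fit_harmonic_map",
    "hnr_db",
    "classify_voicing",
    "fit_tv_harmonic",
    "segment_cycle_marks",
    "estimate_jitter",
    "estimate_shimmer",
]

DEFAULT_H_MAX = 10
DEFAULT_HNR_CEILING_DB = 60.0
DEFAULT_BASIS_ORDER = 3
RIDGE_SCALE = 1e-3  # ridge_lambda = RIDGE_SCALE * N * var(frame) when unspecified
HARMONIC_HEADROOM = 0.95  # harmonics allowed up to this fraction of Nyquist


@dataclass
class HarmonicFit:
    """Fixed-coefficient harmonic-model fit of one frame."""

    f0_hz: float
    H: int
    a0: float
    alpha: np.ndarray  # cosine coefficients, length H
    beta: np.ndarray  # sine coefficients, length H
    noise_var: float
    harmonic_energy: float
    residual_energy: float
    score: float
    reconstruction: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.alpha) != self.H or len(self.beta) != self.H:
            raise ValueError("alpha/beta length must equal H")
        if not np.isfinite(self.score):
            raise ValueError("fit score must be finite")


@dataclass
class TVHarmonicFit:
    """Time-varying harmonic fit with per-harmonic amplitude trajectories."""

    f0_hz: float
    H: int
    B: int
    a0: float
    alpha_traj: np.ndarray  # (H, N) cosine-coefficient trajectory
    beta_traj: np.ndarray  # (H, N) sine-coefficient trajectory
    residual_energy: float
    reconstruction: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    envelope: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    cycle_periods_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    cycle_amplitudes: np.ndarray = field(default=None)  # type: ignore[assignment]


def n_harmonics_for(
    f0_hz: float, sample_rate_hz: float, h_max: int | None = DEFAULT_H_MAX
) -> int:
    """Deterministic model order: harmonics up to 95% of Nyquist.

    ``h_max=None`` leaves the series uncapped — the rule used when scoring
    pitch candidates, where the growing parameter count of subharmonic
    candidates (penalized by the model-order term of the MAP score) is what
    suppresses octave errors.  Feature fits (HNR, cycle marks) use the capped
    default.
    """
    if f0_hz <= 0:
        raise ValueError("f0 must be positive")
    nyq = sample_rate_hz / 2.0
    h = int(np.floor(HARMONIC_HEADROOM * nyq / f0_hz))
    if h_max is not None:
        h = min(h, h_max)
    return max(1, h)


def design_matrix(f0_hz: float, H: int, times: np.ndarray) -> np.ndarray:
    """Harmonic design matrix with columns [1, cos(h), sin(h)] for h=1..H.

    ``times`` are frame-local sample times in seconds.  Raises if any
    harmonic reaches the Nyquist frequency implied by the sampling of
    ``times`` (uniform spacing assumed).
    """
    times = np.asarray(times, dtype=float)
    if len(times) > 1:
        dt = times[1] - times[0]
        nyq = 0.5 / dt
        top = H * f0_hz
        if top >= nyq:
            h_bad = int(np.ceil(nyq / f0_hz))
            raise ValueError(
                f"aliasing: harmonic {h_bad} of f0={f0_hz:.1f} Hz reaches the "
                f"Nyquist frequency {nyq:.1f} Hz"
            )
    X = np.empty((len(times), 2 * H + 1))
    X[:, 0] = 1.0
    arg = 2.0 * np.pi * f0_hz * np.outer(times, np.arange(1, H + 1))
    X[:, 1::2] = np.cos(arg)
    X[:, 2::2] = np.sin(arg)
    return X


def _map_score(
    rss: float, n: int, penalty_quad: float, n_params: int, frame_energy: float
) -> float:
    """Penalized log-likelihood at the MAP solution.

    The noise variance is profiled over the penalized residual sum of squares
    (the Gaussian coefficient prior shares the noise scale, so the quadratic
    penalty folds into the variance estimate and the score is equivariant
    under frame gain), and a Laplace model-order term ``(k/2) log N`` makes
    candidates of different harmonic counts comparable."""
    var_floor = max(frame_energy / n * 1e-12, 1e-300)
    sigma2 = max((rss + penalty_quad) / n, var_floor)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return loglik - 0.5 * n_params * np.log(n)


def fit_harmonic_map(
    frame: np.ndarray,
    f0_hz: float,
    H: int,
    sample_rate_hz: float,
    ridge_lambda: float | None = None,
) -> HarmonicFit:
    """MAP fit of the harmonic model to one frame.

    Minimizes ``||y - Xc||^2 + lambda * ||c_harmonic||^2`` (the DC offset is
    not penalized), solved by orthogonal decomposition.  ``ridge_lambda=None``
    uses the scale-aware default ``1e-3 * N * var(frame)``; pass ``0`` for
    plain least squares.
    """
    y = np.asarray(frame, dtype=float)
    n = len(y)
    times = np.arange(n) / sample_rate_hz
    X = design_matrix(f0_hz, H, times)
    k = X.shape[1]

    # Fit on the gain-normalized frame so both the ridge prior and the score
    # are invariant to recording level; coefficients are rescaled afterwards.
    sd = float(np.std(y))
    scale = sd if sd > 0 else 1.0
    yn = y / scale
    if ridge_lambda is None:
        lam = RIDGE_SCALE * n
    elif ridge_lambda < 0:
        raise ValueError("ridge_lambda must be >= 0")
    else:
        lam = ridge_lambda / scale**2

    if lam > 0:
        aug = np.zeros((k - 1, k))
        aug[:, 1:] = np.sqrt(lam) * np.eye(k - 1)
        A = np.vstack([X, aug])
        b = np.concatenate([yn, np.zeros(k - 1)])
    else:
        A, b = X, yn
    coef_n, *_ = np.linalg.lstsq(A, b, rcond=None)

    recon_n = X @ coef_n
    rss_n = float(np.sum((yn - recon_n) ** 2))
    score = _map_score(
        rss_n, n, lam * float(coef_n[1:] @ coef_n[1:]), k, float(yn @ yn)
    )
    coef = coef_n * scale
    recon = recon_n * scale
    rss = rss_n * scale**2
    harmonic_part = recon - coef[0]
    return HarmonicFit(
        f0_hz=f0_hz,
        H=H,
        a0=float(coef[0]),
        alpha=coef[1::2].copy(),
        beta=coef[2::2].copy(),
        noise_var=rss / n,
        harmonic_energy=float(harmonic_part @ harmonic_part),
        residual_energy=rss,
        score=score,
        reconstruction=recon,
    )


def hnr_db(fit: HarmonicFit, ceiling_db: float = DEFAULT_HNR_CEILING_DB) -> float:
    """Harmonic-to-noise ratio 10*log10(E_harmonic / E_residual) in dB."""
    if fit.residual_energy <= 0:
        return ceiling_db
    if fit.harmonic_energy <= 0:
        return -ceiling_db
    return float(
        min(10.0 * np.log10(fit.harmonic_energy / fit.residual_energy), ceiling_db)
    )


def classify_voicing(
    hnr_values_db: np.ndarray, hnr_threshold_db: float = 0.0
) -> np.ndarray:
    """Voiced iff the selected pitch candidate's HNR reaches the threshold."""
    return np.asarray(hnr_values_db, dtype=float) >= hnr_threshold_db


def _legendre_basis(n: int, B: int) -> np.ndarray:
    """(N, B) matrix of Legendre polynomials P_0..P_{B-1} on [-1, 1]."""
    tau = np.linspace(-1.0, 1.0, n)
    return np.column_stack(
        [legendre.legval(tau, np.eye(B)[b]) for b in range(B)]
    )


def fit_tv_harmonic(
    frame: np.ndarray,
    f0_hz: float,
    H: int,
    sample_rate_hz: float,
    basis_order: int = DEFAULT_BASIS_ORDER,
    ridge_lambda: float = 0.0,
) -> TVHarmonicFit:
    """Time-varying harmonic fit: polynomial amplitude trajectories per harmonic.

    Each harmonic's coefficient pair becomes a ``basis_order``-term Legendre
    expansion over frame time (2*H*B+1 parameters).  With ``basis_order=1``
    and ``ridge_lambda=0`` this reproduces :func:`fit_harmonic_map` exactly.
    Cycle marks are taken at peaks of the reconstructed fundamental component
    (noise-robust, unlike raw-signal peaks), with parabolic refinement of the
    peak positions; per-cycle amplitudes sample the instantaneous fundamental
    envelope at the refined marks.
    """
    y = np.asarray(frame, dtype=float)
    n = len(y)
    B = int(basis_order)
    if B < 1:
        raise ValueError("basis_order must be >= 1")
    k = 2 * H * B + 1
    if k >= n:
        raise ValueError(
            f"basis order {B} too large for frame of {n} samples "
            f"(needs 2*H*B+1 = {k} < N)"
        )
    times = np.arange(n) / sample_rate_hz
    arg = 2.0 * np.pi * f0_hz * np.outer(times, np.arange(1, H + 1))
    if H * f0_hz >= sample_rate_hz / 2.0:
        raise ValueError("aliasing: harmonic series exceeds Nyquist")
    P = _legendre_basis(n, B)

    # Columns: intercept, then for each harmonic h and basis term b the
    # modulated cosine and sine carriers.
    X = np.empty((n, k))
    X[:, 0] = 1.0
    col = 1
    cos_h, sin_h = np.cos(arg), np.sin(arg)
    for h in range(H):
        for b in range(B):
            X[:, col] = cos_h[:, h] * P[:, b]
            X[:, col + 1] = sin_h[:, h] * P[:, b]
            col += 2
    if ridge_lambda > 0:
        aug = np.zeros((k - 1, k))
        aug[:, 1:] = np.sqrt(ridge_lambda) * np.eye(k - 1)
        A = np.vstack([X, aug])
        bvec = np.concatenate([y, np.zeros(k - 1)])
    else:
        A, bvec = X, y
    coef, *_ = np.linalg.lstsq(A, bvec, rcond=None)
    recon = X @ coef
    rss = float(np.sum((y - recon) ** 2))

    # Coefficient trajectories alpha_h(t), beta_h(t).
    alpha_traj = np.empty((H, n))
    beta_traj = np.empty((H, n))
    for h in range(H):
        c = coef[1 + 2 * B * h : 1 + 2 * B * (h + 1)]
        alpha_traj[h] = P @ c[0::2]
        beta_traj[h] = P @ c[1::2]

    envelope = np.hypot(alpha_traj[0], beta_traj[0])
    fundamental = alpha_traj[0] * cos_h[:, 0] + beta_traj[0] * sin_h[:, 0]

    periods, amplitudes = _cycle_marks(
        fundamental, envelope, f0_hz, sample_rate_hz
    )
    return TVHarmonicFit(
        f0_hz=f0_hz,
        H=H,
        B=B,
        a0=float(coef[0]),
        alpha_traj=alpha_traj,
        beta_traj=beta_traj,
        residual_energy=rss,
        reconstruction=recon,
        envelope=envelope,
        cycle_periods_s=periods,
        cycle_amplitudes=amplitudes,
    )


def _cycle_marks(
    fundamental: np.ndarray,
    envelope: np.ndarray,
    f0_hz: float,
    sample_rate_hz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle periods and amplitudes from the reconstructed fundamental."""
    min_dist = max(1, int(0.7 * sample_rate_hz / f0_hz))
    peaks, _ = find_peaks(fundamental, distance=min_dist)
    if len(peaks) < 2:
        return np.empty(0), envelope[peaks] if len(peaks) else np.empty(0)
    # Parabolic refinement of peak positions (sub-sample).
    t_peaks = []
    for p in peaks:
        if 0 < p < len(fundamental) - 1:
            y0, y1, y2 = fundamental[p - 1 : p + 2]
            denom = y0 - 2.0 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        t_peaks.append((p + delta) / sample_rate_hz)
    t_peaks = np.asarray(t_peaks)
    periods = np.diff(t_peaks)
    amplitudes = np.interp(t_peaks, np.arange(len(envelope)) / sample_rate_hz, envelope)
    return periods, amplitudes


def segment_cycle_marks(
    samples: np.ndarray,
    sample_rate_hz: float,
    f0_hz: float,
    h_max: int | None = DEFAULT_H_MAX,
    upsample: int = 16,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cycle marks over a voiced stretch from its denoised waveform.

    The signal is band-limited to the harmonic series (everything above
    ``(H + 1/2) * f0`` is noise by model assumption and removed), resampled
    ``upsample``-fold for sub-sample peak timing, and one mark is placed per
    glottal pulse.  Per-cycle amplitudes are the least-squares gain of each
    cycle against the mean cycle shape, which averages the in-band noise over
    the whole cycle instead of trusting a single peak sample.

    Returns ``(mark_times_s, periods_s, amplitudes)``; ``periods_s`` has one
    entry fewer than the marks, ``amplitudes`` aligns with the marks (NaN
    where the cycle window would leave the signal).

    Pulse-synchronous timing assumes the voiced waveform has one dominant
    peak per cycle, which holds for glottal-pulse-like phase alignment; see
    the TV-HM cycle marks for the within-frame alternative.
    """
    from scipy.fft import irfft, rfft as _rfft
    from scipy.signal import resample

    x = np.asarray(samples, dtype=float)
    n = len(x)
    fs = sample_rate_hz
    if f0_hz <= 0 or n < int(2 * fs / f0_hz):
        return np.empty(0), np.empty(0), np.empty(0)
    H = n_harmonics_for(f0_hz, fs, h_max)
    fcut = min((H + 0.5) * f0_hz, HARMONIC_HEADROOM * fs / 2.0)
    spec = _rfft(x)
    freqs = np.arange(len(spec)) * fs / n
    xd = irfft(np.where(freqs <= fcut, spec, 0.0), n)

    xu = resample(xd, n * upsample)
    peaks, _ = find_peaks(xu, distance=max(1, int(0.7 * fs * upsample / f0_hz)))
    t = peaks / (fs * upsample)
    if len(t) < 4:
        return np.empty(0), np.empty(0), np.empty(0)
    periods = np.diff(t)

    L = max(4, int(round(0.8 * fs / f0_hz)))
    half = L // 2
    ip = np.round(t * fs).astype(int)
    keep = (ip - half >= 0) & (ip - half + L < n)
    amplitudes = np.full(len(t), np.nan)
    if keep.sum() >= 2:
        cycles = np.array([xd[p - half : p - half + L] for p in ip[keep]])
        template = cycles.mean(axis=0)
        denom = float(template @ template)
        if denom > 0:
            amplitudes[keep] = cycles @ template / denom
    return t, periods, amplitudes


def estimate_jitter(cycle_periods_s: np.ndarray) -> float:
    """Local jitter: mean absolute consecutive period difference over the mean
    period, as a percentage.  Returns NaN below 3 cycles."""
    T = np.asarray(cycle_periods_s, dtype=float)
    if len(T) < 3:
        return float("nan")
    return float(np.mean(np.abs(np.diff(T))) / np.mean(T) * 100.0)


def estimate_shimmer(cycle_amplitudes: np.ndarray) -> float:
    """Local shimmer: mean absolute consecutive amplitude difference over the
    mean amplitude, as a percentage.  Returns NaN below 3 cycles."""
    A = np.asarray(cycle_amplitudes, dtype=float)
    if len(A) < 3:
        return float("nan")
    return float(np.mean(np.abs(np.diff(A))) / np.mean(A) * 100.0)
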