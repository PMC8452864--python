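"""Pitch candidate scoring and Viterbi contour tracking.

Each non-silent frame is scored against a log-spaced grid of fundamental
frequency candidates with the MAP harmonic-model objective.  The
per-candidate harmonic count follows the f0-dependent rule *uncapped*, so a
subharmonic candidate carries roughly twice the parameters of the true pitch
and the model-order term of the MAP score suppresses the octave error that a
plain likelihood comparison cannot (a subharmonic spans the same partials
with a nested model).  Raw scores are additionally smoothed over adjacent
candidates, which stabilizes the score surface.  A first-order Markov
smoothness prior on log2 pitch links successive frames and the contour is
decoded with the Viterbi algorithm, then refined off-grid by maximizing the
raw MAP score around the winning candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize_scalar

from .harmonic_model import (
    RIDGE_SCALE,
    design_matrix,
    fit_harmonic_map,
    n_harmonics_for,
    _map_score,
)

__all__ = [
    "PitchLattice",
    "PitchContour",
    "candidate_grid",
    "score_candidates",
    "build_lattice",
    "viterbi_track",
    "refine_contour",
]

DEFAULT_FMIN_HZ = 60.0
DEFAULT_FMAX_HZ = 600.0
DEFAULT_BINS_PER_OCTAVE = 24
DEFAULT_SMOOTH_WIDTH = 5
DEFAULT_TRANSITION_SIGMA_LOG2 = 0.1


@dataclass
class PitchLattice:
    """Per-frame MAP scores over a shared pitch-candidate grid."""

    candidate_grid: np.ndarray  # strictly increasing Hz values
    score_matrix: np.ndarray  # (n_frames, n_candidates), smoothed if `smoothed`
    raw_scores: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    smoothed: bool = True

    def __post_init__(self) -> None:
        g = self.candidate_grid
        if len(g) > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("candidate grid must be strictly increasing")


@dataclass
class PitchContour:
    """Decoded pitch per frame; NaN where no estimate exists."""

    f0_hz: np.ndarray
    candidate_index: np.ndarray


def candidate_grid(
    fmin_hz: float = DEFAULT_FMIN_HZ,
    fmax_hz: float = DEFAULT_FMAX_HZ,
    bins_per_octave: int = DEFAULT_BINS_PER_OCTAVE,
) -> np.ndarray:
    """Log-uniform grid of pitch candidates, endpoints included."""
    if not 0 < fmin_hz < fmax_hz:
        raise ValueError("need 0 < fmin < fmax")
    n = 1 + int(round(bins_per_octave * np.log2(fmax_hz / fmin_hz)))
    return fmin_hz * 2.0 ** (np.arange(n) / bins_per_octave)


def score_candidates(
    frame: np.ndarray,
    grid: np.ndarray,
    sample_rate_hz: float,
    ridge_lambda: float | None = None,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
    h_max: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Score one frame against every candidate.

    Returns ``(raw, smoothed)`` score rows; the smoothed row is a moving
    average of the raw scores over ``smooth_width`` adjacent candidates.
    """
    raw = np.array(
        [
            fit_harmonic_map(
                frame,
                f0,
                n_harmonics_for(f0, sample_rate_hz, h_max),
                sample_rate_hz,
                ridge_lambda,
            ).score
            for f0 in grid
        ]
    )
    smoothed = uniform_filter1d(raw, size=smooth_width, mode="nearest")
    return raw, smoothed


def build_lattice(
    frame_matrix: np.ndarray,
    sample_rate_hz: float,
    grid: np.ndarray | None = None,
    smooth_width: int = DEFAULT_SMOOTH_WIDTH,
    h_max: int | None = None,
) -> PitchLattice:
    """Vectorized lattice construction for many frames at once.

    Frames are normalized to unit variance so one ridge factorization per
    candidate serves every frame (the MAP score is invariant to this gain
    change apart from a per-frame constant, which cancels in the decoding).
    """
    if grid is None:
        grid = candidate_grid()
    Y = np.asarray(frame_matrix, dtype=float)
    n_frames, n = Y.shape
    times = np.arange(n) / sample_rate_hz
    sd = Y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Yn = (Y / sd).T  # (n, n_frames)
    energy = np.sum(Yn**2, axis=0)

    lam = RIDGE_SCALE * n  # frames are unit variance after normalization
    raw = np.empty((n_frames, len(grid)))
    for j, f0 in enumerate(grid):
        H = n_harmonics_for(f0, sample_rate_hz, h_max)
        X = design_matrix(f0, H, times)
        k = X.shape[1]
        D = np.eye(k)
        D[0, 0] = 0.0
        M = X.T @ X + lam * D
        C = np.linalg.solve(M, X.T @ Yn)  # (k, n_frames)
        resid = Yn - X @ C
        rss = np.sum(resid**2, axis=0)
        pen = lam * np.sum(C[1:] ** 2, axis=0)
        for i in range(n_frames):
            raw[i, j] = _map_score(rss[i], n, pen[i], k, energy[i])
    smoothed = uniform_filter1d(raw, size=smooth_width, axis=1, mode="nearest")
    return PitchLattice(
        candidate_grid=np.asarray(grid, dtype=float),
        score_matrix=smoothed,
        raw_scores=raw,
        smoothed=True,
    )


def viterbi_track(
    lattice: PitchLattice,
    transition_sigma_log2: float = DEFAULT_TRANSITION_SIGMA_LOG2,
) -> PitchContour:
    """Decode the maximum-score pitch path under a Gaussian log2-pitch
    smoothness prior between successive frames.

    Maximizes ``sum_t score(t, c_t) - sum_t (log2(f_{c_t}/f_{c_{t-1}}))^2 /
    (2 sigma^2)``; ties break toward the lower-frequency candidate.
    """
    S = lattice.score_matrix
    if S.size == 0:
        return PitchContour(f0_hz=np.empty(0), candidate_index=np.empty(0, dtype=int))
    n_frames, n_cand = S.shape
    log2f = np.log2(lattice.candidate_grid)
    penalty = (log2f[None, :] - log2f[:, None]) ** 2 / (
        2.0 * transition_sigma_log2**2
    )  # penalty[i, j]: cost of moving from candidate i to j

    delta = S[0].copy()
    back = np.zeros((n_frames, n_cand), dtype=int)
    for t in range(1, n_frames):
        trans = delta[:, None] - penalty  # (from, to)
        best_from = np.argmax(trans, axis=0)  # argmax → lowest index on ties
        delta = trans[best_from, np.arange(n_cand)] + S[t]
        back[t] = best_from

    path = np.zeros(n_frames, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n_frames - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return PitchContour(
        f0_hz=lattice.candidate_grid[path], candidate_index=path
    )


def refine_contour(
    contour: PitchContour,
    frame_matrix: np.ndarray,
    sample_rate_hz: float,
    grid: np.ndarray,
    h_max: int | None = 10,
) -> np.ndarray:
    """Off-grid refinement: maximize the raw MAP score over f0 between the
    winning candidate's neighbors (bounded scalar search per frame)."""
    refined = contour.f0_hz.astype(float).copy()
    for t, idx in enumerate(contour.candidate_index):
        lo = grid[max(idx - 1, 0)]
        hi = grid[min(idx + 1, len(grid) - 1)]
        if hi <= lo:
            continue
        frame = frame_matrix[t]

        def neg_score(f0: float) -> float:
            H = n_harmonics_for(f0, sample_rate_hz, h_max)
            return -fit_harmonic_map(frame, f0, H, sample_rate_hz).score

        res = minimize_scalar(
            neg_score, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-2},
        )
        refined[t] = float(res.x)
    return refined
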