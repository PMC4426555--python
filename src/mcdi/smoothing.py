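"""PSTH accumulation and local-linear-regression rate smoothing.

Spike counts are accumulated in 5 ms bins across all presentations of a
stimulus type, and the smoothed firing rate is obtained by tricube-weighted
local linear regression evaluated on the analysis grid (55-250 ms in 5 ms
steps by default).  Because local linear regression with a fixed design is a
linear map of the binned counts, the smoother is exposed as an explicit
operator matrix; the shuffle test exploits this to evaluate thousands of
surrogate rate differences as a single matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import Session

__all__ = [
    "SmoothedRate",
    "analysis_grid",
    "trial_count_matrix",
    "accumulate_psth",
    "smoothing_operator",
    "smooth_rate",
]

DEFAULT_WINDOW_MS = (55.0, 250.0)
DEFAULT_BIN_MS = 5.0
DEFAULT_BANDWIDTH_MS = 12.0


def analysis_grid(
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS, bin_ms: float = DEFAULT_BIN_MS
) -> np.ndarray:
    """Evaluation grid: 5 ms steps from 55 to 250 ms inclusive (40 points)."""
    lo, hi = window_ms
    return np.arange(lo, hi + 0.5 * bin_ms, bin_ms)


def trial_count_matrix(
    session: Session, kind: str, bin_ms: float = DEFAULT_BIN_MS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial binned spike counts for one stimulus type.

    Returns ``(counts, bin_centers_ms, onsets_s)`` with ``counts`` of shape
    (n_trials, n_bins) covering the whole presentation.
    """
    trials = session.trials_of_kind(kind)
    dur = session.protocol.presentation_ms
    edges = np.arange(0.0, dur + 0.5 * bin_ms, bin_ms)
    counts = np.zeros((len(trials), edges.size - 1), dtype=np.int64)
    for i, t in enumerate(trials):
        if len(t.spike_times_s):
            counts[i], _ = np.histogram(t.spike_times_s * 1000.0, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    onsets = np.array([t.onset_s for t in trials])
    return counts, centers, onsets


def accumulate_psth(
    session: Session, kind: str, bin_ms: float = DEFAULT_BIN_MS
) -> tuple[np.ndarray, np.ndarray, int]:
    """PSTH across all presentations of ``kind``.

    Returns ``(counts_per_bin, bin_centers_ms, n_trials)``; dividing counts
    by ``n_trials * bin_ms / 1000`` gives the raw rate in Hz.
    """
    counts, centers, _ = trial_count_matrix(session, kind, bin_ms)
    return counts.sum(axis=0), centers, counts.shape[0]


def smoothing_operator(
    bin_centers_ms: np.ndarray,
    eval_ms: np.ndarray,
    bandwidth_ms: float = DEFAULT_BANDWIDTH_MS,
) -> np.ndarray:
    """Matrix L such that L @ psth evaluates the tricube-weighted local
    linear regression of the PSTH at ``eval_ms``.

    Local linear regression reproduces straight lines exactly, so the
    operator rows sum to 1 and have zero first moment around each evaluation
    point.
    """
    if bandwidth_ms <= 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(bin_centers_ms, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two bins to smooth")
    L = np.zeros((len(eval_ms), x.size))
    for i, t0 in enumerate(np.asarray(eval_ms, dtype=float)):
        u = (x - t0) / bandwidth_ms
        w = np.where(np.abs(u) < 1.0, (1.0 - np.abs(u) ** 3) ** 3, 0.0)
        if np.count_nonzero(w) < 2:
            raise ValueError(
                f"bandwidth {bandwidth_ms} ms leaves fewer than two support "
                f"points at t = {t0} ms"
            )
        d = x - t0
        s0, s1, s2 = w.sum(), (w * d).sum(), (w * d * d).sum()
        denom = s0 * s2 - s1 * s1
        if denom <= 0:
            raise ValueError(f"degenerate local design at t = {t0} ms")
        L[i] = w * (s2 - s1 * d) / denom
    return L


@dataclass(frozen=True)
class SmoothedRate:
    bin_centers_ms: np.ndarray
    rate_hz: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        if np.any(self.rate_hz < 0):
            object.__setattr__(self, "rate_hz", np.maximum(self.rate_hz, 0.0))


def smooth_rate(
    psth_counts: np.ndarray,
    bin_centers_ms: np.ndarray,
    n_trials: int,
    eval_ms: np.ndarray | None = None,
    bin_ms: float = DEFAULT_BIN_MS,
    bandwidth_ms: float = DEFAULT_BANDWIDTH_MS,
) -> SmoothedRate:
    """Smoothed firing rate (Hz) from an accumulated PSTH."""
    if eval_ms is None:
        eval_ms = analysis_grid()
    L = smoothing_operator(bin_centers_ms, eval_ms, bandwidth_ms)
    rate = np.asarray(psth_counts, dtype=float) / (n_trials * bin_ms / 1000.0)
    return SmoothedRate(np.asarray(eval_ms), L @ rate, n_trials)
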