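"""Post-processing of component time courses: detrend, despike, low-pass.

The pipeline applies the three steps in this order — polynomial detrending
(linear, quadratic, cubic), spike replacement by local cubic-spline
interpolation, and zero-phase fifth-order Butterworth low-pass filtering at
0.15 Hz. ``process_timecourse`` enforces the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

__all__ = [
    "ProcessedTimecourse",
    "detrend_poly",
    "despike",
    "lowpass_butterworth",
    "process_timecourse",
]


@dataclass
class ProcessedTimecourse:
    values: np.ndarray
    tr_seconds: float
    spike_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


def _as_values(tc) -> tuple[np.ndarray, float, list[int]]:
    if isinstance(tc, ProcessedTimecourse):
        return tc.values, tc.tr_seconds, list(tc.spike_indices)
    raise TypeError("expected a ProcessedTimecourse")


def detrend_poly(tc: ProcessedTimecourse, order: int = 3) -> ProcessedTimecourse:
    """Remove a least-squares polynomial trend of the given order.

    The default order 3 removes linear, quadratic and cubic trends (the
    constant term goes with them). The output is orthogonal to the polynomial
    basis.
    """
    x, tr, spikes = _as_values(tc)
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    n = x.size
    if n <= order + 1:
        raise ValueError(f"need more than {order + 1} timepoints for order {order}")
    # orthonormal polynomial basis via QR of the Vandermonde matrix
    t = np.linspace(-1.0, 1.0, n)
    basis = np.vander(t, order + 1, increasing=True)
    q, _ = np.linalg.qr(basis)
    resid = x - q @ (q.T @ x)
    return ProcessedTimecourse(resid, tr, spikes)


def _neighbour_median(x: np.ndarray, window: int) -> np.ndarray:
    """Running median of each point's neighbours, the point itself excluded.

    Including the centre sample deflates the residual scale (a running median
    reproduces the centre on locally monotone stretches, making half the
    residuals exactly zero) so a MAD-based threshold over-flags; the
    leave-one-out median keeps the residual at full noise scale. Boundaries
    are mirrored so an edge spike cannot hide among replicated copies of
    itself. The even-count median averages the two middle order statistics.
    """
    half = window // 2
    padded = np.concatenate([x[half:0:-1], x, x[-2:-half - 2:-1]])
    views = np.lib.stride_tricks.sliding_window_view(padded, window)
    keep = np.arange(window) != half
    return np.median(views[:, keep], axis=1)


def _detect_spikes(x: np.ndarray, window: int, n_mads: float) -> np.ndarray:
    med = _neighbour_median(x, window)
    resid = x - med
    mad = np.median(np.abs(resid - np.median(resid)))
    # robust scale, floored at 10% of the series SD: on (near-)noiseless
    # smooth data the residual MAD shrinks to curvature level, and deviations
    # below a tenth of the signal's own scale are not spikes worth replacing
    scale = 1.4826 * mad if mad > 0 else resid.std()
    sd = max(scale, 0.1 * x.std())
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(resid) > n_mads * sd)


def _spline_replace(x: np.ndarray, flagged: np.ndarray, n_neighbours: int) -> np.ndarray:
    out = x.copy()
    clean = np.setdiff1d(np.arange(x.size), flagged)
    for idx in flagged:
        left = clean[clean < idx][-n_neighbours:]
        right = clean[clean > idx][:n_neighbours]
        support = np.concatenate([left, right])
        if support.size < 4:  # cubic needs 4 points
            support = np.sort(clean[np.argsort(np.abs(clean - idx))[:4]])
        spline = CubicSpline(support, x[support])
        out[idx] = float(spline(idx))
    return out


def despike(
    tc: ProcessedTimecourse,
    window: int = 7,
    n_mads: float = 3.0,
    n_neighbours: int = 4,
    max_passes: int = 10,
) -> ProcessedTimecourse:
    """Replace outlying samples with values from a cubic spline through clean neighbours.

    A point is an outlier when its deviation from a running median (window 7)
    exceeds ``n_mads`` robust standard deviations (1.4826 x MAD) of the
    residual series. Each flagged point is replaced by a third-order spline
    fitted to the nearest ``n_neighbours`` clean points on each side (boundary
    spikes are handled by spline extrapolation). Detection and replacement
    iterate to a fixpoint (a spike can mask a neighbour in a single pass), so
    the operation is idempotent: a despiked series is returned unchanged. A
    clean series passes through untouched; more than 50% of points flagged in
    total is an error.
    """
    x, tr, _ = _as_values(tc)
    n = x.size
    if n < 10:
        raise ValueError("despike needs at least 10 timepoints")
    out = x.copy()
    all_flags: set[int] = set()
    for _ in range(max_passes):
        new = [i for i in _detect_spikes(out, window, n_mads) if i not in all_flags]
        if not new:
            break
        all_flags.update(int(i) for i in new)
        if len(all_flags) > n / 2:
            raise ValueError(
                f"{len(all_flags)}/{n} points flagged as spikes; data unusable"
            )
        out = _spline_replace(out, np.array(sorted(all_flags)), n_neighbours)
    return ProcessedTimecourse(out, tr, sorted(all_flags))


def lowpass_butterworth(
    tc: ProcessedTimecourse,
    cutoff_hz: float = 0.15,
    order: int = 5,
) -> ProcessedTimecourse:
    """Zero-phase Butterworth low-pass (forward-backward, so DC gain is exactly 1).

    Because the filter runs in both directions its magnitude response is the
    squared one-pass response; phase is identically zero. The cutoff must lie
    below the Nyquist frequency 1/(2*TR).
    """
    x, tr, spikes = _as_values(tc)
    nyquist = 0.5 / tr
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist:.3f} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / tr, output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    return ProcessedTimecourse(filtered, tr, spikes)


def process_timecourse(
    values: np.ndarray,
    tr_seconds: float,
    detrend_order: int = 3,
    cutoff_hz: float = 0.15,
    filter_order: int = 5,
) -> ProcessedTimecourse:
    """Detrend → despike → low-pass, in that (fixed) order."""
    tc = ProcessedTimecourse(values, tr_seconds)
    tc = detrend_poly(tc, order=detrend_order)
    tc = despike(tc)
    return lowpass_butterworth(tc, cutoff_hz=cutoff_hz, order=filter_order)
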