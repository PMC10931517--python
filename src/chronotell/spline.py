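"""Periodic monotone cubic interpolation and positive-definite repair.

Two numerical primitives used by the probability model:

* :class:`PeriodicPchip` — a 24 h periodic piecewise cubic Hermite
  interpolating spline.  Knots are replicated over three periods and scipy's
  ``PchipInterpolator`` (Fritsch–Carlson derivative limiting) is evaluated on
  the central copy at ``t mod period``.  Because PCHIP derivatives depend
  only on the two adjacent secant slopes, the central period is exactly
  periodic and C1 across the seam.
* :func:`nearest_pd` — eigenvalue clipping of a symmetric matrix so the
  smallest eigenvalue is at least a trace-scaled floor; the identity on
  matrices that are already comfortably positive definite.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["PeriodicPchip", "periodic_pchip", "nearest_pd"]


class PeriodicPchip:
    """Periodic shape-preserving cubic interpolant of knot values.

    Parameters
    ----------
    knot_times : array
        Strictly increasing times within [0, period).
    knot_values : array
        Values at the knots; may be 2-d (knots x channels).
    period : float
        Period, 24 h by default.
    """

    def __init__(self, knot_times, knot_values, period: float = 24.0):
        t = np.asarray(knot_times, dtype=float)
        v = np.asarray(knot_values, dtype=float)
        if t.ndim != 1 or len(t) < 3:
            raise ValueError("need at least 3 knots")
        if np.any(np.diff(t) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if t[0] < 0 or t[-1] >= period:
            raise ValueError(f"knot times must lie in [0, {period})")
        if v.shape[0] != len(t):
            raise ValueError("knot_values first axis must match knot_times")
        self.period = float(period)
        self.knot_times = t
        self.knot_values = v
        ext_t = np.concatenate([t - period, t, t + period])
        ext_v = np.concatenate([v, v, v], axis=0)
        self._interp = PchipInterpolator(ext_t, ext_v, axis=0, extrapolate=False)

    def __call__(self, times) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return self._interp(times % self.period)


def periodic_pchip(knot_times, knot_values, period: float = 24.0) -> PeriodicPchip:
    """Build a periodic PCHIP spline; see :class:`PeriodicPchip`."""
    return PeriodicPchip(knot_times, knot_values, period)


def nearest_pd(S: np.ndarray, eps_scale: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues of a symmetric matrix up to a trace-scaled floor.

    Returns ``(repaired, changed)``.  The floor is
    ``eps_scale * trace(S_sym) / d`` (with an absolute fallback when the
    trace is not positive), so the output's smallest eigenvalue is at least
    that floor.  Already-PD matrices are returned unchanged (``changed`` is
    False).  Non-symmetric input is symmetrised first.
    """
    S = np.asarray(S, dtype=float)
    d = S.shape[0]
    sym = 0.5 * (S + S.T)
    tr = np.trace(sym)
    floor = eps_scale * (tr / d if tr > 0 else 1.0)
    w, V = np.linalg.eigh(sym)
    if w[0] >= floor and np.allclose(S, sym, atol=1e-12, rtol=0):
        return S, False
    w_clipped = np.maximum(w, floor)
    out = (V * w_clipped) @ V.T
    return 0.5 * (out + out.T), True
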