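"""Piecewise-constant hazard utilities shared by the cohort generator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PiecewiseHazard:
    """Piecewise-constant hazard rate on [0, inf).

    ``breaks`` are ascending segment start times (the first must be 0);
    ``rates`` are events/month on each segment, the last extending to
    infinity. Rates may be zero (a segment with no event intensity).
    """

    breaks: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if b.ndim != 1 or b.size == 0 or b[0] != 0.0:
            raise ValueError("breaks must be a non-empty 1-D sequence starting at 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("breaks must be strictly increasing")
        if r.shape != b.shape:
            raise ValueError("rates and breaks must have equal length")
        if np.any(r < 0):
            raise ValueError("hazard rates must be non-negative")

    def rate_at(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.breaks, t, side="right") - 1
        return np.asarray(self.rates, dtype=float)[idx]

    def cumulative(self, t):
        """Cumulative hazard at time(s) t (exact for piecewise-constant rates)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        b = np.asarray(self.breaks, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        # cumulative hazard at each breakpoint
        seg = np.diff(b) * r[:-1]
        H_at_break = np.concatenate([[0.0], np.cumsum(seg)])
        idx = np.searchsorted(b, t, side="right") - 1
        return H_at_break[idx] + r[idx] * (t - b[idx])

    def refine(self, extra_breaks) -> "PiecewiseHazard":
        """Insert extra breakpoints without changing the rate function."""
        pts = np.union1d(np.asarray(self.breaks, float), np.asarray(extra_breaks, float))
        pts = pts[pts >= 0.0]
        return PiecewiseHazard(tuple(pts), tuple(self.rate_at(pts)))


def sample_piecewise_times(breaks, rate_matrix, rng) -> np.ndarray:
    """Draw one event time per row of ``rate_matrix`` by inverse transform.

    ``breaks``: (K,) ascending segment starts beginning at 0, last segment
    unbounded. ``rate_matrix``: (n, K) per-subject per-segment rates. Rows
    whose total cumulative hazard is finite and exhausted yield ``inf``
    (the event never occurs).
    """
    breaks = np.asarray(breaks, dtype=float)
    R = np.asarray(rate_matrix, dtype=float)
    n, K = R.shape
    widths = np.diff(breaks)  # (K-1,)
    H_right = np.cumsum(R[:, :-1] * widths[None, :], axis=1)  # (n, K-1)
    H_left = np.concatenate([np.zeros((n, 1)), H_right], axis=1)  # (n, K)
    e = rng.exponential(size=n)
    # first segment whose right cumulative hazard reaches the exponential draw
    idx = np.sum(e[:, None] >= H_right, axis=1)  # in [0, K-1]
    rates_sel = R[np.arange(n), idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = breaks[idx] + (e - H_left[np.arange(n), idx]) / rates_sel
    t = np.where(rates_sel > 0, t, np.inf)
    # a zero-rate final segment after exhausted hazard means "never"
    return t
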