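"""Detrended fluctuation analysis (DFA) and the activity balance index.

DFA estimates the self-similarity (scaling) exponent ``alpha`` of a bounded
signal such as per-epoch acceleration:

1. integrate the mean-centred signal, ``c_t = sum_{i<=t} (x_i - xbar)``;
2. split ``c`` into ``B = floor(T/n)`` non-overlapping boxes of size ``n``
   and remove, per box, an order-``l`` polynomial trend fitted by ordinary
   least squares;
3. the fluctuation at scale ``n`` is the root mean square residual
   ``F(n)``; repeat over a log-spaced grid of box sizes in ``[4, T/4]``;
4. ``alpha`` is the OLS slope of ``log F(n)`` on ``log n``.

Interpretation: ``alpha = 0.5`` is white noise, ``1`` pink/fractal noise,
``1.5`` a random walk; ``(0, 1)`` indicates a stationary and ``(1, 2)`` a
non-stationary process.

The activity balance index rescales the exponent's distance from the
fractal point onto a (0, 1] scale that is easier to read:

    ABI(alpha) = exp(-|alpha - 1| / exp(-2))

so ABI = 1 at perfect fractal balance and falls to exp(-e^2) ~ 0.0006 at
the theoretical extremes alpha = 0 or 2.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

import numpy as np
from scipy import stats

from .series import AccelerationSeries

__all__ = ["integrate_signal", "fluctuation", "box_size_grid",
           "estimate_alpha", "abi", "DFAResult"]

_ALPHA_RANGE = (0.0, 2.0)


def _as_values(x) -> np.ndarray:
    if isinstance(x, AccelerationSeries):
        return x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("signal must be 1-d")
    if not np.isfinite(arr).all():
        raise ValueError("signal contains non-finite values")
    return arr


def integrate_signal(x) -> np.ndarray:
    """Accumulated mean-centred signal ``c_t = sum_{i<=t} (x_i - xbar)``.

    By construction the final value is zero up to rounding. A record must
    have T >= 16 to admit any box size in [4, T/4]; that requirement is
    enforced where box sizes are chosen (:func:`box_size_grid`).
    """
    vals = _as_values(x)
    if vals.size < 1:
        raise ValueError("empty signal")
    return np.cumsum(vals - vals.mean())


def fluctuation(c, n: int, order: int = 1) -> float:
    """Root mean square fluctuation of the integrated signal at box size n.

    The integrated signal is cut into ``B = floor(T/n)`` boxes of exactly
    ``n`` epochs (trailing ``T mod n`` epochs are dropped); an order-
    ``order`` polynomial is fitted per box by least squares and the RMS of
    the residuals over the ``B*n`` fitted epochs is returned.
    """
    c = np.asarray(c, dtype=float)
    T = c.size
    if not (4 <= n <= T // 4):
        raise ValueError(f"box size n={n} outside [4, {T // 4}] for T={T}")
    if order < 1:
        raise ValueError("detrend order must be >= 1")
    B = T // n
    boxes = c[: B * n].reshape(B, n)
    # within-box time index, centred for conditioning; the fitted polynomial
    # space is identical to one in the global epoch index
    t = np.arange(n, dtype=float) - (n - 1) / 2.0
    design = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, boxes.T, rcond=None)
    resid = boxes.T - design @ coef
    return float(np.sqrt(np.mean(resid ** 2)))


def box_size_grid(T: int, grid_size: int = 40) -> np.ndarray:
    """Log-spaced unique integer box sizes in ``[4, T//4]``."""
    n_max = T // 4
    if n_max < 4:
        raise ValueError(f"record too short for DFA (T={T})")
    raw = np.geomspace(4, n_max, num=grid_size)
    return np.unique(np.round(raw).astype(int))


@dataclass(frozen=True)
class DFAResult:
    """DFA fit for one subject: the log-log regression and the ABI."""

    box_sizes: np.ndarray
    fluctuations: np.ndarray
    alpha_hat: float
    alpha_stderr: float
    intercept: float
    order: int
    n_excluded: int = 0

    @property
    def in_theoretical_range(self) -> bool:
        """Whether alpha-hat lies in the theoretical (0, 2) range."""
        return _ALPHA_RANGE[0] < self.alpha_hat < _ALPHA_RANGE[1]

    @property
    def abi(self) -> float:
        return abi(self.alpha_hat)


def estimate_alpha(x, grid_size: int = 40, order: int = 1) -> DFAResult:
    """Full DFA chain: integrate, detrend per box, fit the log-log slope.

    Parameters
    ----------
    x
        Acceleration series (or plain signal vector), T >= 16 epochs.
    grid_size
        Number of log-spaced box sizes requested in [4, T/4]; duplicates
        after integer rounding are merged.
    order
        Polynomial detrending order ``l`` (1 = linear, the default).

    Box sizes where F(n) is exactly zero (a record that is piecewise
    perfectly polynomial) are excluded from the regression with a warning.
    Natural logarithms are used; the slope is base-invariant.
    """
    c = integrate_signal(x)
    sizes = box_size_grid(c.size, grid_size)
    fn = np.array([fluctuation(c, int(n), order) for n in sizes])
    usable = fn > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} box size(s) with zero fluctuation excluded from "
            "the log-log fit", stacklevel=2,
        )
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable box sizes; cannot fit alpha")
    fit = stats.linregress(np.log(sizes[usable]), np.log(fn[usable]))
    result = DFAResult(
        box_sizes=sizes,
        fluctuations=fn,
        alpha_hat=float(fit.slope),
        alpha_stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        order=order,
        n_excluded=n_excluded,
    )
    if not result.in_theoretical_range:
        warnings.warn(
            f"alpha-hat = {result.alpha_hat:.3f} outside the theoretical "
            "(0, 2) range", stacklevel=2,
        )
    return result


def abi(alpha_hat: float) -> float:
    """Activity balance index ``exp(-|alpha - 1| / exp(-2))``.

    Symmetric about 1 and strictly decreasing in ``|alpha - 1|``; equals 1
    at alpha = 1 and ~0.0006 at alpha = 0 or 2.
    """
    if not math.isfinite(alpha_hat):
        raise ValueError("alpha_hat must be finite")
    return math.exp(-abs(alpha_hat - 1.0) / math.exp(-2.0))
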