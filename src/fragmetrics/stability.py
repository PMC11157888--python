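"""Inter-daily stability (IS) and intradaily variability (IV).

IS measures how constant the 24-hour activity profile is across days:

    IS(z) = P * sum_h (zbar_h - zbar)^2 / (H * sum_p (z_p - zbar)^2)

where ``zbar_h`` is the mean of hour ``h`` across days and ``zbar`` the
grand mean over all ``P = D*H`` hours. IS lies in [0, 1]; 1 means every day
has the identical hourly profile.

IV measures hour-to-hour fragmentation as a normalised mean squared
successive difference:

    IV(z) = P * sum_{p>=2} (z_p - z_{p-1})^2 / ((P-1) * sum_p (z_p - zbar)^2)

Under a stationary AR(1) model with non-negative lag-1 autocorrelation phi,
IV converges to 2*(1 - phi) as P grows, hence the usual [0, 2] range: ~0
for smooth rhythms, ~2 for uncorrelated noise. Values above 2 are legal
(short records, or negative phi — an ultradian rhythm) and are flagged, not
clipped.

Both metrics are undefined for a constant series (zero total variance);
:class:`~fragmetrics.exceptions.UndefinedMetricError` is raised rather than
returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedMetricError
from .series import HourlyProportionSeries

__all__ = ["compute_is", "compute_iv", "estimate_phi", "stability_summary",
           "StabilityResult"]


def _as_hourly_matrix(z, hours_per_day=None) -> np.ndarray:
    """Coerce input to a (D, H) matrix of hourly values.

    Accepts an :class:`HourlyProportionSeries` or any 1-d array (in which
    case ``hours_per_day`` must be given for IS). Raw AR(1) simulations may
    fall outside [0, 1]; the formulas do not require proportions, so plain
    arrays are not range-checked here.
    """
    if isinstance(z, HourlyProportionSeries):
        return z.values.reshape(z.n_days, z.hours_per_day)
    arr = np.asarray(z, dtype=float)
    if arr.ndim == 2:
        return arr
    if hours_per_day is None:
        raise ValueError("hours_per_day is required for a flat array input")
    if arr.size % hours_per_day:
        raise ValueError(f"length {arr.size} not divisible by H={hours_per_day}")
    return arr.reshape(-1, hours_per_day)


def _as_vector(z) -> np.ndarray:
    if isinstance(z, HourlyProportionSeries):
        return z.values
    arr = np.asarray(z, dtype=float)
    return arr.reshape(-1)


def compute_is(z, hours_per_day: int | None = None) -> float:
    """Inter-daily stability of an hourly activity series.

    Parameters
    ----------
    z
        :class:`HourlyProportionSeries`, a (D, H) matrix, or a flat vector
        (then ``hours_per_day`` is required).

    Raises
    ------
    UndefinedMetricError
        If the series is constant (zero total variance).
    """
    zmat = _as_hourly_matrix(z, hours_per_day)
    D, H = zmat.shape
    zbar = zmat.mean()
    denom = ((zmat - zbar) ** 2).sum()
    if denom <= 0:
        raise UndefinedMetricError("IS undefined: constant hourly series")
    hour_means = zmat.mean(axis=0)
    return float(D * ((hour_means - zbar) ** 2).sum() / denom)


def compute_iv(z) -> float:
    """Intradaily variability of an hourly activity series.

    The value is not clipped: IV > 2 is returned as-is (it signals a short
    record or an ultradian rhythm).

    Raises
    ------
    UndefinedMetricError
        If the series is constant.
    """
    vec = _as_vector(z)
    P = vec.size
    if P < 2:
        raise ValueError("IV needs at least two hours")
    denom = ((vec - vec.mean()) ** 2).sum()
    if denom <= 0:
        raise UndefinedMetricError("IV undefined: constant hourly series")
    num = (np.diff(vec) ** 2).sum()
    return float(P * num / ((P - 1) * denom))


def estimate_phi(z, return_stderr: bool = False):
    """Lag-1 autocorrelation of the hourly series under an AR(1) model.

    Fits ``z_p = mu + phi * z_{p-1} + eps_p`` by ordinary least squares
    (equivalent to conditional maximum likelihood for a Gaussian AR(1)).
    Estimates outside [0, 1] are returned as-is; a negative value indicates
    an ultradian rhythm.

    Returns ``phi_hat`` or ``(phi_hat, stderr)`` when ``return_stderr``.
    """
    vec = _as_vector(z)
    if vec.size < 3:
        raise ValueError("phi estimation needs at least three hours")
    if np.ptp(vec) == 0:
        raise UndefinedMetricError("phi undefined: constant hourly series")
    lagged, current = vec[:-1], vec[1:]
    if np.ptp(lagged) == 0:
        raise UndefinedMetricError("phi undefined: constant regressor")
    fit = stats.linregress(lagged, current)
    if return_stderr:
        return float(fit.slope), float(fit.stderr)
    return float(fit.slope)


@dataclass(frozen=True)
class StabilityResult:
    """IS, IV and the AR(1) diagnostic for one subject."""

    is_value: float
    iv_value: float
    phi_hat: float
    phi_stderr: float

    @property
    def ultradian_flag(self) -> bool:
        """True when the series behaves ultradianly (phi < 0 or IV > 2)."""
        return bool(self.phi_hat < 0 or self.iv_value > 2)


def stability_summary(z) -> StabilityResult:
    """Compute IS, IV and phi together for one hourly series."""
    phi, se = estimate_phi(z, return_stderr=True)
    return StabilityResult(compute_is(z), compute_iv(z), phi, se)
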