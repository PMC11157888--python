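"""Rest/activity transition-probability estimation.

The transition probability (TP) from rest to activity after ``s`` epochs of
uninterrupted rest is ``pi_ra(s) = P(Y_t = a | Y_{t-1} = ... = Y_{t-s} = r)``
(and symmetrically ``pi_ar(s)``). Three estimators are provided, all
operating on the run-length (bout) decomposition of the state series:

* **ML** — the maximum-likelihood estimator with a censoring correction: the
  final bout of the record never ends in an observed transition, so an
  indicator for the last state is subtracted from both the transition count
  and the opportunity count. For ``s = 1`` this is
  ``(n_r - I(y_T=r)) / (T_r - I(y_T=r))``.
* **Bayesian** — a Beta-Binomial shrinkage estimator,
  ``(n_r - I(y_T=r) + lambda) / (T_r - I(y_T=r) + lambda)``, defined for any
  ``lambda > 0`` even when the state is never observed (then it equals 1:
  were the subject ever to enter the unobserved state, an immediate return
  is the best guess). ``lambda = 0.5`` corresponds to a horseshoe-type
  prior, ``lambda = 1`` to a uniform prior, and ``lambda -> 0`` recovers the
  ML estimate.
* **RAD** — the reciprocal average duration heuristic ``n_r / T_r``, which
  ignores censoring and therefore never undershoots the ML estimate for the
  state that closes the record.

Windowed variants accumulate bout counts separately over wake and sleep
windows, censoring every bout cut at a window boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedMetricError
from .series import (
    ACTIVE,
    REST,
    BoutDecomposition,
    SegmentedStates,
    StateSeries,
    WindowAnnotation,
    partition_windows,
)

__all__ = ["ml_tp", "bayes_tp", "rad", "windowed_tp",
           "TransitionEstimate", "WindowedTPSet"]

_DIRECTIONS = ("ra", "ar")


@dataclass(frozen=True)
class TransitionEstimate:
    """One transition-probability estimate with its counting provenance."""

    direction: str          # 'ra' (rest->active) or 'ar' (active->rest)
    s: int
    method: str             # 'ML', 'Bayesian' or 'RAD'
    numerator: float
    denominator: float
    lambda_: float | None = None

    @property
    def value(self) -> float:
        return self.numerator / self.denominator


def _direction_counts(b: BoutDecomposition, direction: str):
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    if direction == "ra":
        return b.rest_bouts, REST
    return b.activity_bouts, ACTIVE


def ml_tp(b: BoutDecomposition, direction: str, s: int = 1) -> TransitionEstimate:
    """Maximum-likelihood transition probability after ``s`` epochs in state.

    The transition count is the number of bouts of length >= s, minus one if
    the record ends in the state (that bout's ending transition is
    unobserved); the opportunity count is the number of length-s windows of
    the state, with the same censoring correction.

    Raises
    ------
    ValueError
        If ``s`` is outside ``[1, S_state]`` (no bout of the state is long
        enough to condition on).
    UndefinedMetricError
        If the opportunity count is not positive (state absent or observed
        only as a single fully censored bout) — use :func:`bayes_tp` then.
    """
    bouts, state = _direction_counts(b, direction)
    s_max = int(bouts.max()) if bouts.size else 0
    if not (1 <= s <= s_max):
        raise ValueError(
            f"s={s} out of range [1, {s_max}] for direction {direction!r} "
            f"(longest bout {s_max})"
        )
    censor = int(b.last_state == state)
    long_enough = bouts[bouts >= s]
    num = long_enough.size - censor
    den = int((long_enough - s + 1).sum()) - censor
    if den <= 0:
        raise UndefinedMetricError(
            f"ML TP_{direction}({s}) undefined (denominator {den}); "
            "the Bayesian estimator is always defined"
        )
    return TransitionEstimate(direction, s, "ML", float(num), float(den))


def bayes_tp(b: BoutDecomposition, direction: str,
             lambda_: float = 0.5) -> TransitionEstimate:
    """Bayesian (Beta-Binomial) transition probability at ``s = 1``.

    Always defined for ``lambda_ > 0``; equals 1 when the state never
    occurs.
    """
    if not (np.isfinite(lambda_) and lambda_ > 0):
        raise ValueError("lambda_ must be > 0")
    bouts, state = _direction_counts(b, direction)
    censor = int(b.last_state == state)
    num = bouts.size - censor + lambda_
    den = int(bouts.sum()) - censor + lambda_
    return TransitionEstimate(direction, 1, "Bayesian", float(num), float(den),
                              lambda_=lambda_)


def rad(b: BoutDecomposition, direction: str) -> TransitionEstimate:
    """Reciprocal average duration: bout count over total time in state."""
    bouts, state = _direction_counts(b, direction)
    total = int(bouts.sum())
    if total == 0:
        raise UndefinedMetricError(f"RAD_{state} undefined: state never observed")
    return TransitionEstimate(direction, 1, "RAD", float(bouts.size), float(total))


@dataclass(frozen=True)
class WindowedTPSet:
    """The four wake/sleep-windowed Bayesian transition probabilities.

    A label with no epochs at all (e.g. an annotation that is entirely one
    wake window) leaves that label's pair of estimates as ``None``.
    """

    tp_ra_wake: TransitionEstimate | None
    tp_ra_sleep: TransitionEstimate | None
    tp_ar_wake: TransitionEstimate | None
    tp_ar_sleep: TransitionEstimate | None

    def values(self) -> dict[str, float]:
        return {
            name: (est.value if est is not None else float("nan"))
            for name, est in (
                ("tp_ra_wake", self.tp_ra_wake),
                ("tp_ra_sleep", self.tp_ra_sleep),
                ("tp_ar_wake", self.tp_ar_wake),
                ("tp_ar_sleep", self.tp_ar_sleep),
            )
        }


def _windowed_estimate(part: SegmentedStates, direction: str,
                       lambda_: float) -> TransitionEstimate:
    active = direction == "ar"
    n, total, censored = part.bout_counts(active)
    # Every bout whose run reaches a segment end (window boundary or end of
    # record) is censored: its closing transition is unobserved, so it is
    # removed from both the transition count and the opportunity count. With
    # a single window spanning the whole record this reduces to the usual
    # last-state indicator correction.
    num = n - censored + lambda_
    den = total - censored + lambda_
    return TransitionEstimate(direction, 1, "Bayesian", float(num), float(den),
                              lambda_=lambda_)


def windowed_tp(y: StateSeries, w: WindowAnnotation,
                lambda_: float = 0.5) -> WindowedTPSet:
    """Bayesian s=1 transition probabilities split by wake/sleep windows.

    Bout counts and time-in-state totals are accumulated per label over all
    of that label's intervals; runs are never merged across a boundary, and
    a run cut at a boundary is censored on the cut side. All four values
    are defined for ``lambda_ > 0`` even when a state is absent in a window
    (the estimate is then 1).
    """
    if not (np.isfinite(lambda_) and lambda_ > 0):
        raise ValueError("lambda_ must be > 0")
    parts = partition_windows(y, w)

    def pair(label: str, direction: str):
        if parts[label].n_epochs == 0:
            return None
        return _windowed_estimate(parts[label], direction, lambda_)

    return WindowedTPSet(
        tp_ra_wake=pair("wake", "ra"),
        tp_ra_sleep=pair("sleep", "ra"),
        tp_ar_wake=pair("wake", "ar"),
        tp_ar_sleep=pair("sleep", "ar"),
    )
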