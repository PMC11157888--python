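"""Per-subject rest-activity fragmentation model.

:class:`RestActivityModel` is built from one subject's epoch-level
acceleration (optionally with a precomputed state column and wake/sleep
window annotations) and :meth:`RestActivityModel.fit` returns a
:class:`RestActivityResults` carrying the full metric panel:

====================  =====================================================
metric                meaning
====================  =====================================================
IS                    inter-daily stability, [0, 1]
IV                    intradaily variability, ~[0, 2], >2 flagged ultradian
phi_hat               AR(1) lag-1 autocorrelation of hourly activity
TP (ML/Bayes/RAD)     whole-series rest<->activity transition probabilities
TP_{ra,w} ... TP_{ar,s}  Bayesian TPs split by wake/sleep windows
alpha_hat             DFA self-similarity exponent, (0, 2)
ABI                   activity balance index exp(-|alpha-1|/exp(-2)), (0, 1]
====================  =====================================================

Degenerate inputs (e.g. constant acceleration) leave the affected metrics
as NaN with an explanatory status entry rather than aborting the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dfa, stability, transitions
from .exceptions import UndefinedMetricError
from .series import (
    AccelerationSeries,
    StateSeries,
    WindowAnnotation,
    extract_bouts,
    hourly_proportions,
    threshold_states,
)

__all__ = ["RestActivityModel", "RestActivityResults"]

METRIC_NAMES = (
    "is_value", "iv_value", "phi_hat",
    "tp_ra_ml", "tp_ra_bayes", "rad_r",
    "tp_ar_ml", "tp_ar_bayes", "rad_a",
    "tp_ra_wake", "tp_ra_sleep", "tp_ar_wake", "tp_ar_sleep",
    "alpha_hat", "abi",
)


class RestActivityModel:
    """Rest-activity fragmentation metrics for one subject.

    Parameters
    ----------
    acceleration
        :class:`AccelerationSeries` or a plain vector of per-epoch
        acceleration magnitudes in milli-g.
    states
        Optional precomputed :class:`StateSeries`; when omitted, states are
        derived by thresholding at ``threshold_mg``.
    windows
        Optional :class:`WindowAnnotation` of alternating wake/sleep
        intervals covering the record; required for the windowed TPs.
    threshold_mg
        Rest/active cut-point in milli-g (default 40).
    hours_per_day
        Hours per day for the IS/IV day grid (default 24).
    """

    def __init__(self, acceleration, *, states: StateSeries | None = None,
                 windows: WindowAnnotation | None = None,
                 threshold_mg: float = 40.0, epoch_seconds: int = 60,
                 hours_per_day: int = 24, subject_id: str | None = None):
        if isinstance(acceleration, AccelerationSeries):
            self.acceleration = acceleration
        else:
            self.acceleration = AccelerationSeries(
                np.asarray(acceleration, dtype=float), epoch_seconds, subject_id
            )
        self.subject_id = subject_id or self.acceleration.subject_id
        self.threshold_mg = float(threshold_mg)
        self.hours_per_day = int(hours_per_day)
        if states is not None and len(states) != len(self.acceleration):
            raise ValueError(
                f"states length {len(states)} != acceleration length "
                f"{len(self.acceleration)}"
            )
        self.states = states if states is not None else threshold_states(
            self.acceleration, self.threshold_mg
        )
        self.windows = windows

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, value_col: str = "value_mg",
                       state_col: str | None = None,
                       windows: WindowAnnotation | None = None,
                       **kwargs) -> "RestActivityModel":
        """Build a model from an epoch-per-row DataFrame.

        Rows must already be in temporal order (sort by ``epoch_index``
        upstream). A ``state`` column of 0/1 (1 = active) overrides
        thresholding when ``state_col`` is given.
        """
        if value_col not in df.columns:
            raise ValueError(f"missing column {value_col!r}")
        states = None
        if state_col is not None:
            if state_col not in df.columns:
                raise ValueError(f"missing column {state_col!r}")
            states = StateSeries(
                df[state_col].to_numpy(),
                kwargs.get("epoch_seconds", 60),
                kwargs.get("subject_id"),
            )
        return cls(df[value_col].to_numpy(dtype=float), states=states,
                   windows=windows, **kwargs)

    def fit(self, *, lambda_: float = 0.5, dfa_order: int = 1,
            dfa_grid_size: int = 40) -> "RestActivityResults":
        """Compute the full metric panel.

        Parameters
        ----------
        lambda_
            Beta-prior hyperparameter for the Bayesian TPs (default 0.5,
            a horseshoe-type prior; 1.0 = uniform prior, 1e-6 ~ ML).
        dfa_order, dfa_grid_size
            Detrending polynomial order and number of log-spaced box sizes
            for the DFA fit.
        """
        metrics: dict[str, float] = {name: float("nan") for name in METRIC_NAMES}
        stderr: dict[str, float] = {}
        status: dict[str, str] = {}
        nobs = len(self.acceleration)

        # hourly profile -> IS / IV / phi
        try:
            z = hourly_proportions(self.states, self.hours_per_day)
        except ValueError as exc:
            z = None
            for name in ("is_value", "iv_value", "phi_hat"):
                status[name] = str(exc)
        if z is not None:
            for name, fn in (("is_value", stability.compute_is),
                             ("iv_value", stability.compute_iv)):
                try:
                    metrics[name] = fn(z)
                except (UndefinedMetricError, ValueError) as exc:
                    status[name] = str(exc)
            try:
                phi, se = stability.estimate_phi(z, return_stderr=True)
                metrics["phi_hat"], stderr["phi_hat"] = phi, se
            except (UndefinedMetricError, ValueError) as exc:
                status["phi_hat"] = str(exc)

        # whole-series transition probabilities
        bouts = extract_bouts(self.states)
        tp_specs = (
            ("tp_ra_ml", lambda: transitions.ml_tp(bouts, "ra", 1)),
            ("tp_ar_ml", lambda: transitions.ml_tp(bouts, "ar", 1)),
            ("tp_ra_bayes", lambda: transitions.bayes_tp(bouts, "ra", lambda_)),
            ("tp_ar_bayes", lambda: transitions.bayes_tp(bouts, "ar", lambda_)),
            ("rad_r", lambda: transitions.rad(bouts, "ra")),
            ("rad_a", lambda: transitions.rad(bouts, "ar")),
        )
        for name, call in tp_specs:
            try:
                est = call()
                metrics[name] = est.value
            except (UndefinedMetricError, ValueError) as exc:
                status[name] = str(exc)

        windowed = None
        if self.windows is not None:
            try:
                windowed = transitions.windowed_tp(self.states, self.windows,
                                                   lambda_)
                for name, value in windowed.values().items():
                    metrics[name] = value
                    if np.isnan(value):
                        status[name] = "label has no epochs"
            except (UndefinedMetricError, ValueError) as exc:
                for name in ("tp_ra_wake", "tp_ra_sleep",
                             "tp_ar_wake", "tp_ar_sleep"):
                    status[name] = str(exc)
        else:
            for name in ("tp_ra_wake", "tp_ra_sleep",
                         "tp_ar_wake", "tp_ar_sleep"):
                status[name] = "no window annotation supplied"

        # DFA and ABI
        dfa_result = None
        try:
            dfa_result = dfa.estimate_alpha(self.acceleration,
                                            grid_size=dfa_grid_size,
                                            order=dfa_order)
            metrics["alpha_hat"] = dfa_result.alpha_hat
            stderr["alpha_hat"] = dfa_result.alpha_stderr
            metrics["abi"] = dfa_result.abi
            if not dfa_result.in_theoretical_range:
                status["alpha_hat"] = (
                    f"alpha {dfa_result.alpha_hat:.3f} outside (0, 2)"
                )
        except ValueError as exc:
            status["alpha_hat"] = status["abi"] = str(exc)

        return RestActivityResults(
            model=self,
            metrics=metrics,
            stderr=stderr,
            status=status,
            bouts=bouts,
            dfa_result=dfa_result,
            windowed_tp=windowed,
            params={"lambda_": lambda_, "dfa_order": dfa_order,
                    "dfa_grid_size": dfa_grid_size,
                    "threshold_mg": self.threshold_mg,
                    "epoch_seconds": self.acceleration.epoch_seconds,
                    "hours_per_day": self.hours_per_day},
            nobs=nobs,
        )


@dataclass
class RestActivityResults:
    """Fitted fragmentation metrics for one subject."""

    model: RestActivityModel
    metrics: dict
    stderr: dict
    status: dict
    bouts: object
    dfa_result: object
    windowed_tp: object
    params: dict
    nobs: int

    def __getattr__(self, name):
        metrics = object.__getattribute__(self, "metrics")
        if name in metrics:
            return metrics[name]
        raise AttributeError(name)

    @property
    def ultradian_flag(self) -> bool:
        phi, iv = self.metrics["phi_hat"], self.metrics["iv_value"]
        return bool((not np.isnan(phi) and phi < 0)
                    or (not np.isnan(iv) and iv > 2))

    def to_frame(self) -> pd.DataFrame:
        """One-row DataFrame of the metric panel (the per-subject record)."""
        row = {"subject_id": self.model.subject_id, "n_epochs": self.nobs}
        row.update(self.metrics)
        row["ultradian_flag"] = self.ultradian_flag
        row["status"] = "; ".join(f"{k}: {v}" for k, v in self.status.items())
        return pd.DataFrame([row])

    def summary(self) -> str:
        """Human-readable summary table."""
        labels = {
            "is_value": "Inter-daily stability (IS)",
            "iv_value": "Intradaily variability (IV)",
            "phi_hat": "AR(1) autocorrelation (phi)",
            "tp_ra_ml": "TP rest->active, ML",
            "tp_ra_bayes": "TP rest->active, Bayesian",
            "rad_r": "RAD rest",
            "tp_ar_ml": "TP active->rest, ML",
            "tp_ar_bayes": "TP active->rest, Bayesian",
            "rad_a": "RAD activity",
            "tp_ra_wake": "TP rest->active, wake",
            "tp_ra_sleep": "TP rest->active, sleep",
            "tp_ar_wake": "TP active->rest, wake",
            "tp_ar_sleep": "TP active->rest, sleep",
            "alpha_hat": "DFA self-similarity (alpha)",
            "abi": "Activity balance index (ABI)",
        }
        width = max(len(v) for v in labels.values())
        lines = [
            "Rest-activity fragmentation summary",
            "=" * (width + 24),
            f"{'subject':<{width}}  {self.model.subject_id or '-'}",
            f"{'epochs':<{width}}  {self.nobs}",
            f"{'ultradian flag':<{width}}  {self.ultradian_flag}",
            "-" * (width + 24),
        ]
        for name, label in labels.items():
            val = self.metrics[name]
            if np.isnan(val):
                shown = f"undefined ({self.status.get(name, 'n/a')})"
            else:
                shown = f"{val:.4f}"
                if name in self.stderr:
                    shown += f" (se {self.stderr[name]:.4f})"
            lines.append(f"{label:<{width}}  {shown}")
        lines.append("=" * (width + 24))
        return "\n".join(lines)

    def plot_fluctuation(self, ax=None):
        """Log-log plot of (n, F(n)) with the fitted scaling line."""
        if self.dfa_result is None:
            raise ValueError("no DFA fit available")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = self.dfa_result
        ax.loglog(res.box_sizes, res.fluctuations, "o", ms=4, label="F(n)")
        grid = np.log(res.box_sizes.astype(float))
        ax.loglog(res.box_sizes, np.exp(res.intercept + res.alpha_hat * grid),
                  "-", label=f"alpha = {res.alpha_hat:.3f}")
        ax.set_xlabel("box size n (epochs)")
        ax.set_ylabel("fluctuation F(n)")
        ax.legend()
        return ax
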