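"""Synthetic generators with known ground truth for every estimator.

Each generator matches the stochastic structure an estimator assumes, so
parameter recovery can be tested without any external dataset:

* :func:`gen_ar1` — stationary Gaussian AR(1) hourly series (the model
  under which the IV range results hold);
* :func:`gen_markov_states` — first-order two-state Markov chain of
  rest/active epochs (the model under which the ML transition-probability
  estimator is derived);
* :func:`gen_colored_noise` — spectrally synthesised 1/f^beta Gaussian
  noise with ``beta = 2*alpha_target - 1``, so DFA should recover
  ``alpha_target``;
* :func:`gen_random_walk` — cumulative sum of iid Gaussian noise
  (DFA alpha = 1.5);
* :func:`gen_daily_profile` — a square-wave day/night acceleration profile
  with Gaussian noise and matching wake/sleep window annotations, for
  end-to-end tests.

All generators consume a ``numpy.random.default_rng`` seed (PCG64) and are
byte-deterministic given the seed.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .series import (
    AccelerationSeries,
    HourlyProportionSeries,
    StateSeries,
    WindowAnnotation,
)

__all__ = ["gen_ar1", "gen_markov_states", "gen_colored_noise",
           "gen_random_walk", "gen_daily_profile", "AR1Sample"]

RNG_ALGORITHM = "PCG64 (numpy.random.default_rng)"


class AR1Sample(NamedTuple):
    """An AR(1) draw: the raw stationary series and a [0,1]-clipped copy.

    Clipping makes the values valid hourly proportions but perturbs the
    AR(1) structure wherever the raw path leaves [0, 1]; recovery tests
    should use ``raw``.
    """

    raw: np.ndarray
    squashed: np.ndarray


def gen_ar1(phi: float, n_hours: int, *, mu: float = 0.0, sigma: float = 1.0,
            seed: int | None = None) -> AR1Sample:
    """Stationary Gaussian AR(1): ``Z_p = mu + phi * Z_{p-1} + eps_p``.

    Initialised from the stationary distribution
    ``N(mu / (1 - phi), sigma^2 / (1 - phi^2))``.
    """
    if not abs(phi) < 1:
        raise ValueError(f"|phi| must be < 1 for stationarity, got {phi}")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n_hours < 1:
        raise ValueError("n_hours must be >= 1")
    rng = np.random.default_rng(seed)
    z = np.empty(n_hours)
    z[0] = rng.normal(mu / (1 - phi), sigma / np.sqrt(1 - phi ** 2))
    eps = rng.normal(0.0, sigma, size=n_hours - 1)
    for p in range(1, n_hours):
        z[p] = mu + phi * z[p - 1] + eps[p - 1]
    return AR1Sample(raw=z, squashed=np.clip(z, 0.0, 1.0))


def gen_markov_states(p_ra: float, p_ar: float, n_epochs: int, *,
                      seed: int | None = None, epoch_seconds: int = 60,
                      subject_id: str | None = None) -> StateSeries:
    """First-order two-state rest/active Markov chain.

    ``p_ra`` is the per-epoch probability of leaving rest and ``p_ar`` of
    leaving activity. The chain starts from its stationary distribution, so
    the expected active fraction is ``p_ra / (p_ra + p_ar)`` and bout
    lengths are geometric with means ``1/p_ra`` (rest) and ``1/p_ar``
    (activity).
    """
    for name, p in (("p_ra", p_ra), ("p_ar", p_ar)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {p}")
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=bool)
    active = u[0] < p_ra / (p_ra + p_ar)  # stationary start
    states[0] = active
    for t in range(1, n_epochs):
        flip = u[t] < (p_ar if active else p_ra)
        if flip:
            active = not active
        states[t] = active
    return StateSeries(states, epoch_seconds, subject_id)


def gen_colored_noise(alpha_target: float, n_epochs: int, *,
                      seed: int | None = None, mean_mg: float = 50.0,
                      epoch_seconds: int = 60,
                      subject_id: str | None = None) -> AccelerationSeries:
    """Spectrally synthesised 1/f^beta Gaussian noise.

    The power spectrum follows ``S(f) ~ f^-beta`` with
    ``beta = 2*alpha_target - 1``: alpha 0.5 is white noise (flat
    spectrum), 1.0 pink noise, 1.5 Brownian scaling. The signal is shifted
    by its minimum and rescaled to a non-negative milli-g range; location
    and scale do not affect the scaling exponent.
    """
    if not 0 < alpha_target < 2:
        raise ValueError(f"alpha_target must lie in (0, 2), got {alpha_target}")
    if n_epochs < 16:
        raise ValueError("n_epochs must be >= 16")
    beta = 2.0 * alpha_target - 1.0
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_epochs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = amp * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    spec[0] = 0.0
    signal = np.fft.irfft(spec, n=n_epochs)
    signal = signal - signal.min()
    peak = signal.max()
    if peak > 0:
        signal = signal * (2.0 * mean_mg / peak)
    return AccelerationSeries(signal, epoch_seconds, subject_id)


def gen_random_walk(n_epochs: int, *, seed: int | None = None,
                    step_sd: float = 1.0, epoch_seconds: int = 60,
                    subject_id: str | None = None) -> AccelerationSeries:
    """Cumulative sum of iid Gaussian steps, shifted/scaled non-negative.

    The canonical DFA alpha = 1.5 benchmark; the affine rescaling onto a
    milli-g range leaves the exponent untouched.
    """
    if n_epochs < 16:
        raise ValueError("n_epochs must be >= 16")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(0.0, step_sd, size=n_epochs))
    walk = walk - walk.min()
    peak = walk.max()
    if peak > 0:
        walk = walk * (100.0 / peak)
    return AccelerationSeries(walk, epoch_seconds, subject_id)


def gen_daily_profile(n_days: int = 7, *, wake_hours: int = 16,
                      active_level: float = 80.0, rest_level: float = 20.0,
                      noise_sd: float = 20.0, epoch_seconds: int = 60,
                      seed: int | None = None, subject_id: str | None = None,
                      ) -> tuple[AccelerationSeries, WindowAnnotation]:
    """Square-wave day/night acceleration with matching window annotations.

    Each day starts with ``wake_hours`` hours at ``active_level`` mg
    followed by sleep at ``rest_level`` mg; iid Gaussian noise of SD
    ``noise_sd`` is added and the result clipped at zero. The defaults
    (16 h wake at 80 mg, 8 h sleep at 20 mg, 20 mg noise) keep daytime
    epochs mostly above and night-time epochs mostly below the 40 mg
    cut-point while still producing occasional sedentary bouts by day and
    brief movements by night, so every windowed transition probability is
    informative.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0 < wake_hours < 24:
        raise ValueError("wake_hours must lie in (0, 24)")
    if min(active_level, rest_level) < 0 or noise_sd < 0:
        raise ValueError("levels and noise_sd must be non-negative")
    if 3600 % epoch_seconds:
        raise ValueError("epoch_seconds must divide an hour")
    per_hour = 3600 // epoch_seconds
    day_epochs = 24 * per_hour
    wake_epochs = wake_hours * per_hour
    day = np.concatenate([
        np.full(wake_epochs, float(active_level)),
        np.full(day_epochs - wake_epochs, float(rest_level)),
    ])
    signal = np.tile(day, n_days)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)
    signal = np.clip(signal, 0.0, None)
    intervals = []
    for d in range(n_days):
        base = d * day_epochs
        intervals.append((base, base + wake_epochs, "wake"))
        intervals.append((base + wake_epochs, base + day_epochs, "sleep"))
    return (
        AccelerationSeries(signal, epoch_seconds, subject_id),
        WindowAnnotation(intervals),
    )


def ar1_hourly_series(phi: float, n_days: int, *, hours_per_day: int = 24,
                      mu: float = 0.0, sigma: float = 1.0,
                      seed: int | None = None) -> HourlyProportionSeries:
    """Convenience: a squashed AR(1) draw packaged as hourly proportions."""
    sample = gen_ar1(phi, n_days * hours_per_day, mu=mu, sigma=sigma, seed=seed)
    return HourlyProportionSeries(sample.squashed, hours_per_day, n_days)
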