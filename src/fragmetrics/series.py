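"""Data model for epoch-level rest-activity time series.

Three per-subject representations are used throughout the package:

* :class:`AccelerationSeries` — acceleration magnitude per epoch (milli-g),
  typically 1-minute ENMO averages. Input to detrended fluctuation analysis.
* :class:`StateSeries` — a binary rest/active state per epoch, obtained by
  thresholding the acceleration (active iff value strictly exceeds the
  cut-point, 40 mg by default). Input to transition-probability estimation.
* :class:`HourlyProportionSeries` — the proportion of active epochs per
  hour, arranged as D days of H hours. Input to inter-daily stability and
  intradaily variability.

Epoch indices are 0-based and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REST = "r"
ACTIVE = "a"

_SYMBOL_MAP = {
    "r": False, "a": True,
    "rest": False, "active": True,
    0: False, 1: True,
    False: False, True: True,
}


def _as_bool_states(states) -> np.ndarray:
    arr = np.asarray(states)
    if arr.dtype == bool:
        return arr.copy()
    if arr.dtype.kind in "iu":
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            raise ValueError(
                f"integer states must be 0 (rest) or 1 (active); "
                f"offending epoch index {int(np.flatnonzero(bad)[0])}"
            )
        return arr.astype(bool)
    out = np.empty(arr.shape, dtype=bool)
    for i, s in enumerate(arr.ravel()):
        key = s.item() if isinstance(s, np.generic) else s
        if key not in _SYMBOL_MAP:
            raise ValueError(f"unrecognised state {s!r} at epoch index {i}")
        out.ravel()[i] = _SYMBOL_MAP[key]
    return out


@dataclass(frozen=True)
class AccelerationSeries:
    """Per-epoch acceleration magnitudes in milli-g.

    Parameters
    ----------
    values
        Non-negative, finite acceleration magnitudes, one per epoch.
    epoch_seconds
        Epoch duration in seconds (default 60, i.e. 1-minute epochs).
    subject_id
        Opaque subject label carried through to summaries.
    max_mg
        Declared measurement ceiling of the device (the series must lie in
        ``[0, max_mg]``). Defaults to 8000 mg, the range of a +/-8 g wrist
        accelerometer.
    """

    values: np.ndarray
    epoch_seconds: int = 60
    subject_id: str | None = None
    max_mg: float = 8000.0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("values must be a non-empty 1-d sequence")
        bad = ~np.isfinite(vals)
        if bad.any():
            raise ValueError(
                f"non-finite acceleration at epoch index {int(np.flatnonzero(bad)[0])}"
            )
        if (vals < 0).any():
            raise ValueError(
                f"negative acceleration at epoch index {int(np.flatnonzero(vals < 0)[0])}"
            )
        if (vals > self.max_mg).any():
            raise ValueError(
                f"acceleration exceeds declared maximum {self.max_mg} mg at "
                f"epoch index {int(np.flatnonzero(vals > self.max_mg)[0])}"
            )
        if not (isinstance(self.epoch_seconds, (int, np.integer)) and self.epoch_seconds > 0):
            raise ValueError("epoch_seconds must be a positive integer")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class StateSeries:
    """Per-epoch binary rest/active states.

    States are stored as a boolean array with ``True`` = active. The
    symbolic view (``'r'``/``'a'``) is available via :meth:`to_symbols`.
    """

    states: np.ndarray
    epoch_seconds: int = 60
    subject_id: str | None = None

    def __post_init__(self):
        arr = _as_bool_states(self.states)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("states must be a non-empty 1-d sequence")
        if not (isinstance(self.epoch_seconds, (int, np.integer)) and self.epoch_seconds > 0):
            raise ValueError("epoch_seconds must be a positive integer")
        object.__setattr__(self, "states", arr)

    def __len__(self) -> int:
        return self.states.size

    def to_symbols(self) -> list[str]:
        return [ACTIVE if s else REST for s in self.states]

    @classmethod
    def from_symbols(cls, symbols, epoch_seconds: int = 60, subject_id=None) -> "StateSeries":
        return cls(_as_bool_states(list(symbols)), epoch_seconds, subject_id)


@dataclass(frozen=True)
class HourlyProportionSeries:
    """Per-hour proportion of active epochs, over D days of H hours.

    The flat vector has length ``P = hours_per_day * n_days`` and is filled
    day by day (hour h of day d sits at flat index ``d * H + h``).
    """

    values: np.ndarray
    hours_per_day: int = 24
    n_days: int = 1

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be 1-d")
        if self.hours_per_day < 1 or self.n_days < 1:
            raise ValueError("hours_per_day and n_days must be positive")
        if vals.size != self.hours_per_day * self.n_days:
            raise ValueError(
                f"length {vals.size} != hours_per_day*n_days = "
                f"{self.hours_per_day * self.n_days}"
            )
        if not np.isfinite(vals).all():
            raise ValueError("non-finite hourly proportion")
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("hourly proportions must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BoutDecomposition:
    """Run-length encoding of a state series.

    ``rest_bouts`` and ``activity_bouts`` hold the lengths of maximal runs
    of each state in temporal order. Together with ``last_state`` they
    determine the original series exactly (the first state is implied by
    the bout counts and the final state).
    """

    rest_bouts: np.ndarray
    activity_bouts: np.ndarray
    last_state: str

    def __post_init__(self):
        r = np.asarray(self.rest_bouts, dtype=int)
        a = np.asarray(self.activity_bouts, dtype=int)
        if (r <= 0).any() or (a <= 0).any():
            raise ValueError("bout lengths must be positive integers")
        if self.last_state not in (REST, ACTIVE):
            raise ValueError("last_state must be 'r' or 'a'")
        if abs(r.size - a.size) > 1:
            raise ValueError("rest and activity bout counts must differ by at most 1")
        if r.size + a.size == 0:
            raise ValueError("empty decomposition")
        object.__setattr__(self, "rest_bouts", r)
        object.__setattr__(self, "activity_bouts", a)

    # Definition-5/6 totals
    @property
    def n_r(self) -> int:
        return self.rest_bouts.size

    @property
    def n_a(self) -> int:
        return self.activity_bouts.size

    @property
    def T_r(self) -> int:
        return int(self.rest_bouts.sum())

    @property
    def T_a(self) -> int:
        return int(self.activity_bouts.sum())

    @property
    def S_r(self) -> int:
        return int(self.rest_bouts.max()) if self.n_r else 0

    @property
    def S_a(self) -> int:
        return int(self.activity_bouts.max()) if self.n_a else 0

    @property
    def first_state(self) -> str:
        if self.n_r != self.n_a:
            return REST if self.n_r > self.n_a else ACTIVE
        # equal counts: the series starts in the opposite state to the last
        return ACTIVE if self.last_state == REST else REST


@dataclass(frozen=True)
class WindowAnnotation:
    """Alternating wake/sleep intervals, half-open on 0-based epoch indices.

    Intervals must be sorted, non-overlapping and contiguous; labels must
    alternate. Full coverage of a series is checked when the annotation is
    applied via :func:`partition_windows`.
    """

    intervals: tuple

    def __init__(self, intervals):
        ivs = []
        for start, end, label in intervals:
            start, end = int(start), int(end)
            if label not in ("wake", "sleep"):
                raise ValueError(f"label must be 'wake' or 'sleep', got {label!r}")
            if end <= start:
                raise ValueError(f"empty or inverted interval [{start}, {end})")
            ivs.append((start, end, label))
        if not ivs:
            raise ValueError("at least one interval required")
        for (s0, e0, l0), (s1, e1, l1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping intervals at epoch {s1}")
            if s1 > e0:
                raise ValueError(f"gap in window annotation at epochs [{e0}, {s1})")
            if l1 == l0:
                raise ValueError(f"labels must alternate; repeated {l0!r} at epoch {s1}")
        object.__setattr__(self, "intervals", tuple(ivs))

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


@dataclass(frozen=True)
class SegmentedStates:
    """States of one window label, kept as per-interval segments.

    Keeping segments separate (rather than only the concatenated vector)
    lets bout extraction respect window boundaries: a run touching a
    segment edge was cut there, so its end is censored — no rest/activity
    transition is observed at the cut.
    """

    label: str
    segments: tuple  # tuple of boolean ndarrays, temporal order

    @property
    def n_epochs(self) -> int:
        return int(sum(seg.size for seg in self.segments))

    def concatenated(self) -> np.ndarray:
        if not self.segments:
            return np.zeros(0, dtype=bool)
        return np.concatenate(self.segments)

    def bout_counts(self, active: bool) -> tuple[int, int, int]:
        """Count bouts of one state across segments.

        Returns ``(n_bouts, total_epochs, n_censored_ends)`` where a bout's
        end is censored when the run reaches the end of its segment (window
        boundary or end of record), so the transition that would close it
        is unobserved.
        """
        n = total = censored = 0
        for seg in self.segments:
            runs = _run_lengths(seg)
            for state, length in runs:
                if state == active:
                    n += 1
                    total += length
            if runs and runs[-1][0] == active:
                censored += 1
        return n, total, censored


def _run_lengths(states: np.ndarray) -> list[tuple[bool, int]]:
    """Maximal runs of a boolean vector as (state, length) pairs, in order."""
    if states.size == 0:
        return []
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    bounds = np.concatenate(([0], change, [states.size]))
    return [
        (bool(states[b]), int(e - b)) for b, e in zip(bounds[:-1], bounds[1:])
    ]


# ---------------------------------------------------------------------------
# transformations


def threshold_states(x: AccelerationSeries, delta_y: float = 40.0) -> StateSeries:
    """Dichotomise acceleration into rest/active states.

    An epoch is *active* iff its acceleration strictly exceeds ``delta_y``
    (milli-g); equality is classified as rest. The default 40 mg cut-point
    separates inactivity from light-or-higher intensity on wrist-worn
    devices.
    """
    if not np.isfinite(delta_y) or delta_y < 0:
        raise ValueError("delta_y must be a finite non-negative threshold")
    return StateSeries(x.values > delta_y, x.epoch_seconds, x.subject_id)


def hourly_proportions(y: StateSeries, hours_per_day: int = 24) -> HourlyProportionSeries:
    """Aggregate epoch states into per-hour active proportions.

    The series length must be an exact multiple of the number of epochs per
    hour (no partial hours), and the hour count an exact multiple of
    ``hours_per_day`` (no partial days).
    """
    if 3600 % y.epoch_seconds:
        raise ValueError(f"epoch_seconds={y.epoch_seconds} does not divide an hour")
    delta_z = 3600 // y.epoch_seconds
    T = len(y)
    if T % delta_z:
        raise ValueError(
            f"series length {T} is not a whole number of hours "
            f"({delta_z} epochs per hour)"
        )
    n_hours = T // delta_z
    if n_hours % hours_per_day:
        raise ValueError(
            f"{n_hours} hours is not a whole number of {hours_per_day}-hour days"
        )
    props = y.states.reshape(n_hours, delta_z).mean(axis=1)
    return HourlyProportionSeries(props, hours_per_day, n_hours // hours_per_day)


def extract_bouts(y: StateSeries) -> BoutDecomposition:
    """Run-length encode a state series into rest and activity bouts."""
    runs = _run_lengths(y.states)
    rest = [length for state, length in runs if not state]
    act = [length for state, length in runs if state]
    return BoutDecomposition(
        np.asarray(rest, dtype=int),
        np.asarray(act, dtype=int),
        ACTIVE if y.states[-1] else REST,
    )


def reconstruct_states(b: BoutDecomposition, epoch_seconds: int = 60,
                       subject_id=None) -> StateSeries:
    """Inverse of :func:`extract_bouts`: interleave bouts back to a series."""
    first_active = b.first_state == ACTIVE
    seqs = (b.activity_bouts, b.rest_bouts) if first_active else (b.rest_bouts, b.activity_bouts)
    out = []
    state = first_active
    i = j = 0
    while i < seqs[0].size or j < seqs[1].size:
        if state == first_active:
            out.append(np.full(seqs[0][i], first_active, dtype=bool))
            i += 1
        else:
            out.append(np.full(seqs[1][j], not first_active, dtype=bool))
            j += 1
        state = not state
    return StateSeries(np.concatenate(out), epoch_seconds, subject_id)


def partition_windows(y: StateSeries, w: WindowAnnotation) -> dict[str, SegmentedStates]:
    """Split a state series into wake and sleep parts.

    The annotation must cover ``[0, len(y))`` exactly. Each label's part
    keeps its per-interval segments so that downstream bout extraction
    never merges runs across a window boundary.

    Returns a dict with keys ``'wake'`` and ``'sleep'``.
    """
    if w.start != 0 or w.end != len(y):
        raise ValueError(
            f"window annotation covers [{w.start}, {w.end}) but the series "
            f"spans [0, {len(y)})"
        )
    parts: dict[str, list] = {"wake": [], "sleep": []}
    for start, end, label in w.intervals:
        parts[label].append(y.states[start:end])
    return {
        label: SegmentedStates(label, tuple(segs))
        for label, segs in parts.items()
    }


def reshape_days(z: HourlyProportionSeries) -> np.ndarray:
    """Arrange the flat hourly vector as a (n_days, hours_per_day) matrix."""
    return z.values.reshape(z.n_days, z.hours_per_day)
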