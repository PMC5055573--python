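"""Accumulated degree-day (ADD) thermal accounting.

Postmortem decomposition is driven jointly by elapsed time and ambient
temperature.  The standard forensic device for collapsing the two onto one
axis is the accumulated degree-day: the time integral of ambient temperature
(in degrees Celsius, floored at 0 °C) expressed in day units,

    ADD(t) = sum_i max(T_i, 0) * dt_i / 24      [°d]

over the piecewise-constant temperature segments covering the first ``t``
hours postmortem.  The 0 °C floor prevents sub-zero phases from subtracting
thermal "work" that decomposition cannot undo.

The module provides the forward map (:func:`compute_add`) and its monotone
inversion (:func:`invert_add`), which turns calibrated ADD thresholds back
into clock-time bounds.  Because accumulation stalls during phases at or
below 0 °C, the inverse is interval-valued on such plateaus: a delimitation,
not a point estimate.

Durations are hours postmortem (hpm) throughout; ADD is in degree-days (°d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSegment",
    "TemperatureProfile",
    "AddInversion",
    "compute_add",
    "invert_add",
    "round_trip_check",
]

#: absolute tolerance (°d) for plateau / boundary comparisons
_ADD_TOL = 1e-9


@dataclass(frozen=True)
class TemperatureSegment:
    """One phase of constant ambient temperature.

    Parameters
    ----------
    duration_h : float
        Length of the phase in hours postmortem; strictly positive.
    temp_c : float
        Ambient temperature in °C.  May be negative as recorded; the 0 °C
        floor is applied at accumulation time, not here.
    """

    duration_h: float
    temp_c: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.duration_h) or self.duration_h <= 0:
            raise ValueError(
                f"segment duration must be positive and finite, got {self.duration_h!r}"
            )
        if not math.isfinite(self.temp_c):
            raise ValueError(f"segment temperature must be finite, got {self.temp_c!r}")

    @property
    def effective_temp(self) -> float:
        """Temperature after the 0 °C floor."""
        return max(self.temp_c, 0.0)

    @property
    def add(self) -> float:
        """Degree-days accumulated over the whole segment."""
        return self.effective_temp * self.duration_h / 24.0


@dataclass(frozen=True)
class TemperatureProfile:
    """Chronological sequence of constant-temperature phases from death onward.

    A typical forensic profile has two segments: the scene's ambient
    temperature followed by 4 °C mortuary cooling.
    """

    segments: tuple[TemperatureSegment, ...]
    label: str = ""

    def __init__(self, segments: Iterable[TemperatureSegment], label: str = ""):
        segments = tuple(segments)
        if not segments:
            raise ValueError("profile needs at least one segment")
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "label", label)

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[float, float]], label: str = ""
    ) -> "TemperatureProfile":
        """Build from ``(duration_h, temp_c)`` pairs, skipping zero-length phases."""
        return cls(
            (TemperatureSegment(d, t) for d, t in pairs if d > 0), label=label
        )

    @property
    def total_hours(self) -> float:
        return float(sum(s.duration_h for s in self.segments))

    @property
    def total_add(self) -> float:
        return float(sum(s.add for s in self.segments))

    # -- CSV round trip (header: segment,duration_h,temp_c) ----------------
    @classmethod
    def from_csv(cls, path, label: str = "") -> "TemperatureProfile":
        df = pd.read_csv(path)
        required = {"duration_h", "temp_c"}
        if not required.issubset(df.columns):
            raise ValueError(f"profile file {path} must have columns {sorted(required)}")
        return cls.from_pairs(
            list(zip(df["duration_h"].astype(float), df["temp_c"].astype(float))),
            label=label or str(path),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "segment": np.arange(1, len(self.segments) + 1),
                "duration_h": [s.duration_h for s in self.segments],
                "temp_c": [s.temp_c for s in self.segments],
            }
        ).to_csv(path, index=False)


def compute_add(profile: TemperatureProfile, elapsed_h: float | None = None) -> float:
    """Degree-days accumulated over the first ``elapsed_h`` hours of ``profile``.

    ``elapsed_h=None`` uses the full profile.  Raises ``ValueError`` when
    ``elapsed_h`` lies outside ``[0, profile.total_hours]`` — the profile is
    never extrapolated; append an explicit trailing segment instead.
    """
    total = profile.total_hours
    if elapsed_h is None:
        elapsed_h = total
    if not math.isfinite(elapsed_h) or elapsed_h < 0:
        raise ValueError(f"elapsed time must be finite and >= 0, got {elapsed_h!r}")
    if elapsed_h > total * (1 + 1e-12) + 1e-9:
        raise ValueError(
            f"elapsed {elapsed_h} h exceeds profile duration {total} h; "
            "no extrapolation — append a trailing segment instead"
        )
    elapsed_h = min(elapsed_h, total)
    add = 0.0
    remaining = elapsed_h
    for seg in profile.segments:
        if remaining <= 0:
            break
        dt = min(seg.duration_h, remaining)
        add += seg.effective_temp * dt / 24.0
        remaining -= dt
    return add


@dataclass(frozen=True)
class AddInversion:
    """Result of inverting an ADD target on a temperature profile.

    ``t_lo`` is the earliest elapsed time (hpm) at which the target is
    reached; ``t_hi`` is the latest time at which the accumulation still
    equals the target (t_hi > t_lo only across 0 °C-effective plateaus).
    When the profile never accumulates the target, ``reached`` is False and
    both times are NaN.
    """

    t_lo: float
    t_hi: float
    reached: bool
    target: float
    total_add: float


def invert_add(profile: TemperatureProfile, target: float) -> AddInversion:
    """Earliest/latest elapsed times at which ``profile`` accumulates ``target`` °d."""
    if not math.isfinite(target) or target < 0:
        raise ValueError(f"ADD target must be finite and >= 0, got {target!r}")
    total_add = profile.total_add
    if target > total_add + _ADD_TOL:
        return AddInversion(math.nan, math.nan, False, target, total_add)

    # locate earliest crossing
    t_lo = None
    cum = 0.0
    t_start = 0.0
    for seg in profile.segments:
        rate = seg.effective_temp / 24.0  # °d per hour
        cum_end = cum + rate * seg.duration_h
        if cum_end >= target - _ADD_TOL:
            if rate > 0:
                t_lo = t_start + max(target - cum, 0.0) / rate
            else:  # plateau already at the target
                t_lo = t_start
            if target <= cum + _ADD_TOL:
                t_lo = t_start  # reached at (or before) the segment start
            break
        cum = cum_end
        t_start += seg.duration_h
    if t_lo is None:  # numerically at the profile end
        t_lo = profile.total_hours
    if target <= _ADD_TOL:
        t_lo = 0.0

    # extend across any zero-accumulation plateau following t_lo
    t_hi = t_lo
    elapsed = 0.0
    for seg in profile.segments:
        seg_start, seg_end = elapsed, elapsed + seg.duration_h
        elapsed = seg_end
        if seg_end <= t_hi + 1e-12:
            continue
        if seg.effective_temp > 0:
            break  # accumulation resumes (or never stopped) — plateau ends
        if seg_start <= t_hi + 1e-12:
            t_hi = seg_end
        else:
            break
    return AddInversion(float(t_lo), float(t_hi), True, target, total_add)


def round_trip_check(
    profile: TemperatureProfile, elapsed_h: float, tol: float = 1e-6
) -> bool:
    """True iff ``elapsed_h`` falls within the inversion interval of its own ADD."""
    inv = invert_add(profile, compute_add(profile, elapsed_h))
    return bool(inv.reached and inv.t_lo - tol <= elapsed_h <= inv.t_hi + tol)
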