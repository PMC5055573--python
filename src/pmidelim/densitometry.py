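"""Band calling from 1-D gel-lane densitometric traces.

A Western blot or zymogram lane is reduced upstream (e.g. by ImageJ's gel
tools) to a position-versus-intensity trace.  This module maps lane
positions to molecular weights through a ladder calibration (log-linear
interpolation), integrates baseline-corrected band areas inside expected
molecular-weight windows, and converts them to binary presence calls with
the ratio rule used throughout this pipeline: any signal whose area is
below 1 % of the lane's dominant band is background, not a band.

Presence calls are therefore invariant to global intensity scaling of a
lane — only area ratios matter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, minimum_filter1d

__all__ = [
    "LadderCalibration",
    "LaneTrace",
    "BandWindow",
    "BandCall",
    "MarkerCallSet",
    "PRESENCE_THRESHOLD",
    "integrate_bands",
    "call_marker_set",
]

#: relative-area cutoff of the background rule: signals < 1 % of the
#: dominant band are background; exactly 1 % is a band.
PRESENCE_THRESHOLD = 0.01

MISSING = "missing"


@dataclass(frozen=True)
class LadderCalibration:
    """Molecular-weight ladder: lane positions with known band weights.

    Migration distance is close to linear in log10(MW) on SDS-PAGE, so
    position → MW conversion interpolates log10(MW) against position.
    Positions must be strictly increasing and weights strictly decreasing
    (heavier proteins migrate less).
    """

    positions: tuple[float, ...]
    mw_kda: tuple[float, ...]

    def __init__(self, points: Iterable[tuple[float, float]]):
        pts = sorted((float(p), float(m)) for p, m in points)
        if len(pts) < 2:
            raise ValueError("ladder needs at least 2 calibration points")
        pos = tuple(p for p, _ in pts)
        mws = tuple(m for _, m in pts)
        if any(m <= 0 for m in mws):
            raise ValueError("ladder molecular weights must be positive")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("ladder positions must be strictly increasing")
        if any(b >= a for a, b in zip(mws, mws[1:])):
            raise ValueError("ladder weights must strictly decrease with position")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "mw_kda", mws)

    @property
    def span(self) -> tuple[float, float]:
        return self.positions[0], self.positions[-1]

    def position_to_mw(self, position: float) -> float:
        """Molecular weight (kDa) at a lane position.

        Outside the ladder span the edge slope is extended linearly in
        log-space and a ``RuntimeWarning`` is emitted — such values are
        extrapolations, not calibrated weights.
        """
        pos = np.asarray(self.positions)
        logmw = np.log10(self.mw_kda)
        if position < pos[0] or position > pos[-1]:
            warnings.warn(
                f"position {position} outside ladder span {self.span}; "
                "extrapolating",
                RuntimeWarning,
                stacklevel=2,
            )
            if position < pos[0]:
                slope = (logmw[1] - logmw[0]) / (pos[1] - pos[0])
                return float(10 ** (logmw[0] + slope * (position - pos[0])))
            slope = (logmw[-1] - logmw[-2]) / (pos[-1] - pos[-2])
            return float(10 ** (logmw[-1] + slope * (position - pos[-1])))
        return float(10 ** np.interp(position, pos, logmw))

    def mw_to_position(self, mw: float) -> float:
        """Inverse of :meth:`position_to_mw` (within the ladder span)."""
        if mw <= 0:
            raise ValueError("molecular weight must be positive")
        # log10(MW) decreases with position; interp needs increasing x
        logmw = np.log10(self.mw_kda)[::-1]
        pos = np.asarray(self.positions)[::-1]
        lo, hi = self.mw_kda[-1], self.mw_kda[0]
        if not (lo <= mw <= hi):
            warnings.warn(
                f"{mw} kDa outside ladder range [{lo}, {hi}]; extrapolating",
                RuntimeWarning,
                stacklevel=2,
            )
            slope = (pos[1] - pos[0]) / (logmw[1] - logmw[0]) if mw < lo else (
                (pos[-1] - pos[-2]) / (logmw[-1] - logmw[-2])
            )
            anchor = (pos[0], logmw[0]) if mw < lo else (pos[-1], logmw[-1])
            return float(anchor[0] + slope * (math.log10(mw) - anchor[1]))
        return float(np.interp(math.log10(mw), logmw, pos))

    def covers_mw(self, mw_lo: float, mw_hi: float) -> bool:
        return self.mw_kda[-1] <= mw_lo and mw_hi <= self.mw_kda[0]


@dataclass(frozen=True)
class LaneTrace:
    """1-D densitometric profile of one lane: sampling positions, tonal
    intensities, and (for blots) the lane's ladder calibration."""

    positions: np.ndarray
    intensities: np.ndarray
    ladder: LadderCalibration | None = None
    label: str = ""

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.shape != inten.shape:
            raise ValueError("positions and intensities must be equal-length 1-D arrays")
        if pos.size < 2 or np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(inten < 0) or not np.all(np.isfinite(inten)):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @classmethod
    def from_csv(cls, path, ladder: LadderCalibration | None = None) -> "LaneTrace":
        df = pd.read_csv(path)
        return cls(df["position"].to_numpy(), df["intensity"].to_numpy(),
                   ladder=ladder, label=str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame({"position": self.positions, "intensity": self.intensities}
                     ).to_csv(path, index=False)


@dataclass(frozen=True)
class BandWindow:
    """Expected location of one band, in kDa (blots) or directly in lane
    position units (zymograms, where no ladder applies)."""

    name: str
    mw_lo: float | None = None
    mw_hi: float | None = None
    pos_lo: float | None = None
    pos_hi: float | None = None

    def __post_init__(self):
        if self.mw_lo is not None or self.mw_hi is not None:
            if self.mw_lo is None or self.mw_hi is None or not (
                0 < self.mw_lo < self.mw_hi
            ):
                raise ValueError(f"window {self.name}: need 0 < mw_lo < mw_hi")
        elif self.pos_lo is None or self.pos_hi is None or not (
            self.pos_lo < self.pos_hi
        ):
            raise ValueError(f"window {self.name}: need pos_lo < pos_hi or mw bounds")

    @property
    def is_mw(self) -> bool:
        return self.mw_lo is not None

    def resolve(self, ladder: LadderCalibration | None) -> tuple[float, float] | None:
        """Position bounds in the lane, or None when uncallable (mw window
        without ladder coverage)."""
        if not self.is_mw:
            return (self.pos_lo, self.pos_hi)
        if ladder is None or not ladder.covers_mw(self.mw_lo, self.mw_hi):
            return None
        # heavier end migrates less: mw_hi maps to the smaller position
        lo = ladder.mw_to_position(self.mw_hi)
        hi = ladder.mw_to_position(self.mw_lo)
        return (min(lo, hi), max(lo, hi))


@dataclass(frozen=True)
class BandCall:
    """One band's integrated evidence and binary presence decision."""

    name: str
    area: float
    relative_area: float
    present: bool
    status: str = "ok"  # ok | uncallable


@dataclass
class MarkerCallSet:
    """Binary presence of every degradation product for one case.

    ``presence`` maps product name to 1, 0, or ``"missing"`` (assay trace
    absent or window uncallable).  Native-band calls are retained in
    ``native_qc`` as quality control; they carry no PMI information
    themselves but a lane without its native band is suspect.
    """

    presence: dict[str, int | str]
    native_qc: dict[str, BandCall] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def vector(self, order: Sequence[str]) -> list[int | str]:
        return [self.presence.get(name, MISSING) for name in order]

    def to_dict(self) -> dict:
        return {
            "presence": dict(self.presence),
            "native_qc": {
                k: {"area": v.area, "relative_area": v.relative_area,
                    "present": bool(v.present), "status": v.status}
                for k, v in self.native_qc.items()
            },
            "warnings": list(self.warnings),
        }


def _baseline(intensities: np.ndarray, size: int, smooth: float) -> np.ndarray:
    """Rolling-minimum baseline of a lightly smoothed copy of the trace.

    Smoothing before the minimum filter keeps additive noise from biasing
    the minimum downward; the baseline is subtracted from the *raw* trace so
    band areas are not blurred.
    """
    smoothed = gaussian_filter1d(intensities, smooth) if smooth > 0 else intensities
    return minimum_filter1d(smoothed, size=max(int(size), 1), mode="nearest")


def integrate_bands(
    trace: LaneTrace,
    windows: Sequence[BandWindow],
    threshold: float = PRESENCE_THRESHOLD,
    baseline_factor: float = 3.0,
    smooth_sigma_units: float = 0.5,
) -> list[BandCall]:
    """Baseline-corrected band areas and presence calls for one lane.

    The baseline is a rolling minimum whose window is ``baseline_factor``
    times the widest band window.  ``relative_area`` is each band's area
    divided by the largest area among the lane's windows (the dominant
    band); ``present`` applies the >= ``threshold`` rule to that ratio.
    Windows that cannot be placed on the lane come back with status
    ``"uncallable"``.
    """
    if not windows:
        raise ValueError("need at least one band window")
    spacing = float(np.median(np.diff(trace.positions)))
    resolved: dict[str, tuple[float, float] | None] = {
        w.name: w.resolve(trace.ladder) for w in windows
    }
    widths = [hi - lo for b in resolved.values() if b is not None for lo, hi in [b]]
    widest = max(widths) if widths else 1.0
    base = _baseline(
        trace.intensities,
        size=int(round(baseline_factor * widest / spacing)),
        smooth=smooth_sigma_units / spacing,
    )
    resid = np.clip(trace.intensities - base, 0.0, None)

    areas: dict[str, float] = {}
    for w in windows:
        bounds = resolved[w.name]
        if bounds is None:
            continue
        lo, hi = bounds
        mask = (trace.positions >= lo) & (trace.positions <= hi)
        if mask.sum() < 2:
            areas[w.name] = 0.0
        else:
            areas[w.name] = float(
                np.trapezoid(resid[mask], trace.positions[mask])
            )
    dominant = max(areas.values(), default=0.0)

    calls = []
    for w in windows:
        if resolved[w.name] is None:
            calls.append(BandCall(w.name, math.nan, math.nan, False, "uncallable"))
            continue
        area = areas[w.name]
        rel = area / dominant if dominant > 0 else 0.0
        calls.append(BandCall(w.name, area, rel, bool(rel >= threshold - 1e-12)))
    return calls


def call_marker_set(traces: Mapping[str, LaneTrace], panel) -> MarkerCallSet:
    """Assemble one case's binary marker vector from its per-assay lanes.

    ``panel`` is a :class:`pmidelim.panel.Panel`.  Each assay's lane is
    integrated independently (the dominant-band denominator is per lane).
    Products of a missing assay are marked ``"missing"``.  Violations of the
    panel's nesting rules (a later degradation product called present while
    an earlier one is absent) are recorded as warnings, never errors: they
    flag either a calling problem or an unusual sample.
    """
    calls = MarkerCallSet(presence={})
    for assay in panel.assays:
        product_names = [p.name for p in assay.products]
        trace = traces.get(assay.name)
        if trace is None:
            for p in assay.products:
                if p.role == "dp":
                    calls.presence[p.name] = MISSING
            calls.warnings.append(f"assay '{assay.name}': no trace supplied")
            continue
        band_calls = integrate_bands(trace, [p.window for p in assay.products])
        by_name = {c.name: c for c in band_calls}
        for p in assay.products:
            call = by_name[p.window.name]
            if p.role == "native":
                calls.native_qc[p.name] = call
                if call.status == "ok" and not call.present:
                    calls.warnings.append(
                        f"assay '{assay.name}': native band '{p.name}' not detected"
                    )
            else:
                if call.status != "ok":
                    calls.presence[p.name] = MISSING
                else:
                    calls.presence[p.name] = int(call.present)
    for chain in getattr(panel, "nesting", ()):
        for earlier, later in zip(chain, chain[1:]):
            if (
                calls.presence.get(later) == 1
                and calls.presence.get(earlier) == 0
            ):
                calls.warnings.append(
                    f"nesting violation: '{later}' present without '{earlier}'"
                )
    return calls
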