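"""Window planning and reconstruction of stitched SIM² mobilograms.

A SIM² acquisition records a narrow 1/K0 window at maximum TIMS resolution.
To cover a wide mobility range without giving up resolving power, several
adjacent windows with a fixed overlap are acquired back-to-back ("SIM²
stitching") and the segments are merged into one wide mobilogram.

Two merge strategies are supported, mirroring the two ways segmented
acquisitions are processed in practice: ``per_segment`` assigns every 1/K0
point to exactly one source segment (no double counting — the artifact-free
route), while ``combined`` merges overlap regions under an explicit rule
(``sum`` reproduces the intensity doubling seen when a whole acquisition is
processed at once).  Processing the whole acquisition also shows spurious
"edge effect" signals at the interior window boundaries; an optional mask
zeroes a band around each boundary.

Window boundaries are computed on a 1e-6 V·s·cm⁻² integer lattice so that
boundary equality tests are exact in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConsistencyError, DomainError, PlanningError

__all__ = [
    "Window",
    "StitchPlan",
    "Segment",
    "Mobilogram",
    "plan_windows",
    "interior_boundaries",
    "extract_xim",
    "stitch",
]

MICRO = 1_000_000  # lattice resolution: 1e-6 V·s·cm⁻²
_EPS = 1e-9


def _to_micro(x: float) -> int:
    return int(round(x * MICRO))


@dataclass(frozen=True)
class Window:
    """One SIM² acquisition range on the 1/K0 axis (V·s·cm⁻²)."""

    start_inv_k0: float
    end_inv_k0: float

    def __post_init__(self):
        if not self.start_inv_k0 < self.end_inv_k0:
            raise DomainError(
                f"window start {self.start_inv_k0} must precede end {self.end_inv_k0}")

    @property
    def width(self) -> float:
        return self.end_inv_k0 - self.start_inv_k0

    def contains(self, x, eps: float = _EPS):
        x = np.asarray(x, dtype=float)
        return (x >= self.start_inv_k0 - eps) & (x <= self.end_inv_k0 + eps)


@dataclass(frozen=True)
class StitchPlan:
    """Ordered overlapping windows covering a wide 1/K0 range."""

    windows: tuple[Window, ...]
    width: float
    overlap: float

    def __post_init__(self):
        if not self.windows:
            raise PlanningError("a plan needs at least one window")
        starts = [w.start_inv_k0 for w in self.windows]
        if sorted(starts) != starts:
            raise PlanningError("plan windows must be sorted by start")
        for w in self.windows:
            if abs(w.width - self.width) > 1e-12:
                raise PlanningError(f"window {w} deviates from plan width {self.width}")
        for prev, nxt in zip(self.windows, self.windows[1:]):
            if abs((prev.end_inv_k0 - nxt.start_inv_k0) - self.overlap) > 1e-9:
                raise PlanningError(
                    f"windows {prev} and {nxt} do not overlap by {self.overlap}")

    @property
    def range_start(self) -> float:
        return self.windows[0].start_inv_k0

    @property
    def range_end(self) -> float:
        return self.windows[-1].end_inv_k0


def plan_windows(range_start: float, range_end: float,
                 width: float, overlap: float) -> StitchPlan:
    """Plan overlapping SIM² windows over [range_start, range_end].

    Window starts step by ``width − overlap`` from ``range_start``; the plan
    ends with the first window whose end reaches ``range_end`` (it may extend
    past it, preserving the constant width).  All boundary arithmetic is done
    in scaled integers so equal boundaries compare exactly.
    """
    if range_end <= range_start:
        raise PlanningError("range_end must exceed range_start")
    if width <= 0:
        raise PlanningError("width must be positive")
    if overlap < 0 or overlap >= width:
        raise PlanningError("require 0 <= overlap < width")
    start_i, end_i = _to_micro(range_start), _to_micro(range_end)
    width_i, overlap_i = _to_micro(width), _to_micro(overlap)
    step_i = width_i - overlap_i
    windows = []
    s = start_i
    while True:
        e = s + width_i
        windows.append(Window(s / MICRO, e / MICRO))
        if e >= end_i:
            break
        s += step_i
    return StitchPlan(windows=tuple(windows), width=width_i / MICRO,
                      overlap=overlap_i / MICRO)


def interior_boundaries(plan: StitchPlan) -> list[float]:
    """1/K0 positions of interior segment ends — where edge artifacts appear.

    Whole-acquisition processing shows spurious baseline rises at the end of
    every segment except the last; for the reference 4-window plan these sit
    at 0.85, 0.95 and 1.05 V·s·cm⁻².
    """
    return [w.end_inv_k0 for w in plan.windows[:-1]]


@dataclass
class Segment:
    """Raw records of one SIM² window: parallel (1/K0, m/z, intensity) arrays."""

    window: Window
    inv_k0: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    segment_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inv_k0 = np.asarray(self.inv_k0, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = len(self.inv_k0)
        if len(self.mz) != n or len(self.intensity) != n:
            raise ConsistencyError(
                f"segment {self.segment_id!r}: record arrays have unequal lengths")

    def validate(self):
        """Check that every record sits inside the window and is non-negative."""
        if len(self.inv_k0) and not np.all(self.window.contains(self.inv_k0)):
            bad = self.inv_k0[~self.window.contains(self.inv_k0)][0]
            raise ConsistencyError(
                f"segment {self.segment_id!r}: record at 1/K0={bad:g} outside "
                f"window [{self.window.start_inv_k0}, {self.window.end_inv_k0}]")
        if np.any(self.intensity < 0):
            raise ConsistencyError(
                f"segment {self.segment_id!r}: negative intensity record")
        return self

    @property
    def total_intensity(self) -> float:
        return float(np.sum(self.intensity))


@dataclass
class Mobilogram:
    """A 1/K0-vs-intensity trace with per-point provenance.

    ``provenance[i]`` is the tuple of segment ids that contributed to point i;
    ``masked[i]`` marks points zeroed by the edge-artifact mask.
    """

    axis: np.ndarray
    intensity: np.ndarray
    provenance: list[tuple[str, ...]] = field(default_factory=list)
    masked: np.ndarray | None = None

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.axis) != len(self.intensity):
            raise ConsistencyError("mobilogram axis and intensity lengths differ")
        if len(self.axis) > 1 and not np.all(np.diff(self.axis) > 0):
            raise ConsistencyError("mobilogram axis must be strictly increasing")
        if not self.provenance:
            self.provenance = [()] * len(self.axis)
        if self.masked is None:
            self.masked = np.zeros(len(self.axis), dtype=bool)

    def __len__(self):
        return len(self.axis)

    @property
    def total_intensity(self) -> float:
        return float(np.sum(self.intensity))

    def to_segment(self, window: Window | None = None,
                   mz: float = 0.0, segment_id: str = "stitched") -> Segment:
        """Repackage the trace as a single Segment (e.g. for re-stitching)."""
        if window is None:
            window = Window(float(self.axis[0]) - _EPS, float(self.axis[-1]) + _EPS) \
                if len(self.axis) else Window(0.0, 1.0)
        return Segment(window, self.axis.copy(), np.full(len(self.axis), mz),
                       self.intensity.copy(), segment_id=segment_id)


def extract_xim(segments: Sequence[Segment], target_mz: float,
                tol: float = 0.01) -> list[Segment]:
    """Extract the ion mobilogram records at one m/z channel (±tol Da).

    Keeps records with ``|mz − target_mz| ≤ tol``; intensities of co-located
    records (same segment, same 1/K0) are summed.  Window and metadata are
    preserved; the m/z column of the output carries the target value.
    """
    if tol <= 0:
        raise DomainError("extraction tolerance must be positive")
    out = []
    for seg in segments:
        keep = np.abs(seg.mz - target_mz) <= tol
        x = np.round(seg.inv_k0[keep], 9)
        y = seg.intensity[keep]
        ux, inverse = np.unique(x, return_inverse=True)
        summed = np.zeros(len(ux))
        np.add.at(summed, inverse, y)
        meta = dict(seg.metadata)
        meta.update(extracted_mz=target_mz, extraction_tol=tol)
        out.append(Segment(seg.window, ux, np.full(len(ux), float(target_mz)),
                           summed, segment_id=seg.segment_id, metadata=meta))
    return out


def _collapse(seg: Segment) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique 1/K0 axis with intensities summed across m/z records."""
    x = np.round(seg.inv_k0, 9)
    ux, inverse = np.unique(x, return_inverse=True)
    y = np.zeros(len(ux))
    np.add.at(y, inverse, seg.intensity)
    return ux, y


def _series_on(ux: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Values of a sampled series on grid ``ux``; zero outside the sampled span."""
    if len(x) == 0:
        return np.zeros(len(ux))
    if len(x) == 1:
        out = np.zeros(len(ux))
        out[np.abs(ux - x[0]) <= _EPS] = y[0]
        return out
    out = np.interp(ux, x, y)
    out[(ux < x[0] - _EPS) | (ux > x[-1] + _EPS)] = 0.0
    return out


def stitch(segments: Sequence[Segment], plan: StitchPlan,
           mode: str = "per_segment", overlap_rule: str = "first",
           artifact_mask: float = 0.0) -> Mobilogram:
    """Reconstruct one wide-range mobilogram from segmented acquisitions.

    mode ``per_segment``: every output point takes its intensity from exactly
    one segment; in overlap regions the earlier (lower-start) window wins
    under ``overlap_rule='first'`` (``'last'`` selects the later one).  Total
    intensity is conserved — no record is counted twice.

    mode ``combined``: overlap regions combine all covering segments under
    ``overlap_rule`` ∈ {sum, mean, max, first}; with ``sum`` a point covered
    by two windows carries the summed (doubled, for equal signals) intensity.

    ``artifact_mask`` > 0 zeroes intensities within that distance of every
    interior window boundary and flags them in ``masked`` — an optional
    suppression of the edge artifacts seen in whole-acquisition processing.

    Segments whose window is not part of the plan raise a consistency error.
    Segments sampled on different grids are merged onto the union grid by
    linear interpolation.
    """
    if mode not in ("per_segment", "combined"):
        raise DomainError(f"unknown stitch mode {mode!r}")
    if mode == "per_segment" and overlap_rule not in ("first", "last"):
        raise DomainError("per_segment mode supports overlap_rule 'first' or 'last'")
    if mode == "combined" and overlap_rule not in ("sum", "mean", "max", "first"):
        raise DomainError(f"unknown overlap rule {overlap_rule!r}")
    if artifact_mask < 0:
        raise DomainError("artifact_mask must be >= 0")

    # group segments by their plan window
    groups: dict[int, list[Segment]] = {}
    for seg in segments:
        idx = None
        for i, w in enumerate(plan.windows):
            if (abs(seg.window.start_inv_k0 - w.start_inv_k0) <= _EPS
                    and abs(seg.window.end_inv_k0 - w.end_inv_k0) <= _EPS):
                idx = i
                break
        if idx is None:
            raise ConsistencyError(
                f"segment {seg.segment_id!r} window "
                f"[{seg.window.start_inv_k0}, {seg.window.end_inv_k0}] not in plan")
        groups.setdefault(idx, []).append(seg)

    # per-window series on each window's own union grid
    window_series: dict[int, tuple[np.ndarray, np.ndarray, str]] = {}
    for idx, segs in groups.items():
        parts = [_collapse(s) for s in segs]
        ux = np.unique(np.concatenate([p[0] for p in parts])) if parts else np.array([])
        y = np.zeros(len(ux))
        for px, py in parts:
            y += _series_on(ux, px, py)
        ids = ",".join(sorted({s.segment_id for s in segs if s.segment_id})) or f"window{idx}"
        window_series[idx] = (ux, y, ids)

    if not window_series or all(len(v[0]) == 0 for v in window_series.values()):
        return Mobilogram(np.array([]), np.array([]))

    axis = np.unique(np.concatenate([v[0] for v in window_series.values()
                                     if len(v[0])]))
    order = sorted(window_series)  # plan order = ascending window start
    covers = []
    values = []
    for idx in order:
        ux, y, ids = window_series[idx]
        w = plan.windows[idx]
        in_window = w.contains(axis)
        if len(ux):
            # a window only covers where it actually sampled
            in_span = (axis >= ux[0] - _EPS) & (axis <= ux[-1] + _EPS)
        else:
            in_span = np.zeros(len(axis), dtype=bool)
        covers.append(in_window & in_span)
        values.append(np.where(in_window, _series_on(axis, ux, y), 0.0))

    intensity = np.zeros(len(axis))
    provenance: list[tuple[str, ...]] = [()] * len(axis)
    for i in range(len(axis)):
        hit = [j for j, cov in enumerate(covers) if cov[i]]
        if not hit:
            continue
        if mode == "per_segment":
            j = hit[0] if overlap_rule == "first" else hit[-1]
            intensity[i] = values[j][i]
            provenance[i] = (window_series[order[j]][2],)
        else:
            vals = [values[j][i] for j in hit]
            if overlap_rule == "sum":
                intensity[i] = sum(vals)
            elif overlap_rule == "mean":
                intensity[i] = sum(vals) / len(vals)
            elif overlap_rule == "max":
                intensity[i] = max(vals)
            else:  # first
                intensity[i] = vals[0]
            provenance[i] = tuple(window_series[order[j]][2] for j in hit)

    masked = np.zeros(len(axis), dtype=bool)
    if artifact_mask > 0:
        for b in interior_boundaries(plan):
            band = np.abs(axis - b) <= artifact_mask + _EPS
            masked |= band
        intensity[masked] = 0.0

    return Mobilogram(axis, intensity, provenance, masked)
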