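"""Canonical interchange formats: segment TSV, plan JSON, calibration CSV.

The toolkit's on-disk format is deliberately plain text:

* segments — TSV with header columns ``segment_id, window_start,
  window_end, inv_k0, mz, intensity``;
* stitch plan and simulation metadata — a JSON sidecar;
* mobility calibration — two-column CSV ``measured_coordinate,
  reference_inv_k0`` (header required);
* mobilograms and peak lists — CSV.

Readers validate aggressively and report offending line numbers; a converter
hook (:func:`records_to_segments`) turns externally exported peak lists into
the canonical structures.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError
from .stitching import Mobilogram, Segment, StitchPlan, Window, plan_windows

__all__ = [
    "SEGMENT_COLUMNS",
    "write_segments",
    "read_segments",
    "records_to_segments",
    "write_plan",
    "read_plan",
    "read_calibration_table",
    "write_mobilogram",
    "read_mobilogram",
    "write_peaks",
]

SEGMENT_COLUMNS = ("segment_id", "window_start", "window_end",
                   "inv_k0", "mz", "intensity")
PEAK_COLUMNS = ("complex_label", "run", "apex_inv_k0", "fwhm_inv_k0",
                "height", "area", "ccs", "resolution", "annotation")


def write_segments(segments: Sequence[Segment], path: str | Path) -> None:
    """Write segments to the canonical TSV (lossless to float repr)."""
    frames = []
    for seg in segments:
        frames.append(pd.DataFrame({
            "segment_id": seg.segment_id or "seg",
            "window_start": seg.window.start_inv_k0,
            "window_end": seg.window.end_inv_k0,
            "inv_k0": seg.inv_k0,
            "mz": seg.mz,
            "intensity": seg.intensity,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=list(SEGMENT_COLUMNS)))
    df.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[Segment]:
    """Read canonical segment TSV; malformed rows are rejected with line numbers."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse segment TSV ({exc})") from exc
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing header column(s) {sorted(missing)}")
    for col in ("window_start", "window_end", "inv_k0", "mz", "intensity"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise FormatError(f"{path}: line {bad[0] + 2}: non-numeric {col}")
    neg = df.index[df["intensity"] < 0]
    if len(neg):
        raise FormatError(f"{path}: line {neg[0] + 2}: negative intensity")
    segments = []
    for seg_id, group in df.groupby("segment_id", sort=True):
        ws = group["window_start"].to_numpy(dtype=float)
        we = group["window_end"].to_numpy(dtype=float)
        if np.ptp(ws) > 1e-9 or np.ptp(we) > 1e-9:
            raise FormatError(
                f"{path}: segment {seg_id!r} rows disagree on window bounds")
        group = group.sort_values("inv_k0")
        seg = Segment(Window(float(ws[0]), float(we[0])),
                      group["inv_k0"].to_numpy(dtype=float),
                      group["mz"].to_numpy(dtype=float),
                      group["intensity"].to_numpy(dtype=float),
                      segment_id=str(seg_id))
        seg.validate()
        segments.append(seg)
    segments.sort(key=lambda s: s.window.start_inv_k0)
    return segments


def records_to_segments(records: Iterable[Mapping], window_by_id: Mapping[str, Window]
                        ) -> list[Segment]:
    """Convert externally exported records into canonical segments.

    ``records`` iterates mappings with keys ``segment_id, inv_k0, mz,
    intensity``; windows are supplied per segment id.  This is the hook for
    adapting vendor peak-list exports.
    """
    buckets: dict[str, list[tuple[float, float, float]]] = {}
    for i, rec in enumerate(records):
        try:
            buckets.setdefault(str(rec["segment_id"]), []).append(
                (float(rec["inv_k0"]), float(rec["mz"]), float(rec["intensity"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"record {i}: {exc}") from exc
    segments = []
    for seg_id, rows in buckets.items():
        if seg_id not in window_by_id:
            raise ConsistencyError(f"no window supplied for segment {seg_id!r}")
        rows.sort()
        arr = np.asarray(rows, dtype=float)
        seg = Segment(window_by_id[seg_id], arr[:, 0], arr[:, 1], arr[:, 2],
                      segment_id=seg_id)
        seg.validate()
        segments.append(seg)
    segments.sort(key=lambda s: s.window.start_inv_k0)
    return segments


def write_plan(plan: StitchPlan, path: str | Path,
               metadata: Mapping | None = None) -> None:
    doc = {
        "width": plan.width,
        "overlap": plan.overlap,
        "windows": [[w.start_inv_k0, w.end_inv_k0] for w in plan.windows],
        "metadata": dict(metadata or {}),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_plan(path: str | Path) -> StitchPlan:
    """Read a plan JSON: explicit windows, or range/width/overlap to re-plan."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if "windows" in doc:
        windows = tuple(Window(float(s), float(e)) for s, e in doc["windows"])
        return StitchPlan(windows=windows, width=float(doc["width"]),
                          overlap=float(doc["overlap"]))
    try:
        return plan_windows(float(doc["range_start"]), float(doc["range_end"]),
                            float(doc["width"]), float(doc["overlap"]))
    except KeyError as exc:
        raise FormatError(f"{path}: plan JSON missing key {exc.args[0]!r}") from exc


def read_calibration_table(path: str | Path) -> list[tuple[float, float]]:
    """Read the two-column calibration CSV (header required)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse calibration CSV ({exc})") from exc
    required = {"measured_coordinate", "reference_inv_k0"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: calibration CSV needs columns {sorted(required)}")
    return list(zip(df["measured_coordinate"].astype(float),
                    df["reference_inv_k0"].astype(float)))


def write_mobilogram(mob: Mobilogram, path: str | Path) -> None:
    pd.DataFrame({
        "inv_k0": mob.axis,
        "intensity": mob.intensity,
        "masked": mob.masked.astype(int),
        "provenance": [";".join(p) for p in mob.provenance],
    }).to_csv(path, index=False)


def read_mobilogram(path: str | Path) -> Mobilogram:
    df = pd.read_csv(path)
    if not {"inv_k0", "intensity"} <= set(df.columns):
        raise FormatError(f"{path}: mobilogram CSV needs inv_k0 and intensity")
    prov = [tuple(str(p).split(";")) if isinstance(p, str) and p else ()
            for p in df.get("provenance", [""] * len(df))]
    masked = df.get("masked")
    return Mobilogram(df["inv_k0"].to_numpy(dtype=float),
                      df["intensity"].to_numpy(dtype=float),
                      provenance=prov,
                      masked=None if masked is None
                      else masked.to_numpy(dtype=bool))


def write_peaks(rows: Sequence[Mapping], path: str | Path) -> None:
    """Write a peak-list CSV with the documented fixed column order."""
    df = pd.DataFrame(list(rows), columns=list(PEAK_COLUMNS))
    df.to_csv(path, index=False)
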