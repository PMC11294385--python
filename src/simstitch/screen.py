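"""End-to-end chiral screening: enumerate → extract → stitch → pair → report.

For every enumerated copper-complex channel the pipeline extracts the ion
mobilogram at the complex's exact m/z (±0.01 Da by default) from each run
(L-only, D-only, equimolar mix), stitches the segments, detects peaks,
optionally refines partially resolved mix doublets with a two-Gaussian fit,
pairs the enantiomer signals, and classifies the separation.  The result is
a screening table — one row per analyte, one column per cluster
stoichiometry — together with the detection accounting (complexes possible,
detected, separated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .chem import ComplexSpec, PanelConfig, enumerate_complexes
from .metrics import CalibrationModel, SeparationResult
from .peaks import Peak, detect_peaks, fit_gaussians, pair_enantiomers
from .stitching import Mobilogram, StitchPlan, Segment, extract_xim, stitch

__all__ = [
    "ChannelOutcome",
    "ScreenReport",
    "evaluate_channel",
    "run_screen",
    "percent_detected",
    "stoichiometry_pattern",
]

logger = logging.getLogger("simstitch")

RUN_ORDER = ("L", "D", "mix")
_FOOTNOTES = {"additional peaks": "a", "multiple signals": "b"}


def stoichiometry_pattern(spec: ComplexSpec, analyte_name: str) -> str:
    """Generic column label of a complex: its analyte written as ``AA``."""
    return "+".join("AA" if n == analyte_name else n for n in spec.component_names)


def percent_detected(detected: int, possible: int) -> int:
    """Detection percentage rounded to the nearest integer (91/153 → 59)."""
    if possible <= 0:
        return 0
    return int(round(100.0 * detected / possible))


def evaluate_channel(mobs: Mapping[str, Mobilogram], model: CalibrationModel,
                     spec: ComplexSpec, *, min_height_rel: float = 0.05,
                     min_prominence_rel: float = 0.02, refine: bool = True,
                     match_tol_fwhm: float = 1.0
                     ) -> tuple[SeparationResult, dict[str, list[Peak]]]:
    """Detect, refine and pair the peaks of one complex channel.

    ``mobs`` maps run labels (subset of L/D/mix) to stitched mobilograms.
    When the two most intense mix-run peaks lie closer than twice their mean
    FWHM, their apexes are refined by a two-Gaussian fit on a local window
    around the doublet — raw local maxima of partially resolved doublets are
    biased toward each other, which would understate ΔCCS%.
    """
    peaks: dict[str, list[Peak]] = {}
    for run, mob in mobs.items():
        peaks[run] = detect_peaks(mob, min_height_rel=min_height_rel,
                                  min_prominence_rel=min_prominence_rel)
    mix = peaks.get("mix", [])
    if refine and len(mix) >= 2 and "mix" in mobs:
        a, b = sorted(sorted(mix, key=lambda p: p.height)[-2:],
                      key=lambda p: p.apex_inv_k0)
        sep = b.apex_inv_k0 - a.apex_inv_k0
        mean_fwhm = 0.5 * (a.fwhm_inv_k0 + b.fwhm_inv_k0)
        if sep < 2.0 * mean_fwhm:
            mob = mobs["mix"]
            keep = ((mob.axis >= a.apex_inv_k0 - 3 * mean_fwhm)
                    & (mob.axis <= b.apex_inv_k0 + 3 * mean_fwhm))
            local = Mobilogram(mob.axis[keep], mob.intensity[keep])
            try:
                refined = fit_gaussians(local, 2, initial=[a, b])
                peaks["mix"] = sorted(
                    [p for p in mix if p is not a and p is not b] + refined,
                    key=lambda p: p.apex_inv_k0)
            except Exception as exc:  # keep the detected peaks on fit failure
                logger.warning("%s: Gaussian refinement failed (%s)", spec.label, exc)
    result = pair_enantiomers(peaks.get("L", []), peaks.get("D", []),
                              peaks.get("mix", []), model, spec,
                              match_tol_fwhm=match_tol_fwhm)
    return result, peaks


@dataclass
class ChannelOutcome:
    """Per-complex outcome: the separation verdict plus peak counts per run."""

    spec: ComplexSpec
    analyte: str
    result: SeparationResult
    n_peaks: dict[str, int] = field(default_factory=dict)

    @property
    def detected(self) -> bool:
        return self.result.classification != "not_detected"


@dataclass
class ScreenReport:
    """Screening table plus detection accounting.

    ``possible = 9 × n_analytes`` in the two-selector mode; ``detected`` and
    the separation counts never exceed it.  Cells render ΔCCS% to one
    decimal, ``nd`` for undetected channels, ``-`` for detected-but-
    unseparated ones, with footnote markers ``a`` (additional peaks in the
    mix) and ``b`` (multiple signals in a single-enantiomer run).
    """

    analytes: list[str]
    columns: list[str]
    outcomes: list[ChannelOutcome]

    def __post_init__(self):
        self._cells: dict[tuple[str, str], ChannelOutcome] = {}
        for oc in self.outcomes:
            pattern = stoichiometry_pattern(oc.spec, oc.analyte)
            self._cells[(oc.analyte, pattern)] = oc

    @property
    def possible(self) -> int:
        return len(self.outcomes)

    @property
    def detected(self) -> int:
        return sum(oc.detected for oc in self.outcomes)

    @property
    def separated_baseline(self) -> int:
        return sum(oc.result.classification == "baseline" for oc in self.outcomes)

    @property
    def separated_partial(self) -> int:
        return sum(oc.result.classification == "partial" for oc in self.outcomes)

    @property
    def percent_detected(self) -> int:
        return percent_detected(self.detected, self.possible)

    @staticmethod
    def render_cell(result: SeparationResult) -> str:
        marks = "".join(sorted(_FOOTNOTES[a] for a in result.annotations
                               if a in _FOOTNOTES))
        suffix = f" ({marks})" if marks else ""
        cls = result.classification
        if cls == "not_detected":
            return "nd"
        if cls in ("none", "single_signal"):
            return "-" + suffix
        return f"{abs(result.delta_ccs_pct):.1f}{suffix}"

    def to_dataframe(self) -> pd.DataFrame:
        data = {}
        for col in self.columns:
            data[col] = [self.render_cell(self._cells[(a, col)].result)
                         if (a, col) in self._cells else ""
                         for a in self.analytes]
        return pd.DataFrame(data, index=pd.Index(self.analytes, name="analyte"))

    def summary(self) -> dict:
        return {
            "possible": self.possible,
            "detected": self.detected,
            "percent_detected": self.percent_detected,
            "separated_baseline": self.separated_baseline,
            "separated_partial": self.separated_partial,
            "separated_total": self.separated_baseline + self.separated_partial,
        }

    def to_text(self) -> str:
        s = self.summary()
        lines = [self.to_dataframe().to_string(), "",
                 f"complexes possible: {s['possible']}",
                 f"complexes detected: {s['detected']} ({s['percent_detected']}%)",
                 (f"separated: {s['separated_total']} "
                  f"(baseline {s['separated_baseline']}, "
                  f"partial {s['separated_partial']})")]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def run_screen(panel: PanelConfig, runs: Mapping[str, Sequence[Segment]],
               plan: StitchPlan, model: CalibrationModel, *,
               mz_tol: float = 0.01, mode: str = "per_segment",
               overlap_rule: str = "first", artifact_mask: float = 0.0,
               min_height_rel: float = 0.05, min_prominence_rel: float = 0.02,
               refine: bool = True, match_tol_fwhm: float = 1.0) -> ScreenReport:
    """Screen every enumerated complex channel of a panel.

    ``runs`` maps run labels (any subset of ``{"L", "D", "mix"}``) to segment
    lists; missing runs degrade gracefully (mix-only classification, or
    ``not_detected`` when the mix run itself is absent or empty).
    """
    specs = enumerate_complexes(panel.analytes, panel.selectors, panel.metal)
    analyte_names = [m.name for m in panel.analytes]
    columns: list[str] = []
    outcomes: list[ChannelOutcome] = []
    for spec in specs:
        analyte = next(n for n in spec.component_names if n in analyte_names)
        pattern = stoichiometry_pattern(spec, analyte)
        if pattern not in columns:
            columns.append(pattern)
        mobs = {}
        for run in RUN_ORDER:
            if run not in runs:
                continue
            channel = extract_xim(runs[run], spec.mz, tol=mz_tol)
            mobs[run] = stitch(channel, plan, mode=mode,
                               overlap_rule=overlap_rule,
                               artifact_mask=artifact_mask)
        result, peaks = evaluate_channel(
            mobs, model, spec, min_height_rel=min_height_rel,
            min_prominence_rel=min_prominence_rel, refine=refine,
            match_tol_fwhm=match_tol_fwhm)
        outcome = ChannelOutcome(spec=spec, analyte=analyte, result=result,
                                 n_peaks={r: len(p) for r, p in peaks.items()})
        logger.info("%s: %s (%s)", spec.label, result.classification,
                    outcome.n_peaks)
        outcomes.append(outcome)
    # column order: dimers then trimers, lexical within — follows spec order
    columns.sort(key=lambda c: (c.count("+"), c))
    return ScreenReport(analytes=analyte_names, columns=columns,
                        outcomes=outcomes)
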