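"""Mobility peak detection, Gaussian refinement, and enantiomer pairing.

Peaks in a stitched mobilogram are located with a prominence-gated local
maximum search; the FWHM comes from linear interpolation of the half-height
crossings and the area from a trapezoid over the prominence base.  Partially
resolved doublets can be refined with a sum-of-Gaussians least-squares fit.

:func:`pair_enantiomers` reproduces the chiral screening logic: each analyte
is acquired three times (L alone, D alone, and the equimolar mix, always with
the chiral selectors and Cu²⁺ present); the mix-run peaks are matched to the
single-enantiomer apexes, converted to CCS, and the |ΔCCS%| between the two
matched peaks decides the separation class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .chem import ComplexSpec
from .errors import DomainError, FitError
from .metrics import (CalibrationModel, SeparationResult, ccs_from_reduced_mobility,
                      classify_separation, delta_ccs_percent, resolution)
from .stitching import Mobilogram

__all__ = [
    "Peak",
    "GAUSSIAN_FWHM_FACTOR",
    "detect_peaks",
    "fit_gaussians",
    "assign_ccs",
    "pair_enantiomers",
]

GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class Peak:
    """One detected mobility peak on the 1/K0 axis."""

    apex_inv_k0: float
    fwhm_inv_k0: float
    height: float
    area: float
    ccs: float | None = None
    annotation: str = ""

    def __post_init__(self):
        if self.height <= 0:
            raise DomainError("peak height must be positive")
        if self.fwhm_inv_k0 <= 0:
            raise DomainError("peak FWHM must be positive")

    @property
    def resolution(self) -> float:
        """Mobility resolving power of this peak (single source of truth)."""
        return resolution(self.apex_inv_k0, self.fwhm_inv_k0)


def _parabolic_apex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Refine an apex by the vertex of the parabola through three points."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid apex
        return float(x[i])
    # uniform-grid vertex offset in units of the local spacing
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (x[i + 1] - x[i - 1])
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * step)


def detect_peaks(mob: Mobilogram, min_height_rel: float = 0.05,
                 min_prominence_rel: float = 0.02,
                 smooth_window: int = 9) -> list[Peak]:
    """Detect local maxima above relative height and prominence thresholds.

    Thresholds are fractions of the global maximum (defaults 5% height, 2%
    prominence).  Before picking, the trace is passed through a quadratic
    Savitzky–Golay filter of ``smooth_window`` samples (default 9; ≤ 2
    disables it): point-level baseline noise riding on a peak flank would
    otherwise spawn spurious local maxima whose prominence exceeds any
    sensible gate.  The window is an order of magnitude narrower than the
    peaks themselves, so shape distortion is negligible.  FWHM is measured
    by linear interpolation of the half-height crossings; the apex is
    refined by a three-point parabola.  Peaks return sorted by apex.
    """
    y = np.asarray(mob.intensity, dtype=float)
    if len(y) == 0 or np.max(y) <= 0:
        return []
    if smooth_window > 2 and len(y) > smooth_window:
        w = smooth_window + 1 if smooth_window % 2 == 0 else smooth_window
        y = np.clip(savgol_filter(y, w, polyorder=2), 0.0, None)
        if np.max(y) <= 0:
            return []
    ymax = float(np.max(y))
    idx, props = find_peaks(y, height=min_height_rel * ymax,
                            prominence=min_prominence_rel * ymax)
    if len(idx) == 0:
        return []
    widths, _, left_ips, right_ips = peak_widths(y, idx, rel_height=0.5)
    positions = np.arange(len(y), dtype=float)
    left_x = np.interp(left_ips, positions, mob.axis)
    right_x = np.interp(right_ips, positions, mob.axis)
    peaks = []
    for k, i in enumerate(idx):
        fwhm = float(right_x[k] - left_x[k])
        if fwhm <= 0:
            continue
        lb, rb = int(props["left_bases"][k]), int(props["right_bases"][k])
        area = float(np.trapezoid(y[lb:rb + 1], mob.axis[lb:rb + 1]))
        peaks.append(Peak(apex_inv_k0=_parabolic_apex(mob.axis, y, int(i)),
                          fwhm_inv_k0=fwhm, height=float(y[i]), area=area))
    peaks.sort(key=lambda p: p.apex_inv_k0)
    return peaks


def fit_gaussians(mob: Mobilogram, n: int,
                  initial: Sequence[Peak] | None = None,
                  full_output: bool = False):
    """Refine peak parameters by a sum-of-n-Gaussians least-squares fit.

    Initial guesses come from :func:`detect_peaks` unless supplied; the fit
    is deterministic for fixed guesses.  Returns refined peaks sorted by
    centre (optionally with the underlying lmfit result).  Non-convergence
    raises :class:`FitError` carrying the best iterate and residual.
    """
    from lmfit.models import GaussianModel

    if n < 1:
        raise DomainError("number of Gaussians must be >= 1")
    if len(mob) < 3 * n:
        raise DomainError("mobilogram too short for the requested fit")
    x, y = mob.axis, mob.intensity
    guesses = list(initial) if initial is not None else detect_peaks(mob)
    guesses.sort(key=lambda p: p.height, reverse=True)
    guesses = guesses[:n]
    span = float(x[-1] - x[0])
    while len(guesses) < n:  # fall back to quantile placement
        frac = (len(guesses) + 1) / (n + 1)
        apex = float(x[0] + frac * span)
        sigma = max(span / (6 * n), 3 * float(np.min(np.diff(x))))
        guesses.append(Peak(apex, GAUSSIAN_FWHM_FACTOR * sigma,
                            max(float(np.max(y)), 1e-12),
                            float(np.max(y)) * sigma))
    guesses.sort(key=lambda p: p.apex_inv_k0)

    model = None
    params = None
    for i, g in enumerate(guesses):
        comp = GaussianModel(prefix=f"g{i}_")
        sigma0 = max(g.fwhm_inv_k0 / GAUSSIAN_FWHM_FACTOR, 1e-9)
        p = comp.make_params()
        p[f"g{i}_center"].set(value=g.apex_inv_k0, min=float(x[0]), max=float(x[-1]))
        p[f"g{i}_sigma"].set(value=sigma0, min=1e-9, max=span)
        p[f"g{i}_amplitude"].set(value=g.height * sigma0 * math.sqrt(2 * math.pi),
                                 min=0.0)
        model = comp if model is None else model + comp
        params = p if params is None else params.update(p) or params
    result = model.fit(y, params, x=x)
    rmse = float(np.sqrt(np.mean(result.residual ** 2)))
    if not result.success:
        raise FitError("Gaussian fit did not converge",
                       best=result.best_values, residual=rmse)
    out = []
    for i in range(n):
        center = float(result.params[f"g{i}_center"].value)
        fwhm = float(result.params[f"g{i}_fwhm"].value)
        height = float(result.params[f"g{i}_height"].value)
        amplitude = float(result.params[f"g{i}_amplitude"].value)
        out.append(Peak(apex_inv_k0=center, fwhm_inv_k0=max(fwhm, 1e-12),
                        height=max(height, 1e-12), area=amplitude,
                        annotation=f"gaussian_fit rmse={rmse:.6g}"))
    out.sort(key=lambda p: p.apex_inv_k0)
    if full_output:
        return out, result
    return out


def assign_ccs(peaks: Sequence[Peak], mz: float, z: int,
               model: CalibrationModel) -> list[Peak]:
    """Attach CCS values (Mason–Schamp) to peaks on the 1/K0 axis."""
    return [replace(p, ccs=ccs_from_reduced_mobility(p.apex_inv_k0, mz, z,
                                                     model=model))
            for p in peaks]


def _nearest(peaks: Sequence[Peak], apex: float,
             match_tol_fwhm: float) -> Peak | None:
    """Nearest peak to ``apex`` within ``match_tol_fwhm`` of its own FWHM."""
    best = None
    for p in peaks:
        d = abs(p.apex_inv_k0 - apex)
        if d <= match_tol_fwhm * p.fwhm_inv_k0 and (
                best is None or d < abs(best.apex_inv_k0 - apex)):
            best = p
    return best


def pair_enantiomers(peaks_L_run: Sequence[Peak], peaks_D_run: Sequence[Peak],
                     peaks_mix_run: Sequence[Peak], model: CalibrationModel,
                     complex_spec: ComplexSpec,
                     match_tol_fwhm: float = 1.0) -> SeparationResult:
    """Pair mix-run peaks with the single-enantiomer runs and classify.

    The most intense peak of each single-enantiomer run defines that
    enantiomer's apex; the mix peak nearest each apex (within
    ``match_tol_fwhm`` × its FWHM) is taken as that enantiomer's signal in
    the mixture.  ΔCCS% is signed L→D (positive when the L-assigned peak has
    the smaller CCS), ``ccs_A`` is the first-eluting matched peak, and the
    class follows :func:`metrics.classify_separation` on |ΔCCS%|.

    Mix peaks matched to neither single run are flagged as "additional
    peaks" (they indicate poor separation in practice).  An empty mix run
    classifies as ``not_detected``; a single mix peak that cannot be
    cross-checked against both single runs classifies as ``single_signal``.
    """
    label = complex_spec.label
    mz, z = complex_spec.mz, complex_spec.charge
    mix = list(peaks_mix_run)
    if not mix:
        return SeparationResult(complex_label=label, classification="not_detected")

    def ccs_of(p: Peak) -> float:
        return p.ccs if p.ccs is not None else ccs_from_reduced_mobility(
            p.apex_inv_k0, mz, z, model=model)

    annotations: list[str] = []
    apex_L = max(peaks_L_run, key=lambda p: p.height).apex_inv_k0 if peaks_L_run else None
    apex_D = max(peaks_D_run, key=lambda p: p.height).apex_inv_k0 if peaks_D_run else None
    if len(peaks_L_run) > 1 or len(peaks_D_run) > 1:
        annotations.append("multiple signals")

    if apex_L is None or apex_D is None:
        # mix-only (or one single run missing): classify from the mix alone
        if len(mix) == 1:
            p = mix[0]
            c = ccs_of(p)
            return SeparationResult(complex_label=label, ccs_A=c, ccs_B=c,
                                    delta_ccs_pct=0.0, resolution_A=p.resolution,
                                    resolution_B=p.resolution,
                                    classification="single_signal",
                                    annotations=tuple(annotations))
        top2 = sorted(sorted(mix, key=lambda p: p.height, reverse=True)[:2],
                      key=lambda p: p.apex_inv_k0)
        a, b = top2
        delta = delta_ccs_percent(ccs_of(a), ccs_of(b))
        annotations.append("mix only")
        return SeparationResult(complex_label=label, ccs_A=ccs_of(a), ccs_B=ccs_of(b),
                                delta_ccs_pct=delta, resolution_A=a.resolution,
                                resolution_B=b.resolution,
                                classification=classify_separation(abs(delta)),
                                annotations=tuple(annotations))

    p_L = _nearest(mix, apex_L, match_tol_fwhm)
    p_D = _nearest(mix, apex_D, match_tol_fwhm)
    matched = {id(p) for p in (p_L, p_D) if p is not None}
    extras = [p for p in mix if id(p) not in matched]
    if extras:
        annotations.append("additional peaks")

    if p_L is None and p_D is None:
        return SeparationResult(complex_label=label, classification="single_signal",
                                annotations=tuple(annotations + ["unmatched mix peaks"]))
    if p_L is None or p_D is None or p_L is p_D:
        p = p_L or p_D
        c = ccs_of(p)
        return SeparationResult(complex_label=label, ccs_A=c, ccs_B=c,
                                delta_ccs_pct=0.0, resolution_A=p.resolution,
                                resolution_B=p.resolution, classification="none",
                                annotations=tuple(annotations))

    ccs_L, ccs_D = ccs_of(p_L), ccs_of(p_D)
    delta = delta_ccs_percent(ccs_L, ccs_D)  # positive when L elutes first
    first, second = sorted((p_L, p_D), key=lambda p: p.apex_inv_k0)
    return SeparationResult(complex_label=label, ccs_A=ccs_of(first),
                            ccs_B=ccs_of(second), delta_ccs_pct=delta,
                            resolution_A=first.resolution,
                            resolution_B=second.resolution,
                            classification=classify_separation(abs(delta)),
                            annotations=tuple(annotations))
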