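"""Synthetic segmented SIM² acquisitions with known ground truth.

The simulator is the package's stand-in for instrument data: it evaluates
Gaussian mobility peaks on the window grids of a stitch plan, applies the
empirical sensitivity gain of narrow windows (narrower window → less space
charge → proportionally higher signal), adds a seeded, zero-truncated
Gaussian baseline noise, and plants a narrow artifact bump at the end of
every window to emulate the "edge effect" signals seen in whole-acquisition
processing.  Every downstream stage (extraction, stitching, peak detection,
pairing, screening) is testable against the generated ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .chem import ComplexSpec
from .errors import ConfigurationError, DomainError
from .metrics import CalibrationModel, inv_k0_from_ccs
from .stitching import MICRO, Segment, StitchPlan, Window

__all__ = [
    "SimPeakSpec",
    "SimConfig",
    "simulate_segments",
    "make_enantiomer_fixture",
]

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SimPeakSpec:
    """Ground-truth Gaussian mobility peak of one m/z channel."""

    mz: float
    apex_inv_k0: float
    sigma_inv_k0: float
    height: float
    label: str = ""

    def __post_init__(self):
        if self.sigma_inv_k0 <= 0:
            raise DomainError("peak sigma must be positive")
        if self.height <= 0:
            raise DomainError("peak height must be positive")


@dataclass
class SimConfig:
    """Simulation conditions for a segmented acquisition.

    * ``grid_step`` — 1/K0 sampling interval (V·s·cm⁻², default 1e-4).
    * ``noise_sd_rel`` — baseline noise s.d. as a fraction of the tallest
      peak (default 1%); Gaussian, truncated at zero (``noise_model`` may be
      set to ``"poisson"``).
    * ``edge_artifact_height_rel`` / ``edge_artifact_width`` — amplitude
      (fraction of the tallest peak, default 5%) and Gaussian sigma (default
      0.005 V·s·cm⁻²) of the artifact bump at each window end.
    * ``reference_width`` — window width at which the sensitivity gain is 1;
      gain ∝ reference_width/width, so halving the window doubles the signal.
    """

    plan: StitchPlan
    grid_step: float = 1e-4
    noise_sd_rel: float = 0.01
    edge_artifact_height_rel: float = 0.05
    edge_artifact_width: float = 0.005
    reference_width: float = 0.15
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if self.grid_step <= 0:
            raise DomainError("grid_step must be positive")
        step_micro = round(self.grid_step * MICRO)
        if step_micro < 1 or abs(step_micro - self.grid_step * MICRO) > 1e-6:
            raise DomainError("grid_step must be a multiple of 1e-6 V·s·cm⁻²")
        for name in ("noise_sd_rel", "edge_artifact_height_rel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise DomainError(f"unknown noise model {self.noise_model!r}")

    def gain(self, window: Window) -> float:
        """Sensitivity gain of a window relative to ``reference_width``."""
        return self.reference_width / window.width


def _global_axis(config: SimConfig) -> np.ndarray:
    """One shared 1/K0 grid across the plan, so overlap samples align exactly."""
    start_i = round(config.plan.range_start * MICRO)
    end_i = round(config.plan.range_end * MICRO)
    step_i = round(config.grid_step * MICRO)
    n = (end_i - start_i) // step_i
    return (start_i + np.arange(n + 1) * step_i) / MICRO


def simulate_segments(peaks: Sequence[SimPeakSpec],
                      config: SimConfig) -> list[Segment]:
    """Simulate the per-window record arrays of one stitched acquisition.

    Deterministic for a fixed seed: the random stream is consumed in window
    order, then channel order (channels sorted by m/z).  Peaks are evaluated
    on the global grid restricted to each window and scaled by the window's
    sensitivity gain; noise and the edge artifact are per channel.
    """
    rng = np.random.default_rng(config.seed)
    axis = _global_axis(config)
    channels: dict[float, list[SimPeakSpec]] = {}
    for p in peaks:
        channels.setdefault(round(p.mz, 9), []).append(p)
    hmax = max((p.height for p in peaks), default=0.0)
    segments = []
    for k, w in enumerate(config.plan.windows):
        g = config.gain(w)
        x = axis[w.contains(axis)]
        xs, mzs, ys = [], [], []
        for mz in sorted(channels):
            y = np.zeros(len(x))
            for p in channels[mz]:
                y += p.height * g * np.exp(
                    -0.5 * ((x - p.apex_inv_k0) / p.sigma_inv_k0) ** 2)
            if config.edge_artifact_height_rel > 0 and hmax > 0:
                y += (config.edge_artifact_height_rel * hmax * g * np.exp(
                    -0.5 * ((x - w.end_inv_k0) / config.edge_artifact_width) ** 2))
            if config.noise_sd_rel > 0 and hmax > 0:
                if config.noise_model == "gaussian":
                    y = y + rng.normal(0.0, config.noise_sd_rel * hmax * g, len(x))
                else:
                    scale = config.noise_sd_rel * hmax * g
                    y = rng.poisson(np.clip(y, 0, None) / max(scale, 1e-12)) * scale
            y = np.clip(y, 0.0, None)
            xs.append(x)
            mzs.append(np.full(len(x), mz))
            ys.append(y)
        if xs:
            seg = Segment(w, np.concatenate(xs), np.concatenate(mzs),
                          np.concatenate(ys), segment_id=f"seg{k}",
                          metadata={"gain": g, "window_index": k})
        else:
            seg = Segment(w, np.array([]), np.array([]), np.array([]),
                          segment_id=f"seg{k}", metadata={"gain": g,
                                                          "window_index": k})
        segments.append(seg)
    return segments


def _derived_seed(base: int, k: int) -> int:
    return (base * 1_000_003 + k) % (2 ** 31)


def make_enantiomer_fixture(complex_spec: ComplexSpec, ccs_L: float,
                            delta_ccs_pct: float, resolution: float,
                            model: CalibrationModel, config: SimConfig,
                            height: float = 1000.0
                            ) -> tuple[dict[str, list[Segment]], dict]:
    """Generate the three screening runs (L, D, mix) for one complex channel.

    The two enantiomer peaks are placed so that their CCS values differ by
    exactly ``delta_ccs_pct`` (D relative to L, signed) and their common
    width gives the requested mobility resolving power ``resolution`` on the
    1/K0 axis.  Returns the runs keyed ``"L"``, ``"D"``, ``"mix"`` plus the
    ground-truth record used by recovery tests.  Each run draws its noise
    from a seed derived from ``config.seed`` so the three runs are
    independent but jointly reproducible.
    """
    if resolution <= 0:
        raise DomainError("resolution must be positive")
    mz, z = complex_spec.mz, complex_spec.charge
    ccs_D = ccs_L * ((200.0 + delta_ccs_pct) / (200.0 - delta_ccs_pct))
    inv_L = inv_k0_from_ccs(ccs_L, mz, z, model=model)
    inv_D = inv_k0_from_ccs(ccs_D, mz, z, model=model)
    apex_mean = 0.5 * (inv_L + inv_D)
    fwhm = apex_mean / resolution
    sigma = fwhm / _GAUSS_FWHM
    plan = config.plan
    lo = min(inv_L, inv_D) - 4 * sigma
    hi = max(inv_L, inv_D) + 4 * sigma
    if lo < plan.range_start or hi > plan.range_end:
        raise ConfigurationError(
            f"enantiomer peaks ({inv_L:.4f}, {inv_D:.4f} ± 4σ) fall outside the "
            f"plan range [{plan.range_start}, {plan.range_end}]")
    peak_L = SimPeakSpec(mz=mz, apex_inv_k0=inv_L, sigma_inv_k0=sigma,
                         height=height, label="L")
    peak_D = SimPeakSpec(mz=mz, apex_inv_k0=inv_D, sigma_inv_k0=sigma,
                         height=height, label="D")
    runs = {}
    for k, (name, pk) in enumerate((("L", [peak_L]), ("D", [peak_D]),
                                    ("mix", [peak_L, peak_D]))):
        cfg = replace(config, seed=_derived_seed(config.seed, k))
        runs[name] = simulate_segments(pk, cfg)
    truth = {
        "label": complex_spec.label,
        "mz": mz,
        "charge": z,
        "ccs_L": ccs_L,
        "ccs_D": ccs_D,
        "delta_ccs_pct": delta_ccs_pct,
        "resolution": resolution,
        "inv_k0_L": inv_L,
        "inv_k0_D": inv_D,
        "sigma_inv_k0": sigma,
        "fwhm_inv_k0": fwhm,
        "height": height,
    }
    return runs, truth
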