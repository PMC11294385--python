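# Methods

This note documents the models, conventions and numerical choices behind
`simstitch`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and what the synthetic data do and do not emulate.

## Complex enumeration and exact mass

Each screening channel is a singly charged copper-bound cluster
`[Σcomponents − H + Cu]⁺` with 2 or 3 neutral amino-acid components, at
least one of which is the analyte. Enumeration generates, per analyte AA,
all size-2 and size-3 multisets over {AA} ∪ selectors containing at least
one AA copy. For the two-selector panel {Phe, Pro} this yields exactly nine
stoichiometries per analyte (dimers AA+Pro, AA+Phe, AA+AA; trimers
AA+Pro+Pro, AA+Phe+Pro, AA+Phe+Phe, AA+AA+Pro, AA+AA+Phe, AA+AA+AA), hence
9n species for n analytes and 153 for the full 17-analyte panel. The count
is chirality-blind: L- and D-built clusters are isobaric, and handedness
only matters downstream when mobility peaks are paired.

m/z is computed as `(Σ m_i − m(H) + m(⁶³Cu) − m(e)) / z` from a built-in
NIST monoisotopic element table. Conventions:

* **Copper isotope.** ⁶³Cu (most abundant) defines the monoisotopic peak;
  ⁶⁵Cu is selectable. This is the standard MS convention.
* **Electron mass.** The −m(e) correction for the cation is applied; it is
  ~0.5 mDa, i.e. material at the ±0.01 Da extraction tolerance.
* **Cysteine.** Cys is enumerated like any other analyte (keeping the
  9-per-analyte law), but an optional substitution rule replaces Cys pairs
  by the covalent cystine dimer Cys₂ − 2H, which is the species actually
  observed for this amino acid. Substituted dimer specs have a single
  component; the component-count invariant is relaxed to {1, 2, 3} for
  exactly this case.
* Homochiral vs heterochiral self-association (L/L vs L/D dimers) is a peak
  *annotation*, not a distinct species: both map to the same stoichiometry.

## Mobility metrics

**CCS conversion.** The single-field Mason–Schamp relation
`Ω = (3ze/16N₀)·√(2π/(μ·k_B·T))·(1/K₀)` with CODATA-2018 constants
(scipy.constants), N₀ the gas number density at 273.15 K / 1013.25 hPa, and
μ the ion–gas reduced mass with the ion mass taken as z·(m/z − m_e). Drift
gas defaults to N₂ (28.00615 Da). The drift temperature is not a measured
telemetry value here; the default is 305 K, a typical TIMS operating
temperature, and is configurable because CCS scales with √T. The map is
linear in 1/K₀, so its inverse is exact.

**ΔCCS%** is `2·(CCS_B − CCS_A)/(CCS_B + CCS_A)·100`, signed. The sign
carries elution order (positive when the L-assigned peak elutes first);
classification uses the absolute value. Elution order of enantiomers is not
systematic, which is why the sign is kept rather than discarded.

**Resolving power** is apex/FWHM evaluated on the 1/K₀ axis. The textbook
definition K₀/ΔK₀ is algebraically on the mobility axis, but mobilograms
are measured in 1/K₀ and for narrow peaks the two agree to first order; the
measured object wins.

**Classification thresholds.** |ΔCCS%| ≥ 1.0 → baseline; 0.5–1.0 →
partial; < 0.5 → none. Ties at exactly 0.5 and 1.0 are assigned upward —
a deterministic convention well inside measurement noise.

**Calibration** is an ordinary least-squares line from the instrument
elution coordinate to 1/K₀, mirroring the daily "linear mode" calibration
against a tuning mix. The model is agnostic about whether the measured
coordinate is an elution voltage or a scan time.

## Window planning and stitching

Window starts step by (width − overlap) from the range start; the plan ends
with the first window whose end reaches the range end (possibly extending
past it — constant width is preserved). Boundary arithmetic is done in
scaled integers on a 10⁻⁶ V·s·cm⁻² lattice so that boundary equality
(e.g. interior boundaries exactly at 0.85/0.95/1.05) is exact in floating
point.

Stitching merges per-window segments onto the union 1/K₀ grid:

* `per_segment` mode assigns every point to exactly one covering window —
  the earlier one under the default `first` rule. Total intensity is
  conserved (no record counted twice). This mirrors the artifact-free
  practice of processing each mobility segment separately.
* `combined` mode merges overlap regions under an explicit rule; `sum`
  reproduces the intensity doubling of whole-acquisition processing, where
  signals inside an overlap are recorded by two windows.
* Segments on different grids are regridded by linear interpolation — a
  simple, monotone choice. A window only "covers" where it actually
  sampled, so missing data never dilutes a merge.
* The edge-artifact mask is **off by default**: artifacts are a reported
  observation, not something removed by the acquisition itself. When a
  mask width is given, intensities within it of each interior boundary are
  zeroed and flagged in the provenance array.

## Peak detection and pairing

Detection is scipy `find_peaks` with relative gates: height ≥ 5% and
prominence ≥ 2% of the trace maximum. Before picking, the trace passes a
quadratic Savitzky–Golay filter (9 samples by default, ≈ 1/7 of a typical
FWHM at the 10⁻⁴ grid): without it, point-level baseline noise riding on a
peak flank spawns spurious local maxima whose prominence exceeds any
sensible gate. The smoothing window is an order of magnitude narrower than
the peaks, so shape bias is negligible (< 1% on FWHM). FWHM comes from
linear interpolation of the half-height crossings, the apex from a
three-point parabola, the area from a trapezoid over the prominence base.

Partially resolved doublets bias raw local maxima toward each other (at
0.7% ΔCCS and R = 150 the bias is ≈ 0.1 ΔCCS points). The screening
pipeline therefore refines the two most intense mix-run peaks with a
two-Gaussian least-squares fit (lmfit) on a ±3-FWHM window around them
whenever they lie closer than twice their mean FWHM; the local window keeps
edge-artifact bumps out of the fit.

Pairing logic per channel: the most intense peak of each single-enantiomer
run defines that enantiomer's apex; the mix peak nearest each apex within
1 FWHM is its signal in the mixture. Outcomes:

* both matched, distinct → ΔCCS% and class from the matched pair;
* both match the same mix peak → ΔCCS% = 0, class `none`;
* empty mix run → `not_detected`;
* a single mix peak that cannot be cross-checked against both single runs
  (one of them missing/empty) → `single_signal`;
* mix peaks matching neither single run → annotation `additional peaks`
  (footnote *a* in the report — in practice a sign of poor separation);
* more than one peak in a single-enantiomer run → annotation
  `multiple signals` (footnote *b*). Multi-signal channels are flagged,
  never merged.

With only a mix run available, the two most intense mix peaks are used and
the result annotated `mix only`.

## The simulator

The simulator emulates the *data properties* of segmented SIM²
acquisitions, not the physics of the TIMS cell (no electric-field gradient,
space-charge or accumulation modelling):

* Gaussian peaks in 1/K₀ — observed mobilogram peaks are near-symmetric
  and no shape model is established;
* one shared 1/K₀ grid across the plan (default step 10⁻⁴ V·s·cm⁻²), so
  overlap samples align exactly between adjacent windows;
* sensitivity gain ∝ reference_width/width (reference 0.15 V·s·cm⁻²) —
  narrower windows admit fewer ions, reduce space charge and raise
  signal-to-noise; the default makes "halving the width doubles the
  height" exact;
* baseline noise: zero-truncated Gaussian, s.d. 1% of the tallest peak
  (Poisson mode optional);
* edge artifacts: an additive Gaussian bump at each window end (default
  height 5% of the tallest peak, σ = 0.005 V·s·cm⁻²). The true artifact
  amplitude and shape are unknown; this is a stand-in for robustness
  testing only.

Everything is seeded (numpy `default_rng`); the random stream is consumed
in window-major, channel-minor order, so fixed seed ⇒ bit-identical output,
and changing only the seed changes only the noise realisation.

`make_enantiomer_fixture` inverts the metrics: it places two Gaussians so
their CCS values differ by exactly the requested ΔCCS% and their width
gives the requested resolving power, then simulates the three screening
runs (L, D, equimolar mix — each run with its own derived seed) and returns
the ground truth. Passing recovery tests on these fixtures demonstrates the
pipeline's correctness under the simulator's assumptions; real data add
peak-shape asymmetry, intensity differences between enantiomer complexes,
isobaric interferences and calibration drift, none of which are emulated.

## Problem sizes and defaults used in the shipped checks

Recovery checks run the full pipeline on the reference 4-window plan at
grid step 10⁻⁴ (≈ 4500 points per trace) over ten seeds per condition
(ΔCCS% ∈ {1.3, 0.7, 0.3} at R = 150); stitching conservation is checked on
100 random acquisitions; metric oracles on 100–1000 random draws. These
sizes give stable statistics while keeping the whole suite in seconds.

## Known limitations

* Stoichiometric enumeration does not model isotope patterns, binuclear
  (two-copper) clusters, or sodiated/potassiated adducts.
* Enantiomeric-excess quantification is out of scope: MS response can
  differ between enantiomer complexes, so intensity ratios are not read as
  composition.
* The calibration model is strictly linear; nonlinear TIMS calibrations and
  pressure/temperature telemetry corrections are not implemented.
* Vendor raw files are not decoded; data enter via the canonical segment
  TSV (+ plan JSON) or the `records_to_segments` converter hook.
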