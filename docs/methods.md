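# Methods

This note documents the physical model, the signal-processing and fitting
procedures, the synthetic-data generator, the numerical choices, and the
limitations of `npsrheo`.

## Physical model

**Geometry and strain.** A device is a sizing pore (length `L_pore`,
effective diameter `D_eff`) followed by `N` contraction zones separated by
wide nodes. Zone `j` has length `L_zone`, period length `L_p`, and width
`w(x) = w0 + a·cos(2πx/L_p)` with `x` measured from the zone entry, which
is placed at the widest point `w(0) = w0 + a` so that a cell arriving from
a node first meets a converging wall and the strain phase has a defined
reference. A cell of free diameter `D > w0 + a` moving at velocity `v` is
compressed with strain

    ε(t) = ε_m + ε0·cos(ωt + φ0),   ε_m = (D − w0)/D,  ε0 = a/D,
    ω = 2πv/L_p,  φ0 = π.

`φ0 = π` encodes entry at minimum strain; simulator and fitter share this
convention, so it cancels identically in recovery. For the standard
geometry (`w0 = 11.25 µm`, `a = 2.75 µm`) and an 18.4 µm cell this is
ε ≈ 0.39 + 0.15·cos(ωt). Cells with `D ≤ w0 + a` lose wall contact; they
are flagged `unstrained` and excluded from rheology, never fitted.

**Sizing.** The pore blockage follows the volume-ratio law with the
standard cubic shape correction,

    ΔR/R = (D³/(D_eff²·L)) · 1/(1 − 0.8·(D/D_eff)³),

inverted in closed form:
`D = [ (ΔR/R)·L·D_eff² / (1 + 0.8·(ΔR/R)·L/D_eff) ]^{1/3}`. The two
directions are exact algebraic inverses (round-trip at 1e-9 is asserted in
the tests). `D_eff` is a per-device calibration constant;
`fit_effective_diameter` recovers it from (reference diameter, observed
blockage) pairs by least squares. Per-zone effective diameters are carried
in the geometry as calibration metadata but are not consumed by the
stress model, which never Coulter-inverts a zone pulse.

**Deformed diameter.** A squeezed cell's wall-contact diameter comes from
volume conservation, `D_d = √(2D³/(3w))`; it equals `D` at `w = 2D/3` and
exceeds it for narrower gaps.

**Stress and pressure partition.** The compressive stress on the cell is

    σ = 2·ΔP·w / (µ_f·π·D_d),

with `µ_f` the cell–wall friction coefficient and `ΔP` the pressure drop
across the cell. `ΔP` is not directly measured; the package ties it to
the cell's instantaneous fractional electrical blockage,

    ΔP(t)/P_applied = ΔR(t) / (R_base + ΔR(t)),

on the rationale that the electrical and hydraulic constrictions co-scale
in a series channel. This partition model is the single largest modelling
choice in the package: it makes the simulator and the analysis exact
inverses (so the self-consistency tests close the loop), but it carries
an unknown multiplicative calibration with respect to any particular
physical device, as does `µ_f` (default 0.1, the order of magnitude for
lubricated PDMS–cell contact). Absolute moduli should therefore be read
as internally consistent, not traceable, values. A `constant` pressure
mode (in-pulse mean `ΔP`) is provided for sensitivity analysis; it is not
the default because a constant `ΔP` with purely geometric width
modulation cannot produce a quadrature (loss) component.

**Rheology.** With the strain convention above, the stress is fitted by
ordinary linear least squares to

    σ(t) = σ_p + G′·ε0·cos(ωt + φ0) + G″·ε0·sin(ωt + φ0).

`σ_p` (pre-stress) absorbs the mean compressive strain `ε_m`; `ε0` is the
oscillation amplitude only, which keeps the expression in standard
oscillatory-rheology form. The loss tangent is `η = G″/G′`. Negative
fitted moduli are flagged, never clipped, preserving the semantics of the
detection floor: a cell is `below_detection` when `G″ < 0.1 Pa` in at
least one zone. The reported per-zone frequency is the kinematic
`f = v/L_p` from the measured transit time, not a fitted frequency.

## Signal processing

Per channel, in order: (1) zero-phase 4th-order Butterworth low-pass,
default cutoff 2 kHz at 10 kHz sampling — far above every pulse feature
(≤ ~150 Hz) but removing most wideband noise without shifting edge
timing; (2) moving median, default 0.5 ms — removes isolated spikes.
The median window must stay well below half the *shortest* strain
half-period (8.3 ms at 126 Hz), otherwise it crushes the in-zone
oscillation; this is why the default is 0.5 ms and not larger. (3)
baseline normalisation: a rolling 10th-percentile baseline (2 s window,
estimated blockwise at 0.1 s resolution and interpolated) tracks slow
drift but not the upward cell pulses; output is dimensionless `ΔR/R`.
(4) detection: excursions above `5× MAD` of the normalised noise (with an
absolute floor of 2e-4 for noise-free records), where sub-threshold
blips shorter than 2 ms are discarded *before* gap-merging (40 ms) so
that noise cannot chain into phantom pulses while the oscillation trough
cannot split one transit; pulses must last ≥ 5 ms. After a first
detection pass the baseline is re-estimated with pulses masked (local
mean of clean samples), removing the low-quantile bias of the first
pass, and detection is repeated on the refined normalisation. (5)
cross-channel matching: greedy and causal (pore before zone 1 before
zone 2 …) within a 1 s maximum inter-channel gap; events whose
pore-to-last-zone spans overlap are flagged `coincident` and excluded
from fitting — no attempt is made to decode coincident cells.

## Alignment refinement

The fit basis and the width modulation both depend on where (in phase)
the cell is in the zone, but detected pulse edges are only
sample-accurate, and a zone holds up to ~48 strain periods: a sub-sample
timing error rotates elastic response into apparent viscous response at
~1 kPa/rad. Because basis and width modulation shift together, the model
is *periodic* in the entry-time offset with period `1/f`; the
identifiable alignment parameters are the strain phase — taken at the
pulse centre, where it decouples from velocity error — and a relative
velocity shift (bounded at ±6%, generous against trough-phase edge
bias). The per-zone fit therefore: band-limits the pulse to `6f`
(zero-phase, trimming the filter's edge transient), scans a 48×21 grid
over (phase, velocity shift) on strided samples, polishes the best point
with Nelder–Mead on the full samples, and runs the final OLS at the
refined alignment. On noiseless simulations this closes the loop to
better than 0.3% in all parameters; the refinement is a profile
likelihood in the two nuisance parameters, so no further algorithmic
gain is available at a given noise level. It can be disabled
(`refine_alignment=False`) for speed when only `G′` and sizing matter.

## Synthetic data generator

`generate_trace` embeds, per cell, a top-hat pore pulse (Coulter height)
and one oscillatory pulse per zone obtained by running the stress model
forwards through the same pressure partition, then adds white Gaussian
noise and a slow sinusoidal baseline drift. Defaults are chosen once as
the study conditions and emulate an untreated MCF-7-like population in
the standard four-zone device: diameters 18.4 ± 0.9 µm (truncated to the
physical range of the device), driving pressure 13.8 kPa, sampling 10⁴
S/s, mean transit velocity 15 mm/s (≈30 Hz strain in the L_p = 500 µm
zone) with zone-to-zone velocity factors (1, 1.154, 1.207, 1.25) for
four-zone devices, reproducing the upward frequency drift seen in real
transits; moduli: `G′` log-normal with median 500 Pa (σ_log 0.3), `G″`
median 50 Pa, pre-stress 150 ± 15 Pa, floored so the oscillatory stress
never exceeds it (walls cannot pull). Arrivals are evenly spaced at the
configured event rate with ±5% jitter; overlapping occupancies are
recorded as `coincident` in the truth table. Noise levels are most
usefully expressed relative to the signal: `typical_pulse_heights`
returns the mean-cell pore and zone pulse heights, and the realistic
test condition uses white noise at 5% of the zone-pulse height (≈1.5e-4
of baseline R) plus 1% drift.

What the generator does *not* emulate: 1/f electrode noise, cell
rotation or shape anisotropy, multi-cell trains inside one zone,
cytoskeletal recovery during transit, velocity variation *within* a
zone, and any mismatch between the true hydraulic pressure partition and
the electrical-blockage model. Passing recovery tests therefore
demonstrate that the inverse pipeline is correct and noise-robust under
the declared model, not that the partition model itself is accurate for
a physical device — the latter requires the wet-lab calibration that
fixes `µ_f` and `D_eff`.

## Statistics

Outlier removal uses Tukey fences (`Q1 − 1.5·IQR`, `Q3 + 1.5·IQR`) with
linear-interpolation quartiles; fewer than four values pass through with
a warning. Two-group comparisons use the Wilcoxon rank-sum
(Mann–Whitney) test — exact null distribution for small, tie-free
samples, verified against full enumeration in the tests; the signed-rank
variant is provided but applies only to paired designs. k-group
comparisons use Kruskal–Wallis. The per-cell heterogeneity score
standardises each zone's modulus to unit variance across the population
and reports the variance of each cell's standardised values across
zones; cells with fewer than two zones get no score. Alternative
readings of "unit variance across zones" exist (e.g. per-cell
normalisation); the population-standardised reading was chosen because
it makes scores comparable between cells and leaves a
zone-frequency-independent population with scores near zero.

## Numerical choices and degenerate inputs

Quartiles/quantiles: linear interpolation throughout. The sizing inverse
is exact algebra, no iteration. `fit_rheology` refuses rank-deficient
bases (`ε0 = 0` or `ω ≈ 0`) and spans shorter than one strain period.
Stress samples implying `ΔP ≥ 0.8·P_applied` are dropped (counted per
series) as unphysical for a moving cell. All-zero or non-uniformly
sampled traces, channel/geometry mismatches and unknown configuration
keys raise configuration errors rather than being silently coerced.
Every excluded cell carries a machine-readable reason, and
`events = fitted + excluded` holds per run.

## Problem sizes

The validation suite simulates 20 noiseless cells (self-consistency at
1%) and 100 noisy cells (recovery tolerances at 5% zone-pulse noise) in
the standard four-zone device, sizes at which each full pipeline run
completes in a few minutes on one CPU while leaving the acceptance
margins clearly visible.

## Known limitations

* Absolute stress calibration (`µ_f`, pressure partition) is declared,
  not derived; moduli are internally consistent, not traceable.
* `G″` is phase-critical: its error is dominated by the achievable
  strain-phase alignment, and at realistic noise its relative error is
  an order of magnitude larger than `G′`'s. Very viscous-poor cells
  (`G″ < 0.1 Pa`) are below the detection floor by design.
* Coincident cells are flagged and dropped, not decoded.
* No power-law (structural-damping) fitting across frequencies is
  attempted: the accessible frequency range spans less than a decade.
* The event matcher assumes strictly causal, non-interleaved transits;
  heavy coincidence rates (event spacing shorter than the device
  residence time) will mostly be flagged away rather than recovered.
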