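# npsrheo

Single-cell viscoelastic phenotyping from multi-zone node-pore-sensing
resistance traces.

`npsrheo` analyses (and simulates) recordings from an all-electronic
microfluidic platform in which single cells flow through a Coulter sizing
pore followed by several sinusoidal *contraction zones* in series. Each
zone's width varies as

```
w(x) = w0 + a·cos(2πx / L_p)
```

so a cell of free diameter `D` moving at velocity `v` is squeezed with an
oscillatory strain `ε(t) = ε_m + ε0·cos(ωt + φ0)`, where
`ε_m = (D − w0)/D`, `ε0 = a/D` and the strain frequency is set purely by
geometry and speed, `f = v / L_p`. Measuring the zone's electrical
resistance while the cell transits therefore probes the cell's
viscoelastic response at a different frequency in every zone — tens of Hz
across a typical four-zone device — from one cell, in one pass, with no
optics.

The package is aimed at groups building or using resistive-pulse
deformability cytometers: it provides the full inverse pipeline from raw
multi-channel traces to per-cell moduli, and a forward simulator with
ground truth for validating every stage.

## Method

For each detected cell transit:

1. **Sizing** — the pore pulse height gives the free diameter through the
   corrected Coulter relation
   `ΔR/R = (D³ / (D_eff²·L)) · 1/(1 − 0.8·(D/D_eff)³)`,
   inverted in closed form (`D_eff` is the empirically calibrated
   effective pore diameter).
2. **Stress reconstruction** — inside a zone, each resistance sample is
   mapped to the instantaneous compressive stress on the cell,
   `σ(t) = 2·ΔP(t)·w(x) / (µ_f·π·D_d(x))`, with `ΔP` the pressure drop
   across the cell (taken from its fractional blockage,
   `ΔP/P = ΔR/(R + ΔR)`), `w(x)` the local width, `µ_f` the wall friction
   coefficient and `D_d = √(2D³/3w)` the volume-conserving deformed
   diameter.
3. **Rheological fit** — ordinary least squares of the stress on
   `[1, ε0·cos(ωt+φ0), ε0·sin(ωt+φ0)]` yields the pre-stress `σ_p`, the
   storage modulus `G′` and the loss modulus `G″` for that zone's
   frequency; the loss tangent is `η = G″/G′`. A bounded residual
   refinement of the strain phase and transit velocity removes
   sample-quantisation bias before the final fit.

Population tools add Tukey-fence outlier removal, Wilcoxon rank-sum /
Kruskal–Wallis comparisons, per-cell cross-zone heterogeneity scores and
zone-by-cell heatmaps.

## Worked example

Simulate five MCF-7-like cells through the standard four-zone device
(6 mm zones, `L_p` = 500/250/167/125 µm, `w = 11.25 + 2.75·cos` µm,
13.8 kPa), with noise at 5% of the zone-pulse height, then run the full
inverse pipeline:

```python
import numpy as np
from npsrheo import DeviceGeometry, PoreSpec, ZoneSpec, detect_events
from npsrheo.simulate import SimConfig, generate_trace, typical_pulse_heights
from npsrheo.rheology import analyze_events, results_to_frame

zones = tuple(ZoneSpec(index=i, L_zone=6000.0, L_p=lp, w0=11.25, a=2.75, w_node=21.0)
              for i, lp in enumerate([500.0, 250.0, 167.0, 125.0]))
geo = DeviceGeometry(pore=PoreSpec(L_pore=1000.0, D_eff=25.0), zones=zones)

_, zone_h = typical_pulse_heights(SimConfig(geometry=geo, seed=0, n_cells=1))
cfg = SimConfig(geometry=geo, seed=42, n_cells=5, noise_sd=0.05 * zone_h,
                event_rate_per_hour=1440.0)
trace, truth = generate_trace(cfg)

events = detect_events(trace, geo)
results, excluded = analyze_events(events, geo)
print(results_to_frame(results, geo)[
    ["cell_id", "D_cell_um", "zone1_f_Hz", "zone1_Gp_Pa", "zone1_Gpp_Pa",
     "zone1_eta", "zone4_f_Hz", "zone4_Gp_Pa", "zone4_Gpp_Pa"]
].round(3).to_string(index=False))
```

prints

```
 cell_id  D_cell_um  zone1_f_Hz  zone1_Gp_Pa  zone1_Gpp_Pa  zone1_eta  zone4_f_Hz  zone4_Gp_Pa  zone4_Gpp_Pa
       0     18.673      28.438      630.436        60.764      0.096     142.197      623.345        71.039
       1     18.517      29.527      497.318        28.773      0.058     147.632      495.834        27.235
       2     18.461      31.690      573.412        43.364      0.076     158.452      573.036        55.636
       3     19.192      29.926      473.630        28.477      0.060     149.625      471.320        22.506
       4     18.016      29.469      585.825        36.138      0.062     147.360      586.721        52.567
```

Each row is one cell: its Coulter diameter (µm), and per zone the applied
strain frequency (Hz, `v/L_p`), storage modulus `G′` and loss modulus `G″`
(Pa) and loss tangent. The recovered diameters match the generating truth
to well under 0.1%, the storage moduli to ~1% and the loss moduli — the
phase-critical, hardest quantity — to ~10–20% at this noise level.

The same pipeline runs from the shell:

```
npsrheo run-all --config configs/demo_run.yaml --out-dir out/
```

which writes the trace, ground truth, per-cell results and a group
summary as CSV. `simulate`, `detect`, `fit` and `report` run the stages
individually on the trace/config formats documented in
`npsrheo.traceio` and `npsrheo.config`.

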