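# wgmdyn

Single-molecule dynamometry with plasmon-enhanced whispering-gallery-mode
(WGM) biosensors.

## The problem

An optoplasmonic WGM sensor — a silica microsphere (R ≈ 40–45 µm) carrying
gold nanorods, interrogated by a 780 nm tunable laser — resolves single
enzyme molecules immobilised in the plasmonic hotspot at a nanorod tip.
Large-scale (hinge-bending) conformational changes during enzyme turnover
change the molecule's polarisability inside the hotspot field and appear as
rectangular, few-femtometre excursions of the resonance wavelength Δλ(t).

Because the enzyme's atoms move through the optical field gradient, the
sensor does work on the enzyme during every such transition. This package
quantifies that work and the free-energy penalty it imposes — the sensor
acting as a *dynamometer*: an optical-tweezer-like force gauge for single
enzymes. It is aimed at single-molecule biophysicists and WGM-sensor
developers who need to bound the perturbation their instrument applies to
the analyte.

## The model

For an event of amplitude `A` (metres of wavelength shift), the molar work
done by the sensor is

    w = λ0 · P · N_A · (1 − √(1 − S̄)) · A / (π · c · δλ̄)

where `P` is the input power, `S̄` the mean coupling efficiency (dip depth)
and `δλ̄` the mean linewidth. This is the closed form of the photon-number
chain Δλ → Δν = −c·Δλ/λ0², κ = 2πc·δλ̄/λ0², a = (1−√(1−S̄))/2,
N_in = a·4Pλ0/(κhc), w = N_A·N_in·h·|Δν|.

A sample w₁…w_μ of per-event work values yields the free-energy penalty via
the Jarzynski estimator

    ΔG ± σ_ΔG = (1/β)·ln m_w ± (1/β)·(1/μ)·σ_w/m_w,   m_w = ⟨exp(βw)⟩

with β = 1/k_BT applied to per-molecule energies. The mean work grows
linearly with the hotspot intensity I (both are proportional to the
circulating power); the slope Δw/ΔI converts, with the sphere-equivalent
enzyme diameter d̄_E = (6V/π)^{1/3}, to a trap stiffness and apparent force

    T_S = (Δw/ΔI) / (d̄_E · N_A),   F = T_S · I.

Supporting cavity optics (microsphere TE/TM mode solver, effective mode
volume with plasmonic enhancement Λ, hotspot intensity I = hν0·N_in·c/V_eff)
live in `wgmdyn.optics`; a trace simulator with exact ground truth in
`wgmdyn.simulate`; Savitzky–Golay detrending, 3σ event detection with
rectangle fitting and a linewidth veto in `wgmdyn.detect`; exponential
dwell-time kinetics in `wgmdyn.kinetics`.

## Worked example

```python
from wgmdyn import DynamometerModel
from wgmdyn.config import EnzymeConfig

model = DynamometerModel.simulate(
    intensities=[50, 100, 200, 400],     # MW cm^-2
    duration=315.0,                      # s per trace
    seed=21,
    V_eff=25e-18,                        # effective mode volume, m^3
    enzyme=EnzymeConfig(name="3PGK", molecular_volume=5.28e-26),
)
results = model.fit()
print(results.summary())
```

prints

```
Dynamometer analysis summary
============================================================
 I [MW/cm2]  events  w_mean [J/mol]   dG_J [kJ/mol] k_dwell [1/s]
         50     110           111.6          0.1117         0.373
        100      88           221.2          0.2215         0.286
        200     120           454.2           0.455         0.402
        400     107           896.5          0.9001         0.358
------------------------------------------------------------
dw/dI = 2.258 J cm2 MW-1 mol-1 (95% CI [2.163, 2.353])
d_E = 4.65 nm; T_S = 0.806 x 1e-15 N cm2 MW-1
dk/dI = 8.71e-05 s-1 per MW cm-2 (95% CI [-0.000896, 0.00107])
```

Reading this: each simulated measurement detects ≈100 turnover spikes; the
mean per-event work rises from ≈0.11 to ≈0.90 kJ mol⁻¹ as the hotspot
intensity is stepped from 50 to 400 MW cm⁻², i.e. linearly with slope
Δw/ΔI ≈ 2.26 J cm² MW⁻¹ mol⁻¹; the Jarzynski penalty ΔG tracks just above
the mean work (Jensen's inequality); and with the 3PGK molecular volume the
slope converts to a trap stiffness of ≈0.8 × 10⁻¹⁵ N cm² MW⁻¹ — tens of
femtonewtons at experimental intensities.

The same analysis runs on recorded traces via
`DynamometerModel.from_files(...)` or the CLI:

```sh
wgmdyn simulate --duration 315 --seed 1 --out trace.tsv
wgmdyn detect --in trace.tsv --out events.json
wgmdyn quantify --events events.json --out thermo.json
wgmdyn modevolume --radius-um 42.5 --Lambda 800 --out mode.json
wgmdyn report --trace t1.tsv --intensity 100 --trace t2.tsv --intensity 200 --out report.json
```

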