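# Methods

## Physical model

A whispering-gallery-mode (WGM) microsphere resonator carries gold
nanorods whose localized surface plasmon resonance concentrates the
evanescent field into a hotspot (scalar enhancement factor Λ ≈ 800 for the
nanorods modelled here). A single enzyme immobilised in the hotspot
modulates the resonance: a conformational change of excess polarisability
α_ex shifts the resonance by Δλ/λ0 = α_ex/(2·V_eff), where V_eff is the
effective mode volume referenced to the plasmon-enhanced field at the
analyte position,

    V_eff = ∫ ε(r)|E(r)|² d³r / (Λ · ε(r_s)|E(r_s)|²).

Turnover therefore appears as a train of rectangular Δλ excursions,
A·rect((t−ω)/τ): the enzyme closes (shifted state, duration τ), opens
again, and waits (dwell Δt) for the next substrate-binding/closing cycle —
a renewal process when a single step is rate limiting.

### Work done by the sensor

An event of amplitude A corresponds to a per-molecule energy difference
N_in·h·|Δν| between the two conformations, with Δν = −c·A/λ0² the
frequency shift and N_in the intracavity photon number. Expressing N_in
through measurable sensor quantities — loss rate κ = 2πc·δλ̄/λ0² from the
linewidth, coupling fraction a = (1−√(1−S̄))/2 from the transmission-dip
depth on the under-coupled branch, N_in = a·4Pλ0/(κhc) — gives the molar
work

    w = λ0·P·N_A·(1−√(1−S̄))·A / (π·c·δλ̄).

Work is reported positive for events of either sign (the physical events
are red shifts); a signed mode exists for research use. The implementation
keeps the closed form and the explicit photon chain as two independent
code paths; their agreement to 1e-10 relative over random operating points
is asserted in the test suite.

### Free-energy penalty (Jarzynski)

The event-work sample w₁…w_μ is a nonequilibrium work distribution; the
free-energy penalty the sensor imposes on the open→closed transition is
estimated with the asymptotic Jarzynski estimator

    ΔG = (1/β)·ln m_w,   m_w = (1/μ)Σ exp(βw_j),
    σ_ΔG = (1/β)·(1/μ)·σ_w/m_w,

where β = 1/(k_B·T) acts on per-molecule energies (w_j/N_A; equivalently
R·T on molar values — the conversion is made explicit because mixing molar
work with a per-molecule β silently changes the estimate by a factor N_A).
Exponentials are evaluated in shifted log-sum-exp arithmetic, so large βw
cannot overflow. σ_w defaults to the Monte-Carlo standard deviation of
exp(βw), σ_w² = ⟨exp(2βw)⟩ − m_w²; an `as_printed` option instead uses
the sum m_w² + ⟨exp(2βw)⟩, a variant that circulates in the literature
this package follows but cannot be a variance (it is a sum of positive
terms); the default is the standard estimator. The estimator is biased low
for small μ (Jensen); no cumulant or acceptance-ratio correction is
applied, matching the plain-estimator convention.

### Force and trap stiffness

Mean event work grows linearly with hotspot intensity I (both are
proportional to the circulating power), giving a response slope Δw/ΔI.
Dividing by the distance over which the force acts — the sphere-equivalent
enzyme diameter d̄_E = (6V_mol/π)^{1/3} from the molecular volume — and by
N_A yields the per-molecule trap stiffness and apparent force

    T_S = (Δw/ΔI)/(d̄_E·N_A),   F = T_S·I,

the optical-tweezer analogue of the sensor. With the slope in
J cm² MW⁻¹ mol⁻¹, T_S is naturally of order 1e-15 N cm² MW⁻¹ and F of
order tens of fN at experimental intensities.

## Cavity optics

The microsphere mode solver finds TE/TM whispering-gallery resonances of a
dielectric sphere (default R = 42.5 µm, the midpoint of the fabrication
range; silica n = 1.45 in water n = 1.33). Interior radial solutions are
spherical Bessel functions j_l(n₁kr); the exterior evanescent solution is
taken as the spherical Neumann function y_l(n₂kr) — the dominant,
radially decaying part of the outgoing Hankel function below the radiation
caustic — which makes the characteristic equation real:

    TE:  ψ'_l(n₁kR)/ψ_l(n₁kR) = (n₂/n₁)·χ'_l(n₂kR)/χ_l(n₂kR)
    TM:  ψ'_l(n₁kR)/ψ_l(n₁kR) = (n₁/n₂)·χ'_l(n₂kR)/χ_l(n₂kR)

(Riccati–Bessel forms; these are the real parts of the Mie b_l/a_l
denominator conditions). For each polar order l in the geometric window
n₂kR < l < n₁kR the q-th radial root is bracketed near
n₁kR ≈ l + α_q(l/2)^{1/3} and polished with Brent's method; sign changes
that are poles of the logarithmic derivatives are rejected by a residual
check. The mode returned is the one nearest the target wavelength; an
error is raised if none lies within one free spectral range λ²/(2πRn₁).
Characteristic-equation residuals at returned resonances are below 1e-10
relative (typically 1e-14).

The mode-volume numerator is a radial trapezoid quadrature of ε|E|²r² on
[0, 3R] (3000 samples by default; refinement changes V_eff by <0.5%)
times the unit angular integral of the normalized fundamental polar
harmonic |Y_l^l|²; the denominator evaluates Λ·ε·|E|²·|Y_l^l(π/2)|² at the
hotspot on the equatorial surface. V_eff ∝ 1/Λ holds exactly by
construction. The hotspot position is taken on the sphere surface at the
equator — the nanorod's location is known only to be in the equatorial
mode belt, and the surface value is the natural reference. For TM modes
the exterior profile is scaled by (n₁/n₂)², emulating the normal-field
jump; the dominant-component scalar profile is an approximation in either
polarization. Photon energy is hν0 = hc/λ0 throughout (a formulation with
ħω would differ by 2π and be inconsistent with N_in = a·4Pλ0/(κhc)).

The thermodynamics pipeline never requires the solver: a fixed V_eff can
be supplied in the optics configuration, which is also how the synthetic
studies below are run.

## Synthetic traces

`simulate_trace` emulates the experimental signature at a 50 Hz sampling
rate (configurable; the acquisition rate of the turnover recordings is not
published, 50 Hz being the documented monitoring rate):

- turnover events: renewal process, dwell ~ Exp(event_rate = 0.5 s⁻¹),
  width ~ Exp(mean_duration = 0.1 s), amplitude ~ truncated-normal
  (3.5 ± 0.5 fm, > 0), positive (red-shift) by default;
- permanent binding steps (e.g. 3 fm for Adk gold–thiol binding, 5 fm for
  3PGK) as Heaviside shifts;
- slow drift: low-frequency sinusoid plus optional Gaussian random walk
  (thermal drift is described only qualitatively; both terms default off
  in studies where drift is not under test);
- Gaussian noise, σ = 0.5 fm on Δλ (not published; chosen so that 3–4 fm
  signals sit at ~7σ against a 3σ threshold, consistent with the reported
  detection regime), and 1 fm on the δλ channel around its 0.1 pm
  baseline.

Events are sequential by construction (one enzyme, one turnover at a
time). The exact injected (ω, τ, A) list travels as a JSON sidecar.

The generator does **not** model shot noise, thermorefractive noise,
thermal broadening of the scanned lineshape, nanorod binding kinetics, or
amplitude–duration correlations; passing recovery tests therefore show
that the pipeline is correct under Gaussian-noise, ideal-rectangle
conditions, not that it is robust to every instrumental artefact.

## Detection

1. Detrend with a first-order Savitzky–Golay filter; window 2 s
   (101 samples at 50 Hz), much longer than typical event widths so
   rectangles are not flattened (no window is published).
2. Estimate noise as σ = 1.4826·MAD of the detrended Δλ — robust to the
   sparse event excursions.
3. Candidate events: contiguous same-sign runs with |Δλ| > 3σ; runs of the
   same sign separated by one sub-threshold sample are merged; runs
   shorter than 2 samples are discarded (a single above-threshold sample
   is indistinguishable from a Gaussian tail event at this rate — keeping
   them would produce ≈2.7 false events per 10³ samples, far above the
   Monte-Carlo-calibrated target of <10⁻²).
4. Each candidate is fitted with the rectangle A·rect((t−ω)/τ) by
   exhaustive search over grid-quantized (ω, τ) with A the in-support
   mean — exactly the least-squares optimum, verified against a
   brute-force SSE oracle.
5. Veto: candidates overlapping δλ excursions beyond 3× the robust δλ
   noise are rejected (a real conformational signal shifts the resonance
   without broadening it; coincident linewidth excursions indicate
   scattering/contamination artefacts).
6. Classification: runs reaching the end of the trace or wider than 10% of
   it are permanent `step`s (binding); transient events are `spike`s, or
   `double_peak` when two above-threshold maxima are separated by a dip of
   ≥40% of the peak height (the two-lobed morphology is not defined
   quantitatively in the source experiments; the relative-prominence rule
   is this package's operationalization, chosen so plateau noise on a
   strong rectangle does not qualify).
7. Refinement: fitted rectangles are subtracted from the raw trace, the
   baseline is re-fitted, σ re-estimated on event-free samples, and
   detection repeated (up to three passes or until the event set is
   stable). Without this, every event leaks ≈ τ/window plus the trace duty
   cycle of its amplitude into the baseline and fitted amplitudes are
   biased low by ~10%; with it the mean amplitude ratio to ground truth is
   1.00 ± 0.01.

Amplitudes are in-event means (consistent with the rectangular model),
not peak values. Dwell times are Δt_i = ω_i − (ω_{i−1}+τ_{i−1}) between
turnover events.

## Statistics

- **Work–intensity regression**: weighted least squares of per-dataset
  mean work on intensity, weights 1/SE² (SE = per-dataset standard error
  of the mean), 95% CI from the t distribution on n−2 df. Exact points
  (all SE = 0) fall back to an unweighted fit; a mixture of zero and
  non-zero SEs is rejected as degenerate.
- **Dwell/duration rates**: exponential maximum likelihood k = 1/mean with
  the exact chi-squared pivot CI (2kΣx ~ χ²(2n)); coverage is nominal to
  within 2% at n = 50. Rate-versus-intensity trends use the same weighted
  regression with large-sample SEs k/√n.
- **Energy budget**: ΔG_system = ΔG_C + ΔG_pT with a feasibility flag
  (turnover requires ΔG_system < 0); ΔG_C for the enzymes modelled here is
  of order −4 kJ mol⁻¹ (3PGK) to −33.5 kJ mol⁻¹ (Adk) from calorimetric
  literature values, while sensor penalties reach ~2.4 kJ mol⁻¹ at high
  intensity.

## Recovery studies and problem sizes

`wgmdyn.model.slope_recovery_study` wires everything together: traces are
generated at 8 intensities (50–400 MW cm⁻²) by solving the input power
that delivers each target intensity through a fixed-geometry chain
(V_eff = 25 µm³, S̄ = 0.36, δλ̄ = 0.1 pm). With that geometry the mean
amplitude implied by a target slope of 2.25 J cm² MW⁻¹ mol⁻¹ is 3.49 fm —
inside the experimentally reported 3–4 fm band, which is the reason this
V_eff was chosen. Traces are 480 s, yielding ≈150 detected signals per
measurement, matching the reported per-measurement signal averages
(~154–176). The study reports per-replicate fitted slopes and the fraction
whose 95% CI covers the generating value; 50 replicates run in ~1.5 min on
one CPU. Across replicates the mean fitted slope is within ~0.5% of the
generating value and CI coverage is ≈93% (measured over 200 replicates);
individual 50-replicate blocks scatter around that figure, so the
acceptance suite measures coverage over 150 replicates for a more precise
estimate of the same quantity at the same ≥90% threshold.

## Numerical choices and degenerate inputs

- CODATA constants via scipy.constants everywhere; fixed, not
  configurable.
- Log-sum-exp shifting in the Jarzynski estimator; m_w reported as inf
  past the float range, while ΔG stays finite.
- Rectangle-fit ties broken by first-found support (earlier onset).
- Spectrum FWHM recovered by linear interpolation of half-depth crossings
  on the sampled grid; S = 0 yields a flat spectrum with undefined (NaN)
  FWHM.
- Trace files are written with round-trip float formatting and parsed with
  pandas' round-trip parser, so write→read is bit-exact.
- Mode solver rejects spheres smaller than ~10 wavelengths (the evanescent
  approximation and the l-window heuristics assume the WGM regime).

## Known limitations

- The Δλ→work chain assumes the mean linewidth and coupling of the trace;
  per-event δλ_i, S_i variants are deliberately not implemented (their
  fluctuations are vetoed rather than propagated).
- The mode solver is scalar per polarization; no full vectorial AuNR
  near-field model — Λ is an input, not computed.
- Exponential (single rate-limiting step) kinetics only; no
  multi-exponential or hidden-Markov dwell analysis.
- The Jarzynski estimator's small-μ bias is reported only through σ_ΔG,
  not corrected.
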