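# Methods

This note documents the models, numerical choices and defaults behind
`microdma`: what the instrument twin simulates, how the analysis inverts its
recordings, what the synthetic data do and do not emulate, and where the
design was genuinely open.

## Sample models (`microdma.rheology`)

A sample is a linear-viscoelastic half-space described by its complex shear
modulus G*(ω) = G′ + iG″. Supported parameterizations: elastic (G_e),
Kelvin–Voigt (G_e, η), standard linear solid (G_e + one Maxwell branch),
generalized Maxwell (G_e + any number of branches (G_i, τ_i); zero branches
degenerates to elastic), and a springpot c_α(iω)^α with 0 < α < 1. All
moduli are shear moduli in Pa; the single conversion to indentation
(compression) modulus happens in the contact module, mirroring the single
ν-based conversion of the measurement convention.

For simulation, each Maxwell branch dσ/dt + σ/τ = G dε/dt is advanced by
its exact solution under piecewise-linear strain,
σ(t+Δt) = σe^{−Δt/τ} + G(Δε/Δt)τ(1−e^{−Δt/τ}), which is unconditionally
stable — necessary because one control rate must serve sweep frequencies
spanning 2.3 decades. The Kelvin–Voigt dashpot uses the per-step average
rate Δε/Δt; its only error is a half-step rate lag, negligible at the twin's
control rate (≲0.2° at 10 Hz with 0.1 ms steps). The springpot has no
finite-dimensional state, so it is deliberately frequency-domain only: a
Prony approximation inside the twin would blur the exactness that the
recovery tests rely on. A property test verifies that steady-state
sinusoidal simulation reproduces |G*| and arg G* from the frequency-domain
evaluation within 0.5 % / 0.5° for every supported model across the sweep
band.

## Contact mechanics (`microdma.contact`)

Plain Hertzian spherical contact, no adhesion, no finite-thickness
correction, half-space isotropic and homogeneous at the probe scale. The
viscoelastic forward force is the hereditary (Lee–Radok) form: the load
responds to the history of h^{3/2} through the shear relaxation kernel with
the geometric factor 8√R/(3(1−ν)); for a constant modulus this reduces
exactly to F = (4/3)E_eff√R h^{3/2}, E_eff = 2G/(1−ν).

The inversion linearizes about the static depth: S = dF/dh = 2E_eff√(Rh₀),
giving G′ = (1−ν)F₁cos φ/(4h₁√(Rh₀)) and G″ with sin φ. Because twin and
inversion share the same contact law, the forward–inverse loop closes to the
linearization error, which is O(h₁/h₀): a brute-force sweep over amplitude
ratios confirms relative error ≤ 2·(h₁/h₀) up to h₁/h₀ = 0.05. Default
quality bounds: h₁/h₀ ≤ 0.05 (linearity), h₀/R ≤ 0.4 (sphere geometry),
h₀ ≤ 40 µm (maximum static depth). Violations flag rows; they never abort
an analysis.

## Interferometric readout (`microdma.interferometer`)

Two-beam fringe model I = I₀[1 + V cos(4π(L₀−d)/λ_t)] with wavelength
modulation λ_t = λ₀ + Δλ sin(2πf_m t). Defaults: λ₀ = 1550 nm (single-mode
telecom fiber), L₀ = 300 µm, V = 0.6, f_m = 2 kHz, and Δλ chosen so the
modulation index ψ = 4πL₀Δλ/λ₀² equals 2.63, the balanced point where
J₁(ψ) = J₂(ψ). The simulator uses the exact instantaneous wavelength, so
second-order modulation terms the demodulator ignores are present in the
signal.

Demodulation is a phase-generated-carrier arctangent: lock-in mixing at f_m
and 2f_m (4th-order Butterworth lowpass at f_m/4, applied forward-backward
for zero phase), division by the known Bessel factors, atan2, unwrap. The
scheme is ratiometric — I₀ and V cancel — which a test verifies by scaling
the intensity arbitrarily. A second pass re-evaluates ψ per sample from the
first-pass deflection (ψ scales with the instantaneous cavity length), which
removes the dominant systematic for multi-fringe excursions; the noise-free
round trip over >3 fringes is then ~0.03 nm RMS. Quality guards: median
fringe envelope below 5 % of the mean intensity (unusable visibility — such
probes are discarded in practice), a localized envelope collapse below 78 %
of the median (fringes moved faster than the demodulation band; the phase
there is untrustworthy), and unwrap steps approaching π.

The analysis pipeline normally consumes deflection directly
(`fidelity="deflection"`); raw-intensity simulation is an opt-in fidelity
level requiring a recording rate ≥ 10·f_m, kept optional so routine tests
stay fast while the readout path is still exercised end to end.

## Instrument twin (`microdma.twin`)

Coupled per control step (default 10 control steps per recorded sample, i.e.
0.1 ms at the 1 kHz recording rate): controller → optional stick-slip
transmission → quasi-static force balance k·d = F_contact(h) with
h = z_p − d − z_surface, solved by safeguarded Newton (the residual is
strictly monotone) → measurement d_meas = sens·d + noise + drift·t.
Cantilever inertia is neglected: the band ends at 10 Hz, far below any
cantilever resonance.

Protocol state machine: constant-speed approach with debounced contact
detection (threshold 5× the load noise RMS with a 10 nN floor, 20 ms
debounce — which also rejects short spurious force spikes from lumen
contamination), linear load ramp (5 s) to the static setpoint, hold, one
oscillation segment per grid frequency in increasing order, retract.
Segment lengths are planned once and shared with the file reader, so label
reconstruction for legacy files cannot drift from the generator. Identical
configuration and seed give a bit-identical recording (all noise comes from
one seeded generator, consumed in a fixed order).

The load controller is a PI on the load error driving piezo velocity,
gain-scheduled on the twin's own plant linearization g = kS/(k+S) so that a
fixed fraction α = 0.2 of the error is corrected per control step regardless
of sample stiffness; integral time 20 ms, anti-windup clamp, 1 mm/s slew
limit. This holds the static load within 1 % and tracks the commanded
oscillation amplitude within 2 % up to 10 Hz across the supported modulus
range. Faults are explicit: setpoint unreachable within the 500 µm piezo
travel, and deflection divergence.

Protocol defaults follow the measurement procedure: static load 300 µN,
oscillation amplitude 10 µN, 15 log-spaced frequencies 0.05–10 Hz
(full band) or 5 over 0.5–10 Hz (fast in-situ mode), 5 periods per
frequency, ≥60 s hold, 100 µm retraction. The source protocol prints the
load numbers without units; the µN reading — consistent with a 60–70 N/m
cantilever and kPa-scale samples — and the 150 µm bead radius (which must
pass an 18G needle lumen of ~1.1 mm) are package assumptions, as are the
1 kHz recording rate and the piezo travel. One consequence worth knowing:
with these defaults, samples softer than ≈18 kPa indent beyond 40 µm and
h₀/R > 0.4, so their rows carry the geometric advisory flags. Inside the
twin this costs no accuracy (twin and inversion share the exact Hertz
model); on a real instrument those flags mark genuine model risk.

Noise defaults: 0.3 nm RMS white deflection noise per control step and
1 nm/s linear drift, typical of fiber-interferometric readouts; a
multiplicative deflection-sensitivity miscalibration can be injected and is
recovered by the glass calibration (linear fit of deflection vs piezo
position over the loading ramp only — the hold is excluded because drift at
a stationary piezo would bias the slope). Slopes deviating from 1 by more
than 0.1 signal probe rejection.

### Needle-friction artifact (off by default)

Shaft friction that hampers probe motion at very low speed is modeled as a
rate-state stick-slip on the piezo-to-probe transmission: the junction sets
only after the smoothed commanded speed (50 ms EMA, feedback wind-up spikes
clipped at 3× the threshold so they cannot masquerade as sliding) stays
below v_stick = 8 µm/s for a 0.4 s dwell; once stuck, the probe is released
by 0.5 µm of transmission wind-up and re-sticks immediately while still
slow. The dwell gate is what makes the artifact frequency-selective: brief
turning-point crossings at fast oscillation never stick, while the lowest
sweep frequencies spend whole dwell periods below threshold and degenerate
into stick-slip cycles. With the defaults, an NP-mode sweep of the soft SLS
fixture shows a corrupted phase (loss modulus off by ~8 %) and a waveform-
distortion flag at 0.5 Hz only — the documented low-frequency unreliability
of the loss modulus — while every faster frequency stays clean.

## Analysis (`microdma.analysis`)

Per oscillation segment: discard the first period (transient; configurable),
form h(t) = z_p − d − z_contact with z_contact from debounced detection on
the approach (extrapolated back through the cantilever compliance by
threshold/k), then fit a·sin + b·cos + c + e·t to the load and indentation
channels at the known drive frequency. The fit equals the single-bin
discrete Fourier projection on integer-period drift-free segments to 1e−10
relative (tested), and the drift term makes the amplitude robust to slow
creep within a segment. φ is the difference of fitted phases, so any common
convention or time shift cancels (tested). h₀ is the fitted offset of the
segment — not the pre-oscillation hold value — because long low-frequency
segments drift.

Small negative φ within 4× the fit's own phase-noise bound (floor 0.2 mrad)
is clipped to zero and flagged rather than propagated as negative loss
(passivity prior); larger violations or φ ≥ π/2 are flagged as unreliable
but still reported. Waveform distortion — fit residual RMS above 10 % of the
fitted amplitude on either channel — flags rows whose phase cannot be
trusted; this is the flag the stick-slip artifact trips. Repeated sweeps are
averaged arithmetically per frequency (no weighting), dispersion is the
sample standard deviation (zero by convention for n = 1), and QC-flagged
rows are excluded from averages unless requested otherwise.

## What the synthetic data do not emulate

The generator reproduces the measurement chain, not tissue. Real nucleus
pulposus and elastomer samples bring heterogeneity, nonlinearity beyond the
linear viscoelastic regime, poroelastic fluid flow, adhesion, substrate
effects, osmotic swelling and degradation over the measurement — none of
which are modeled. Passing recovery tests therefore demonstrates that the
analysis correctly inverts what the instrument model produces (including
its noise, drift, control dynamics and friction artifact); it does not
validate the Hertzian linear-viscoelastic idealization against real tissue.
Reported tissue values (e.g. nucleus pulposus storage moduli of a few kPa
in situ) require the physical instrument and sample.

## Problem sizes and runtime

Default test and acceptance runs use the full study protocols: full-band
recordings are ≈390 s of simulated time (≈390k samples at 1 kHz, 3.9M
control steps; ~1 s wall time each through the compiled inner loop).
Recovery claims are checked on three ground-truth models spanning
2–55 kPa storage — a soft SLS in the measured tissue range, a two-branch
generalized Maxwell solid, and a stiff SLS — noise-free and as 5-seed
averages at default noise. Unit tests use shortened protocols (reduced hold,
fewer frequencies) wherever the property under test does not depend on the
full sweep.

## Known limitations

- Springpot samples cannot drive the twin (frequency-domain only, by
  design).
- Viscoelastic unloading/separation (Ting's problem) is not modeled; the
  contact strain is simply clamped at zero out of contact. Analysis segments
  never rely on out-of-contact physics.
- The stick-slip artifact is a phenomenological transmission model tuned to
  reproduce the documented failure mode, not a calibrated friction model of
  a needle shaft.
- Readout drift is linear; real interferometer drift is slow but not
  necessarily linear. A consequence the twin reproduces honestly: with
  drift enabled, a sufficiently long approach can fake a contact through the
  rising deflection offset.
- The demodulator's envelope-collapse guard (78 % of median) separates the
  supported deflection bandwidth from aliased fringe jumps with a thin
  margin; deflection slews near the demodulation band edge should be
  avoided rather than trusted to the guard.
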