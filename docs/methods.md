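# Methods

This note documents the models behind `ionobeat`, the parameters that
matter, the numerical choices, and the limits of what the synthetic
experiments demonstrate.

## Thermoacoustic source model

Absorbed dose D(r) [Gy] converts to initial pressure under stress
confinement as

    p0(r) = D(r) · Γ(r) · ρ(r)

with Γ = βc²/Cp the Grüneisen parameter (β the volumetric thermal-expansion
coefficient [K⁻¹], c the speed of sound, Cp the isobaric heat capacity).
Water at 20.5 °C uses ρ = 998 kg m⁻³, c = 1484.1 m s⁻¹, Γ = 0.11; diluted
India ink takes water's acoustic properties and differs only optically
(µ_a = 3.7×10³ mm⁻¹ at 1% concentration, applied flat over the 300–700 nm
band since only the 632.8 nm value is established).  Polyimide foils carry
c = 2400 m s⁻¹ (which sets c_ref and hence the solver time step) with
literature-typical ρ = 1420 kg m⁻³ and Γ = 0.9; these two are configurable
since they are not tightly constrained.  The clinical scenario uses a
hepatic tumor (c = 1556.9 m s⁻¹, ρ = 1041 kg m⁻³, Γ = 0.20) inside liver
(c = 1578 m s⁻¹, ρ = 1060 kg m⁻³, Γ = 0.20); the tumor absorbs light like
India ink, the liver like water.  Temperatures are recorded per scenario;
material values are understood as already evaluated at that temperature.

## Proton depth dose

Monte Carlo particle transport is replaced by a Bortfeld-style analytic
curve in water-equivalent depth w:

    D(w) ∝ (R0−w)^(1/p−1) + (β̃ + γβ̃p)(R0−w)^(1/p),  w < R0,

with β̃ = 1.2 m⁻¹, γ = 0.6, numerically convolved with a Gaussian of
straggling width σ = s·0.012·R0[cm]^0.935 cm.  The singular term is
bin-averaged exactly through its antiderivative before smoothing.  The
range-energy law R0 = a·E^p and the straggling scale s are calibrated once
(nested 1D root finds) against three anchors of the study setup: the 22 MeV
80% distal fall-off at 4.92 mm past the tank entrance, the 130 MeV Bragg
maximum at 11.4 cm, and the 430 µm axial FWHM at 22 MeV.  The solved
constants are a = 2.2043×10⁻⁵ m MeV⁻ᵖ, p = 1.7588, s = 1.0748 — close to
textbook water values, which is the intended sanity check.  Upstream
degraders (11.4 µm Ti, 6 cm air, 50 µm polyimide foils) shift the curve via
water-equivalent ratios (3.0, 1.07×10⁻³, 1.40).  The clinical liver and
tumor are treated as water-equivalent for ranging (the study irradiated a
water-equivalent phantom), so the 130 MeV anchor fixes the geometry
directly.

The ripple filter becomes a uniform water-equivalent range-shift mixture
U[0, t_max]; t_max = 2.373 mm is solved so the spread beam's 90% distal
fall-off lands at 3.04 mm.  Lateral scattering in the aluminum sawtooth is
parametric: the spot σ doubles by default.  Beam spots are Gaussian; the
22 MeV beam uses σ = 0.958 mm (≈4 mm² focal area) and the clinical 130 MeV
pencil beam σ = 5 mm, a typical isocenter spot for that energy (the
study's beamline spot is not printed).  Dose maps are the on-axis value
(1D) or the central slice (2D) of the 3D Gaussian beam, in physical Gy.

## Luminescence photon transport

Photon emission density is proportional to local deposited energy times
the light yield Y [photons/MeV]; wavelengths follow λ⁻² on 300–700 nm
(mean 444.8 nm), directions are isotropic, and transport is
absorption-only: each photon flies a straight exponential path through the
axially layered µ_a(λ) profile and deposits its full energy hc/λ at the
absorption point; photons leaving the domain (or exceeding a 1 km path cap
in near-transparent media) are tallied as escaped.  Scattering,
refraction, re-emission and any physical mechanism of the luminescence are
not modelled — the model is the effective scintillation-equivalent one,
which is all the study's printed parameters support.

Because the simulation grids are reduced-dimensional, the MC distinguishes
energy *bookkeeping* (exact, unweighted: emitted = absorbed + escaped to
machine precision) from *density estimation* on the grid:

* 1D (on-axis) maps weight each deposit by the closed-form lateral
  dilution of a Gaussian emitter column, w(L) = 1 − x√π e^{x²}erfc(x) with
  x = L/(√2σ) and L the emitter-to-deposit axial distance (w(0) = 1,
  w → σ²/L² far away).  Without it, a laterally-infinite slab tally
  overestimates the absorber-interface spike by orders of magnitude.
* 2D (central-slice) maps track the collapsed z coordinate explicitly and
  apply a Gaussian slice kernel, calibrated so in-beam local deposits keep
  unit weight while photons that wandered far in z are diluted away.

## Acoustic propagation

First-order linear acoustics (heterogeneous ρ0, c; lossless — the study
models no attenuation) solved with a k-space pseudospectral scheme:
spectral gradients on staggered grids, exact-propagator correction
sinc(c_ref|k|Δt/2), leapfrog time stepping with a half-step first velocity
update, split-field quartic-profile absorbing boundary strips (20 points,
α = 2).  The time step follows CFL = 0.3 with c_ref the maximum c in the
domain (Δt = 3.125 ns for the tandem grids).  Validation: in homogeneous
1D the recorded trace matches the d'Alembert solution to <0.1%; a compact
2D source decays as 1/√r to within 0.5%.  Disk sensors average their
aperture grid points; point sensors sample on axis.  Impulse responses are
resampled to the 156.25 MHz acquisition rate and convolved with the beam
time structure (charge-preserving train resampling, per-proton
normalization); the detector is a causal second-order Butterworth
band-pass, 0.15–15 MHz, in cascaded second-order sections.

Grids: the 22 MeV scenarios use 25 µm axial / 50 µm lateral spacing as in
the study.  The clinical 2D grid is coarsened to 100 µm axial / 400 µm
lateral (domain 28.8 cm × ±1.92 cm): the analysed band lies below 0.5 MHz
(wavelengths > 3 mm), so this sacrifices nothing relevant while keeping a
29 cm domain tractable on one CPU.  A 1D on-axis clinical mode exists but
is *not* the default for beat analysis: in 1D nothing decays geometrically,
so the dose-plateau pedestal arrives at full amplitude and its sharp distal
onset contaminates the beat phase (≈ +2 mm bias vs ≈ +1.3 mm in 2D).

## Beam time structures

Square trains build pulses by fractional bin coverage (integral exact);
Gaussian pulses are truncated at ±5σ and renormalized (10⁶ protons ↔
0.16 pC).  The synchrotron spill is a 50 ms burst of Gaussian micro-pulses
(σ = 19.75 ns) every 228 ns (4.39 MHz), each scaled by an independent
Poisson(1) draw at a mean fluence of 3.2×10⁹ protons/s; the time axis
refines to ≥8 samples per σ (2.13 ns).  Arrival-time jitter is available
but off by default, matching the amplitude-only reading of the spill
fluctuation.  All stochastic stages are `numpy` `default_rng`-seeded and
bit-reproducible.

## Signal analysis

* **Wavelet denoising**: Daubechies-38, 10 levels (traces zero-padded to
  the required support and cropped back); hard threshold on the level-5
  detail at 10% of its maximum; detail levels whose band reaches above
  10 MHz zeroed (levels 1–3 at 156.25 MHz sampling).
* **Amplitude at f₀**: half-open analysis window on the sample grid
  (default 21–22.5 µs for the tandem scenarios, excluding the tank-window
  signal), zero-padding to df = 5 kHz, magnitude at the bin nearest f₀,
  scaled so a unit sinusoid filling the window reads 1.
* **Phase shift**: both traces band-passed to ±10% of f₀ (causal SOS
  Butterworth), analytic signals via Hilbert transform, phase = circular
  mean over the window of arg(a_test·conj(a_ref)) in (−180°, 180°]; a
  quarter-period delay reads −90°.  The study's own sign convention is not
  stated, so signed comparisons against its printed −50° plateau are
  qualitative only.
* **Spectrum-beat distance**: magnitude spectrum → low-pass along the
  frequency axis (2nd-order SOS Butterworth) with the cutoff expressed as
  a maximum retained quefrency (default 120 µs, the stated time-of-flight
  scale) → Fourier transform of the envelope → quefrency axis mapped to
  distance by d = c·q → global maximum beyond the zero-quefrency lobe
  (d > 2 mm), with parabolic sub-bin refinement.  For clinical
  synchrotron signals two refinements are essential: the envelope FT is
  restricted to the band where the interfering sources overlap
  (60–500 kHz — the beats visibly live below ~0.5 MHz) with a cubic
  polynomial detrend inside the band, because the Poisson pedestal of the
  spill micro-structure otherwise buries the beat under broadband
  quefrency noise; and the peak search carries the physical prior that
  the Bragg peak lies inside the 2 cm tumor (d ≤ 25 mm).  A trace without
  an echo pair returns an explicit no-beat result (boundary-hugging or
  sub-floor maxima).

## Synthetic acquisition campaign

`simulate_acquisitions` adds white Gaussian detector noise to a base trace
(n = 3000 by default); `grouped_stats` partitions into 30 groups of 100,
evaluates the statistic on group means, and quotes t-based 99% intervals
(29 dof).  The default noise level is configurable; the study's true
per-acquisition SNR is unknown, so coverage and scaling tests use
synthetic levels.  What these fixtures do *not* emulate: correlated
electronic noise, drift, beam-current wander between acquisitions.

## Known systematic of the clinical beat recovery

On the reconstructed signals the beat estimator recovers 15.7–15.9 mm for
a geometric Bragg-to-edge distance of 14.49 mm, i.e. a relative range
error of ≈1.1–1.2% — above the ≈0.3% the original study reports
(14.88/14.68 mm).  Cross-spectrum group-delay analysis between the
isolated direct and tumor-entrance pulses gives the same separation, so
this is a property of the physics reconstruction, not of the envelope
processing: the acoustic phase centre of the direct signal sits at the
*distal dose fall-off* (≈1.2 mm beyond the Bragg maximum for the ≈1.26 mm
straggling width that follows from the 22 MeV calibration anchors), while
the ground truth is referenced to the Bragg maximum itself.  The recovered
value lies inside the 12.5–20 mm beat feature the study displays, and the
σ-dependence means the bias shrinks for sharper distal edges.  Users
should read the beat distance as "tumor edge to distal dose edge" on this
class of signals, which is arguably the more treatment-relevant quantity.

## Degenerate inputs and numerical conventions

Zero-charge beams, zero light yields and zero-noise campaigns all return
exact zeros rather than erroring; empty trains, CFL violations, grid
mismatches, out-of-domain sensors, windows outside traces, vanishing phase
references and beams ranging out of the domain raise `ValueError` with the
offending stage named.  Analysis windows are half-open on the sample grid.
FFTs are `scipy.fft`; spectra of real traces use rfft throughout.  HDF5
(h5py) stores traces and maps with axis metadata; CSV mirrors the on-axis
profiles and analysis tables; scenario configs round-trip through YAML
with units stated in-file and a schema version.
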