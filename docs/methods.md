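# Methods

## Physical model

An implanted insulated wire exposed to the RF field of an MR scanner picks up
a voltage at its exposed distal end (the lead tip).  The standard model is a
line integral of the tangential incident electric field along the lead,
weighted by a complex transfer function:

    V = ∫₀ᵈ h(l) · Et(l) dl,        ΔT ∝ |V|²,

with l the arc length from the lead tip and d the lead length.  The quadratic
ΔT law reflects Ohmic deposition of the tip current into tissue (SAR is
quadratic in E).  The proportionality constant between |V|² and degrees
Celsius is unknown a priori; everywhere outside the fitting module ΔT is
reported in arbitrary units with that constant fixed at 1.

Two transfer-function families are implemented:

* **Simple exponential model (SEM)**: h(l) = e^(−ikl).  The single parameter
  is the complex wavenumber k of current propagation along the wire.  k = 0
  gives the unity transfer function, for which ΔT ∝ E²d² without bound.
* **Transmission line model (TLM)**: the capped proximal (device) end reflects
  the travelling wave with coefficient Γ,

      h(l) = e^(−ikl) · (1 − Γe^(−2ik(d−l))) / (1 − Γe^(−2ikd)),

  normalized so h(0) = 1.  Γ = 0 recovers the SEM; Γ = 1 models an
  electrically open (insulator-capped) end.  An equivalent parameterization
  from the capped end (l′ = d − l) is provided; for a symmetric incident
  field the two give identical |V|, which is a test invariant.

## Wavenumbers and sign conventions

A lossy medium (permittivity ε, conductivity σ, permeability μ = μ₀) has

    kR =  ω√(εμ/2)·√(√(1+(σ/εω)²) + 1),
    kI = −ω√(εμ/2)·√(√(1+(σ/εω)²) − 1),

where the second radicand is evaluated as (σ/εω)²/(√(1+(σ/εω)²)+1), an
algebraically identical form that avoids cancellation at small loss tangents.
The package convention is kR ≥ 0, kI ≤ 0, so e^(−ikl) always decays.

The wavenumber of current on an insulated conductor embedded in conductive
tissue comes from insulated antenna theory (the King wavenumber):

    k = ki·[1 + F(kt·b)/ln(b/a)]^½,   F(z) = H₀⁽¹⁾(z)/(z·H₁⁽¹⁾(z)),

with ki the (real) insulator wavenumber, kt the embedding-medium wavenumber,
and a, b the conductor and insulation radii.  The antenna-theory literature
uses the opposite loss convention, so kt is conjugated (Im ≥ 0) **only**
inside the Hankel argument; the principal square root with positive real part
is taken and the result stored with kI ≤ 0.  The theory assumes a conductive
embedding medium; σ = 0 is accepted with a warning because the formula
remains evaluable.  The thick-insulation correction decays only
logarithmically (ε ≈ |F|/(2 ln(b/a))), which the tests assert as a law rather
than as a small absolute deviation.

Physical constants: ε₀ = 8.8541878128e−12 F/m, μ₀ = 4π×10⁻⁷ H/m,
c = 1/√(ε₀μ₀), gyromagnetic ratio 42.58 MHz/T (so 1.5 T → 63.87 MHz, 3 T →
127.74 MHz).  Any frequency can be passed explicitly to decouple from the
field strength.

## Resonant length

With u = −kI/kR (loss ratio) and g = kR·d/π (length in half-wavelengths),
setting dΔT/dd = 0 gives transcendental equations whose smallest positive
root lies in [½, 1]:

* SEM:  −u·e^(−πug) + u·cos(πg) + sin(πg) = 0
* TLM, Γ = 1:  tan(πg) + u·tanh(πug) = 0

so d_res = (λ/2)·g(u) is always between λ/4 and λ/2 in the conductor, with
g(0) = 1 exactly and g → ½ as u → ∞.  Roots are found by Brent bracketing on
g ∈ (½ + 10⁻¹², 1] with xtol 10⁻¹⁴ (the bracket endpoints have opposite
residual signs for every u > 0, which excludes the spurious root at g = 0);
u > 10⁶ returns the asymptote ½ directly.  For a general Γ the closed-form ΔT
is maximized numerically: a 0.5 mm grid over (0, λ] (the optimized-Γ
resonances of interest stay below λ/2; the range is overridable) followed by
bounded scalar minimization between the two neighboring grid points
(xatol 10⁻⁸).  k = 0 raises: the unity-transfer ΔT grows monotonically and
has no resonance.

## Numerical line integral

For spatially varying fields the voltage integral uses the midpoint rule on
the wire-path segments: Σ h(l_mid)·(E(midpoint)·Δl), with l_mid the arc
length of each segment midpoint from the tip (default path discretization
1 mm).  Field grids interpolate trilinearly, each real and imaginary
component independently; no extrapolation — out-of-domain queries raise and
name the offending point.  Midpoint quadrature converges at second order for
smooth integrands; the tests assert the weaker first-order-or-better bound
against the constant-field closed forms.

TLM denominators with magnitude below 10⁻¹⁴ (a lossless wavenumber with
|Γ| = 1 at a resonant length) raise a singularity error rather than return an
arbitrarily amplified value.  The complex-Γ ΔT routes through |V|² of the
closed-form voltage; the explicit trigonometric/hyperbolic ΔT expression is
used for real Γ and is algebraically identical (a property test, restricted
to |k|d ≥ 0.05 because for shorter leads both expressions cancel toward
E²d² at the floating-point noise floor).

## Fitting and model comparison

Measured rises are first transmit-gain corrected:
ΔTc = ΔT_meas · 10^((TG_j − TG_ref)/100), TG in 0.1 dB counts (30 counts =
factor 2 in power).  The reference gain defaults to the first record and can
be overridden.  Measurement error is the root-sum-square of three components:
tip-probe disagreement, TG-variation propagation (first-order sensitivity
|ΔTc|·ln10/100·sd(TG)), and baseline SD.

Each model curve is fitted to the corrected data with a closed-form
least-squares scale c = Σyp/Σp²; RMSE uses 1/n normalization.  The TLM's Γ is
profiled over the real interval [0, 1] (grid 10⁻³, then bounded refinement),
counting 2 free parameters against the SEM's and open-TLM's 1.  Models are
ranked by the ordinary-least-squares AIC, n·ln(RSS/n) + 2(K+1); only AIC
differences are meaningful, and a zero-RSS fit returns −∞ with a warning.
Complex Γ fitting and uncertainty intervals on Γ are out of scope.

## Synthetic data

Because the measured temperature table of any specific experiment is not
bundled, the package generates its own study fixtures:

* **Synthetic body-coil field**: dominant Ez whose magnitude rises linearly
  with lateral distance |x| (floor 10% on the midline), tapers as a cosine
  along z over the phantom half-length, and carries a phase linear in z
  (default period 0.65 m); transverse components are 5% of the local Ez.
  This reproduces the qualitative structure of a body-coil field in a torso
  phantom — strongest E laterally, z-dominant polarization — but none of the
  boundary effects, ellipticity, or near-wire scattering of a full-wave
  simulation, so field-grid tests demonstrate correct integration machinery,
  not field realism.
* **Synthetic measurements**: ΔT_j = scale·ΔT_model(d_j)·10^(−(TG_j−TG_ref)/100)
  + N(0, noise_sd), TG_j ~ N(TG_ref, tg_spread), reproducible under a fixed
  seed.  TG-correcting with the generator's reference exactly inverts the
  gain perturbation, so generate → correct → fit recovers the generating
  scale (and Γ) in the noiseless limit — a round-trip identity in the tests.

The default simulation study (also the parameter-recovery test) uses the King
wavenumber at 1.5 T, the study's 15 wire lengths between 2.38 and 50.78 cm,
Γ = 0.25, noise at 5% of the peak rise, TG spread 3 counts, and a 50 °C peak
scale — conditions representative of a phantom heating experiment near the
resonant length.  Passing it shows the estimator recovers Γ and the AIC
identifies the generating family under those conditions; it says nothing
about model misspecification against real leads (helical conductors, loops,
IPG-terminated ends, tissue heterogeneity), which are out of scope.

## Known limitations

* Straight or gently curved insulated wires only; no helical leads, loops, or
  current-distribution modelling.
* ΔT is relative; converting to absolute degrees requires the fitted scale
  (no thermal diffusion/bioheat model).
* Single-layer insulation, non-dispersive media.
* Only the smallest resonance is solved for; higher-order maxima are ignored.
* The insulated-antenna wavenumber loses accuracy for weakly conductive
  (fat-like) embedding media.
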