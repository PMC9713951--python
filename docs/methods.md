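# Methods

## The model

A fluid-filled, thin-walled, approximately spherical biological
compartment (the motivating case is the bladder in a water bath) is
modeled as an incompressible, isotropic, hyperelastic membrane inflated
from a reference volume V₀ to a volume V. The wall follows the
Demiray–Fung exponential strain energy

    W = (μ₀ / 2b) (exp(b (I₁ − 3)) − 1),

with initial shear modulus μ₀ [Pa] and dimensionless strain-stiffening
exponent b. Spherical inflation is equibiaxial: λ₁ = λ₃ = (V/V₀)^{1/3},
and incompressibility forces λ₂ = λ₁⁻², so I₁ = 2λ₁² + λ₂². The deformed
half-thickness is h = λ₂h₀ and the radius r = (3V/4π)^{1/3}.

Treating the wall stress as homogeneous across the thickness (the
thin-wall assumption), the internal pressure follows the Laplace law
P = (t₁ − t₂)·4h/r, the first-order Taylor expansion of the exact
homogeneous-stress relation P = 2(t₁ − t₂)ln(b_out/a) with a = r,
b_out = r + 2h. The package keeps both; the logarithmic form serves as
the oracle for the thin-wall approximation (≤ 1% discrepancy at
b_out/a = 1.01, growing monotonically with relative thickness).

Small-amplitude antisymmetric (A0-like) waves guided by the pre-stressed
wall and loaded by fluid on both faces obey a leaky-Lamb characteristic
equation Θ(c, f) = 0 whose coefficients are the acoustoelastic
incremental moduli α, γ, 2β. For this constitutive family

    α = λ₁² μ₀ E,   γ = λ₂² μ₀ E,   E = exp(b(I₁ − 3)),
    2β = 2μ₀ b E (λ₁² − λ₂²)² + μ₀ E (λ₁² + λ₂²),

which all reduce to (μ₀, μ₀, 2μ₀) at λ₁ = 1, recovering the classical
unstressed incompressible plate. The 2β closed form is obtained by
differentiating the *constrained* energy W̃(λ₁, λ₂) = W(λ₁, λ₂, 1/λ₁λ₂)
in the generic incremental-modulus expression with λ₁² − λ₂²
denominators; two published algebraic variants that differ from it by a
factor of two in one term each (one fails the classical limit, the other
halves the strain-stiffening term) are kept behind
`beta_variant={"derived","eq17","eq19"}` for reproduction studies. Only
the derived form passes both the finite-difference oracle and the
classical limit, so it is the default.

The key structural fact exploited by the inversion is that dividing the
moduli by the stress difference leaves dimensionless functions of V/V₀
and b alone: α = A·(t₁−t₂), 2β = B·(t₁−t₂) with
A = λ₁²/(λ₁²−λ₂²) and B = [2b(λ₁²−λ₂²)² + (λ₁²+λ₂²)]/(λ₁²−λ₂²). Since
t₁ − t₂ = P·r/4h, the full dispersion relation is parameterized by P,
geometry (V, V₀, h₀) and the single material number b — the shear
modulus never appears, which is what allows calibration-free pressure
estimation.

## The characteristic equation and its solver

With s₁², s₂² the roots of γs⁴ − (2β − ρc²)s² + (α − ρc²) = 0 and
k = 2πf/c,

    Θ = γs₁(1+s₂²)² tanh(s₁kh) − γs₂(1+s₁²)² tanh(s₂kh)
      + ρ_F c² (s₁² − s₂²)/ξ,   ξ = √(1 − c²/c_p²).

Defaults: ρ = ρ_F = 1000 kg/m³, c_p = 1480 m/s, symmetric fluid loading
on both faces. The ξ convention and the algebraic placement of the fluid
term are configurable (`xi_convention`, `fluid_term`); the defaults are
chosen so the fluid term vanishes as ρ_F → 0 (free plate) and diverges
as c → c_p (leaky cutoff).

Numerical choices:

* **Spurious-root removal.** Θ vanishes identically wherever the quartic
  has a double root (both plate terms cancel and the fluid term carries
  the factor s₁² − s₂²). Root finding therefore brackets sign changes of
  the reduced function Θ/(s₁² − s₂²), which is regular there and
  provably real in both the real-root and conjugate-root regimes.
  Emitted roots are still validated on the raw Θ: the residual
  normalized by the largest term magnitude must be < 1e−8.
* **Bracketing.** Uniform scan at 0.25 m/s over c ∈ [0.2, 15] m/s by
  default, refined by Brent's method to ~1e−12 m/s; the smallest root in
  range is taken (the A0-like branch is the slowest). Successive
  frequencies seed a ±1.5 m/s window around the previous root (branch
  continuity), falling back to the full range.
* **Branch cuts.** sᵢ is the principal square root of sᵢ²; the root with
  larger real part (ties: larger imaginary part) is s₁, making Θ
  single-valued. For the derived moduli α + γ − 2β ≤ 0 along the whole
  scan, so the quartic roots in fact stay real; the conjugate regime is
  still handled (and tested) for injected coefficient sets.
* **Degeneracy at P = 0.** The pressure-parameterized moduli all vanish
  with P, so the stressed equation degenerates at exactly zero pressure;
  the solver raises a specific error directing callers to the unstressed
  classical equation, which is provided separately.

## Inversion

P is estimated by Nelder–Mead simplex minimization of
Σᵢ Θᵢ(P)·conj(Θᵢ(P)) over the curve samples within 150–500 Hz, starting
at 100 mmHg, with fixed b = 5 and h₀ = 2.75 mm — values representative
of soft tissue and average bladder wall thickness. The reference volume
is inferred per fill from measured thickness via V₀ = (h/h₀)^{3/2}V and
averaged across fills. Optimization runs in mmHg (scale ~10–100) so the
default simplex is well conditioned; negative trial pressures are pushed
back by a quadratic penalty anchored at the initializer's misfit rather
than hard bounds. Convergence: simplex diameter 1e−3 mmHg and relative
objective change 1e−10, capped at 500 iterations (the optimizer's
diagnostics are returned either way). With replicate acquisitions the
per-frequency median across replicates is taken before fitting.

The objective inherits one benign artifact of the raw Θ: the spurious
zeros at quartic double roots. They contribute isolated near-zero terms
at pressures far from the optimum but never create a competing basin in
the tested regime (the objective-validity test scans a coarse pressure
grid to confirm the global minimum sits at the generating pressure).

The sensitivity grid refits over a Cartesian product of (b, h₀). Because
V₀ is inferred through h₀, each h₀ cell rescales V₀ by (h₀⁰/h₀)^{3/2}
before refitting, mirroring how an error in the assumed thickness
propagates in practice.

## Wavefield processing

The measurement chain emulates ultrasound vibrometry of the wall:

1. **Autocorrelation velocity** (Kasai): v = (c_us·PRF/4πf_demod)·
   arg Σ IQ_t·conj(IQ_{t+1}) over a (default lag-1, ensemble-2) window.
   Positive v is motion toward the transducer; velocities beyond
   c_us·PRF/4f_demod alias.
2. **3×3 spatial median filter** per frame (edge replication at borders)
   — removes isolated outlier pixels from bubbles and dead regions.
3. **Wall profile**: per lateral column, the median of v across the
   masked wall thickness; the lateral coordinate is re-parameterized as
   cumulative arc length along the (moving-average-smoothed) wall
   centerline and resampled uniformly, a first-order curvature
   compensation. The smoothing suppresses the pixel-quantization
   staircase that would otherwise inflate arc length by several percent.
4. **k-space estimation**: Tukey(0.1) windows on both axes, 4× zero
   padding, 2D FFT; per requested frequency the two wavenumber
   half-planes are peak-picked separately with sub-bin quadratic
   interpolation and c = 2πf/k. Per-direction SNR is the peak over the
   median magnitude of the frequency row (threshold 2 by default). A
   frequency whose global row peak sits below one unpadded bin of k = 0
   is dropped (no spatial propagation), and a direction whose peak is
   below 25% of the stronger direction's is treated as leakage of the
   other direction rather than an independent wave. Surviving directions
   merge by median.
5. **Replicate median** per frequency bin across acquisitions
   (nearest-bin alignment; bins present in half the acquisitions or
   fewer are dropped), and **MPVV**: the sample variance (ddof = 1) of c
   per (fill, frequency) cell averaged over all cells with ≥ 2
   replicates — a single noise figure per experiment.

Median-based aggregation is used throughout because the velocity and
k-space estimators are nonlinear and their outliers otherwise dominate
mean-based averages.

## Synthetic data

Every generator is the documented inverse of a processing stage: the IQ
generator is the exact phase-ramp inverse of the autocorrelation
estimator; the wavefield generator superposes dispersive plane waves
v(x,t) = ΣA(f)cos(2πft − k(f)x + φ_f) from a dispersion curve (so the
k-space stage can be checked against its input); replicate curve noise
is iid Gaussian per sample with optional multiplicative outliers uniform
on [0.5, 3]× truth standing in for bubble artifacts; and the
method-comparison generator draws crossed Gaussian variance components
with a closed-form population concordance.

Default study conditions: V₀ = 200 ml, h₀ = 2.75 mm, μ₀ = 5 kPa, b = 5,
fills 210–360 ml in 10 ml steps. These were fixed once so the forward
pressures sweep ≈1–50 mmHg — the physiological detrusor-pressure range —
with fill volumes comparable to ex vivo bladder protocols (initial
volumes of a few hundred ml, 10 ml increments). The excitation amplitude
spectrum is flat over 100–600 Hz with raised-cosine rolloff, loosely
emulating a 400 μs radiation-force burst.

What the generators do **not** emulate: beamforming and compounding
physics, speckle decorrelation, attenuation, viscoelastic dispersion,
non-spherical geometry, thickness-inhomogeneous stress, anisotropy and
active contraction. Passing tests therefore demonstrate the internal
consistency of the mechanics–dispersion–inversion–statistics chain and
its robustness to the modeled noise, not performance on tissue.

## Statistics

RMSD, ME and RME summarize estimated-vs-measured pressure agreement.
Lin's concordance for repeated measures is computed from the crossed
subject × method × repeat variance components,
CCC = (σ²_s + σ²_sn)/(σ²_s + σ²_sn + σ²_sm + σ²_mn + σ²_e), estimated by
balanced three-way ANOVA method of moments (one observation per cell;
the three-way interaction is confounded with the residual; negative
moment estimates truncate at zero with the raw value retained in the
result). The confidence interval is a percentile bootstrap over subjects
(2000 draws by default, seeded). REML-based components, as used by
dedicated mixed-model packages, can be plugged in through the
`components_estimator` hook; method-of-moments was chosen because the
component *definition*, not the estimator, is what the concordance
formula requires, and it keeps the package dependency-light and exactly
reproducible. With a single repeat and no fixed method offset the
estimator agrees with the classic bivariate Lin CCC (tested).

Note the method × repeat component has only (M−1)(N−1) degrees of
freedom regardless of the number of subjects, so it is the least
precisely estimated; the recovery test's tolerance reflects that.

## Problem sizes

The test suite and the acceptance script use deliberately small problem
sizes chosen to exercise every stage with comfortable statistical
margins: dispersion curves of 36 frequencies (150–500 Hz at 10 Hz),
wavefield records of ~134 positions × 512 frames (40 mm at 0.3 mm,
128 ms at 4 kHz), 5 replicate acquisitions, 6 fill volumes, and
concordance designs of 50 subjects × 5 repeats. The full suite runs in
well under a minute.

## Known limitations

* The thin-wall, homogeneous-stress assumption degrades for thick or
  mildly inflated walls; the log-law comparison quantifies the static
  part of that error but the wave model inherits it unquantified.
* Exactly P = 0 is outside the stressed model's domain (moduli vanish);
  estimates are constrained nonnegative but the near-zero regime relies
  on the penalty, not on physics.
* The arc-length wall-profile resampling is a first-order curvature
  compensation only; strongly curved or folded walls violate it.
* The k-space estimator is half-bin-limited: velocity error grows
  quadratically with phase velocity at fixed wavenumber resolution, so
  high-pressure (fast-wave) estimates are intrinsically noisier.
* Bootstrap CIs for the concordance are percentile-based and can be
  optimistic for small numbers of subjects.
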