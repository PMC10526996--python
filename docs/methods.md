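# Methods

## Model

The skin is a single homogeneous slab of thickness L (the rate-limiting
stratum corneum) with constant analyte diffusion coefficient D and unit
partition coefficient everywhere. Analyte metabolism within the skin, shunt
pathways (sweat glands, follicles), the brick-and-mortar microstructure of
the stratum corneum, and any gas headspace between skin and sensor are all
neglected. Transport is one-dimensional Fickian diffusion,
∂c/∂t = D ∂²c/∂x², with the capillary bed at x = 0 and the sensor at x = L.

The blood side imposes a concentration step, c(0,t) = C₀ for t ≥ 0, from a
zero initial state — the idealized "drink arrives instantaneously" input
whose response bounds every smoother input. The sensor side is one of

* **Neumann** (∂c/∂x|_L = 0): a concentration-type sensor that consumes
  nothing — it reads c(L,t) and its steady state is C₀;
* **Dirichlet** (c(L,t) = 0): an ideal flux-type sensor consuming every
  molecule — it reads the exit flux −D ∂c/∂x|_L with steady state C₀D/L;
* **Robin** (D ∂c/∂x|_L = −α c(L,t)): a finite-sensitivity flux sensor with
  mass-transport coefficient α (cm/s), steady state C₀α/(1 + ᾱ) where
  ᾱ = αL/D.

All solvers work in dimensionless variables x̄ = x/L, t̄ = tD/L² (the Fourier
number), c̄ = c/C₀; responses are normalized by their steady state so every
sensor class produces a curve m̄(t̄) rising from 0 to 1.

## Analytic solutions

Neumann and Dirichlet problems use the classical separation-of-variables
sine series; the normalized responses are

    m̄_conc(t̄) = 1 + (4/π) Σ (−1)^i/(2i−1) · exp(−π²(2i−1)²t̄/4)
    m̄_flux(t̄) = 1 + 2 Σ (−1)^i · exp(−π²i²t̄)

The Robin problem separates into modes sin(μₙx̄)·exp(−μₙ²t̄) with μₙ the
positive roots of μ cos μ + ᾱ sin μ = 0 (this form avoids the tangent's
poles). The n-th root lies in ((n−½)π, nπ); each is bracketed there and
refined with Brent's method to machine tolerance (scaled eigencondition
residuals are ~1e-14). The projection coefficients follow from expanding the
negated steady-state profile v̄ss(x̄) = 1 − ᾱx̄/(1+ᾱ) in the orthogonal
eigenbasis:

    bₙ = −⟨v̄ss, sin(μₙx̄)⟩ / ⟨sin(μₙx̄), sin(μₙx̄)⟩,

with both inner products in closed form (and cross-checked against
quadrature in the tests). As ᾱ → ∞, μₙ → nπ and the Dirichlet solution is
recovered; as ᾱ → 0, μₙ → (n−½)π and the temporal shape becomes that of the
Neumann problem — both limits are verified numerically to 1e-4 sup-norm.

### Series truncation and the t̄ = 0 convention

Terms decay like exp(−λₙt̄), so the mode count is chosen so the first
omitted term is below the requested tolerance (default 1e-12) at the
smallest evaluated time, capped at 10 000 modes. Defaults are 200 modes for
Robin profiles and 50 for responses. The series converge non-uniformly as
t̄ → 0 (Gibbs behaviour at the step); below t̄ = 1e-4 the exact
initial/boundary-condition values are returned instead of summing, and
m̄(0) is defined as 0 by physical continuity rather than as the Abel sum of
the divergent series.

A consequence worth knowing: the t̄ = 0 eigenfunction reconstruction of the
initial condition converges only as O(1/(N·x̄)) pointwise, because the
expanded function has a unit jump at the blood boundary (v̄ss(0) = 1, while
every sin(μₙx̄) vanishes there). With 2000 modes the reconstruction error on
x̄ ∈ [0.1, 0.9] is ~1e-3 and halves when the mode count doubles; this is a
property of raw partial sums, not a defect of the coefficients. It has no
bearing on accuracy at t̄ ≥ 0.01, where the exponential damping makes the
series converge in a handful of terms.

## Finite-difference oracle

An independent Crank–Nicolson solver verifies every analytic solution. Space
is discretized with second-order central differences; Neumann and Robin
boundaries use a ghost node (c_ghost = c_{n−2} − 2hᾱc_{n−1}) so the boundary
flux stays second-order; Dirichlet values are imposed directly. The blood
node is held at 1 from the first step, matching the idealized step. Because
Crank–Nicolson only damps the high-frequency content of the initial
discontinuity slowly, the march starts with four backward-Euler half-steps
(Rannacher start-up) before switching to trapezoidal stepping.

Default grid: nx = 601, dt̄ = 5e-5. These were set by a refinement study
against the series solutions: the deviation is spatial-error dominated
(observed order 2.0), giving max |series − FD| ≈ 3.4e-5 at nx = 201 and
4.0e-6 at nx = 601 over the verification grid t̄ ∈ [0.01, 3] × x̄ ∈
{0, 0.1, …, 1}, ᾱ ∈ {0.2, 1, 5}. The 1e-5 agreement target therefore
requires the finer default; the full five-case verification sweep runs in
well under a minute. The exit flux is estimated with a one-sided
second-order three-point gradient.

## Timescale metrics

Two metrics are reported side by side (neither is canonically "the" response
time, so both are):

* **Leading-exponential time constant** τ = L²/(D·λ₁), with λ₁ read off the
  implemented series' slowest mode rather than hard-coded: λ₁ = π²/4
  (Neumann), π² (Dirichlet), μ₁² (Robin). Hence τ_conc/τ_flux = 4 for any
  skin, and the Robin value interpolates monotonically between them.
* **Integrated intercept** t̄\* = ∫₀^∞ (1 − m̄) dt̄, the x-intercept of the
  asymptote of the integrated response (the lag time of the
  membrane-permeation literature). Each exponential integrates in closed
  form, so t̄\* is a term-wise sum truncated at 1e-12: exactly 1/6 for the
  flux sensor, 1/2 for the concentration sensor (ratio 3), and
  −(1+ᾱ) Σ bₙ sin(μₙ)/μₙ² for Robin, which the tests confirm is monotone in
  ᾱ and bounded by (1/6, 1/2).

Classification thresholds: a sensor is labelled effectively flux-type when
ᾱ ≥ 10 and effectively concentration-type when ᾱ ≤ 0.1 — "an order of
magnitude away from unity" made concrete, and configurable, since the
underlying physics only distinguishes ᾱ ≫ 1 from ᾱ ≪ 1.

## Ethanol case study

Internal units are cm/s/mol; converters accept μm, hours, mg/dL, μmol/L.
The Faraday constant is kept at 9.64×10⁴ s·A/mol, the rounding customarily
used in these calibration chains. Two literature parameterisations of
ethanol in dry stratum corneum circulate — D = 5×10⁻¹⁰ cm²/s (permeability
chains, k_skin = 3.3×10⁻⁷ cm/s at L = 15 μm) and D = 3×10⁻¹¹ cm²/s
(timescale estimates, τ between 2.1 and 8.4 h) — both tracing to the same
1971 measurements. The package ships both verbatim as presets
(`ethanol-kskin`, `ethanol-timescale`) and does not adjudicate between
them. The WrisTAS chain likewise keeps the published assumptions (n = 4
electrons per molecule; a patent-derived alternative permeability of
5.3×10⁻⁷ cm/s from a flux of 1.15×10⁻¹¹ mol cm⁻² s⁻¹ at 100 mg/dL), and
reports carry both permeability variants. Note the published amperometric
chains round to two significant figures: the exact no-membrane arithmetic
gives α = 1.037×10⁻⁵ cm/s where 1.0×10⁻⁵ is quoted; the package reports the
exact value.

## Known limitations

* Single-layer skin, unit partition coefficient, constant D: no hydration,
  temperature, or population variability; no two-layer or headspace
  geometry.
* Step input only. Time-varying blood concentrations would need the impulse
  response and a convolution, which the step response determines in
  principle but which is not implemented.
* The Robin condition models the sensor as a linear first-order sink;
  enzyme saturation and depletion effects are outside the model.
* The classification thresholds are conventions, not physics; near
  ᾱ ≈ 0.1 or 10 the labels should be read as a spectrum position.
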