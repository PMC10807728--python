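# Methods

## Scope and model

`siftersim` implements the signal theory of the four-pulse SIFTER experiment
(single-frequency technique for refocusing dipolar couplings) for S = 1/2
radicals in frozen glassy solution, together with the background-correction
procedure that the theory implies.  The trace coordinate is t = τ1 − τ2 at
fixed total transverse evolution time 2τ0 = 2(τ1 + τ2); τ1 = (τ0 + t)/2,
τ2 = (τ0 − t)/2.

Model assumptions, fixed throughout:

1. **Ideal pulses** — infinitely short, infinite bandwidth.  Finite pulses,
   frequency-swept pulses and phase cycling are out of scope.
2. **High dilution** — the intramolecular dipolar coupling of a biradical is
   much stronger than intermolecular couplings.
3. **Secular dipolar coupling only** — H = ω_dd(r, θ) Ŝ_z Î_z per pair, with
   ω_dd = 2π·C_dd/r³·(1 − 3cos²θ), C_dd = μ0 g²μB²/(4πh) ≈ 52.04 MHz·nm³ at
   g = 2.0023 (computed from CODATA constants; a single g value is used for
   both partners).  Pseudosecular (flip-flop) terms are never added; the
   propagator implements the truncated Hamiltonian as written, which is the
   appropriate limit when dipolar frequencies are far below the spectral
   width.  The electron Zeeman interaction is dropped (refocused at every
   echo under ideal pulses).

Nuclear-bath physics (spectral diffusion, dynamical decoupling) is **not**
simulated microscopically; it enters only through the phenomenological decay
factors Bt and BS described below.

## Exact propagator (quantum_core)

Small spin networks (≤ 10 spins, dense 2ⁿ×2ⁿ matrices) are propagated
through SIFTER, SIDRE (SIFTER minus the central π/2 transfer pulse) and Hahn
sequences.  Conventions: spin 0 is the detected A spin and the slowest
tensor factor; pulses are global rotations exp(−i·flip·ΣS_axis); delays use
diagonal exponentiation (the secular Hamiltonian is diagonal in the product
basis), so free evolution is exact to rounding.  Detected signals are
coefficients of single-spin transverse operators, Tr(ρM)/Tr(M_k²).

The propagator is the package's oracle.  Verified properties (tests):

* isolated pair: SIFTER signal = cos(ω0(τ2 − τ1)) to < 1e−10;
* the cosine splits into a no-transfer pathway cos(ω0τ1)cos(ω0τ2) (the
  detected spin's own polarization) and a transfer pathway
  sin(ω0τ1)sin(ω0τ2) (the partner's polarization), separable by restricting
  the initial polarization to one spin;
* SIDRE on a coupled pair gives cos(ω0(τ1 + τ2)) — constant at fixed τ0 —
  because the global π pulses do not refocus the mutual coupling; this is
  precisely why SIDRE serves as a modulation-free relaxation reference;
* monoradical product rule: the A-channel signal of an A spin coupled to
  N bath spins equals ∏cos(ω_lτ1)·∏cos(ω_lτ2) exactly, independent of
  bath–bath couplings (multi-quantum terms never return to detectable
  single-quantum coherence);
* weak-coupling transfer: the signal detected on a remote spin, divided by
  its coupling ω1², converges quadratically to
  τ1τ2·cos(ω0τ1)cos(ω̃1τ2) as ω1 → 0;
* every detected amplitude scales linearly with the initial (Boltzmann)
  polarization.

## Powder kernels (dipolar_model)

The form factor F(t) = ⟨cos(ω_dd t)⟩, the sine-product kernel
Fs(τ1, τ2) = ⟨sin(ω_dd τ1) sin(ω_dd τ2)⟩ and the fixed-sum constant
K(τ0) = ⟨cos(ω_dd τ0)⟩ are averaged over uniform cos θ (Gauss–Legendre,
default 401 nodes — chosen so that doubling the node count changes F by
< 1e−8 for the shortest supported distances) and over the distance
distribution (trapezoid on its grid).  The trigonometric identity
Fs = F(τ2−τ1)/2 − K(τ0)/2 holds on the shared quadrature to < 1e−12 and is
asserted in tests.  Independent oracles: the closed-form Fresnel-integral
Pake signal for a single distance, and a 10⁶-node midpoint rule.

Gaussian distance distributions are truncated at mean ± 6σ with a hard
floor of 0.8 nm: sub-contact distances are unphysical and their ~1/r³
frequencies degrade trigonometric identities through argument-reduction
rounding.

## Intermolecular Monte Carlo (ensemble_mc)

The detected A spin sits at the centre of a sphere; surrounding spins are
Poisson-distributed (grand canonical — required for the exact exponential
background limit) and uniform in the shell r_min ≤ r ≤ R.  Defaults:

* r_min = 1.5 nm — physical contact distance for typical spin labels; the
  summed second moment diverges as r_min → 0 and the weak-transfer
  linearization fails for closer spins;
* R chosen so truncation changes B2p by < 0.1 % at the longest delay
  (floor 30 nm; ~80 nm for 4 µs traces);
* concentration conversion 1 µM = 6.02214076×10⁻⁷ spins/nm³.

Computed quantities, each with an analytic cross-check:

* **B2p(τ) = ⟨∏cos(ω_lτ)⟩** — for a homogeneous distribution equals
  exp(−kCτ) with k = 8π²Δ/(9√3), Δ = 2π C_dd (the closed-form volume
  integral; the DEER-type exponential background).  Measured agreement at
  50 µM, 10⁴ realizations: ≲ 1 %, within the 2 % test tolerance.
* **D = ⟨Σ_l ω_l²⟩** — the summed second moment that sets the
  coherence-transfer factor Dτ1τ2.  Matches the shell integral
  (16π/15)CΔ²(r_min⁻³ − R⁻³).  D is cutoff dominated (∝ r_min⁻³) and its
  naive Poisson-sum estimator is heavy-tailed: rare near-cutoff spins carry
  most of the sum.  The concentration-scaling scan therefore uses a compact
  box (max(8 r_min, 12 nm)) with ≥ 2×10⁵ realizations; the measured
  exponent of D versus concentration is 1.0 (the sum is linear in C at
  fixed r_min).  Reported with its r_min, never asserted against a target.
* **Factorization check** — the composition law assumes that cosine
  products centred on the A spin and on a transfer-weighted B spin average
  independently.  Direct MC at 50 µM, τ1 = τ2 = 2 µs, with the B spin
  chosen ∝ ω_n² from the shared geometry, measures a relative discrepancy
  of ≈ +9 % ± 1.5 % (joint average above the factorized product): the
  surroundings of strongly coupled spins are positively correlated.  The
  package reports this number with MC error bars; no target is asserted.
  With independently resampled surroundings the discrepancy is consistent
  with zero, validating the estimator.

## Relaxation filtering (relaxation_models)

Two-pulse decay: Bt(τ) = Σ w_i exp(−(2τ/τd_i)^β_i) (SSE, weights summing
to 1, decay in echo time 2τ).  SIDRE surface: per component

    BS(τ1, τ2) = exp(−((2τ1)^ξ + (2τ2)^ξ)^{β/ξ} / τd^β),

a generalized-power-mean stretched exponential with a single decoupling
shape exponent ξ ≥ max(β, 1).  The experiment constrains only the shape
qualitatively; this family is the minimal one satisfying all constraints
*exactly*: BS(τ, 0) = Bt(τ); BS = Bt·Bt at ξ = β; maximum at τ1 = τ2
(the CPMG-like condition) for ξ > 1; BS(τ, τ) ≥ Bt(τ)² (dynamical
decoupling).  Conclusions sensitive to the specific family are model
dependent and flagged as such.

Fitting: deterministic multi-start trust-region least squares (scipy),
linear amplitude, 1–3 SSE components.  SSE parameters are sloppy — at
SNR 100 single-fit time constants scatter by ~5–10 % and for closely
spaced components a different basin can fit the noise better than the
truth basin — so recovery claims are made on ensemble means over noise
realizations.  A non-decaying trace is flagged degenerate (τd unbounded)
rather than fitted.

## Signal composition (signal_composition)

Monoradical: V = BS + Dτ1τ2·Bt·Bt.  Biradical, modulation depth λ:

    V = (1 − λ)·V_nm + λ·V_mod
    V_mod = F(t)·[BS + Bt·Bt]/2 + F(τ1)F(τ2)·Dτ1τ2·Bt·Bt
    V_nm  = BS + Dτ1τ2·Bt·Bt + λ/(2(1−λ))·K·(BS − Bt·Bt)

The K bookkeeping follows from the pathway split: the no-transfer
(cos·cos) pathway relaxes with BS, the transfer (sin·sin) pathway with
Bt·Bt, so ⟨cos cos⟩·BS + ⟨sin sin⟩·Bt·Bt = F·(BS + Bt·Bt)/2 +
K·(BS − Bt·Bt)/2.  This composed form is verified numerically (to 1e−10,
100 random parameter draws) against the direct pathway sum
F·BS + Fs·(Bt·Bt − BS) + A·Bt·Bt, and against the powder-averaged exact
propagator in the relaxation-free two-spin limit.  At λ = 0 the biradical
expression reduces exactly to the monoradical one; λ = 1 is excluded by
the parametrization (the λ/(1−λ) bookkeeping), and λ → 1 recovers pure
F(t) when relaxation and transfer are switched off.

λ is a free input parameter: the mechanism producing it (incomplete
excitation) is not modelled under ideal pulses.

## Background correction (background_pipeline)

The composition law implies that the unmodulated part must be **fitted and
subtracted**, and the remainder **divided** by the main-term background
(BS + Bt·Bt)/2 — which differs in shape from both the unmodulated signal
and the SIDRE trace.  Pipeline:

1. Bt from the Hahn decay (SSE fit); ξ and amplitude of BS from the SIDRE
   trace with Bt fixed.
2. Robust (soft-L1) linear fit of V_nm = a·BS + b·τ1τ2·Bt·Bt +
   c·(BS − Bt·Bt) with the modulated centre (|t| < τ0/3) down-weighted
   (weight 0.05).  If the t = 0 excess over the fitted model is below 3×
   the robust wing-noise level, the trace is treated as unmodulated: the
   fit is repeated on the full grid without the K column (which scales
   with λ and is otherwise collinear with the transfer column).  A
   near-singular design (ξ ≈ β makes BS ∝ Bt·Bt) is flagged via the
   condition number.
3. λ anchored at the t = 0 amplitude excess; F_rec = (V − V_nm)/(sλ·
   (BS + Bt·Bt)/2), normalized to 1 at t = 0; sub-floor divisors masked
   (NaN), counted, never interpolated.
4. Gaussian distance fit through a precomputed powder kernel matrix
   (341 r-nodes × 101 orientation nodes — fitting does not need the
   1e−8 generation accuracy), deterministic multi-start over r̄.
5. Parametric refinement (default 1–2 rounds): with the fitted Gaussian
   form factor, all scalars (s, λ, D, K) are refit against the complete
   signal model and the form factor re-extracted.  For noise-free Gaussian
   truth this converges to the generator to ~1e−5 sup-norm.

The superseded heuristic — dividing the SIFTER trace by SIDRE — is kept
for comparison.  Whenever ξ > β it distorts the modulated part by
(1 + Bt·Bt/BS)/2; on noise-free synthetic data the proposed correction's
form-factor error is strictly smaller on every trace, which the tests
assert as a theorem of the generating model.

## Synthetic studies (synthetic_data_io)

The default study emulates a frozen-glass (o-terphenyl-like) design at
50 µM: {monoradical, biradical} × {nitroxide-like, trityl-like} × four
trace lengths (τ0 = 1.5, 2.5, 3.5, 4.5 µs), each with SIFTER + SIDRE +
Hahn traces, grid step 0.05 µs, SNR 50 (additive white Gaussian noise,
σ = max|amplitude|/SNR — echo-integrated detection noise).  Relaxation
presets: nitroxide-like τd = 3.5 µs, β = 1.4, ξ = 2.4 (shorter
decoherence, stronger decoupling); trityl-like τd = 7.0 µs, β = 1.0,
ξ = 1.6.  Biradical default: Gaussian distances r̄ = 3.0 nm, σ = 0.2 nm,
λ = 0.3.  The transfer amplitude default D = 0.02 rad²/µs² represents the
dilute regime where the artefact is a percent-level perturbation, as
appropriate for tens-of-µM samples with a nanometre exclusion distance;
it can also be taken from the MC module.  Everything is deterministic
given the master seed, which is recorded (with per-trace noise seeds and
ground truth) in every file header.

What the generator does **not** emulate: orientation selection, exchange
coupling, ESEEM/nuclear modulation, finite-bandwidth pulse effects,
non-uniform (clustered or excluded-volume) spatial statistics, vendor
binary formats, or transient echo shapes.  Closed-loop test passes
therefore demonstrate correctness of the composition/correction algebra
and estimator calibration under the stated noise model — not robustness
to the instrumental non-idealities of real spectrometers.

## Numerical choices

* Angular frequencies rad/µs everywhere; MHz and µM only at I/O borders.
* Orientation quadrature 401 Gauss–Legendre nodes (generation), 101
  (kernel fitting); distance grids 513 nodes (Gaussian construction),
  341 (fit kernel).
* Division floors at 1e−6 with masked-point bookkeeping.
* All fits use deterministic multi-start grids; no stochastic optimizers.
* Trace files are plain ASCII; round trips preserve floats via repr.

## Known limitations

* The BS(τ1, τ2) family is an ansatz constrained only by qualitative
  experimental facts; real surfaces need not lie in it.
* Heterogeneous spin pairs (different g values) are not distinguished;
  a single g enters C_dd.
* The factorization assumption underlying the composed background is
  measurably violated (~9 % at 50 µM for transfer-weighted partners); the
  composition law is therefore an approximation whose error the MC module
  quantifies but the pipeline does not propagate.
* Closed-loop accuracy is demonstrated against synthetic truth only;
  validation against experimental reference data (e.g. DEER on the same
  sample) is outside the package's reach.
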