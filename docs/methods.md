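# Methods

## Model

A two-level chromophore with electronic gap Ω is bilinearly coupled to a
single harmonic bath,

    H = (Ω/2) σ_z + Σ_j ω_j a_j†a_j + S ⊗ B,
    S = α_z σ_z + α_x σ_x,   B = Σ_j g_j (a_j + a_j†),

starting from a factorized initial state ρ_s(0) ⊗ e^{−βH_b}/Z_b.  The bath's
influence is fully captured by the spectral density J(ω) and the bath
correlation function

    C(t) = ∫₀^∞ dω J(ω) [coth(βω/2) cos ωt − i sin ωt].

Conventions: all energies in cm⁻¹, times in fs (lifetimes in ps);
ω[rad/fs] = 2πc·ν̃ with c = 2.99792458×10⁻⁵ cm/fs; k_B = 0.6950348 cm⁻¹/K;
reorganization energy λ = ∫₀^∞ J(ω)/ω dω with no factor of 1/π anywhere.
This normalization is fixed jointly by three cross-checks the package
reproduces: a peak with (ω_k, γ_k, λ_k) = (1500, 10, 20) cm⁻¹ has height
λω_k/(πγ_k) ≈ 955 cm⁻¹; the pure-dephasing decoherence function is
exp[−4α_z² ∫ J/ω² coth(βω/2)(1−cos ωt) dω]; and the Drude–Lorentz solvent
gives a 10.49 ps golden-rule lifetime at the production parameters.

Default initial state: the equal superposition (ρ₀₀ = ρ₁₁ = ρ₀₁ = 1/2), so
both dephasing and relaxation are visible in one trajectory.  It is
configurable; the extracted lifetimes are initial-state insensitive, the
recurrence amplitudes are not.

## Spectral-density forms

Every supported peak form is an odd rational function with simple complex
poles, represented internally as a numerator polynomial over an explicit
pole product.  With D(ω) = ((ω−ω_k)²+γ_k²)((ω+ω_k)²+γ_k²):

| form             | J(ω)                                  | onset | tail |
|------------------|---------------------------------------|-------|------|
| drude_lorentz    | (2λ/π) γω/(ω²+γ²)                     | ω     | ω⁻¹  |
| displaced_drude  | (λγ/π)[ω/((ω−ω_k)²+γ²) + ω/((ω+ω_k)²+γ²)] | ω | ω⁻¹ |
| ubo              | (4λγ(ω_k²+γ²)/π) ω / D(ω)             | ω     | ω⁻³  |
| rlc              | (4λγ/π) ω³ / D(ω)                     | ω³    | ω⁻¹ (2× Drude prefactor) |
| ohmic_2pk        | Λ′ ω / D₁(ω)D₂(ω)                     | ω     | ω⁻⁷  |
| superohmic_2pk   | Λ′ ω³ / D₁(ω)D₂(ω)                    | ω³    | ω⁻⁵  |

The UBO and RLC denominators are parametrized so that the poles sit exactly
at ±ω_k ± iγ_k — the same set as the displaced Drude oscillator.  The three
single-peak forms therefore contribute BCF exponentials with *identical*
frequencies and decay rates and differ only in the complex prefactors; this
is the representation in which "the forms differ only in their tails" is
exact.  (The equivalent centered parametrization uses ω₀² = ω_k² + γ_k²,
an O(γ²/ω_k²) relabeling.)  The single-peak normalizations are exact by
contour integration; the 2-peak intensity constant Λ′ is fixed numerically
(residue integration of J/ω, quadrature-cross-checked) so a pair integrates
to the sum of its two sub-peak λ's.  Consecutive table rows form the pairs.
A degenerate single-peak presentation of the 2-peak forms (equal centers,
doubled widths, Λ = λ_k) is supported for evaluation; its double poles are
rejected by the BCF expansion, which requires simple poles.  Exponential
cutoffs are out of scope: an essential singularity admits no finite
exponential BCF expansion.

Asymptotic exponents are reported both analytically (from the rational
representation) and by log–log regression on [ω_ref/1000, ω_ref/100] and
[30ω_ref, 300ω_ref]; the windows are placed deep enough in the asymptotic
regime that the routes agree to 1% even for the broadest tabulated peaks.

## Bath correlation function

C(t) is computed two independent ways.  The *oracle* route integrates the
definition with the exact coth by adaptive oscillatory quadrature
(QUADPACK weighted rules, panels split at the peak positions, analytic
sine/cosine-integral corrections for the ω⁻¹ tails beyond the 2×10⁵ cm⁻¹
cutoff).  For ω⁻¹-tailed forms Re C(0) diverges logarithmically with the
cutoff — a known property of Lorentzian-type spectral densities — so oracle
comparisons are made for t ≥ 1 fs.

The *expansion* route closes C(t) = ½∫J(ω)[coth(βω/2)+1]e^{−iωt}dω in the
lower half-plane.  Each vibrational peak contributes one exponential per
lower-half-plane pole (2 for single-peak forms, 4 for 2-peak forms, 1 for
the undisplaced solvent), with residues evaluated in closed form from the
pole representation.  The thermal factor is replaced by its bosonic [N−1/N]
Padé spectrum decomposition (poles and residues from the standard tridiagonal
eigenvalue construction; the package reproduces ξ₁² = 60, η₁ = 5/2 at N = 1
and the first pole converges to the Matsubara frequency), contributing N
purely decaying terms at ν_j = ξ_j/β; the coth factor at the peak poles is
evaluated with the same approximant, so the expansion is the exact BCF of
the approximated kernel.  At 300 K with N = 8 the expansion matches the
exact-coth quadrature to ~2×10⁻⁵ of max|C| for every composite built from
the packaged table — well inside the 10⁻³ oracle tolerance.  Each Table
composite yields 25 terms (1 + 16 + 8).

## HEOM propagation

Standard scaled-ADO hierarchy over the exponential terms, truncated at a
global tier L (a per-term cap is also supported, matching the
per-term-cutoff reading of hierarchy depth), terminated by dropping
couplings out of the top tier.  The conjugate-BCF coefficients are obtained
by matching each exponent to its complex-conjugate partner in the same term
set.  The full generator is assembled once as a sparse matrix (the trace
functional is an exact left null vector, so trace is conserved to roundoff)
and integrated with the adaptive embedded Dormand–Prince RK45 scheme at
atol = 10⁻⁸, rtol = 10⁻⁵.  Validation: the σ_x = 0 limit matches the exact
independent-boson decoherence function to < 10⁻³ (solvent bath, depth 14
over the 5-term N_Padé = 4 expansion, 80 fs); with couplings scaled down
10× the fitted decay rate matches the golden-rule rate to < 5%.

Problem sizes: the production-grade hierarchy of the underlying study
(per-term cutoff 25) is cluster-scale; this package's analyses use tier-2
hierarchies for the 25-term composites (351 ADOs) and tier-4–14 for the
solvent-only model, which are converged for the reported observables — the
solvent-only fitted lifetime changes by < 0.1% from tier 2 to tier 4, and
the early-time (< 25 fs) coherence is converged at tier 2 to ~10⁻².  The
long-time (> 35 fs) coherence *tail* at shallow depth shows a spurious rise
— a truncation artifact absent at depth ≥ 14 — which is why dephasing
observables are extracted from depth-converged solvent runs and recurrence
detection is restricted to the window where the reference retains ≥ 5% of
its initial coherence.

## Extracted observables

* **Lifetime** — least-squares fit of ln(p(t) − p_eq) on 0.1–0.5 ps
  (skipping the sub-25 fs transient), p_eq taken as the canonical two-level
  value (≈ 0 here, βΩ ≈ 171).
* **Dephasing time** — first crossing of |ρ₀₁|/|ρ₀₁(0)| below a level.
  The API default is 1/e; the package additionally reports the 10%
  *extinction* timescale.  For the solvent-only model these are 18.7 fs and
  30.7 fs respectively: the ~30 fs timescale quoted for this system in the
  literature corresponds to the visual extinction of the coherence, not the
  amplitude-1/e crossing — every convention-pinning cross-check above rules
  out a normalization in which the 1/e time itself is 30 fs.
* **Recurrences** — local maxima of the smoothed |ρ₀₁| (centered moving
  average over ~1 fs, suppressing the ripple at the electronic period) with
  a prominence filter, after the first local minimum.  Against the full
  Table composite the exact decoherence function is monotone — the ~20 fs
  vibrational recurrence is a shoulder riding on the solvent decay — so the
  detector optionally normalizes by a solvent-only reference trajectory on
  the same grid, which exposes the recurrence as a clean maximum at
  ≈ 19.6 fs for every form.
* **Near-peak form agreement** — max |J_form − J_displaced-Drude| within
  ±γ_k of each vibrational peak, as a fraction of the SD peak intensity
  (0.36% for the packaged table).  A pointwise relative metric is
  structurally ≥ 2γ_k/ω_k at the window edges (≈ 22% for the broadest peak)
  and cannot express the sub-percent equivalence the forms actually have on
  the intensity scale.
* **Tail-dominance ratio** — J(Ω)/max_{ω ≤ peaks} J(ω), with the
  tail-dominated regime flagged below 10⁻² (Table composites: ~10⁻⁴ – 10⁻⁵).

## Tail-correction transform

p_real(t) = p_eq + (p_sim(t) − p_eq)e^{−(Γ_real−Γ_sim)t} with golden-rule
rates.  Exact for exponential relaxation differing only in rate; fixed point
at p_eq; round trip is the identity to machine precision.  Applied to the
RLC-form trajectory with the displaced-Drude target it reproduces the
directly simulated displaced-Drude populations to max|Δp| = 7×10⁻⁴ at
matched tier-2 depth (UBO target: 1.3×10⁻³), early-time oscillations
included, since those are form-independent.

## Synthetic data

`generate_peak_table` draws one solvent row and an even number of
vibrational rows uniformly from ranges mirroring the packaged table's spans
(ω ∈ [300, 4000] cm⁻¹, λ ∈ [10, 400] cm⁻¹, γ ∈ [5, 60] cm⁻¹; solvent
λ ∈ [400, 1000], γ ∈ [30, 150] cm⁻¹); distributions are uniform because the
empirical inputs constrain only the ranges.  `generate_decay_trajectory`
produces p(t) = p_eq + (p₀−p_eq)e^{−Γt}(1 + a·e^{−t/τ_d}cos ωt) plus seeded
Gaussian noise.  These emulate the *structure* of the real inputs — peak
sparsity, scale ranges, exponential relaxation with a vibronic transient —
but not line-shape correlations, anharmonicity, or experimental noise
spectra, so passing the recovery tests validates the estimators and the
transform algebra, not the fidelity of any particular molecular model.
Generated tables satisfy the same normalization invariants as the packaged
one; the fit → adjust → fit chain recovers target rates to ≪ 1%, and noisy
recovery is unbiased within two standard errors over 100 seeds.

## Known limitations

Two-level systems only; a single shared bath for the σ_z and σ_x channels;
no tensor-network acceleration (dense/sparse hierarchy only, so per-term
depth 25 over 25 terms is out of desk reach); no exponential-cutoff SDs
inside the expansion route; no fitting of SDs to measured spectra; the
degenerate 2-peak presentation supports evaluation but not BCF expansion.
The superohmic 2-peak composite built from the packaged widths — which were
constructed for the *Ohmic* 2-peak form — deviates from the single-peak
forms slightly more than the others (early-time coherence deviation up to
0.011 vs < 0.01 for every other pair), while its 1/e dephasing time still
agrees with the other forms to 0.2%.
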