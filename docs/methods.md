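# Methods

## Model and reduction

A free active Brownian particle in two dimensions moves at fixed speed along
an internal orientation φ that undergoes rotational diffusion.  After
rescaling time by the rotational diffusion time and lengths by the
interaction length, the Langevin equations are dφ = √2 dW and
dr = Pe (cos φ, sin φ) dt, with the Péclet number Pe the single parameter.
The corresponding one-particle Fokker–Planck equation, Fourier transformed
in space (wave vector taken along x by isotropy) and in the angle, couples
angular harmonics f_m through the advection term.  The physically admissible
sector is even and π-periodic in the half-angle (the odd sector is excluded
by the φ → φ + π symmetry of the spectrum's construction); folding the even
harmonics onto m ≥ 0 gives a tridiagonal complex-symmetric eigenproblem for
the decay rates λ:

* diagonal: m² (pure Fourier relaxation),
* interior bonds: −i q/4 with q = 2 k Pe,
* 0↔1 bond: the boundary term of the fold doubles the coupling out of m=0;
  symmetrizing yields a √2-weighted bond −i √2 q/4.

This is the recurrence of the even π-periodic Mathieu functions at purely
imaginary parameter; eigenvalues are a/4 where a(q) are the cosine-elliptic
characteristic values.  The truncation keeps m = 0…Q ("cutoff" Q).

### Bond conventions

The package carries two conventions.  `fold="exact"` is the folding above;
it reproduces the Mathieu characteristics — small-q series a₀ = q²/2, first
double point at q_c = 1.4687686 (matching the double-point literature to
every printed digit), the large-q Poincaré asymptotics — and is the default
for every physical result.  `fold="printed"` uses uniform bonds −i q/2; it
is the textbook two-mode normalization in which the Q=1 truncation

    [[0, −iq/2], [−iq/2, 1]],   λ = (1 ± √(1−q²))/2,

is the model exceptional point with coalescence exactly at q\* = 1,
λ\* = 1/2, and it is also the convention in which the advection-dominated
(q ≫ Q²) limit is a clean tridiagonal Toeplitz matrix.  The two conventions
differ by an activity rescaling plus the boundary-bond weight; only the
exact fold has the continuum (Q → ∞) limit of the physical operator.  They
are never mixed within a computation.

## Spectral contracts

`diagonalize` is a dense LAPACK eigendecomposition (complex general; Q up to
~1000 is comfortably desk-scale, so no sparse path is provided) with three
verified contracts: per-pair residual ‖Av − λv‖ ≤ 10⁻⁹‖A‖, eigenvalue sum
equal to the exact trace Q(Q+1)(2Q+1)/6 to 10⁻⁹ relative, and spectrum
closed under conjugation.  Eigenvectors are unit-norm with the phase gauge
"largest-magnitude component real and positive", which removes the sign
ambiguity of projection magnitudes.  Sorting is ascending Re, then
ascending Im; the slowest mode breaks Re-ties toward minimal |Im|, then
non-negative Im.  An eigenvalue is treated as real iff
|Im λ| ≤ 10⁻⁹ max(1, |λ|).

Conjugation closure is not an accident of symmetry arguments: the diagonal
gauge diag(iᵐ) maps the operator to a *real* matrix (bonds ±q/4).  All
real-eigenvalue counting uses this real form, because LAPACK's real
eigensolver returns exactly zero imaginary parts for real eigenvalues and
exactly conjugate pairs otherwise — the count is integer-exact, with no
tolerance tuning near transitions.

## Exceptional points

Each exceptional point (EP) converts one real eigenvalue pair into a
conjugate pair, so the real count drops by exactly 2.  Detection bisects
this integer signal rather than thresholding eigenvalue distances, which is
robust against the near-degeneracies between non-coalescing branches that
plague distance-based detectors.  `scan_cascade` sweeps a log grid (60
points per decade by default), recursively subdivides any step whose count
drops by more than 2, and bisects each transition (default tolerance 10⁻⁶
in q).  Defectiveness at the EP itself is not certified numerically —
eigenvector condition numbers diverge there — the EP is characterized by the
realness transition alone.

Two scaling laws are measured around the cascade.  Just below each EP the
gap of the two slowest *real* eigenvalues closes as (q\* − q)^{1/2}, the
generic Puiseux behavior of a second-order EP; the fit uses relative offsets
δ/q\* ∈ [10⁻⁵, 10⁻²].  Along the cascade, the count N(q) of EPs below q
grows as q^{1/2}, i.e. EP density ~ q^(−1/2); the density fit is taken over
the full cascade from the first EP up to the scan bound and gives −0.51 at
Q=400, q ≤ 10⁴.

A reliability caveat belongs here.  The counted locations reproduce the
known double points of the imaginary-parameter Mathieu characteristics
(1.46877, 16.471, 47.81, 95.48, …, asymptotically q_r ≈ 2.04 (2r+1)²)
exactly up to q ≈ 2×10³ at Q=400.  Beyond q ≈ 3.6×10³ the real-eigenvalue
count starts to flicker non-monotonically and inflates relative to the
Mathieu sequence (counted N(10⁴) ≈ 74 versus ≈ 35 double points): in the
crossover band Re λ ~ q/2 the matrix is so non-normal that double-precision
eigenvalues complexify spuriously — a pseudospectral effect, not a
truncation artifact (Q=800 counts agree with Q=400).  The operational count
is exactly what a direct numerical diagonalization of the truncated
operator measures — the quantity behind the q^{1/2} growth observed in this
kind of experiment — and the scan now skips count rises with a warning and
merges flicker duplicates; the contamination range and the Mathieu
ground-truth comparison are stated so that users do not mistake
high-q counted EPs for certified double points.

## Perturbative and asymptotic oracles

**Small q.**  Second-order perturbation theory in the exact fold gives
λ_r = r² − q²/(8(4r²−1)) for r = 0 and r ≥ 2; for r = 1 the √2 boundary bond
contributes and the exact coefficient is λ₁ = 1 − 5q²/48 (equivalently
a₂ = 4 − 5q²/12, the classical value continued to imaginary parameter).  The
generic 1/(8(4r²−1)) formula at r=1 is a large-index approximation; the
package implements the exact series and verifies it against diagonalization
(residual ratio 16 per halving of q).  First-order eigenvector mixing gives
the polar overlap |⟨1|0⟩| = (√2/4) q ≈ 0.35355 q — this prefactor is the
package's measured and derived value — and the nematic overlap appears only
at second order, |⟨2|0⟩| = (√2/64) q², the structural origin of γ = 0 for
nematic interactions at low activity.

**Advection limit (q ≫ Q², printed convention).**  With the diagonal
dropped the operator is tridiagonal Toeplitz: eigenvalues
−i q cos((n+1)π/(Q+2)), sine eigenvectors.  The first-order real correction
is computed as the contraction of diag(m²) with the normalized sine
eigenvector — an operationally defined first-order shift, used instead of a
closed-form expression, and checked against full diagonalization (≤ 1% for
every mode at Q=6, q=10⁴).

**Large q.**  The Poincaré asymptotics of the Mathieu characteristic with
s = 2m + 1 give, in the decay convention (branch fixed by Re λ ≥ 0 and
continuity with the numerics),

    Re a_m = s√(2q) − (s²+1)/8,    |Im a_m| = 2q − s√(2q).

Note the minus sign of the (s²+1)/8 term in Re; the numerics settle the
branch (0.02 % agreement at q = 100 versus 3.6 % for the opposite sign).
The even π-periodic sector contains only every other Mathieu mode, so the
operator's r-th conjugate pair corresponds to Mathieu index 2r (s = 4r + 1):
consecutive pairs have Re ratios 5, 9/5, 13/9, … — verified to five digits
at q = 100 s².  For the Fourier content of the slowest mode, the reliable
asymptotic statement is the q^(−1/8) decay, uniform across harmonics; the
l-dependent prefactor implemented as √((2l)!)/(l! 4ˡ)·√2·(π²q)^(−1/8) is an
asymptotic estimate whose source expression is ambiguous and which has not
converged at q ≤ 10⁴ (measured c₀…c₅ at q = 10³: 0.346, 0.478, 0.447,
0.400, 0.342, 0.279), so it is exposed for orientation but never asserted
quantitatively.  Each harmonic joins the −1/8 law at its own activity
threshold: at Q=400 the fitted slopes over q ∈ [10³, 10⁴] are −0.125 (c₀)
and −0.119 (c₁), while c₂ and c₃ approach the law only in the next decade.

## Exponent extraction

All exponents are plain OLS on (log q, log y) — the inputs are
deterministic, so no weighting scheme is justified — with the standard OLS
slope error reported.  Default windows: low q ∈ [10⁻³, 10⁻²] at Q=50 and
high q ∈ [10³, 10⁴] at Q=400, giving two safety decades to both the first
EP and the truncation edge.  Grid density beyond 20 points per decade moves
the slopes by < 0.005.  A practical note on validity: the slowest mode
localizes in the first ~3 q^{1/4} harmonics, so its window of truncation
independence is far wider than the q ≪ Q² criterion suggests (Q=60 already
reproduces Q=400 at q = 10⁴ to machine precision); the conservative Q²/10
bound is still enforced for sweeps that use the full spectrum.

## Toy model of coupled exceptional points

The 4×4 model places two square-root EPs at ε = 1 and ε = 20 in two 2×2
blocks offset by 10, coupled by a nearest-neighbour chain of strength
c√ε (c = 0.1); the √ε growth mirrors the N ~ q^{1/2} cascade count, and a
linear-coupling variant is available for sensitivity analysis.  The entry
placement within the blocks is a documented reconstruction — the block
spectra ±√(1−ε) and 10 ± √(20−ε), the EP locations, the offset, and the
coupling pattern are fixed; the realness transitions of the coupled model
are verified numerically at ε ≈ 1.11 and ε ≈ 20.45 ("slightly shifted" by
the coupling, as expected).  The projection of the slowest mode onto
(0,0,0,1) — the fourth component of the unit-norm lowest-Re eigenvector —
decays with a small fractional power far beyond both EPs, the qualitative
signature of coupled-EP scaling.  Quantitatively this implementation
measures a log-log slope of −0.159 over ε ∈ [10², 10⁴] (crossing over to
−1/2 beyond ε ~ 10⁶) rather than −1/8; within the documented transcription
space (block-entry placements, inter-block-only coupling, linear coupling,
eigenbasis-coefficient projections) no variant reproduces −1/8 in that
window, so the measured value is reported as is.

## Mean-field instability

Linearizing the mean-field kinetic equation with a Kuramoto-type alignment
of symmetry n around the disordered state adds Γ̃ to the n-th diagonal
entry of the mode dynamics.  The default threshold is the leading-order
balance Γ̃_c = Re λ₀ / c_n; the "exact" method bisects the rank-one
perturbed operator A − Γ̃ e_n e_nᵀ for the smallest coupling with a
non-positive real eigenvalue.  For a complex-symmetric operator the true
first-order shift involves the bilinear overlap rather than |c_n|, so the
two methods agree in scaling but can differ by an O(1), q-dependent factor;
both are computed and compared in the tests.  At q = 0 the slowest mode is
marginal (λ₀ = 0) and Γ̃_c = 0; a projection below 10⁻¹⁴ is reported as a
structural zero (that symmetry cannot be excited).  γ exponents are fitted
from the ratio threshold, so γ = α − β_n holds by construction and serves
as a regression consistency check.

Spatial diffusion adds a uniform shift λ → λ + (D/D_r ℓ²) k² to all
branches; at low activity this replaces the q² scaling of the threshold's
numerator by k², at high activity it is subleading.

## Langevin simulation and closed loop

`simulate_abp` integrates the free dynamics by Euler–Maruyama with
dt ≤ 0.05 enforced: the angular step is exactly Gaussian, so the only
integrator bias is the O(dt) positional quadrature.  Seeding is
counter-based: particles are grouped in blocks of 1024, block j drawing from
Philox(key = (seed, j)), so enlarging the ensemble appends streams without
reshuffling existing trajectories, and equal seeds give bit-identical runs.

The decay estimate forms the intermediate scattering function
F(k, t) = ⟨exp(i k Δx)⟩ from particle averages with time origins strided by
half a relaxation time, then fits the *complex* correlation on
t ∈ [0.3, 5]/λ̂ with a two-exponential variable-projection least squares
(amplitudes solved linearly at each iterate), initialized from the spectral
module: the two slowest real modes below the first EP, the conjugate pair
above it.  A log-linear tail fit is ill-posed past the EP — |F| oscillates
through zeros — and linear-prediction (Prony) estimators showed a strong
noise-induced bias on synthetic data (+10 % at realistic noise), while the
variable-projection fit is unbiased there; this motivated the estimator
choice.  Uncertainty is a seeded bootstrap over particles (1000 resamples
by default); a correlation below three standard errors everywhere in the
window raises an insufficient-signal error.

What the generator does and does not emulate: it is the exact free model —
constant speed, pure rotational white noise — so closed-loop agreement
validates the operator construction and the estimator, not the robustness
of the spectra to interactions, speed fluctuations, or spatial diffusion,
which are outside the free dynamics.  The closed-loop tests run q = 0.25, 1
and 4 at 10⁴ particles (dt = 0.02, duration 12/λ₀) and the activity-collapse
pair (Pe, k) = (1, 1) versus (2, 0.5); agreement within three bootstrap
standard deviations ties the Langevin level to the spectral level across
the first EP.

## Problem sizes and numerical choices

Dense diagonalization of the 401×401 operator takes ~0.5 s with
eigenvectors, ~20 ms for the real-form eigenvalues, so the default study
sizes (Q = 50 low sweep, Q = 400 high sweep and cascade to q = 10⁴,
10⁴-particle simulations) complete in minutes on one core.  Bisection
tolerances: 10⁻⁶ in q for EP location (10⁻⁴ in the bulk cascade scan, where
location precision is irrelevant to the density fit), 10⁻¹⁰ relative for
thresholds.  Ties in branch matching during sweeps are resolved by Hungarian
assignment on eigenvector overlaps, with a logged warning when two overlaps
are within 10⁻⁶.

## Known limitations

* The odd angular sector and wave vectors off the x-axis are excluded by
  symmetry, not computed.
* EPs of order higher than two are not classified; the realness count would
  drop by more than 2 in a single unresolvable step.
* The large-q Fourier-coefficient prefactor is indicative only (see above).
* The toy model's projection exponent differs from the idealized −1/8 in
  the standard window; see the toy-model section.
* The mean-field treatment fixes q = 2kPe as one parameter; spatially
  resolved mode coupling (density gradients on the interaction scale) is
  out of scope.
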