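# Methods

## Model and geometry

A d-variate normal `N(μ, Σ)` lives on the `d(d+3)/2`-dimensional manifold
`N(d)` with the Fisher metric
`ds² = dμᵀΣ⁻¹dμ + ½ tr((Σ⁻¹dΣ)²)`.  The induced geodesic distance ρ_N is
invariant under the affine action `(A, a)·N(μ, Σ) = N(Aμ + a, AΣAᵀ)` and
has closed forms on three totally tractable subfamilies:

* d = 1: `ρ = √2 · log((1+Δ)/(1−Δ))` with the cross-ratio
  `Δ(μ₁,σ₁;μ₂,σ₂) = √(((μ₂−μ₁)² + 2(σ₂−σ₁)²) / ((μ₂−μ₁)² + 2(σ₂+σ₁)²))`
  (hyperbolic geometry of the upper half-plane at scale √2);
* equal means (totally geodesic submanifold): the affine-invariant SPD
  distance `ρ = (1/√2)‖Log(Σ₁^{-1/2}Σ₂Σ₁^{-1/2})‖_F`;
* equal covariances: `ρ = h_fr(Δ_Σ)` with `h_fr(u) = √2 arccosh(1+u²/4)`,
  where Δ_Σ is the Mahalanobis distance of the means.  The Mahalanobis
  distance is a maximal invariant of the translation action, so any
  invariant distance on that submanifold must factor through it; the
  scalar profile is read off the univariate case.

The general distance is bracketed by the Calvo–Oller lower bound
ρ_CO — the half-trace-metric distance between the embedded matrices
`f(μ,Σ) = [[Σ+μμᵀ, μ],[μᵀ, 1]]` in `P(d+1)` — and by three closed-form
upper bounds: the triangle route through a common-mean corner
(`ρ_P(Σ₁,Σ₂) + min(Δ_Σ₁, Δ_Σ₂)`), the Strapasson–Porto–Costa (SPC) bound,
and `√DJ` (square root of the Jeffreys divergence, from Cauchy–Schwarz on
the exponential-geodesic energy).

The SPC bound is implemented as

    U = √(2 Σᵢ log²((Aᵢ+Bᵢ)/(Aᵢ−Bᵢ))),
    Aᵢ = √((1+Dᵢᵢ)² + mᵢ²),  Bᵢ = √((1−Dᵢᵢ)² + mᵢ²),

with D the eigenvalues of the Σ₁-whitened Σ₂ and m the correspondingly
rotated whitened mean gap.  This grouping of the radicals reproduces all
three published reference evaluations (5.4302, 2.6072, 6.0392), which is
how the ambiguity in the displayed formula was resolved.

## Curve-length approximation

For any curve c(t) with `c(0)=N₁, c(1)=N₂` and closed-form points, the
discretized length `Σᵢ √DJ(c(tᵢ), c(tᵢ₊₁))` converges to the Riemannian
length as the grid refines, and every length upper-bounds ρ_N.  Curves
implemented: linear interpolation of (μ, Σ); the mixture geodesic (linear
in the moment parameters `η = (μ, −Σ−μμᵀ)`); the exponential geodesic
(linear in the natural parameters `θ = (Σ⁻¹μ, ½Σ⁻¹)`, covariance path the
matrix harmonic mean); their parameter-wise average; and the projected
Calvo–Oller curve `t ↦ f⁻¹(proj(γ_P(f(N₁), f(N₂); t)))`, where γ_P is the
SPD-cone geodesic and the projection back onto the embedded submanifold
simply rescales the last row/column by the corner entry β.

Two exact identities anchor the machinery: the embedding preserves KL
divergences (`KL(N₁:N₂)` equals the KL of centered (d+1)-variate normals
with the embedded matrices as covariances), so segment divergences along
the projected curve can be evaluated on the matrices directly; and the
discrete energy `T·Σᵢ DJ(c(tᵢ),c(tᵢ₊₁))` along the mixture/exponential
geodesics equals DJ(N₁,N₂) exactly for every T (the chord divergences are
Bregman divergences of affinely reparameterized dual geodesics).  The
latter gives the discrete Cauchy–Schwarz guarantee
`length(m/e-geodesic) ≤ √DJ` at any resolution.

### Discretization conventions

Two node conventions coexist deliberately:

* `nodes="trimmed"` (default of `curve_length`): sum over segments with
  nodes `i/T, i = 1..T`.  This is the convention that reproduces the
  published worked-example values (5.31667 at T=1000; 3.1136 / 3.1362 /
  3.1391 at T=100/500/1000 on the benchmark pair) and is therefore used
  for all reference comparisons.
* `nodes="full"`: all T segments, `i = 0..T`.  This is a genuine
  discretized curve length (no omitted segment), hence ≥ ρ_CO up to
  O(1/T²); it is used wherever that inequality matters structurally — the
  benchmark ratios κ, ordering property tests, and DTI edge weights.

The trimmed estimate under-counts by roughly one segment (one part in T of
the length); tests that compare it against lower bounds allow a few
average segments of slack.  The projection certificate
`δ_T = (1/T) Σ_{i=1..T} |log β(tᵢ)|/√2` samples nodes `i/T, i = 1..T`, and
the sandwich reported by `sandwich()` is
`(ρ_CO, trimmed length, ρ_CO + 2 δ_T)`.

## Dissimilarity D_CO

The maximal-invariant dissimilarity `D_CO = 2 Σᵢ log²((1+Δᵢ)/(1−Δᵢ))`
(with `Δᵢ = Δ(0,1; μ̄ᵢ, σ̄ᵢ)`) requires a choice of diagonalizing basis for
`Σ₂Σ₁⁻¹`: raw eigenvectors of the nonsymmetric product carry arbitrary
scalings that change `μ̄` and break symmetry.  The package fixes the
canonical whitening eigenbasis `Q = Σ₁^{1/2}Ω` with
`Σ₁^{-1/2}Σ₂Σ₁^{-1/2} = Ω diag(σ̄²) Ωᵀ`, which restores exact symmetry.
In this basis the square-root variant collapses to the univariate
closed form at d=1, so the literal squared-sum reading is the default
(the two are both exposed; no published numeric anchor exists for D_CO).

## Exponential-family conventions

The sufficient statistic is `(x, −xxᵀ)` with natural parameter
`θ = (Σ⁻¹μ, ½Σ⁻¹)` and log-partition

    F(θ) = (d/2)·log π − ½ log|θ_M| + ¼ θ_vᵀ θ_M⁻¹ θ_v,

the unique form that satisfies the defining properties used downstream:
`∇F(θ) = η`, the Legendre identity `F(θ) + F*(η) = ⟨θ, η⟩`,
`F*(η) = −½ log((2πe)^d |Σ|)` (negentropy), and
`B_F(θ₁:θ₂) = KL(N₂:N₁)`.  All are verified against independent oracles
(numeric quadrature, finite differences, the closed-form entropy).

## Enclosing balls

`rieseb_spd` is the Hadamard-space farthest-point iteration: start at the
first matrix and step a fraction `1/(t+1)` along the geodesic toward the
currently farthest input; ties break to the lowest index and the loop
stops early when the center moves less than 1e−10.  For Gaussian sets the
three-step heuristic embeds, solves in `P(d+1)`, projects the center back
(the reported `projection_gap` measures how far the cone center sat from
the embedded submanifold) and recomputes the max-ρ_CO radius.  For
shared-covariance sets the *within-family* circumcenter is exact: whiten
the means by a Cholesky factor of Σ, solve the Euclidean smallest
enclosing ball (Welzl's algorithm, deterministic insertion; an iterative
fallback beyond 10³ points), and map back.  Note that the shared-Σ family
is not minimax-closed — the unconstrained heuristic center can have a
strictly smaller ρ_CO radius than the within-family circumcenter, and the
tests assert exactly that inequality rather than agreement of the two
centers.

## Synthetic scenarios and the benchmark

The generator implements the two study conditions used for curve
comparison: (1) `cholesky-uniform` — means entrywise Unif(0,1) and
`Σ = LLᵀ` for lower-triangular L with entries Unif(0,1), both normals
drawn independently; (2) `standard-vs-diagonal` — `N(0, I)` against a
zero-mean normal with `diag(u)` covariance, `uᵢ ~ Unif(0, a)`.  Raw
Cholesky draws occasionally produce numerically singular covariances (a
diagonal entry of L near zero); those are redrawn (~1e−4 of draws).  All
randomness flows from one seeded NumPy PCG64 generator; the seed is
echoed in every report.

The benchmark reports `κ_c = ρ̃_c / ρ_CO` per curve kind, averaged over
pairs reused across kinds, with full-node lengths so that κ ≥ 1 holds
structurally.  Replication runs use d=1 with 200 pairs at T=200 and
d=2..5 with 60 pairs at T=100 — sizes chosen so the whole suite completes
in a couple of minutes on one core while leaving the qualitative pattern
(the projected Calvo–Oller curve wins at these dimensions and separations)
clearly resolved.

What the generator does *not* emulate: real DTI tensors (no Rician noise,
no spatial correlation), heavy-tailed or degenerate covariances, or the
d ≳ 11 regime where the mixture geodesic overtakes the projected curve.
Passing benchmarks therefore certify the geometry code, not performance
on any particular imaging pipeline.

## Numerical choices

* Covariances are symmetrized as `(M+Mᵀ)/2` on input; SPD validation
  rejects smallest eigenvalues below `1e−12 × λ_max` rather than clamping.
* Generalized eigenvalues are computed by Cholesky whitening (`eigh(P₂,
  P₁)`), never by forming the nonsymmetric `P₁⁻¹P₂`.
* SPD geodesics use the generalized eigendecomposition
  `γ(t) = (P₁V) diag(wᵗ) (P₁V)ᵀ` with `VᵀP₁V = I` — no explicit matrix
  square roots, stable for badly conditioned pairs.
* `arccosh(1+x)` is evaluated as `log1p(x + √(x(x+2)))` so the scalar
  profiles `h_fr`, `h_co` stay accurate for tiny separations.
* Geodesic parameters outside [0, 1] are rejected unless an explicit
  `extrapolate=True` is passed.

## Known limitations

* The fixed-mean projection *distance* formula
  `(1/√2) arccosh(d + Δ²)` is exact at d=1 but cannot vanish at zero
  separation for d ≥ 2; it is shipped as
  `fixed_mean_projection_distance` and flagged experimental (the
  projection *point* `N(μ₂, Σ₁ + ½ΔμΔμᵀ)` is exact and unambiguous).
* The trimmed discretization can sit a few parts in T below ρ_CO for very
  close pairs; use `nodes="full"` when the lower-bound inequality matters.
* ρ̃ is not a metric (no triangle inequality); ρ_CO and the exact
  subfamily distances are.
* The enclosing-ball heuristic approximates the Fisher–Rao circumcenter
  through the ρ_CO relaxation; `projection_gap` is its quality signal, and
  no optimality guarantee is claimed for the returned Gaussian center.
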