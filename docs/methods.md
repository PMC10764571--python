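# Methods

## Model and assumptions

The package analyses two reaction-cross-diffusion layers coupled by linear
inter-layer transport of the first n species. Standing assumptions, checked
where feasible at run time:

* both diffusion matrices have spectra in the open right half plane at the
  equilibrium (positive definiteness; `build_linearization` rejects
  violations);
* a homogeneous equilibrium exists: in the 1D-1D geometry it solves the
  coupled algebraic system and may be η-dependent and asymmetric between
  layers; in the 1D-2D geometry the interface condition forces a shared,
  η-independent equilibrium (`coupled_equilibrium` refuses layer kinetics
  whose roots differ by more than 1e-10);
* only stationary (Turing) bifurcations are characterised: the marginal
  conditions are a₀ = ∂ξ a₀ = 0 at λ = 0. Oscillatory (Hopf/wave)
  instabilities are out of scope; in the 1D-1D geometry the Routh–Hurwitz
  classification still *detects* them per mode, but no Hopf curves are
  continued. In the 1D-2D geometry the dispersion relation is transcendental
  in λ and no polynomial-type criterion exists, so stability claims are
  restricted to the marginal (λ = 0) level plus simulator verification;
* ξ is treated as a continuous variable in all analytics; the only
  discrete-mode surface is `mode_scan` (ξ = (qπ/L)²).

## Key parameters

| name | meaning | default / typical |
| --- | --- | --- |
| η | coupling strength multiplying A and B | analysis argument; presets use 0–10³ |
| A, B | n×n exchange matrices (into surface / into bulk) | identity; diag(α, β) in the reference scenarios |
| δ | bifurcation parameter: any diffusion coefficient or χ, via `with_param` | usually the inhibitor diffusion `d_vS`/`d_vB` |
| L, H | domain length, bulk depth | presets: L = 1000 (1D-1D), L = H = 50 (1D-2D) |
| χ | chemotactic sensitivity, h(c) = χc with k(u) = u₁ | 50–120 in the chemotaxis scenarios |
| M | clip cap of the pseudo-linear kinetics | 10 × the largest linear-branch equilibrium image, so the kinetics are exactly linear near equilibrium; configurable |

The chemotactic sensitivity is bound to h (h(c) = χc, k(u) = u_attr with
unit gradient): the caption-level χ values enter the linearisation only
through h(c*) = χc*, which this binding reproduces.

## Numerical choices

* **Dispersion polynomial**: det(λI + C) is sampled at n+m+1
  Chebyshev-spaced λ values (radius 1 + ‖C‖₂) and interpolated; this keeps
  the construction independent of the eigenvalue solver used as test oracle.
* **Routh–Hurwitz**: marginal tolerance τ = 1e-10·max|coeff|; verdicts
  within τ of zero count as unstable so instability regions are closed sets.
* **Matrix entire functions** F₁, F₂, F̃₂: direct power series for
  H²‖R‖ ≤ 100 (terminates exactly for nilpotent R, the generic two-species
  critical case); otherwise eigendecomposition with scalar closed forms when
  the eigenvector matrix has condition number < 1e8, else an
  extended-precision series with a cancellation guard that raises rather
  than return digits it cannot support. No matrix square root is formed
  anywhere.
* **Coupled equilibria**: Newton with the analytic block Jacobian, continued
  in η with an adaptive step (halve on failure, double on success, capped by
  max(1, η/4)). The residual tolerance grows with η·‖A,B‖ because round-off
  in the exchange term is proportional to it. Only the branch rooted at the
  user's η = 0 equilibrium is tracked; no global root enumeration.
* **Critical points**: damped Newton on (a₀, ∂ξa₀) in (ξ, δ) with
  finite-difference Jacobian (steps 1e-6·(1+ξ), 1e-6·(1+|δ|)), warm-started
  from the driving layer's classical values. ξ-branches are enumerated by
  sign changes of ∂ξa₀ on a 64-point log grid over [1e-4, 1e2]; the branch
  with smallest δ is the reported global onset.
* **Marginal-curve continuation** uses natural continuation in η with the
  same adaptive stepping, not pseudo-arclength: every reference curve
  δ_c(η) here is single-valued in η (non-monotone curves fold in value, not
  in parameter), and natural continuation reaches η = 10³ in a few dozen
  steps. A folded curve would require re-introducing arclength
  parametrisation.
* **Single-layer numeric onset** (≥3 species or chemotaxis): bisection
  (brentq, rtol 1e-8) on δ of min_ξ det(ξD − J), the minimum located on a
  geometric ξ-grid refined by bounded scalar minimisation. The homogeneous
  stability of the layer is *warned about*, not enforced: one reference
  Schnakenberg parameter set (a = 0.15, b = 0.2) has tr J = +0.01 yet its
  closed-form critical diffusion is still standardly quoted, so the guard
  must not refuse it.
* **Simulator**: first-order IMEX — implicit diagonal diffusion by
  tridiagonal solves (approximate x/y factorisation in 2D), explicit
  reactions, exchange and chemotaxis flux (centred, face-averaged h, no flux
  limiter and no positivity clamp: positivity must emerge from the kinetics,
  which makes it a genuine test). Node-based grids with reflecting ends;
  with trapezoid weights the discrete diffusion conserves mass exactly,
  which the conservation test exploits. The Robin interface condition is
  closed with a ghost point: the implicit solve sees a reflecting boundary
  and the exchange flux enters the interface row as an explicit source
  2/Δy·ηB̃(ũ_S − u_B). Default dt = 1e-2, halved automatically (up to a
  configurable number of times) when the blow-up detector (any field beyond
  1e8 × equilibrium scale, or non-finite) fires. Initial data are the
  equilibrium plus uniform noise of relative amplitude 1e-2, with one
  spawned random stream per layer so an uncoupled surface reproduces a
  standalone run bit for bit. Stored 2D arrays put the interface at the last
  y index (y = H); the analytics use the flipped depth coordinate
  internally.

## What the reference scenarios do and do not show

The figure presets (`fig2a` … `fig7`) expand to the caption parameter sets
of the reference bilayer study of coupled Schnakenberg, pseudo-linear
chemotaxis and J_p systems. Two caveats, both inherited from the printed
parameters and deliberately not patched in the presets:

* the pseudo-linear *surface* parameter set of the 1D-2D scenarios has
  f_u = a₁ − a₂ = 0 at equilibrium, which rules out a classical two-species
  surface instability, and its equilibrium (0.25, 0.5) differs from the bulk
  one (0.5, 0.75), which violates the shared-equilibrium requirement of the
  1D-2D geometry. The printed surface-critical values for those scenarios
  are therefore not reproducible and are excluded from verification; the
  bulk-side values (≈8 and ≈37.5) reproduce exactly as printed.
* qualitative 1D-2D morphology checks in the test suite therefore use
  self-consistent stand-ins: a Schnakenberg surface over a Schnakenberg bulk
  for interface-localised surface-driven patterns, and a pseudo-linear
  surface with a₀ = 1.5 (which shares the bulk equilibrium (0.5, 0.75,
  0.25)) for bulk-driven chemotaxis runs. With these, perturbations at the
  printed sub-threshold "wave" parameters decay — the interface-nucleated
  spreading pattern is a multistability phenomenon that does not survive the
  parameter reconstruction — so no wave-nucleation claim is asserted.

The test suite's simulations run at reduced problem sizes chosen for a
wavelength-resolving but economical discretisation: 1D-1D concordance runs
use L = 100 with 128–256 nodes (≳8 nodes per pattern wavelength), the
1D-2D runs 64×64 to 96×32 nodes on L, H ∈ {30, 50, 100}, and the
amplitude-proportionality check uses d_vS = 25 (patterned surface) over a
strongly slaved bulk (d_vB = 5), where linear slaving predicts the bulk
amplitude ∝ η; the measured η-ratio is 0.52 for η ∈ {0.005, 0.01}. These
scaled-down runs probe the same regimes as the full-resolution figures but
do not resolve fine spot morphology; synthetic noise is uniform and
homogeneous, unlike biological initial conditions.

## Degenerate inputs and tie-breaks

* Clipped kinetics evaluated off the linear branch: the Jacobian uses the
  one-sided φ′ ∈ {0, 1} and emits a warning; equilibria are required to sit
  strictly inside (0, M).
* αβ = 0 collapses the homogeneous-mode quadratic to a linear equation; its
  root is returned only when positive, otherwise the band is empty.
* Mass-conserving pairs f_S = −f_B reduce, at strong coupling, to a pure
  (cross-)diffusion equation; `strong_coupling_limit` then reports "no
  finite critical value" (None) rather than a number.
* δ_c′(0) with ∂δ|P₀| = 0 (degenerate transversality) raises instead of
  returning ±∞.

## Known limitations

* No Hopf/wave bifurcation tracking, no weakly nonlinear (amplitude)
  analysis, no spherical or deforming-interface geometries, and no
  spatially heterogeneous bulk equilibria.
* The 1D-2D transcendental dispersion relation is only ever evaluated at
  λ = 0; growth rates of 1D-2D modes come from the simulator, not from a
  root finder in λ.
* The simulator is first-order in time; it verifies growth/decay and
  wavelength selection, not high-accuracy transient dynamics.
* Continuation assumes the marginal curve is single-valued in η (see
  above).
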