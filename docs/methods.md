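# Methods

## Model class

`acmekit` solves hybrid master-equation systems for a family of densities
`p_k(x, t)` over a continuum state `x ∈ R^d_+` (scaled copy numbers
`x = X/Ω`) and discrete states `k`:

```
∂t p_k = Σ_i  −e_iᵀ∇[r_ik p_k] + (1/2Ω) e_iᵀ H(r_ik p_k) e_i        (reactions)
       + Σ_j  −f_jk p_k + ‖e_j‖ ∫ f_jk B_jk (shifted along e_j) dz   (jumps)
       + Σ_ℓ  −g_kℓ p_k + g_ℓk p_ℓ                                    (transitions)
```

Each reaction advects (and, at finite system size Ω, diffuses) density along
its integer displacement `e_i`; jump processes redistribute density along
`e_j` with a size kernel (exponential bursts, fragmentation); transitions
exchange density between discrete states pointwise in `x`.

Two deliberate departures from a classical probabilistic model are supported
and are what make population-level processes expressible:

* **signed transition rates** (opt-in via `allow_signed_rates`): a transition
  into a *phantom* state at rate `−G(x)` adds `+G(x) p` to the physical
  state, linearising exponential growth/selection.  The phantom density is
  bookkeeping only and may be negative.
* **non-probability kernels**: a fragmentation kernel integrates to two (two
  fragments per division), so number is *not* conserved while volume is.

## Discretisation

Uniform cell-centred tensor grid, cells `[m·dx, (m+1)·dx)^d`, cell averages,
`mass = Σ values · dx^d`.  Because every operator acts along one integer
direction, the grid is partitioned into 1-D *rays* per direction; all
operators are assembled and applied ray-wise, so no spurious diffusion enters
orthogonal directions.

**Advection** is the semi-discrete second-order Kurganov–Tadmor central flux

```
F_{j+1/2} = ½ v (p_L + p_R) − ½ |v| (p_R − p_L)
```

with MUSCL reconstruction.  Limiters: `minmod` (default, most dissipative),
`vanleer`, and `none` (unlimited central slopes — the *linear* variant used
wherever a matrix representation is needed).  Interface velocities are the
rate function evaluated at interface coordinates.  Ray-end fluxes are zero
(no-flux boundaries), so interior fluxes telescope and mass is conserved to
round-off.  The limited scheme is nonlinear in `p` (homogeneous of degree
one but not additive); the unlimited variant is exactly linear.

**Diffusion** is the conservative second difference of `r·p` along the ray
with zero-flux ends, scaled by `1/(2Ω dx²)`.  (For a ray with physical
spacing `dx·‖e‖` the `‖e‖²` of `eᵀHe` cancels against the spacing, leaving
`1/(2Ω dx²)` for any integer direction.)

**Jump operators** become per-ray matrices `W[m, s]`: the kernel mass
reaching destination cell `m` from source cell `s`, integrated exactly over
destination-cell arc intervals when the kernel has a closed-form cell
integral (exponential, uniform fragmentation) and by midpoint quadrature
otherwise.  Normalisation by mode:

* *probability* mode — kernel mass that would land beyond the ray end is
  parked in the boundary cell and each column is then scaled to sum to one
  exactly.  The boundary pile-up mimics the untruncated process, where an
  overshooting burst re-enters the bulk by drift; renormalising the escaped
  mass proportionally into the retained entries instead would effectively
  shorten bursts near the boundary and measurably biases the stationary
  density of the burst model (L1 error 0.027 vs 0.016 at dx = 0.05 on
  `[0, 4]`).
* *fragmentation* mode — exact-overlap integrals of the uniform kernel
  `2/y`, then each column is rescaled so its destination first moment equals
  the source coordinate exactly.  Volume conservation is therefore exact by
  construction; the per-event number gain is 2 up to O(dx²) quadrature error
  (and degenerates in the very first cell, whose fragments cannot be
  distinguished from their parent).

**Transitions** are pointwise exchanges; each loss appears as a gain
cell-by-cell, including for signed rates.  States flagged *absorbing* have
no outgoing terms evaluated.

## Time integration

Explicit SSP-RK3 (Shu–Osher; RK2 and Euler available) with a CFL-safe step

```
dt = safety · min( dx / max Σ|r|,  2Ω dx² / max Σ r|e|²,  1 / max local outflow )
```

recomputed each step (`safety = 0.4`).  The local-outflow bound covers jump
losses, transition rates and first-passage absorption, so stiff absorption
(α = 1000) is stable under plain explicit stepping; an optional
*split-local-sinks* mode treats autonomous sink transitions into absorbing
states with the exact factor `e^{−g dt}` per step instead, removing them
from the CFL bound (used for speed, validated against explicit stepping to
~0.1% in absorbed mass).  Snapshots are taken exactly at requested times by
clipping the step.  The solver contains no randomness; runs are bit-identical.

**Steady states.**  Besides time marching to `‖dp/dt‖₁/‖p‖₁ < 10⁻⁸`, a
`direct` method assembles the linear (unlimited-slope) operator as a sparse
matrix and solves for its null vector with one row replaced by the
normalisation.  This is the default for autonomous models because the
bistable gene-expression benchmarks mix modes on the switching-time scale
(~10–100 time units), which makes marching to 10⁻⁸ impractically long, while
the stationary densities here are smooth so the unlimited scheme is reliable.
The direct result agrees with a dense eigendecomposition on small grids to
10⁻¹⁰ and with time marching to the discretisation level.

## Closed-form benchmarks (`acmekit.analytic`)

* **Stationary bursty density** `∝ e^{−x/b} x^{r0/γ0−1} (1+x^n)^{r1/(nγ0)}`,
  normalised by adaptive quadrature on the truncated domain.
* **Mean switching times** across a threshold `x_c` for the burst process
  with decay `γ0 x` and Hill burst rate `H`:
  `T_high→low(x) = ∫_{x_c}^x e^{−M}[V − V(∞)] dy` and
  `T_low→high(x) = [1 − γ0 x_c V(x_c) e^{−M(x_c)}]/H(x_c) + ∫_{x_c}^x e^{−M} V dy`,
  with `M = log(x/H) − x/b + ∫ H/(γ0 y) dy` (closed form for Hill `H`) and
  `V = −∫_0^x [1/(bγ0y) + H′/(γ0yH)] e^{M}dy`.  These follow from the
  backward equation of the piecewise-deterministic process: differentiating
  once converts the exponential-kernel integral equation into a first-order
  ODE for `T′` with integrating factor `e^{M}`; the boundary term at `x_c`
  comes from the undifferentiated equation with an empty jump integral, and
  regularity at `x = 0` fixes the low→high constant.  Evaluation uses
  composite Simpson on a dense grid (4·10⁴ nodes, upper cut where `e^{M}`
  has decayed by 10⁻¹⁶ relative to its peak; ~10⁻⁸ determinism).  The
  formulas were cross-validated against a 2·10⁴-path Monte Carlo of the jump
  process (agreement ~1%) and against the PDE first-passage simulation
  (~1–3%).
* **Selection asymptotics**: critical point `x_c = 1 − 1/Λ` of the birth–
  death field `Λx(1−x) − x`, asymptotic growth rate `r0 = G(x_c)`, and a
  limiting Gaussian profile whose variance `σ² = x_c/(Ω(Λ−1))` follows from
  linearising the drift (restoring rate `Λ−1`) against the demographic
  diffusion `x_c/Ω`; a growth-field gradient shifts the centre by
  `G′(x_c)σ²/(Λ−1)` (negligible here).  The width was verified by the
  dominant eigenvector of the assembled operator on refined grids
  (σ → 0.01828 vs 0.01826).  Because the benchmark resolution dx = 1/143
  puts only ~2.6 cells per σ, the *realised* profile width is inflated by
  numerical diffusion (σ ≈ 0.027 with minmod); the profile-shape comparison
  therefore pins the Gaussian centre at `x_c` and fits the width by least
  squares (`fit_gaussian_width`), and both widths are reported.
* **Growth–fragmentation**: the self-similar solution
  `c(at)^{2/k}e^{−atx^k}` of pure fragmentation at rate `a x^k` with uniform
  binary offspring, and the growth(+x)/unit-decay variant
  `c e^{−2t}[a(e^{kt}−1)]^{2/k} e^{−a(e^{kt}−1)(e^{−t}x)^k}` with limit
  `c a^{2/k}e^{−ax^k}`.  The time rescaling mapping the first onto the
  second multiplies the fragmentation constant by `k`; the growth–decay
  builder uses rate `k·a·x^k` accordingly (with `a x^k` the solver
  reproduces neither the number growth nor the exact solution).  Both closed
  forms are residual-checked in their PDEs in the test suite.

## Benchmark problem sizes and tolerances

Chosen as the package's standard validation settings:

| case | grid | horizon | checked against |
|---|---|---|---|
| bursty stationary | dx 0.05 on [0,4] | steady (direct) | exact density, L1 ≤ 0.02, 2 modes |
| finite-mRNA ladder | dx 0.025, K=30, γ∈{5..80} | steady (direct) | 1/γ convergence, slope −1±0.2 |
| first passage | dx 0.025, α=1000, horizon 150 | explicit stepping | quadrature means within 5% |
| selection | dx 1/143, Ω=1000 | t = 5 | growth rate 2%, profile L1 0.05 |
| fragmentation | dx 0.005 | t − t0 = 2 | sup-error 5%, volume 10⁻³, shape L1 0.02 |

Domain truncations: gene expression `[0, 4]` (the stationary tail beyond 4
carries ~1.4% of mass — the price paid by the boundary treatment above and
the reason the bursty L1 tolerance is not tighter); selection `[0, 1]`
(natural support); fragmentation `[0, 3]` pure and `[0, 6]` with growth
(the broad early-time profile of the growth benchmark carries ~3% of its
number mass beyond 3, which would corrupt the comparison on the narrower
box).  The growth–decay shape comparison is made between unit-mass
normalised profiles because even the exact solution at `t − t0 = 2` still
differs from the `t → ∞` profile by L1 ≈ 0.027 in raw normalisation while
the shapes agree to ≈ 0.009.

The discrete-CME cross-check (protein marginal of the hybrid finite-mRNA
model vs the full truncated CME at γ = 10) plateaus at L1 ≈ 0.022 for all
dx ∈ {0.1, 0.05, 0.025}: that gap is the model difference between geometric
molecule bursts at B = 40 and their noiseless continuum limit (O(1/B)), not
discretisation error, so refinement does not reduce it.

## Random-model fuzzing

`generate_random_model(seed)` emits small well-posed models — 1–2 discrete
states, 1–3 reactions with non-negative quadratic-polynomial rates on
`[0, 1]`, optionally an exponential probability-mode burst kernel and
constant two-way transitions, diffusion on in half the models (Ω ∈ [50,
500]).  These exercise exactly the conservation structure (probability
kernels, non-negative transitions, no-flux ends) for which total mass is an
invariant; they do not emulate stiffness, signed rates, boundary-heavy
kernels or multi-dimensional networks, so passing the conservation fuzz says
nothing about accuracy on such regimes — those are covered by the case-study
benchmarks above.

## Degenerate inputs and numerical edge cases

Rates are validated (finiteness, sign policy) on a sample grid at model
validation and at operator compile time; non-finite densities abort
integration with the offending time and cell.  Zero-rate models integrate
exactly (dt collapses to the remaining time).  Kernel columns with all mass
beyond the boundary cannot occur for kernels with support at zero; custom
kernels that are negative anywhere on their support are rejected.  The
limited scheme can undershoot to tiny negative densities near sharp fronts;
nothing clips them, as mass accounting is exact either way.

## Known limitations

* One- and few-dimensional continuum spaces only (dense per-ray jump
  matrices are O(L²)); no adaptive meshing.
* Explicit time stepping only; strongly stiff non-sink terms will force tiny
  steps.
* Fragmentation kernels must be axis-aligned; binary fragmentation only (no
  aggregation/coalescence, which is quadratic in `p`).
* The direct steady-state path uses the unlimited linear scheme; for
  stationary densities with sharp fronts prefer `method="integrate"`.
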