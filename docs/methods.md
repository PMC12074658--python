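# Methods

This note documents the models, numerical procedures, parameter choices
and known limitations of `illcond-eco`. It is the package's own account of
its science; every empirical statement here is one the test suite or the
acceptance script computes.

## Model

The package studies the generalized Lotka-Volterra (GLV) system

    dn_i/dt = n_i ( r_i + sum_j A_ij n_j ),

where `n_i(t) >= 0` is the abundance of species `i`, `r_i` its intrinsic
growth rate, and `A_ij` the per-capita effect of species `j` on species
`i`. Every steady state solves the constrained linear problem
`-A n* = r`, `n* >= 0` (on its support), so equilibration is an analogue
linear solve; its difficulty is measured by the condition number
`kappa(A) = sigma_max(A) / sigma_min(A)`.

## The redundant ensemble

Interaction matrices are drawn from

    A = P^T (A0 - d I) P + eps * E,

with `A0_ij, E_ij ~ N(0,1)`, an `N x N` assignment matrix `P` of rank
`M <= N` encoding exact functional redundancies, density limitation
`d > 0`, and a small symmetry-breaking amplitude `eps`. A fraction
`1 - rho` of interspecific entries is zeroed (default connectance
`rho = 0.05`); a warning is raised at or below the percolation threshold
`rho <= 1/N`. With `P = I`, `eps = 0` this is the classical dense random
community. Four assignment constructions are supported (identity,
duplicate-columns, random-groups, random-low-rank).

Design choices that the formulation leaves open, and how we resolved
them:

- **Growth rates of redundant species.** Exact redundancy must extend to
  growth rates, so by default `r = P^T r0` with `r0 ~ N(0,1)`: species
  that share a functional role share `r`. This is forced by the
  phenomenology: if clones kept independent `N(0,1)` growth rates, their
  growth-rate gap (an O(1) number) would set the within-group exclusion
  rate, the eps=0 equilibrium set would contain no continuum (two
  same-group survivors would need exactly equal `r`), and settling times
  would be independent of `eps` — we verified numerically that the
  literal per-species reading gives tau flat over four decades of `eps`,
  while the lifted version gives `tau ~ 1/eps` exactly. With `P = I` the
  lift is the identity, so the well-studied baseline ensemble is
  unchanged. Set `redundant_r=False` for the literal per-species
  reading.
- **Where the sparsity mask acts.** Masking the assembled `A` ("post-hoc")
  destroys the rank-M degeneracy that the eps=0 analysis needs, so by
  default a shared mask is applied to `A0` and `E` *before* lifting
  through `P` ("group-level"); the post-hoc mode is available as a
  config switch. The mask keeps the diagonal and zeroes an exact count
  `floor((1-rho) N (N-1))` of interspecific entries (hypergeometric
  rather than per-entry Bernoulli sampling, so tests are deterministic
  given the seed).
- **Density limitation `d`.** No numerical value is standard. The default
  starts at `d0 = 3 sqrt(rho N)` — three times the effective
  post-sparsification interaction scale `sigma_eff sqrt(N)`,
  `sigma_eff = sqrt(rho)` — and doubles (at most 10 times) until the
  eps=0 part of `A` passes the diagonal-stability check. For `M < N`
  that check uses a small positive semidefinite tolerance: `A + A^T`
  then has exact zero modes on the redundant subspace and strict
  negative definiteness is impossible at any `d`; the eps-scale
  perturbation leaves those modes marginal, which is precisely the
  slow-manifold mechanism under study.
- **RNG discipline.** One root seed; `A0`, `E`, `r`, mask and `P` are
  drawn from named substreams, so the eps=0 counterpart is rebuilt from
  bit-identical draws and `A(eps) - A(0) = eps * (masked E)` holds
  exactly.

## The scaled-interaction ensemble

The alternative family `A = -I - (mu/N) * ones - (sigma/sqrt(N)) * A'`
has off-diagonal pairs `(A'_ij, A'_ji)` drawn from a bivariate Gaussian
with unit variance and correlation `gamma`; the diagonal of `A'` is zero
(self-limitation is the `-I` term) and growth rates default to `r_i = 1`.
The published formatting of the scale factors is ambiguous; we read them
as `mu/N` and `sigma/sqrt(N)`, the convention of the literature this
family comes from. The ensemble has a known transition from a unique
globally stable equilibrium to multistability at
`sigma_c = 2 / (1 + gamma)`, which the package detects numerically.

## Numerical integration

`integrate` uses the implicit Radau scheme with the analytic Jacobian
`J_ij = delta_ij (r_i + (A n)_i) + n_i A_ij`; default
`rtol = atol = 1e-12`. Termination is event-based: a derivative floor
`max|dn/dt| < 1e-14` (evaluated in log scale), a blow-up guard
`max n > 1e12` (reported, not raised), or the horizon `t_max` (default
`1e6`, logged when reached — the settling studies raise it so the floor
always fires first). Negative abundances are never clipped; the stiff
solver keeps them at the tolerance scale, which matters because clipping
would corrupt settling times and Lyapunov indicators.

## Equilibria and settling time

`find_equilibrium` integrates to the floor and then verifies: local
stability from the Jacobian spectrum; the complementarity conditions
(survivors have zero net growth, residual `<= 1e-8 ||r||`; extinct
species have non-positive invasion rate); and a Lawson-Hanson
nonnegative-least-squares solve of `-A n = r` as a direct residual
check. An independent, integration-free oracle (`equilibrium_lcp`)
solves the equilibrium linear complementarity problem by Murty's
least-index principal pivoting, which terminates for P-matrices — in
particular whenever `A + A^T` is negative definite. We use the LCP
solution, not NNLS, as the primary oracle: for nonsymmetric `A` the
NNLS optimality conditions (column conditions on the gradient) differ
from ecological non-invasibility (row conditions on growth rates), so
NNLS alone does not pin the equilibrium.

The settling time is `tau = inf{t : ||n(t) - n*||_2 <= xi}` with floor
`xi = 1e-7` (absolute distance, as the formula is usually printed). By
default tau uses *persistent* semantics — the trajectory must stay
inside the xi-ball for the rest of the record — which guards against
transient grazes; the plain infimum is available via `mode="first"`.
tau is evaluated on the solver's dense output with per-step refinement,
so it is invariant to the step grid. The survivor count `Ncoex` uses a
relative threshold `1e-6 x` (mean positive abundance), since the zero
norm of a numerically integrated vector is ill-defined.

## Conditioning analytics

All norms are spectral, so `kappa = ||A|| ||A^-1||` and the singular
value ratio coincide exactly. `kappa` is reported as infinity when
`sigma_min` falls below the machine-relative floor. The restricted
condition number uses the `N x |support|` column minor. The
iterative-solver bound `tau = log(xi) / log((kappa-1)/(kappa+1))` is
evaluated with natural logarithms. Weyl gaps compare the singular
values of `A` against its eps=0 counterpart; the package checks both
the sharp bound (spectral norm of the perturbation) and the looser
analytic form `eps rho N`. The analytic form dominates the sharp bound
only when `rho N > 4` (the spectral norm of the masked perturbation
concentrates near `2 eps sqrt(rho N)`), so it is asserted only at sizes
inside that regime.

### Multistability scan

`bunin_transition_scan` sweeps `sigma`, integrating 10 (configurable)
uniform(0,1) initial conditions for each of 20 replicate ecosystems per
grid point, and clusters endpoints by single linkage at absolute
tolerance `1e-4` (well below inter-equilibrium spacing); a replicate is
multistable when it shows at least two distinct endpoints, and the
onset `sigma_c` is the 50% crossing of the multistable fraction,
linearly interpolated on the grid. Because relaxation suffers critical
slowing near the transition, endpoints are first *polished*: the
survivor support is read off the endpoint and the interior balance
`A[S,S] n_S = -r_S` is solved exactly (dropping species the solve
drives negative). Polishing projects each trajectory onto the
equilibrium of the basin it has committed to, which lets the scan use a
short horizon (`t_max = 250`) and coarse tolerances (`rtol = 1e-5`)
without spurious cluster splitting. Divergent runs (blow-up guard
`1e4`) are excluded from clustering; at large `sigma` most runs
diverge, so the multistable fraction is non-monotone and the *first*
upward 50% crossing is the reported onset. Finite size (N = 150), the
finite grid (step 0.2) and the 10-trajectory detection probability all
bias the estimate; the acceptance script reports the value the
protocol produces.

## Fast Lyapunov indicator

The FLI co-integrates the matrix variational equation
`dw/dt = J[n(t)] w`, `w(0) = I`, with step control driven jointly, and
reports `lambda_F = max_t log ||w(t)||_2` (natural log; the spectral
norm as printed — a Frobenius option exists for speed and upper-bounds
the spectral value by at most `sqrt(N)`). Whenever `||w||` crosses an
overflow guard (default `1e100`) the matrix is rescaled to unit norm
and the log scale factor accumulated; the reconstructed
`log ||w|| = log ||w_stored|| + sum(log scales)` is exact, and
`lambda_F` is invariant to the guard (tested at `1e50` vs `1e100`).
Since `w(0) = I` has unit norm, `lambda_F >= 0` by construction. For
large systems a column-subset mode evolves `K << N` random orthonormal
tangent columns instead of the full identity; it lower-bounds the
full-matrix value and is flagged in the result. Slice maps
(`fli_slice`) evaluate `lambda_F` on a 2-D grid of initial conditions
around a base point; directions default to a random orthonormal pair
from the seeded stream, and grid points with negative coordinates are
clamped to `1e-9` (recorded per cell).

## Slow-manifold analysis

Degenerate (eps=0) solutions are found by re-integrating initial
conditions under the eps=0 counterpart and deduplicating endpoints by
the same clustering rule as the multistability scan. The Morse index
`alpha = N_-/N` counts Jacobian eigenvalues with real part above a
machine-relative floor at the point, in the *perturbed* system, where
former solutions are weakly unstable saddles. Escape (dwell) time sums
the time a trajectory spends inside a ball of radius
`1e-2 (1 + ||point||)` around the point (cumulative over episodes by
default; per-visit available) — the radius is a package choice, as no
standard value exists. Ecomode projections take the first / last K
right singular vectors of `A` (`W_fast`, `W_slow`), with a
deterministic sign convention (first nonzero component positive);
`preconditioning_ratio` reports `kappa(W A)/kappa(A)`. The linearized
dynamics about a point on the eps=0 solution set are
`d(delta n)/dt = diag(n*) A_eps0 delta n + eps n* .* (E_masked n*)`:
the community matrix of the unperturbed system plus an O(eps) drift
along the manifold.

Trajectory embedding pools all states, fits PCA (feature-mean
centering, no variance scaling — the transformation must stay linear
for the vector-field pullback to be exact), and truncates to K
components (default `K = M`). The velocity field on a 2-D mesh is
built by promoting mesh points with the mean of the remaining PCA
coordinates, inverting the linear map, evaluating the GLV right-hand
side, and projecting back onto the two leading components.

## Evolutionary simulations

The genetic algorithm evaluates fitness as the steady-state diversity
`Ncoex` (individuals that blow up or fail to equilibrate score 0 and
are logged), keeps the top 10% (ties broken by a seeded shuffle), and
rebuilds the rest from blocks of row-column pairs: species indices are
partitioned into contiguous blocks (default size `N/10`; size 1 gives
per-species recombination), and for each block one elite parent
donates both the block's rows and its columns, preserving row-column
pairing. "Random blocks of row-column pairs" admits several readings;
we default to many parents per child with a single-parent switch.
Mutation (off by default) perturbs existing nonzero off-diagonal
entries. The growth-rate vector `r` is sampled once and shared by all
individuals in all generations: growth rates are the only trait that
distinguishes niches, and letting them evolve collapses the population
onto identical species. Fitness integrations use looser solver
settings (`rtol = 1e-8`, floor `1e-8`) than the timing studies, since
only the equilibrium support is needed; elite survivors are not
re-integrated (fitness cache keyed by matrix hash).

## Pulse probes

`apply_pulse` adds a Gaussian kick of standard deviation `amplitude`
(default `1e-3`) to the surviving species only (entries of extinct
species are exactly zero) and clips the state to be nonnegative.
`probe_ensemble` integrates each pulse back to equilibrium, projects
responses onto the first and last right singular vectors of `A`, and
computes the per-time alignment of the finite-difference velocity with
those directions. The primary alignment statistic is the sign-folded
normalized inner product `|v . d| / ||v||` (singular vectors are
sign-ambiguous); a component-wise Pearson variant is provided, since
the two are often conflated. Stationary segments (numerically zero
velocity) are masked.

## Problem sizes used by the shipped studies

The reference studies in the tests and the acceptance script run at
desk scale, chosen as the smallest sizes at which each phenomenon is
statistically resolvable: 200 replicates at N=50 for the diversity
baseline; one N=100, M=10, eps=1e-4 instance with 200 initial
conditions for transient spread; N=1000 (SVD only) for the
preconditioning ratios; an 11-point sigma grid with 20 replicates and
10 initial conditions at N=150 for the multistability onset; 300
ecosystems at N=100 (eps log-uniform over 1e-5..1e-1) for the
tau-kappa scaling cloud; 300 (ecosystem, pseudo-solution) pairs for
the escape-time versus Morse-index correlation -- the effect size is
|r| ~ 0.15, and 300 pairs is the standard power requirement to resolve
it; a population of 100 foodwebs at N=40 evolved for 60 generations;
and 100 pulses on a verified N=100 equilibrium for the
velocity-alignment signature.

## What the generators do and do not emulate

The samplers reproduce the stated statistical structure: unit-normal
interactions and growth rates, exact-count sparsification, rank-M
assignment, eps-scale redundancy breaking, and the bivariate-Gaussian
scaled ensemble. They do not emulate structured empirical foodwebs
(niche or cascade models), spatial extension, demographic noise, or
immigration. Passing tests therefore demonstrate the mechanisms —
ill-conditioning, slow manifolds, transient chaos, selection-driven
redundancy — in the random-matrix setting, not calibrated predictions
for any particular ecosystem.

## Known limitations

- For `M < N` the strict diagonal-stability guarantee cannot hold;
  global convergence of the eps>0 system is an empirical observation
  (verified per run through the termination diagnostics), not a
  theorem.
- The multistability onset estimator inherits finite-size and
  finite-grid bias, and at strong heterogeneity most replicates
  diverge, capping the measurable multistable fraction.
- Full-matrix FLI costs O(N^2) state; slices at large N should use the
  column-subset mode, which is a lower bound.
- The GA's recombination operator is one concrete reading of
  block-wise row-column mixing; alternatives (per-species blocks,
  single parent) are provided but not exhaustively studied.
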