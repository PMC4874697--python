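# Methods

## Model

Each lineage of a rooted, ultrametric, time-calibrated phylogeny (branch
lengths in Myr) carries one of `2^K` states, the combinations of `K` binary
characters.  State `i` confers a speciation rate `λ_i`, an extinction rate
`μ_i`, and anagenetic transition rates `q_ij` that are non-zero only between
hypercube neighbours (combinations differing in exactly one character);
multi-character jumps are prohibited.  This is a multistate SSE (MuSSE-type)
model; there is no cladogenetic state change and no rate variation through
time or among clades beyond the state dependence itself.

### State encoding

A combination is written with character 1 leftmost and encoded as the
binary number read left to right (`001 → 1`, `010 → 2`, `111111 → 63`).
Mask strings over `{0,1,*}` are read positionally the same way.  Any
consistent bijection would do; this one makes mask strings and printed
state labels agree with positional intuition and is fixed throughout the
I/O formats.

### Tied-rate models over focal-area bipartitions

A bipartition mask splits the states into a focal set F (matching all fixed
mask positions) and its complement N.  The four set-level transition slots
(`q_FF`, `q_NN`, `q_FN`, `q_NF`) and four diversification slots (`λ_F`,
`λ_N`, `μ_F`, `μ_N`) are constrained by a transition model and a
diversification model drawn from a registry:

| transition model | free parameters |
| --- | --- |
| one-rate | q |
| within-between | q_w, q_b |
| equal | q_FF, q_NN, q_x (= q_FN = q_NF) |
| outflow | q_w (= q_FF = q_NN), q_FN, q_NF |
| free | q_FF, q_NN, q_FN, q_NF |

| diversification model | free parameters |
| --- | --- |
| all-equal | λ, μ |
| free-lambda | λ_F, λ_N, μ |
| free-mu | λ, μ_F, μ_N |
| free | λ_F, λ_N, μ_F, μ_N |
| two/one | λ_N, μ (λ_F fixed at 2 λ_N) |
| equal-r | r, μ_F, μ_N (λ = r + μ per set) |

The 5 × 6 grid has 30 members with 3–8 free parameters.  Every slot is a
non-negative linear combination of free parameters, so all expanded rates
are automatically non-negative; the registry is configurable from a JSON
file so alternative model families can be substituted without code
changes.  The `equal-r` model is parameterised as `(r, μ_F, μ_N)` rather
than through a subtraction so that its constraint (`λ = r + μ`) can never
produce a negative rate during optimisation.

Bipartitions whose focal or complement side contains no observed tip state
are dropped before fitting (viability filtering, applied per bipartition).

## Likelihood

The standard SSE pruning quantities are integrated from the tips to the
root: `E_i(t)` (probability a lineage in state `i` at time `t` before the
present leaves no sampled descendant) and `D_i(t)` (density of the observed
subtree).  Tips contribute `D_i = f_i` for the observed state (all states if
the tip is unscored) and `E_i = 1 − f_i`, with one per-state sampling
fraction vector `f` shared by all tips.  Internal nodes multiply
`D_i = λ_i D_L,i D_R,i`; the root node applies the same λ factor, and the
likelihood is the root-weight inner product `Σ w_i D_i`.

Root treatment defaults to a point mass on the all-ancestral combination
(state 0), reflecting analyses that fix ancestral character states rather
than inferring or equilibrium-weighting them; an arbitrary weight vector is
available for sensitivity analyses.  Conditioning on survival (dividing by
`λ_i (1 − E_i(T))²` per root state) is implemented but **off** by default.

Two integration back ends:

- **fast** (default): because the tree is ultrametric and all tips share
  one sampling-fraction vector, `E(t)` is identical on every branch.  One
  synchronous sweep from the present integrates E jointly with the D
  vectors of all branches alive in the current time slice.  Given E the D
  equation is linear, so each classical Runge–Kutta stage is a single
  (n_states × n_active) matrix operation.  The step is bounded by
  `max_step` (default 0.25 Myr; 1.0 Myr during optimisation) and
  additionally by the reciprocal of the fastest total rate, which keeps the
  explicit scheme stable when an optimiser probes extreme rates.
- **per-branch**: textbook post-order recursion solving the joint
  nonlinear (D, E) system on every branch with an adaptive stiff-capable
  solver (LSODA, rtol 1e−8 / atol 1e−10).  It makes no shared-E assumption
  and serves as an independent cross-check; the two routes agree to ~1e−8
  on small trees at tight steps.

Underflow is controlled by renormalising D at every node and accumulating
the removed log factors.  A root state with zero likelihood mass yields
`−inf` rather than an exception, so degenerate parameter points are simply
rejected during optimisation.

In the degenerate `λ ≡ 0` limit the process cannot generate the tree; the
model then reduces to pure character evolution on a *given* tree, the node
speciation factor is dropped, and the likelihood equals the Mk pruning
likelihood — this is also how the implementation is validated against a
dense matrix-exponential oracle.

### Marginal ancestral states

Given E, the D equation is linear, so each branch has an exact propagator
matrix obtained by integrating the matrix ODE along the branch.  A
down-pass computes conditional likelihoods and an up-pass distributes the
root weighting, giving marginal state probabilities at every node in one
sweep (`P(v=i) ∝ U_v,i D_v,i`).  Propagators cost `n_states²` ODE
components per branch, so reconstruction is intended for trees of moderate
size; the fitting pipeline never needs it.

## Maximum likelihood and model comparison

Rates are optimised on a log scale with L-BFGS-B, bounds `[1e−9, 10]` per
Myr, from up to three starting points: a birth–death heuristic
(`r₀ = ln(n/2)/depth`, `μ₀ = r₀/4`) combined with a Fitch-parsimony
transition heuristic (state changes per unit tree length per character), a
high-turnover/high-q variant, and a log-normal jitter.  Additional
user-supplied starts are accepted (the nested-model tests seed larger
models with the constrained optimum).  Non-converged results are retained
and flagged, not discarded.  Because the data are never altered across
bipartitions or models, log-likelihoods, AIC scores and Akaike weights are
comparable across the entire search.

Model averaging expands every fit to full per-state `λ`, `μ` and per-edge
`Q` first, then takes the Akaike-weighted elementwise mean across **all**
fitted models (no top-N truncation).  Ranked tables report weight,
cumulative weight, focal mask, the set-level diversification (`r_F`, `r_N`)
and transition rates; ties in weight break deterministically by mask and
model name, so results are independent of fit execution order.

## Simulators

Both simulators use the exact Gillespie algorithm (exponential waiting
times; event chosen proportionally to rate) with per-replicate RNG
substreams spawned from a mandatory master seed, so fixed seeds give
bit-identical output.

- **Tree simulator**: every lineage is tracked; speciation replaces a
  lineage by two daughters, extinction terminates it, transitions move it
  along a hypercube edge.  Lineages are grouped by state, so each event
  costs O(n_states).  Extinct lineages are retained and marked; a lineage
  cap (default 5 × 10⁵) truncates runaway runs with an explicit flag.
  Uniform pruning to a target number of extant tips preserves branch
  lengths along retained paths and therefore ultrametricity.
- **Counts simulator**: only the per-state count vector evolves, recorded
  on a regular grid (default 1 Myr) together with the exact first time each
  state's count becomes positive.  When the total exceeds the cap the run
  is either stopped (default) or hypergeometrically downsampled to half the
  cap with the removed factor accumulated on a log scale
  (`renormalize=True`); downsampling preserves state proportions in
  expectation and keeps long-horizon frequency trajectories affordable,
  while the accumulated log factor preserves the total-growth signal.

Stationary frequencies are the normalised dominant right eigenvector of
the mean-growth matrix `A` (`A_ii = r_i − Σ_j q_ij`, `A_ij = q_ji`), whose
dominant eigenvalue is the asymptotic growth rate; a complex or
sign-changing dominant eigenpair raises a diagnostic error.  First-origin
summaries report the median and 2.5/97.5% quantiles over replicates, with
replicates that never reach the queried state set counted as censored
rather than folded into the quantiles.  "Origin" means first appearance of
the state, not majority frequency.

## Synthetic data

The generator's defaults are the study conditions: a single lineage
evolving for 136 Myr over the 64-state hypercube, focal mask `0*11**` with
`λ_F = 0.070`, `μ_F = 0.006` (r_F = 0.064) against `λ_N = 0.042`,
`μ_N = 0.004` (r_N = 0.038), every per-edge transition rate 0.001/Myr, root
in the all-ancestral combination, pruned uniformly to 464 extant tips.
Seed substreams are retried (bounded) until a replicate survives with
enough extant lineages.  Because transitions are two orders of magnitude
slower than diversification, generated datasets show the non-equilibrium
signature: observed focal frequencies far below the stationary eigenvector
value.

What the generator does **not** emulate: family-level taxonomic structure
(tree simulation is family-agnostic; a log-series family table generator
exists only to exercise the stratified sampler), molecular data and its
availability biases, character-scoring error, and fossil-calibration
uncertainty.  Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
the empirical messiness of real supermatrices.

The stratified sampling design allocates each family
`total_n · richness / Σ richness` expected species: the integer part
deterministically, the fractional part by dynamic rounding (one extra
species with probability equal to the fraction), which is unbiased — a
family holding 1% of the clade contributes exactly 5 species to a
500-species design in expectation.

## Problem sizes used in the validation analyses

The validation suite and `scripts/acceptance.py` use deliberately chosen
problem sizes: likelihood oracles on 50 random 8-tip two-character trees
(1e−6 agreement) and 4-tip trees against the per-branch integrator (1e−5);
simulator/eigenvector consistency on the two-set system `r_F = 0.064`,
`r_N = 0.038`, `q = 0.001` over 400 Myr with a 2 × 10⁴ renormalisation cap;
parameter recovery on 20 replicate 400-tip three-character datasets with a
doubled focal contrast, fitted with a single heuristic optimiser start
(further starts change the optima by less than the comparison tolerances
on these data); and the non-equilibrium check on 50 counts-only 136 Myr
replicates at the generator's default rates.

## Known limitations

- No cladogenetic (at-speciation) state change, hidden states, or time- or
  clade-varying rates.
- The fast likelihood sweep requires an ultrametric tree and a single
  sampling-fraction vector shared by all tips; per-tip sampling would need
  the per-branch back end.
- The explicit fixed-step sweep trades a small, smooth discretisation bias
  (well below optimizer tolerances at the default steps) for an
  order-of-magnitude speedup; oracle comparisons use tighter steps.
- The full 728 × 30 grid at K = 6 on a 464-tip tree is an overnight-scale
  computation on one core; the validation analyses use reduced grids and
  masks, which exercise every code path without the exhaustive sweep.
- Likelihood ridges toward extreme turnover can appear when the sampling
  fraction is inconsistent with the data-generating clade size; sampling
  fractions should reflect the actual extant richness of the study clade.
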