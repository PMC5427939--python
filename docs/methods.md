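# Methods

## Model

A metabolic network is the usual constraint-based object: a metabolites-by-
reactions stoichiometric matrix `S`, flux bounds `L <= v <= U` (mmol/gDW/h),
a growth reaction whose flux is the objective, and per-reaction boolean
gene rules. A reaction is reversible iff `L_j < 0 < U_j`; a fixed flux
(`L_j = U_j`, ATP-maintenance style) is an implied equality. Infinite or
absent bounds are replaced by ±1000 (the COBRA convention; configurable via
`big_bound`). The objective is restricted to the growth flux: the chance
constraints are built around the growth column, and a general linear
objective would interact with the scenario structure in ways the method does
not define.

The robust counterpart treats each row of `S` as uncertain with `q` discrete
scenarios. Writing `P_i = diag(p_i)` for the scenario probabilities and
`S_hat_i` for the `q x n` scenario-row matrix, the steady-state equality
`S_i v = 0` becomes

    ||R_i v|| - M_i <= p_i^T S_hat_i v <= M_i - ||R_i v||,
    R_i = delta * sqrt(P_i) (I - e p_i^T) S_hat_i.

`p_i^T S_hat_i v` is the expected net production of metabolite `i` and
`||R_i v||` equals `delta` times its scenario standard deviation, so the
constraint demands that a `delta`-sigma excursion of the net production stays
within `±M_i`. The region is convex (two second-order cones per row); it
neither contains nor is contained in the FBA region — the slack `M_i` relaxes
the mean while the deviation term cuts away flux states whose scenario
variance is large.

### Linearized path (default)

All shipped scenario builders perturb only the growth column. Then
`R_i v = delta*sqrt(P_i)(I - e p_i^T) s_i * v_Growth` for the scenario column
`s_i`, so `||R_i v|| = r_i * v_Growth` with the scalar
`r_i = ||delta*sqrt(P_i)(I - e p_i^T) s_i||`, provided `v_Growth >= 0`. The
robust system is then an LP with `2m` rows. The linear assembler therefore
requires `L_Growth >= 0` (growth is nonnegative in every experiment the
method targets) and refuses scenario sets whose uncertain column is not the
growth reaction, directing callers to the cone path. Each row pair is divided
by `max(1, r_i)` before the solve — an exact reformulation that keeps the
matrix well-scaled even when `r_i` is astronomically large (the
maximal-sigma search probes `sigma` up to 1e26).

### Cone path

The general system is solved by a cutting-plane loop: start from the mean
rows `±(p_i^T S_hat_i) v <= M_i`, and at each LP optimum add the violated
tangent cuts `(±mean_i + u^T R_i) v <= M_i` with `u = R_i v / ||R_i v||`
(the maximizer of `u^T R_i v` over the unit ball). The loop terminates when
no row is violated beyond 1e-9, or reports a numeric failure after 100
rounds. This path is intended for small instances and as a cross-check of
the linear path; interior-point cone solvers are famously fragile on
genome-scale flux systems because many variables are unsigned and nearly
unbounded and the LPs are highly degenerate.

## Scenario families

All families share `q = 5`, the probability vector
`(0.0351, 0.2389, 0.4520, 0.2389, 0.0351)`, and `delta = 3` unless stated.
The probability constants are the published values for the standard-normal
bands with cut points ±1/2 and ±3/2; they sum to exactly 1 but are not the
literal band masses (those are 0.0668/0.2417/0.3829 and are available as
`normal_band_probabilities()` for users who prefer the exact reading).

* **Digit model (default).** Each growth coefficient `c` printed with `d`
  decimals is perturbed in its first unspecified digit:
  `c + eta * 10^-(d+1)`, `eta` in {0, ±1, ±2}. Integers get step 0.1.
  The printed decimal is inferred from the shortest round-trip repr of the
  stored float and can be overridden per coefficient, since SBML/JSON store
  binary floats and the authoritative decimal lives in the source document.
  Zero coefficients have no unspecified digit and receive no spread.
* **Scaled digit model.** The digit steps multiplied by an integer `rho`;
  accepted range 1..9 (beyond 9 the perturbation flips coefficient signs on
  realistic biomass rows; `rho = 1` is the identity).
* **Proportional model.** `c * (1 + eta*sigma)`, `eta` in {0, ±1/2, ±1}.
  The factor reading `(1 ± sigma)` (rather than adding ±sigma itself) is used
  because only it makes `sigma -> 0` collapse the robust model onto FBA.
  `sigma = 0` is allowed as the degenerate zero-spread family used by the
  limit tests.
* **Tail-mass model.** Digit scenarios with
  `delta = Phi^{-1}(1 - epsilon2/2)` for a total two-sided tail mass
  `epsilon2` in (0, 1): `epsilon2 = 0.0027` reproduces `delta = 3`.
* **Single coefficient.** Proportional scenarios on one chosen metabolite
  row only; all other rows carry zero spread. Used by the maximal-sigma
  search.

Every family is symmetric about the base coefficient, so the probability-
weighted mean row equals the deterministic row exactly — the stoichiometric
coefficients of the deterministic model are interpreted as averages.

## Slack bounds M

`fit_M` solves the joint LP

    min sum_i M_i   s.t.  robust rows, v_Growth >= gamma*, L <= v <= U, M >= 0,

with `gamma*` the FBA optimum, so the total permitted deviation from steady
state is as small as possible while the robust model still reaches the FBA
growth rate. Ties among alternative optimal `M` are left to the solver. Two
numerical details:

* the objective is normalized by `max_i r_i`; when the growth norms span more
  than ~9 orders of magnitude the small weights fall below the solver's
  tolerance, so a second lexicographic stage pins the normalized optimum and
  re-minimizes exactly those rows;
* the returned `M` is clipped up to `|mean_i v| + r_i v_Growth` evaluated at
  the LP's own optimum, because components smaller than the solver's primal
  feasibility tolerance (~1e-7) can come back as zero even though the growth
  target needs them in exact arithmetic. Without the clip, re-solving with
  the fitted `M` can lose the target entirely once scenario spreads shrink
  below ~1e-6.

A target above the FBA optimum is rejected: calibrating the slack to a growth
rate FBA cannot reach would manufacture growth out of constraint violation.

## Essentiality screening

A gene is essential when knocking it out (evaluating each reaction's gene
rule with the gene false and zeroing the bounds of disabled reactions —
columns are kept so indexing is stable) drops the optimal growth below
`threshold` (default 0.5) of wild type. Infeasible or numerically failed
knockout solves score as zero growth. The threshold comparison carries a 1e-9
guard: knockouts whose ratio equals the threshold up to LP round-off (a
knife-edge that genuinely occurs in small networks with integer capacities)
would otherwise be classified differently by the FBA and robust code paths.

For robust screens, `M` is fitted once on the wild type and held fixed across
knockouts. Re-fitting per knockout (available as `refit_m=True`) would
re-anchor the robust model to each mutant's own FBA optimum and erase the
FBA/robust contrast; it is off by default.

Predictive power against experimental labels is `(TP + TN) / scored genes`,
with unlabeled genes excluded from the counts but tallied.

### Maximal-sigma search

For one biomass coefficient, the search doubles `sigma` from 1e-4 until the
robust essential-gene set (exact set equality) departs from the FBA
reference, then bisects the bracket to an absolute accuracy of 1e-4. If
doubling exceeds the cap of 1e26 without a mismatch, only a lower bound
exists (`bounded = False`) — this happens when the metabolite's steady-state
row can absorb arbitrary spread, e.g. a precursor that is freely exchangeable
with the environment so its mean net production is unconstrained at zero
cost. A mismatch already at `sigma = 1e-4` reports `sigma_max = 0` with a
flag.

## Flux fitting

Given measured fluxes for `N` reactions, both fits minimize the squared
residual over the measured coordinates only (penalizing the thousands of
unmeasured fluxes toward zero would change the problem), subject to a growth
floor `v_Growth >= theta * gamma*` (default `theta = 0.9`, since measured
cultures need not be growth-optimal) and either strict steady state or the
robust linearized rows with fitted `M`. The default robust scenario family
for fitting is the proportional model with `sigma = 0.2`. The QP is solved
by sequential quadratic programming (SLSQP) with an exact gradient and a
trust-region fallback; the fits reported by the tests are verified against
closed-form projections on one-dimensional cases. Fits are scored by
`MSE = ||v_fit - v_exp||^2 / N`; measurement standard deviations are
accepted and can drive inverse-variance weights, but the default objective
is unweighted.

## Synthetic data

The fixtures module generates everything the tests need:

* the fully printed two-flux worked example (one uncertain row, three
  scenarios, `delta = 3`, `M = 0.2`), whose deviation matrix, mean row, and
  infeasible point are asserted digit for digit;
* deterministic chains and a two-route network whose knockout ratio sits just
  below the 50% threshold (alternate capacity 4.5 against wild-type growth
  10), so the essentiality call flips at a finite, analytically checkable
  sigma — the transition the search tests locate; a variant with a freely
  exchangeable biomass precursor exercises the unbounded-search branch;
* seeded random networks (up to 50 x 100): a gene-gated backbone chain from
  a capped uptake (10 mmol/gDW/h) through intermediates into a biomass drain
  with non-integer coefficients of 1-6 decimal places spanning several orders
  of magnitude (so the digit rule is exercised across scales), plus random
  integer side reactions (~30% reversible) and a fixed maintenance flux.
  Construction retries with derived seeds until the FBA optimum is positive;
* essentiality labels equal to the FBA-screen truth with independent flips at
  a configurable rate, so confusion matrices have known expected counts.

What the generator does **not** emulate: genome-scale degeneracy structure
(large alternate-optima spaces), compartments, realistic gene-rule depth, or
mass balance of the side reactions. Passing tests therefore demonstrate the
correctness of the algebra and the search/screening logic, not predictive
performance on real reconstructions — for that, point `scripts/genome_scale.py`
at a real model and label set.

Test problem sizes are deliberately small (8 metabolites x 14 reactions for
the 20-network property panels); every LP involved solves in milliseconds and
the full suite runs in well under a minute.

## Numerical choices

* LP backend: HiGHS via scipy; statuses mapped to
  {optimal, infeasible, unbounded, numeric_failure}; infeasible/unbounded
  outcomes are reported in the returned state, never raised.
* Feasibility audits: absolute tolerance 1e-9 per row; growth-rate equality
  claims: 1e-6 relative.
* Cutting-plane convergence: 1e-9 violation tolerance, 100 rounds.
* Deterministic outputs: CLI numbers are printed at six significant digits so
  identical configurations give byte-identical files.
* All stochastic tests fix their seeds; the hypothesis profile is
  derandomized.

## Known limitations

* The general multi-column cone path is not intended for genome-scale
  instances; only the linearized growth-column path is.
* `fit_M`'s minimality is solver-tolerance accurate; in the extreme-sigma
  regime its small components are meaningful only relative to the huge ones.
* The scenario-possibility test (identical components of `S_hat_i v` over the
  nonzero fluxes) reports the common value `alpha_i` and flags rows with
  `alpha_i ~ 0` instead of failing them: steady-state feasibility of the mean
  row already forces the probability-weighted alpha to zero, so a hard
  nonzero requirement would be self-contradictory.
* Only single-gene knockouts are implemented; no flux variability analysis,
  kinetics, or regulatory extensions.
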