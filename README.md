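# rampfba

Robust flux balance analysis for genome-scale metabolic models whose biomass
stoichiometry is uncertain.

## The problem

Flux balance analysis (FBA) finds a flux distribution `v` maximizing the
growth flux subject to exact steady state and flux bounds:

    max  v_Growth
    s.t. S v = 0,   L <= v <= U.

The biomass (growth) column of `S` is an empirical average over a culture:
its coefficients are printed to a few digits and vary between cells and
conditions. `rampfba` replaces each steady-state equality with a
scenario-based chance constraint. Row `i` gets `q` discrete scenarios
`S_hat_i` (a `q x n` matrix) with probabilities `p_i`, and the constraint
becomes the pair of second-order-cone inequalities

    ||R_i v|| - M_i  <=  p_i^T S_hat_i v  <=  M_i - ||R_i v||,

where

* `R_i = delta * sqrt(P_i) (I - e p_i^T) S_hat_i`, so `||R_i v||` is `delta`
  times the standard deviation of the scenario values `S_ik v`;
* `delta` is a standard-normal percentile (default 3, i.e. a three-sigma
  guarantee of near-steady state);
* `M_i >= 0` is the permitted deviation from steady state for metabolite `i`,
  chosen by L1 minimization so the robust optimum reproduces the FBA growth
  rate exactly.

When uncertainty is confined to the growth column and the growth flux is
nonnegative, `||R_i v||` collapses to `r_i * v_Growth` for a scalar `r_i` and
the whole system is an ordinary LP — the default computational path. The full
cone form is kept for small instances and cross-checks.

On top of the solver the package provides:

* four scenario families for the biomass coefficients (first-unspecified-digit
  perturbations, integer-scaled digit perturbations, proportional `1 ± eta*sigma`
  scenarios, and a tail-mass variant that recomputes `delta`), plus a
  single-coefficient mode;
* gene essentiality screens (knockout growth < 50% of wild type) under FBA or
  the robust model, scored against experimental labels by predictive power
  `(TP + TN) / total`;
* a maximal-multiplier search: the largest proportional spread `sigma` on one
  biomass coefficient at which the robust screen still returns exactly the FBA
  essential-gene set (doubling then bisection, accuracy 1e-4, cap 1e26);
* quadratic flux fitting `min ||v - v_exp||^2` over measured reactions under
  either constraint regime with a growth floor `v_Growth >= theta * gamma*`;
* synthetic fixtures (including the fully printed two-flux worked example) so
  everything is testable with no downloads.

Models are read from SBML (level 3 + fbc) or COBRA-style JSON via cobrapy;
LPs are solved with scipy's HiGHS backend.

## Worked example

The two-flux illustrative system has one uncertain row with base coefficients
`(1, -1)`, bounds `[-1, 1]^2`, three scenarios `(0.9, -1.2)`, `(1, -1)`,
`(1.1, -0.8)` with probabilities `(1/4, 1/2, 1/4)`, `delta = 3`, `M = 0.2`:

```python
>>> import numpy as np, rampfba as rf
>>> toy = rf.fixtures.toy_example()
>>> toy.mean                      # probability-weighted row = the FBA row
array([ 1., -1.])
>>> toy.R                         # deviation matrix
array([[-0.15, -0.3 ],
       [ 0.  ,  0.  ],
       [ 0.15,  0.3 ]])
>>> rf.audit_feasibility(np.array([0.75, 0.75]), toy.problem()).feasible
False
>>> state = rf.solve_ramp(toy.problem())
>>> state.objective               # robust optimum of max v1
0.31426968052735443
```

The point `(0.75, 0.75)` satisfies the static constraint `v1 - v2 = 0` but its
scenario deviation `||R v|| = 0.477` exceeds `M = 0.2`, so the robust model
rejects it: the chance-constrained region neither contains nor is contained in
the FBA region.

On a small linear chain (uptake capped at 10, FBA optimum `gamma* = 10`),
fitting the slack bounds and re-solving reproduces the FBA growth rate while a
gene knockout is judged against the robust geometry:

```python
>>> net = rf.fixtures.chain_network()
>>> scen = rf.build_model3(net, sigma=0.2)     # proportional scenarios
>>> M = rf.fit_M(net, scen, gamma_star=10.0)
>>> M.round(4)
array([0.    , 2.6129, 2.6129])
>>> rf.solve_ramp(rf.assemble_linear_ramp(net, scen, M)).objective
10.0
>>> screen = rf.screen_knockouts(net, "ramp", scenarios=scen, M=M)
>>> screen.essential_set
{'g1'}
```

`M = 2.6129` on the uncertain rows is exactly `r * gamma*` with
`r = 3 * sigma * sqrt(2*0.0351 + 0.2389/2) ≈ 0.2613`, the minimal slack that
lets the robust model reach the FBA optimum.

## Command line

```sh
ramp make-fixture --seed 7 --out fixture/
ramp solve --model fixture/model.json --fit-m --out fluxes.tsv
ramp knockouts --model fixture/model.json --method ramp --labels fixture/labels.tsv
ramp sigma-search --model fixture/model.json --coefficient M4
ramp fit-fluxes --model fixture/model.json --measurements fluxes.tsv
ramp audit --model fixture/model.json --flux fluxes.tsv
```

Outputs are TSV/JSON with numbers at six significant digits, so identical
configurations give byte-identical files.

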