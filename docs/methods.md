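# Methods

## Scope and model

`mininf` works entirely at the level of exact discrete distributions. A
`DiscreteJointDistribution` is a dense probability table over named
finite-cardinality variables (masses ≥ 0, summing to 1 within 1e-12; at
most 10^6 cells — exactness is preferred over scalability). All information
measures use base-2 logarithms with the `0·log 0 = 0` convention, so every
quantity in the package is in bits; the "1 bit" scale of the canonical
examples (a relayed bit, a copied bit) is then directly readable. No
estimation from finite samples is performed anywhere: the plug-in path
(`empirical_distribution`) normalizes a count table with no smoothing, and
the only finite-sample device offered is a naive multinomial bootstrap of
an inequality slack, labelled heuristic.

Causal hypotheses are DAGs with designated hidden nodes. Bidirected arcs
are expanded into fresh hidden common parents before any query, so all
separation questions reduce to ordinary d-separation (delegated to
networkx, with a path-enumeration oracle used in the test suite as an
independent cross-check). Rejection logic assumes only that d-separation
implies conditional independence — faithfulness is not needed, since an
unfaithful independence can weaken but never falsely trigger a rejection.

## Inequality construction

Every test has the form `upper bound ≥ Σ lower-bound terms`. The upper
bound comes from the instrumental-style independence (`Z ⊥ U | B0` gives
`H(X|B0)`; the group conditions give `H(Y|Z)`; `X ⊥ U` gives the
Information Causality combination `H(M) − H(X) + Σ H(X_i)`). Lower-bound
terms are licensed one data-processing (DP) step at a time:

- plain conditional mutual information, when the licensing independence
  conditions on everything so far;
- unique information `I(Z̄; D1 \\ D2 | O1)`, when the reference block `D2`
  must be excluded from the conditioning (colliders);
- general minInf terms within marginal-preserving families, when a chain of
  independencies with intertwined conditioning sets has to be exploited
  sequentially.

The recursion is driven by an `IterationPlan`: step *j* inserts observables
`A_j` using `Z̄_j ⊥ A_j | Ū_j, B̄_j`, with bookkeeping collections
`C_j = {A_{j−1}, B̄_{j−1}, Ž_j}` and `B̄_j = {B̄'_j, Ž_j}`,
`B̄'_j ⊆ {A_{j−1}, B̄_{j−1}}`. The step-*j* estimable term is the minimum of
`I_Q(Z̄_j; A_j | E, A_[j−1], Ž_[j])` over the family preserving
`P(Z̄_j, A_j, B̄_j)` and `P(Z̄_k, C_k)` for `k ≤ j` (hidden variables
marginalized; preserved subsets contained in another are collapsed away,
mirroring the listing of maximal marginals only). Consecutive steps whose
`B̄_j` equals the whole of `{A_{j−1}, B̄_{j−1}}` contract into a single
step, by the contraction property of conditional independence. Plan
structure and each licensing independence are validated against the graph
before evaluation.

Slack is reported with provenance per term. The decision threshold for
"violated" is `max(1e-6, 3 × worst solver constraint violation)` bits: a
rejection must exceed numerical slop, and closed-form terms effectively use
the 1e-6 floor. A failed minimization *drops* its term — minInf terms are
nonnegative additions to a lower bound, so losing one weakens the test but
can never produce a spurious rejection.

## The minInf solver

A minInf instance is a smooth minimization of a conditional mutual
information over the polytope of joint tables with fixed marginals. The
objective's gradient in the flat table is the log-ratio
`log p(t,v,c) + log p(c) − log p(t,c) − log p(v,c)` of the relevant
marginals, which we feed to SLSQP together with the affine constraints
(reduced to an independent row set by pivoted QR — SLSQP rejects redundant
equality systems). Design choices:

- **Convex certification.** The two-marginals-sharing-the-target pattern of
  unique information is a convex program; such instances are labelled
  `convex-certified` and solved from deterministic starts only. A family
  whose preserved marginals pin the whole scope is returned closed-form.
- **Starts** (default budget 8): the reference member, the iterative
  proportional fitting (IPF) projection of the uniform table
  (independent-product start), the conditional-independence coupling of the
  two preserved blocks when applicable, any caller-supplied feasible
  points, then seeded Dirichlet draws projected by IPF. IPF converges here
  because all preserved marginals come from one common reference. The
  reported value is the best over all evaluated starts and polished
  solutions, clipped at 0; values within 1e-9 bits of zero are reported as
  exactly 0, and iteration stops early once 0 is reached (the objective is
  bounded below by 0).
- **Feasibility.** A solution must reproduce every preserved marginal
  within 1e-8 L1, reported as `constraint_violation`; otherwise the solve
  is `failed` (no silent value).
- **Witness seeding.** Asserted *relations between* minima (the DP
  equality, predictor monotonicity, the unique-information sandwich) are
  verified by cross-seeding each solve with the constructive witness from
  the corresponding proof — the lift `Q̄ = P(D′|D,O1)·Q*` of one argmin,
  marginal projections of the other, the conditional-independence coupling
  for the `I(Z̄;D1|O1)` bound. These are ordinary feasible starting points,
  so each relation holds at solver accuracy (the 2e-6 bits used in the
  verification suites) instead of depending on global optimality of
  independent local solves. Global-optimality certificates for non-convex
  instances are out of scope.
- **Oracle.** `brute_force_mininf` upper-bounds a minInf value by scanning
  IPF projections of random simplex draws (mixed Dirichlet concentrations
  for interior and boundary coverage, starting from the barycenter, plus
  multiplicative perturbations of the incumbent with shrinking strength).
  It is restricted to scopes of ≤ 4 variables of cardinality ≤ 3, is
  non-increasing in the sample count for a fixed seed chain, and never
  shares code with the SLSQP path it checks. Solver and oracle agree within
  1e-3 bits on the instances where the oracle is admissible.

All stochastic routines take an explicit seed (default 0) and are
deterministic given it.

## Synthetic scenarios

The figure registry fixes one canonical DAG per scenario (`fig1A`–`fig3B`
plus documented variants). The published drawings are not machine-readable,
so each encoding is pinned instead to a checklist of the conditional
independencies and dependencies that define the scenario's logic (for
example, for `fig2C`: `Z ⊥ U | W2,W3`, `Z ⊥ Y1 | U,X,W2,W3`,
`Z ⊥ Y2 | U,X,W3`, `Z ⊥ Y3 | U,X,Y2`, with the corresponding failures when
`W2`, `Y1` or `W3` enter the wrong conditioning set); the checklist is
re-verified at test time both graphically and, for sampled models, at the
distribution level. One structural consequence fixed at design time: a
variable playing the `W3` role cannot also be an ancestor of `Y2`, since
conditioning on `Y2` would then re-activate the `W3` collider and destroy
`Z ⊥ Y3 | U,X,Y2`; the registry encodes `W3` with the collider role only.

`sample_scm` computes the *exact* joint by multiplying conditional
probability tables in topological order — there is no sampling noise, so
structurally implied independencies hold to machine precision and every
causally imposed inequality must hold up to solver tolerance (1e-9 bits for
closed-form bounds, 1e-5 for minInf-bearing bounds). Default mechanisms are
Dirichlet(1) random tables on binary variables; named deterministic
mechanisms (copy, xor, and, or, noisy-copy) are available. What this
generator does **not** emulate: sampling variability, measurement noise,
near-violations of its own independencies, non-binary real-world
cardinalities, or selection effects — passing tests show correctness of the
machinery on exact in-model distributions, not robustness of the tests on
finite noisy data.

Violating fixtures are deterministic closed-form tables (byte-identical
across runs, shipped alongside the scenario DAGs). The `fig2C-breaker`
fixture gives the instrument four states and routes the bit the one-bit
channel `X` drops directly into `Y3`; the preserved marginal
`P(Z, X, Y2, Y3)` then pins the third minInf term at a full bit in every
family member, so the three-term bound rejects (slack −1) while the
`Y1`-only standard bound does not. No search happens at test time.

## Known limitations

- Dense tables only; scopes beyond ~20 binary variables are out of reach by
  design.
- The general minInf solve is a non-convex local method; outside the
  witness-seeded relations, a reported value is an upper bound on the true
  minimum (which conservatively weakens lower bounds but can overstate
  slack tightness).
- Automatic search over iteration plans for the tightest bound, the
  Fourier–Motzkin marginalization of minInf entropy cones, GD2 (ancestral
  set) inequalities, quantum (von Neumann) extensions, and finite-sample
  testing theory are not implemented.
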