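# mininf — entropic inequality tests for hidden-variable causal structures

`mininf` tests whether a hypothesized causal structure with hidden variables
is compatible with an observed discrete joint distribution. It is aimed at
researchers doing causal structure learning on systems that are only
partially observed — gene-regulatory and signalling networks, neural
recordings, any setting where unmeasured confounders make plain
conditional-independence tests uninformative.

## The idea

A DAG `G` over observable variables and hidden variables `U` implies
conditional independencies that cannot be checked directly because they
involve `U` (for example the instrumental conditions `Z ⊥ U | B0` and
`Z ⊥ Y | U, X, B0`). Those untestable independencies nevertheless constrain
the *entropies* of the observable distribution. The standard instrumental
entropic inequality is

    H(X | B0)  ≥  I(Z; X | B0) + I(Z; Y | B0, X).

If the data violate it (negative **slack** = upper bound − summed terms),
the structure is rejected; fulfillment is necessary but not sufficient.

The package's distinctive machinery replaces plain conditional mutual
informations in the lower bound with **minimum-information (minInf)
terms**

    min_{Q ∈ Δ_P} I_Q(Z̄ ; V̄ | E),

where `Δ_P` is the family of distributions preserving a stated set of
marginals of the observed `P`. The unique information
`I(Z̄; D1 \\ D2 | O1)` (minimum of `I_Q(Z̄; D1 | D2, O1)` over the family
preserving `P(Z̄, D1, O1)` and `P(Z̄, D2, O1)`) is the canonical special
case. MinInf terms obey a data-processing inequality in the predictor slot:
if `Z̄ ⊥ D′ | D, O1`, then

    min_{Q∈Δ_P^{DD′}} I_Q(Z̄; D, D′, E2 | E)
        = min_{Q∈Δ_P^{D}} I_Q(Z̄; D, E2 | E)
        ≥ min_{Q∈Δ_P^{D′}} I_Q(Z̄; D′, E2 | E),

which lets independencies with *different* conditioning sets — ones that can
never be exploited together in a single standard inequality because a
variable must be conditioned on in one and excluded in the other — be
chained: each step relaxes the preserved marginals just enough to license
the next data-processing replacement, inserting one more estimable term
into the lower bound. `mininf` implements this iteration (an
`IterationPlan` tracks the collections `A_[k], Z̄_[k], Ž_[k], Ū_[k], B̄_[k],
C_[k]` and the preserved-marginal relaxation sequence), plus the same
extension applied to groups-decomposition (GD1) inequalities and the
Information Causality inequality for marginal scenarios where only
`p(X, M, Y_i)` are jointly observable.

Everything operates at the distribution level on exact dense probability
tables (base-2 logarithms; all quantities in bits). A plug-in path from
count tables is provided without any smoothing or finite-sample correction.

## Worked example

The classic counterexample: a four-state instrument `Z = (Z1, Z2)` relayed
through a one-bit channel `X = Z1` to an outcome `Y = Z2`. No one-bit
channel can account for two transmitted bits, so the instrumental structure
is rejected:

```
$ mininf fixtures emit fx
$ cat > spec.yaml <<EOF
kind: standard
z: [Z1, Z2]
x: [X]
y: [Y]
EOF
$ mininf test --dist fx/two_bit_relay.csv --spec spec.yaml ; echo "exit $?"
{
 "result": {
  "slack": -1.0,
  "terms": [
   {"name": "I(Z1,Z2;X|∅)",   "value": 1.0, "status": "exact", ...},
   {"name": "I(Z1,Z2;Y|∅,X)", "value": 1.0, "status": "exact", ...}
  ],
  "upper_bound": 1.0,
  "violated": true, ...
 }, ...
}
exit 3
```

The upper bound `H(X) = 1` bit falls one full bit short of the two summed
lower-bound terms: slack `-1.0`, exit code 3 (violated). Exit code 0 means
not violated, 2 means a minInf solve failed (inconclusive).

The same from Python, together with a unique-information computation — for
the COPY distribution `Z = (D1, D2)` the predictor `D1` carries exactly one
bit not available from `D2`:

```python
>>> import mininf
>>> case = mininf.violating_distribution("two-bit-relay")
>>> case.evaluate().slack
-1.0
>>> res = mininf.unique_information(copy_dist, ["Z1", "Z2"], ["D1"], ["D2"])
>>> round(res.value, 6), res.status
(1.0, 'convex-certified')
```

Unique-information instances are solved as convex programs; general minInf
terms use seeded multistart local minimization over the marginal-preserving
polytope, and every solver answer records its constraint violation and
status. A `brute_force_mininf` sampling oracle provides an independent
upper bound for desk-scale cross-checks.

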