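# minnut — minimal nutrient sets from metabolic networks

`minnut` predicts **all minimal growth media** for an organism from its
stoichiometric metabolic network.  It is aimed at microbiologists and
modelers who have a reaction network (manually curated or inferred from an
annotated genome), a list of transportable metabolites, and a list of biomass
compounds, and who want to know *every* combination of nutrients from which
the biomass compounds are producible — not just variations of a seed medium
one element source at a time, an assumption that fails whenever element
sources cannot substitute for one another across pathways.

## The model

Let `M` be the stoichiometric matrix (rows = compounds, columns = reactions),
`r` the vector of reaction rates with `r_j ≥ 0` for irreversible reactions
(sign-free for reversible ones), and `p = M r` the net production vector.
For a candidate nutrient set `N ⊆ T` (plus always-available auxiliary
compounds), two growth definitions are supported:

* **steady state** — `p_i > 0` for biomass compounds `i ∉ N`, and `p_i ≥ 0`
  for every other non-nutrient compound: internal pools may be recycled but
  never depleted.
* **machinery duplicating** (default) — additionally, for every non-nutrient,
  non-biomass compound `i` that some reaction touches,

  ```
  p_i > 0   ∨   ∧_{j mentions i}  r_j = 0
  ```

  i.e. every intermediate on an *active* pathway must itself be made at a
  strictly positive rate.  A dividing cell must duplicate its active
  metabolic machinery; pure recycling of an inherited pool does not survive
  repeated cell division.  These disjunctions of linear constraints are
  outside ordinary linear programming; `minnut` decides them exactly over the
  rationals (no floating point anywhere in the verdict path).

`nutset(N)` — "is `N` a nutrient set?" — is a **monotone** Boolean function of
`N`, because adding a nutrient only removes constraints.  Minimal nutrient
sets are exactly its **prime implicants**, which `minnut` enumerates
exhaustively: repeatedly minimize a known-growing vector to a prime
implicant, maintain the monotone choice function `g(x) = ∧_i ∨_{j∈T_i} x_j`
over the primes found so far as a binary decision diagram, and scan the
prime implicants of `g` (read off the BDD for `pi_g` by path tracing) for a
candidate `u` with `nutset(¬u)` true; when none exists the collection is
provably complete.

Finally, compounds that are mutually substitutable across the whole
collection are factored into **equivalence classes**; rewriting every set
over class representatives and deduplicating yields a reduced collection
that, together with the classes, encodes the original **with zero
information loss**.  Predictions can be scored against phenotype-array style
growth calls (exact or subset matching, TP/TN/FP/FN and accuracy).

## Worked example

The network `R1: A+B -> C+D`, `R2: C+F -> B+E` with biomass `{E}` separates
the two growth definitions (`python examples/worked_example.py`):

```
   steady model, N = {A, F}: growth  (exact flux witness: R1 = 1, R2 = 1)
machinery model, N = {A, F}: no growth
```

With `r1 = r2 = 1` an inherited pool of B is recycled through C forever, so
the steady model accepts {A, F}.  The machinery model rejects it: balancing B
and C forces `r1 = r2`, but duplicating the actively used C would require
`r1 − r2 > 0` — a contradiction.  Supplying B as a nutrient resolves it, and
enumeration returns `{A, B, F}` as the unique machinery-minimal set.

The cross-feeding network `C1+N1 -> M`, `C2+N2 -> M`
(`python examples/enumerate_minimal_sets.py`) yields

```
minimal nutrient sets (BDD-guided enumeration):
   ['C2', 'N2']
   ['C1', 'N1']
```

and `{C1, N2}` does not grow — the carbon sources cannot substitute for one
another, which is why seed-and-vary search over single element sources is
insufficient and exhaustive enumeration is the point.

Other narrative scripts in `examples/` cover equivalence-class compression,
phenotype-array scoring, and the end-to-end pipeline; each prints the
numbers it computes and what they mean.

## Command line

```sh
minnut fixture example1 -o model.json
minnut check model.json --nutrients A,F --mode machinery
minnut enumerate model.json --mode machinery -o sets.json
minnut classes sets.json -o classes.json
minnut reduce sets.json classes.json -o reduced.json
minnut evaluate sets.json pm.tsv -o report.tsv
minnut run pipeline.cfg        # all of the above from a flat config file
```

`minnut export-constraints ... --format smtlib2` emits any constraint system
in SMT-LIB 2 syntax for use with an external solver.

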