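# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `minnut`, in the package's own terms.

## Growth as constraint satisfiability

A metabolic model is a pair ⟨R, B⟩ of stoichiometric reactions and biomass
compounds, with an ordered list T of transportables (candidate nutrients) and
an optional set of auxiliary compounds.  For a candidate nutrient set
N ⊆ T, let A = N ∪ auxiliaries be the *exempt* compounds — assumed available
in arbitrary amounts and therefore carrying no production constraint.  With
flux vector r (r_j ≥ 0 for irreversible reactions, sign-free for reversible
ones) and net production p = M r:

* **steady mode**: p_i > 0 for i ∈ B∖A; p_i ≥ 0 for every other i ∉ A that
  any reaction touches.
* **machinery mode**: steady constraints plus, for every i ∉ A ∪ B mentioned
  by at least one reaction, the disjunctive clause
  `p_i > 0 ∨ (r_j = 0 for every reaction j mentioning i)`.
  A growing cell that divides must duplicate the intermediates its active
  pathways consume; recycling an inherited pool at exactly zero net
  production cannot keep pace with division.

Two conventions exist for the machinery clause: zero out reactions that *use*
the compound as a reactant, or reactions that *mention* it on either side.
With the reactant-only form, reversible reactions must be split into two
non-negative half-reactions; with the symmetric mention form, a single
sign-free variable per reversible reaction suffices, and the two
formulations accept exactly the same nutrient sets.  `minnut` implements
both (`encoding="free-variable"` pairs with mention semantics by default,
`encoding="split-unidirectional"` with use semantics) and their agreement on
every subset of T is a standing property test; the free-variable/mention
pairing is the default because it has one variable and one code path per
reaction.

Biomass compounds that are themselves offered as nutrients are fully exempt
(no p_i > 0 requirement): the constraint definitions apply to compounds "in B
and not in N".  Auxiliaries are treated exactly like nutrients in every
query — exempt from all production constraints — and never appear in
candidate sets or equivalence classes; this models compounds whose synthesis
is outside the model's scope but which must be present for it to run.  The
alternative (pseudo-synthesis reactions) was rejected because it would give
auxiliaries flux variables that the machinery clauses would then constrain.

No objective function is used anywhere; growth is feasibility, not an
optimum.  The fudge-factor alternative to the disjunctive clause
(p_j ≥ α·s_j for the summed consuming flux s_j) is deliberately not
implemented: any fixed α can wrongly reject feasible fluxes, and the exact
form (α depending on s_j) is quadratic.

## Exact satisfiability

All arithmetic in the verdict path is over `fractions.Fraction`.  Strict
atoms `e > 0` are rewritten to `e ≥ 1`: every constraint is homogeneous
(zero right-hand side), so the solution set is a union of convex cones and
any solution with `e > 0` scales to one with `e ≥ 1`.  Conjunctions are
decided by a phase-1 simplex with Bland's rule (termination unconditional;
free variables as differences of non-negative pairs).  Disjunctive clauses
are handled by depth-first case splitting with a linear-relaxation
feasibility check at every node.  Two structural facts keep this fast in
practice: machinery-feasible flux sets are closed under addition, so when the
system is satisfiable at all, taking the production-positive disjunct of
*every* clause simultaneously is almost always satisfiable (one LP); and an
infeasible steady relaxation refutes the whole system immediately (one LP).
Returned witnesses are re-verified by exact evaluation of every original
clause, strict inequalities included.

A `SolverIndeterminate` error type exists for backend exhaustion (pivot
budget); it is never converted into a truth value.

## Enumeration

`nutset` is monotone, so minimal nutrient sets are the prime implicants of a
monotone Boolean function evaluated as a black box.  The algorithm:

1. If nutset(T) is false, there are no nutrient sets.  Otherwise minimize the
   all-true vector: a single left-to-right pass flipping each true component
   to false when the oracle stays true.  The result is always a prime
   implicant, and the pass is deterministic given T's order.
2. Maintain g(x) = ∧_i ∨_{j∈T_i} x_j over the true-index sets T_i of the
   primes found so far, as a reduced ordered BDD with variable order = T's
   listed order (determinism is preferred over dynamic reordering; a
   reordering hook could be added behind the same interface).  A further
   prime exists iff some choice vector u — sharing a true component with
   every known prime — has nutset(¬u) true, and it then suffices to scan the
   *minimal* choice vectors, i.e. the prime implicants of g.
3. Build the BDD for `pi_g(x) = g(x) ∧ ∧_i(¬x_i ∨ ¬g(x|x_i:=false))` and
   enumerate its implicants by tracing root-to-true paths, depth-first with
   the false branch first.  Variables skipped along a path are expanded to
   both values, false first — for pi_g of a monotone g every variable in fact
   labels a node on every accepting path, but the tracer does not rely on
   that argument.  On the first u with nutset(¬u) true: minimize ¬u, record
   the new prime, update g, restart the scan.  When the scan is exhausted the
   collection is complete.

Discovery order is therefore a pure function of the model and T's order.  A
`limit` argument truncates long runs and flags the result incomplete.  The
brute-force reference (`brute_force_minimal_sets`) tests subsets in
increasing size, skipping supersets of already-found minimal sets (sound by
monotonicity), and refuses |T| > 16.

The oracle is memoized per (model, mode, encoding) and counts its calls; the
enumeration loop re-evaluates candidates against the shared cache.  The
candidate-scan could be parallelized with a deterministic merge, but a
single-process scan is used here: at the problem sizes the test fixtures and
acceptance runs use, the oracle cache makes the scan cheap.

## Simplification

On the split-unidirectional form, two removals alternate to a joint fixed
point, then complementary pairs are re-merged:

* **Impossible** compounds — no producing reaction and not a potential
  nutrient (transportable or auxiliary) — are deleted with every reaction
  mentioning them; deletions can expose new impossible compounds.
* **Useless** compounds — no downstream biomass compound, computed as the
  complement of the least fixed point "biomass is useful; reactants of
  reactions producing something useful are useful" — are pruned from product
  lists, and reactions with no useful product are deleted.  A reaction left
  "unbalanced" by product pruning merely loses a redundant non-negativity
  constraint.

Impossible-removal runs first because producer deletion is what typically
exposes useless branches; the two are alternated because each can enable the
other.  Transportables (and auxiliaries, and biomass) are never removed from
the model's tables even when pruned from every reaction: |T| and its order
index the enumeration's Boolean vectors and must be stable.  A biomass
compound eliminated as impossible raises `biomass unproducible: <id>` — the
model cannot grow on any medium and the gap should be fixed, not silently
enumerated over.  Simplification never changes any growth verdict; this is
asserted exhaustively over all subsets of T on randomized models in the test
suite.

## Generic reaction instantiation

Reactions over compound classes are expanded by substituting instances
independently per class slot, in all combinations.  A substitution is kept
only if the instance-level equation is mass balanced (hydrogen included;
charge is not modeled — protonation adjustments are curation, not
algorithm), and skipped as ambiguous when the chosen instance shares its
formula with another instance of the same class, since the balance check
cannot then discriminate.  Instances without formulas cannot be verified and
are not added.  Instantiated ids are `<generic>/<inst1-inst2-...>` for
traceability.  When one class occupies several slots of the same reaction the
slots vary independently; combinations that make no chemical sense are
relied upon to fail the balance filter.

## Equivalence classes and compression

Compounds c1, c2 occurring in a collection are equivalent when each can
replace the other in every set where it occurs, with the result still in the
collection.  On a complete collection of minimal sets this is an equivalence
relation; the implementation nevertheless audits transitivity on every
computed partition and raises on violation rather than emit a wrong
partition.  Representatives are the lexicographically smallest member by
default — a deterministic stand-in for "the most familiar compound", which is
a human judgement — and a preference list can override.  The partition and
the reduced-set count are invariant under representative choice (tested).
Element annotations (which of C/N/P/S a class's members contain) are derived
from formulas when available and are labels only.

## Evaluation against growth experiments

Each assay well is a nutrient set plus a growth call from the closed
vocabulary {growth, no-growth, low-growth}.  A prediction matches a well when
it equals the well's set or is a proper subset (a predicted compound sourcing
two elements makes a fixed supplement redundant).  growth+match → TP,
growth+no-match → FN, no-growth+no-match → TN, no-growth+match → FP;
low-growth wells are excluded as inconclusive.  Accuracy is
(TP+TN)/(TP+TN+FP+FN) as an exact rational, undefined (reported as
not-applicable) when every well is excluded.  Compound-name reconciliation
between assay labels and model ids goes through an explicit synonym table —
never fuzzy matching, which would silently corrupt the confusion matrix.
"low-growth" is a caller-supplied label; respiration thresholds are upstream
wet-lab territory.

## Synthetic data

`fixtures.random_model` generates seeded networks with a planted linear
pathway (unit coefficients, unidirectional) from a random transportable
subset to every biomass compound, plus random reactions with coefficients up
to `max_coefficient` and a configurable reversible fraction.  Defaults
(12 compounds, 10 reactions, 5 transportables, 1 biomass compound, 25%
reversible, coefficients ≤ 2) are sized so that exhaustive verification over
all 2^|T| subsets stays cheap.  The planting guarantees steady-state
producibility of biomass from the full set T; machinery feasibility is
deliberately *not* guaranteed, so random draws exercise both verdicts and the
gap between the two growth definitions.  These models emulate the shape of
curated networks (stoichiometry, reversibility, dead ends) but not their
scale, their compartment structure, their degree distribution, or biological
pathway motifs — passing tests on them certify algorithmic correctness
(enumeration completeness, encoding equivalence, compression losslessness),
not predictive accuracy on a real organism.

## Problem sizes and determinism

Randomized verification uses models with |T| between 3 and 7 and 8–11
compounds: 100 models for enumeration-vs-brute-force agreement in both modes,
15–20 models with a raised reversible fraction for encoding agreement
(exhaustive over all subsets at |T| ≤ 5), and 8 models for simplification
invariance.  These sizes give full-subset coverage with exact arithmetic in
seconds per model while exercising every code path (UNSAT machinery systems
included).  All randomness flows from explicit integer seeds through
`random.Random`; reruns are byte-identical, and `scripts/acceptance.py`
derives every model seed from its `--seed` argument.

## Known limitations

* Regulation, toxicity, enzyme kinetics, and nutrient concentrations are not
  modeled; a predicted medium is arithmetically possible growth, not a
  guarantee (conversely, with a complete reaction set and a sound biomass
  list, a rejected medium is arithmetically impossible).
* Compartments are carried as opaque id suffixes with no semantics.
* The disjunct case-split is exponential in the number of machinery clauses
  in the worst case; the additive-closure fast path makes satisfiable systems
  cheap, but adversarial infeasible systems at genome scale would need the
  incremental-solver and parallel-scan engineering that this implementation
  keeps out of scope.
* Charge balance is not checked during instantiation.
* Genome-scale curated inputs (reaction/transportable/biomass tables of a
  real organism) are not bundled; the package reads them from canonical
  JSON/TSV or SBML when the user supplies them.
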