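"""Growth oracle: disjunctive linear constraint systems and exact satisfiability.

Two growth definitions are supported for a putative nutrient set N drawn from
the transportables T of a model ⟨R, B⟩ (with A = N ∪ auxiliaries the exempt
compounds):

* **steady**: reaction rates r with r_j ≥ 0 for unidirectional reactions
  (sign-free for reversible ones), net production p = M r, p_i > 0 for biomass
  compounds i ∉ A and p_i ≥ 0 for other compounds i ∉ A.

* **machinery**: the steady system plus one disjunctive clause per non-exempt,
  non-biomass compound i mentioned by at least one reaction:

      p_i > 0   ∨   ∧_{j mentions i} r_j = 0

  i.e. every intermediate that participates in an active reaction must itself
  be produced at a strictly positive rate, so that dividing cells can
  duplicate their active metabolic machinery rather than dilute it.

Satisfiability is decided exactly over the rationals.  Every strict atom
``e > 0`` is replaced by ``e ≥ 1``: the systems are homogeneous, so any
solution of the strict system can be scaled until each strict expression
reaches 1, and conversely.  Disjunctive clauses are handled by depth-first
case splitting with linear-relaxation pruning at every node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .exactlp import LinearConstraint, PivotLimitExceeded, solve_feasibility
from .model import MetabolicModel, split_directions

__all__ = [
    "LinearAtom",
    "Clause",
    "ConstraintSystem",
    "FluxWitness",
    "SolverIndeterminate",
    "build_constraints",
    "is_satisfiable",
    "verify_witness",
    "nutset",
    "NutsetOracle",
    "export_smtlib",
]

ZERO = Fraction(0)
FluxWitness = dict[str, Fraction]


class SolverIndeterminate(Exception):
    """The backend could not decide satisfiability (never a truth value)."""


@dataclass(frozen=True)
class LinearAtom:
    """Homogeneous atom ``coeffs · r  rel  0`` with rel in {">", ">=", "="}."""

    coeffs: tuple[tuple[str, Fraction], ...]
    rel: str

    def __post_init__(self) -> None:
        if self.rel not in (">", ">=", "="):
            raise ValueError(f"unsupported relation {self.rel!r}")

    def evaluate(self, assignment: Mapping[str, Fraction]) -> bool:
        value = sum((k * assignment.get(v, ZERO) for v, k in self.coeffs), ZERO)
        if self.rel == ">":
            return value > 0
        if self.rel == ">=":
            return value >= 0
        return value == 0

    def as_nonstrict(self) -> LinearConstraint:
        """Strict atoms become ``≥ 1`` (valid by homogeneity), others pass."""
        if self.rel == ">":
            return LinearConstraint(self.coeffs, ">=", Fraction(1))
        return LinearConstraint(self.coeffs, self.rel, ZERO)


@dataclass(frozen=True)
class Clause:
    """Disjunction of conjunctions of atoms.  Steady clauses have a single
    disjunct; machinery clauses have two (production-positive | all-zero)."""

    disjuncts: tuple[tuple[LinearAtom, ...], ...]

    def evaluate(self, assignment: Mapping[str, Fraction]) -> bool:
        return any(
            all(atom.evaluate(assignment) for atom in disjunct)
            for disjunct in self.disjuncts
        )


@dataclass
class ConstraintSystem:
    variables: dict[str, str]  # variable -> "nonneg" | "free"
    clauses: list[Clause]
    provenance: list[str] = field(default_factory=list)  # compound/reaction per clause

    def unit_atoms(self) -> list[LinearAtom]:
        return [c.disjuncts[0][0] for c in self.clauses if len(c.disjuncts) == 1]

    def disjunctive(self) -> list[Clause]:
        return [c for c in self.clauses if len(c.disjuncts) > 1]


class _Skeleton:
    """Pre-computed per-(model, encoding) pieces reused across nutrient sets."""

    def __init__(self, model: MetabolicModel, encoding: str) -> None:
        work = (
            split_directions(model) if encoding == "split-unidirectional" else model
        )
        self.variables: dict[str, str] = {}
        for rxn in work.reactions:
            if rxn.reversible and encoding == "free-variable":
                self.variables[rxn.id] = "free"
            else:
                self.variables[rxn.id] = "nonneg"
        self.compound_order = list(work.compounds)
        self.production: dict[str, list[tuple[str, Fraction]]] = {
            cid: [] for cid in work.compounds
        }
        self.mentions: dict[str, list[str]] = {cid: [] for cid in work.compounds}
        self.uses: dict[str, list[str]] = {cid: [] for cid in work.compounds}
        for rxn in work.reactions:
            for cid, v in rxn.net().items():
                if v != 0:
                    self.production[cid].append((rxn.id, v))
            for cid in rxn.mentioned():
                self.mentions[cid].append(rxn.id)
            for cid, _ in rxn.reactants:
                self.uses[cid].append(rxn.id)


def _build_from_skeleton(
    skel: _Skeleton,
    model: MetabolicModel,
    N: set[str],
    mode: str,
    machinery_mentions: str,
) -> ConstraintSystem:
    exempt = N | set(model.auxiliaries)
    clauses: list[Clause] = []
    provenance: list[str] = []
    for cid in skel.compound_order:
        if cid in exempt:
            continue
        expr = tuple(skel.production[cid])
        if cid in model.biomass:
            clauses.append(Clause(((LinearAtom(expr, ">"),),)))
            provenance.append(cid)
        elif expr:
            clauses.append(Clause(((LinearAtom(expr, ">="),),)))
            provenance.append(cid)
    if mode == "machinery":
        mention_map = skel.mentions if machinery_mentions == "mention" else skel.uses
        for cid in skel.compound_order:
            if cid in exempt or cid in model.biomass:
                continue
            touching = mention_map[cid]
            if not touching:
                continue
            positive = (LinearAtom(tuple(skel.production[cid]), ">"),)
            all_zero = tuple(
                LinearAtom(((rid, Fraction(1)),), "=") for rid in touching
            )
            clauses.append(Clause((positive, all_zero)))
            provenance.append(cid)
    return ConstraintSystem(dict(skel.variables), clauses, provenance)


def build_constraints(
    model: MetabolicModel,
    N: Iterable[str],
    mode: str,
    encoding: str = "free-variable",
    machinery_mentions: str | None = None,
) -> ConstraintSystem:
    """Construct the constraint system for putative nutrient set N.

    ``encoding`` selects how reversible reactions are handled: one sign-free
    flux variable (``free-variable``, default) or a split into two
    non-negative unidirectional variables (``split-unidirectional``).

    ``machinery_mentions`` selects the machinery-clause convention:
    ``"mention"`` zeroes every reaction that has the compound as reactant *or*
    product ("make it if you mention it"); ``"use"`` zeroes reactant-mentions
    only ("make it if you use it").  The two are feasibility-equivalent for
    their intended encodings; the default pairs "mention" with free variables
    and "use" with the split encoding.
    """
    if mode not in ("steady", "machinery"):
        raise ValueError(f"unknown mode {mode!r}")
    if encoding not in ("free-variable", "split-unidirectional"):
        raise ValueError(f"unknown encoding {encoding!r}")
    N = set(N)
    extra = N - set(model.transportables)
    if extra:
        raise ValueError(
            "nutrient set contains non-transportables: " + ", ".join(sorted(extra))
        )
    if machinery_mentions is None:
        machinery_mentions = "mention" if encoding == "free-variable" else "use"
    if machinery_mentions not in ("mention", "use"):
        raise ValueError(f"unknown machinery_mentions {machinery_mentions!r}")
    skeleton = _Skeleton(model, encoding)
    return _build_from_skeleton(skeleton, model, N, mode, machinery_mentions)


def _lp_feasible(
    variables: Mapping[str, str], atoms: Sequence[LinearAtom]
) -> dict[str, Fraction] | None:
    try:
        return solve_feasibility(variables, [a.as_nonstrict() for a in atoms])
    except PivotLimitExceeded as exc:  # pragma: no cover - defensive
        raise SolverIndeterminate(str(exc)) from exc


def is_satisfiable(
    system: ConstraintSystem, want_witness: bool = True
) -> tuple[bool, FluxWitness | None]:
    """Exact satisfiability decision with optional verified flux witness."""
    base = list(system.unit_atoms())
    disjunctive = system.disjunctive()

    if not system.clauses:
        witness = {v: ZERO for v in system.variables} if want_witness else None
        return True, witness

    base_witness = _lp_feasible(system.variables, base)
    if base_witness is None:
        return False, None
    if not disjunctive:
        return True, base_witness if want_witness else None

    # Fast path: take the production-positive disjunct of every machinery
    # clause at once.  Because feasible fluxes are closed under addition, this
    # succeeds for most satisfiable systems.
    eager = base + [atom for c in disjunctive for atom in c.disjuncts[0]]
    witness = _lp_feasible(system.variables, eager)
    if witness is not None:
        return True, witness if want_witness else None

    def dfs(idx: int, atoms: list[LinearAtom]) -> FluxWitness | None:
        sol = _lp_feasible(system.variables, atoms)
        if sol is None:
            return None
        if idx == len(disjunctive):
            return sol
        for disjunct in disjunctive[idx].disjuncts:
            sol = dfs(idx + 1, atoms + list(disjunct))
            if sol is not None:
                return sol
        return None

    sol = dfs(0, base)
    if sol is None:
        return False, None
    return True, sol if want_witness else None


def verify_witness(system: ConstraintSystem, witness: Mapping[str, Fraction]) -> bool:
    """Re-evaluate every clause of ``system`` exactly under ``witness``."""
    for rid, sign in system.variables.items():
        if sign == "nonneg" and witness.get(rid, ZERO) < 0:
            return False
    return all(clause.evaluate(witness) for clause in system.clauses)


def nutset(
    model: MetabolicModel,
    N: Iterable[str],
    mode: str,
    encoding: str = "free-variable",
    machinery_mentions: str | None = None,
) -> bool:
    """Is N a nutrient set of the model under the given growth definition?"""
    system = build_constraints(model, N, mode, encoding, machinery_mentions)
    sat, _ = is_satisfiable(system, want_witness=False)
    return sat


class NutsetOracle:
    """Memoized nutset function for one (model, mode, encoding) triple.

    The oracle is monotone: enlarging N removes constraints, so a satisfiable
    system stays satisfiable.  Call counters expose the oracle as the cost
    center of enumeration.
    """

    def __init__(
        self,
        model: MetabolicModel,
        mode: str,
        encoding: str = "free-variable",
        machinery_mentions: str | None = None,
    ) -> None:
        if mode not in ("steady", "machinery"):
            raise ValueError(f"unknown mode {mode!r}")
        if encoding not in ("free-variable", "split-unidirectional"):
            raise ValueError(f"unknown encoding {encoding!r}")
        if machinery_mentions is None:
            machinery_mentions = "mention" if encoding == "free-variable" else "use"
        self.model = model
        self.mode = mode
        self.encoding = encoding
        self.machinery_mentions = machinery_mentions
        self._skeleton = _Skeleton(model, encoding)
        self._transportables = set(model.transportables)
        self._cache: dict[frozenset[str], bool] = {}
        self.n_calls = 0
        self.n_solver_calls = 0

    def __call__(self, N: Iterable[str]) -> bool:
        key = frozenset(N)
        self.n_calls += 1
        if key not in self._cache:
            extra = key - self._transportables
            if extra:
                raise ValueError(
                    "nutrient set contains non-transportables: "
                    + ", ".join(sorted(extra))
                )
            self.n_solver_calls += 1
            system = _build_from_skeleton(
                self._skeleton, self.model, set(key), self.mode,
                self.machinery_mentions,
            )
            self._cache[key] = is_satisfiable(system, want_witness=False)[0]
        return self._cache[key]


def _smt_term(coeffs: Sequence[tuple[str, Fraction]]) -> str:
    if not coeffs:
        return "0"
    parts = []
    for var, k in coeffs:
        if k == 1:
            parts.append(f"|{var}|")
        else:
            num = (
                str(k)
                if k.denominator == 1
                else f"(/ {k.numerator} {k.denominator})"
            )
            if k < 0:
                num = f"(- {str(-k) if k.denominator == 1 else f'(/ {-k.numerator} {k.denominator})'})"
            parts.append(f"(* {num} |{var}|)")
    return parts[0] if len(parts) == 1 else "(+ " + " ".join(parts) + ")"


def export_smtlib(system: ConstraintSystem) -> str:
    """Emit the system in SMT-LIB 2 syntax over the theory QF_LRA."""
    lines = ["(set-logic QF_LRA)"]
    for var, sign in system.variables.items():
        lines.append(f"(declare-const |{var}| Real)")
        if sign == "nonneg":
            lines.append(f"(assert (>= |{var}| 0))")

    def atom_str(atom: LinearAtom) -> str:
        rel = {"=": "=", ">": ">", ">=": ">="}[atom.rel]
        return f"({rel} {_smt_term(atom.coeffs)} 0)"

    for clause in system.clauses:
        djs = []
        for disjunct in clause.disjuncts:
            conj = [atom_str(a) for a in disjunct]
            djs.append(conj[0] if len(conj) == 1 else "(and " + " ".join(conj) + ")")
        body = djs[0] if len(djs) == 1 else "(or " + " ".join(djs) + ")"
        lines.append(f"(assert {body})")
    lines.append("(check-sat)")
    return "\n".join(lines) + "\n"
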