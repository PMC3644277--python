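"""Enumeration of all minimal nutrient sets as prime implicants of nutset.

The nutset function is monotone — adding a transportable only removes
constraints — and the minimal nutrient sets are exactly its prime implicants.
The algorithm evaluates nutset as a black box:

1. If nutset(T) is false there are no nutrient sets at all.
2. Otherwise minimize the all-true vector to obtain a first prime implicant.
3. Maintain the monotone *choice function* g(x) = ∧_i ∨_{j ∈ T_i} x_j over the
   prime implicants found so far (T_i = true positions of the i-th prime).
   A new prime implicant exists iff some choice vector u satisfies
   nutset(¬u); it then suffices to scan the *minimal* choice vectors, i.e.
   the prime implicants of g, which are read off a BDD for

       pi_g(x) = g(x) ∧ ∧_i (¬x_i ∨ ¬g(x with x_i := false))

   by tracing root-to-true paths.  On the first u with nutset(¬u) true,
   minimize ¬u, add the new prime, rebuild pi_g, and restart the scan; when no
   such u exists the collection is complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Iterator, Sequence

from .bdd import BDDManager, TRUE
from .constraints import NutsetOracle
from .model import MetabolicModel

__all__ = [
    "BoolVec",
    "PrimeImplicantSet",
    "ChoiceFunction",
    "minimize",
    "is_prime_implicant",
    "enumerate_minimal_nutrient_sets",
    "brute_force_minimal_sets",
    "vector_to_set",
    "set_to_vector",
]

BoolVec = tuple[bool, ...]
BoolFunc = Callable[[BoolVec], bool]


def vector_to_set(vector: BoolVec, names: Sequence[str]) -> frozenset[str]:
    return frozenset(name for name, bit in zip(names, vector) if bit)


def set_to_vector(ids: Iterable[str], names: Sequence[str]) -> BoolVec:
    ids = set(ids)
    return tuple(name in ids for name in names)


def _negate(v: BoolVec) -> BoolVec:
    return tuple(not b for b in v)


def minimize(f: BoolFunc, v: BoolVec) -> BoolVec:
    """Single left-to-right pass turning an implicant of a monotone f into a
    prime implicant: flip each true component to false whenever f stays true."""
    if not f(v):
        raise ValueError("minimize requires f(v) = true")
    u = list(v)
    for i, bit in enumerate(u):
        if bit:
            u[i] = False
            if not f(tuple(u)):
                u[i] = True
    return tuple(u)


def is_prime_implicant(f: BoolFunc, v: BoolVec) -> bool:
    if not f(v):
        return False
    for i, bit in enumerate(v):
        if bit:
            flipped = v[:i] + (False,) + v[i + 1 :]
            if f(flipped):
                return False
    return True


class ChoiceFunction:
    """BDD representation of g (conjunction of disjunctions over the true
    positions of known prime implicants) and its prime-implicant filter pi_g."""

    def __init__(self, n_vars: int) -> None:
        self.manager = BDDManager(n_vars)
        self.n_vars = n_vars
        self.g = TRUE  # empty conjunction
        self._pi_g: int | None = None

    def update(self, new_prime: BoolVec) -> None:
        """Conjoin g with the disjunction of the prime's true components."""
        mgr = self.manager
        disjunction = 0  # FALSE: empty disjunction
        for i, bit in enumerate(new_prime):
            if bit:
                disjunction = mgr.apply_or(disjunction, mgr.var(i))
        self.g = mgr.apply_and(self.g, disjunction)
        self._pi_g = None

    @property
    def pi_g(self) -> int:
        """pi_g(x) = g(x) ∧ ∧_i (¬x_i ∨ ¬g(x|x_i:=false))."""
        if self._pi_g is None:
            mgr = self.manager
            result = self.g
            for i in range(self.n_vars):
                g_without_i = mgr.restrict(self.g, i, False)
                term = mgr.apply_or(
                    mgr.negate(mgr.var(i)), mgr.negate(g_without_i)
                )
                result = mgr.apply_and(result, term)
            self._pi_g = result
        return self._pi_g

    def iter_minimal_choice_vectors(self) -> Iterator[BoolVec]:
        """Minimal choice vectors = implicants of pi_g, in deterministic
        path-tracing order (depth-first, false branch first)."""
        return self.manager.iter_implicants(self.pi_g)


@dataclass
class PrimeImplicantSet:
    """Minimal nutrient sets in discovery order, over a fixed T ordering."""

    names: tuple[str, ...]
    vectors: list[BoolVec] = field(default_factory=list)
    complete: bool = True
    oracle_calls: int = 0

    def as_sets(self) -> list[frozenset[str]]:
        return [vector_to_set(v, self.names) for v in self.vectors]

    def as_sorted_lists(self) -> list[list[str]]:
        return [sorted(s) for s in self.as_sets()]

    def __len__(self) -> int:
        return len(self.vectors)


def enumerate_minimal_nutrient_sets(
    model: MetabolicModel,
    mode: str,
    limit: int | None = None,
    oracle: NutsetOracle | None = None,
) -> PrimeImplicantSet:
    """Enumerate all minimal nutrient sets of the model under ``mode``.

    ``limit`` truncates the run after that many sets (the result is then
    flagged incomplete).  Passing a pre-built ``oracle`` allows cache sharing
    across calls.
    """
    if oracle is None:
        oracle = NutsetOracle(model, mode)
    names = tuple(model.transportables)
    n = len(names)

    def f(v: BoolVec) -> bool:
        return oracle(vector_to_set(v, names))

    result = PrimeImplicantSet(names=names)
    all_true = (True,) * n
    if not f(all_true):
        result.oracle_calls = oracle.n_calls
        return result

    prime = minimize(f, all_true)
    cf = ChoiceFunction(n)
    result.vectors.append(prime)
    cf.update(prime)

    while limit is None or len(result.vectors) < limit:
        found: BoolVec | None = None
        for u in cf.iter_minimal_choice_vectors():
            if f(_negate(u)):
                found = u
                break
        if found is None:
            break
        prime = minimize(f, _negate(found))
        result.vectors.append(prime)
        cf.update(prime)
    else:
        # Loop left via the limit; unseen primes may remain.
        result.complete = False

    result.oracle_calls = oracle.n_calls
    return result


def brute_force_minimal_sets(
    model: MetabolicModel,
    mode: str,
    oracle: NutsetOracle | None = None,
    max_transportables: int = 16,
) -> PrimeImplicantSet:
    """Reference enumeration: test subsets of T in increasing size and keep
    the minimal satisfiable ones.  Guarded to small |T|."""
    names = tuple(model.transportables)
    n = len(names)
    if n > max_transportables:
        raise ValueError(
            f"brute force refused: |T| = {n} exceeds guard {max_transportables}"
        )
    if oracle is None:
        oracle = NutsetOracle(model, mode)
    minimal: list[frozenset[str]] = []
    for size in range(n + 1):
        for combo in combinations(names, size):
            candidate = frozenset(combo)
            # By monotonicity any superset of a known minimal set is a
            # non-minimal nutrient set; skip the oracle call.
            if any(m <= candidate for m in minimal):
                continue
            if oracle(candidate):
                minimal.append(candidate)
    result = PrimeImplicantSet(names=names)
    result.vectors = [set_to_vector(m, names) for m in minimal]
    result.oracle_calls = oracle.n_calls
    return result
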