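"""Built-in toy models and seeded random model generation.

Every stage of the pipeline is testable without external data:

* ``example1_model`` — the two-reaction network A+B→C+D, C+F→B+E with biomass
  {E}.  With nutrients {A, F} it is steady-state feasible (the internal pool
  of B is recycled: r1 = r2 = k) but machinery-infeasible (recycling B and C
  exactly balances their production, so the active machinery cannot be
  duplicated) — the canonical separation between the two growth definitions.

* ``crossfeed_model`` — C1+N1→M, C2+N2→M: two carbon and two nitrogen sources
  that cannot substitute across pathways, so the minimal nutrient sets are
  {C1,N1} and {C2,N2} and single-element variation from one seed set misses
  the other solution.

* ``random_model`` — seeded random networks with at least one planted linear
  pathway from transportables to every biomass compound, guaranteeing
  steady-state producibility of biomass from the full nutrient set T
  (machinery feasibility is deliberately not guaranteed: infeasible draws
  exercise the gap between the two growth definitions).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import Compound, MetabolicModel, parse_equation

__all__ = ["RandomModelParams", "example1_model", "crossfeed_model", "random_model"]


def _simple_model(
    equations: list[tuple[str, str]],
    transportables: list[str],
    biomass: set[str],
    extra_compounds: tuple[str, ...] = (),
) -> MetabolicModel:
    reactions = [parse_equation(rid, eq) for rid, eq in equations]
    compound_ids: list[str] = list(extra_compounds)
    for rxn in reactions:
        for cid in [c for c, _ in rxn.reactants] + [c for c, _ in rxn.products]:
            if cid not in compound_ids:
                compound_ids.append(cid)
    model = MetabolicModel(
        compounds={cid: Compound(cid) for cid in sorted(compound_ids)},
        reactions=reactions,
        transportables=transportables,
        biomass=biomass,
    )
    model.validate()
    return model


def example1_model(transportables: tuple[str, ...] = ("A", "B", "F")) -> MetabolicModel:
    """Two unidirectional reactions, biomass {E}, T = [A, B, F] by default."""
    return _simple_model(
        [("R1", "A + B -> C + D"), ("R2", "C + F -> B + E")],
        list(transportables),
        {"E"},
    )


def crossfeed_model() -> MetabolicModel:
    """Two independent source pairs feeding one biomass compound."""
    return _simple_model(
        [("R1", "C1 + N1 -> M"), ("R2", "C2 + N2 -> M")],
        ["C1", "C2", "N1", "N2"],
        {"M"},
    )


@dataclass(frozen=True)
class RandomModelParams:
    n_compounds: int = 12
    n_reactions: int = 10
    n_transportables: int = 5
    n_biomass: int = 1
    reversible_fraction: float = 0.25
    max_coefficient: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_biomass < 1:
            raise ValueError("n_biomass must be >= 1")
        if self.n_transportables < 1:
            raise ValueError("n_transportables must be >= 1")
        if self.n_transportables + self.n_biomass > self.n_compounds:
            raise ValueError(
                "n_compounds must cover transportables and biomass disjointly"
            )
        if not 0.0 <= self.reversible_fraction <= 1.0:
            raise ValueError("reversible_fraction must be a probability")
        if self.max_coefficient < 1:
            raise ValueError("max_coefficient must be >= 1")


def random_model(params: RandomModelParams) -> MetabolicModel:
    """Seeded, reproducible random model with planted biomass pathways."""
    params.validate()
    rng = random.Random(params.seed)
    width = max(2, len(str(params.n_compounds - 1)))
    compound_ids = [f"C{i:0{width}d}" for i in range(params.n_compounds)]
    transportables = sorted(rng.sample(compound_ids, params.n_transportables))
    pool = [c for c in compound_ids if c not in transportables]
    biomass = sorted(rng.sample(pool, params.n_biomass))
    intermediates = [c for c in pool if c not in biomass]

    reactions = []
    # Planted pathways: transportable sources -> (intermediates) -> biomass,
    # unit coefficients so rate-1 fluxes witness steady feasibility from T.
    for b in biomass:
        n_sources = rng.randint(1, min(2, len(transportables)))
        sources = rng.sample(transportables, n_sources)
        max_len = min(2, len(intermediates))
        chain = rng.sample(intermediates, rng.randint(0, max_len)) if max_len else []
        stops = chain + [b]
        prev = sources
        for k, target in enumerate(stops):
            rid = f"P_{b}_{k}"
            eq = " + ".join(prev) + " -> " + target
            reactions.append(parse_equation(rid, eq))
            prev = [target]

    n_extra = max(0, params.n_reactions - len(reactions))
    for k in range(n_extra):
        n_react = rng.randint(1, 2)
        reactants = rng.sample(compound_ids, n_react)
        remaining = [c for c in compound_ids if c not in reactants]
        products = rng.sample(remaining, rng.randint(1, 2))
        terms_l = " + ".join(
            f"{rng.randint(1, params.max_coefficient)} {c}" for c in reactants
        )
        terms_r = " + ".join(
            f"{rng.randint(1, params.max_coefficient)} {c}" for c in products
        )
        reversible = rng.random() < params.reversible_fraction
        arrow = "<->" if reversible else "->"
        reactions.append(parse_equation(f"R{k:03d}", f"{terms_l} {arrow} {terms_r}"))

    model = MetabolicModel(
        compounds={cid: Compound(cid) for cid in compound_ids},
        reactions=reactions,
        transportables=transportables,
        biomass=set(biomass),
    )
    model.validate()
    return model
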