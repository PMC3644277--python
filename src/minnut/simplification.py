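"""Model simplification: removal of Impossible and Useless compounds.

Both removals are defined on a split-unidirectional model and iterated to a
joint fixed point; complementary reaction pairs are merged back afterwards.

* A compound is **Impossible** if it is neither a potential nutrient
  (transportable or auxiliary) nor the product of any reaction.  It can never
  have non-negative net production while being consumed, so it is deleted
  together with every reaction mentioning it; deletions can expose further
  impossible compounds, hence the iteration.

* A compound is **Useless** if it has no downstream biomass compound.  The
  complement — the Useful set — is the least fixed point of: biomass is
  useful, and any reactant of a reaction producing a useful compound is
  useful.  Useless compounds are eliminated from product lists (leaving a
  reaction "unbalanced" is harmless: it merely drops a redundant
  non-negativity constraint) and reactions whose products are all useless are
  deleted.

Neither removal ever touches membership of T or B: transportables stay listed
(they index the Boolean vectors of the enumeration stage) even when pruned
from every reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model import (
    MetabolicModel,
    ModelError,
    merge_directions,
    split_directions,
)

__all__ = ["SimplificationTrace", "remove_impossible", "remove_useless", "simplify"]


@dataclass
class SimplificationTrace:
    removed_impossible: list[str] = field(default_factory=list)
    removed_useless: list[str] = field(default_factory=list)
    deleted_reactions: list[str] = field(default_factory=list)
    modified_reactions: list[str] = field(default_factory=list)
    iterations: int = 0

    def is_empty(self) -> bool:
        return not (
            self.removed_impossible
            or self.removed_useless
            or self.deleted_reactions
            or self.modified_reactions
        )

    def merge(self, other: "SimplificationTrace") -> None:
        self.removed_impossible.extend(other.removed_impossible)
        self.removed_useless.extend(other.removed_useless)
        self.deleted_reactions.extend(other.deleted_reactions)
        self.modified_reactions.extend(other.modified_reactions)
        self.iterations += other.iterations


def _require_split(model: MetabolicModel) -> None:
    bad = [r.id for r in model.reactions if r.reversible]
    if bad:
        raise ModelError(
            "simplification rules require a split-unidirectional model; "
            f"reversible reactions present: {', '.join(bad)}"
        )


def remove_impossible(
    model: MetabolicModel,
) -> tuple[MetabolicModel, SimplificationTrace]:
    """Iteratively delete compounds with no producer that are not potential
    nutrients, together with all reactions mentioning them."""
    _require_split(model)
    out = model.copy()
    trace = SimplificationTrace()
    potential = set(out.transportables) | set(out.auxiliaries)
    while True:
        trace.iterations += 1
        produced = {cid for rxn in out.reactions for cid, _ in rxn.products}
        doomed = {
            cid
            for cid in out.compounds
            if cid not in potential and cid not in produced
        }
        if not doomed:
            break
        trace.removed_impossible.extend(sorted(doomed))
        survivors = []
        for rxn in out.reactions:
            if rxn.mentioned() & doomed:
                trace.deleted_reactions.append(rxn.id)
            else:
                survivors.append(rxn)
        out.reactions = survivors
        for cid in doomed:
            del out.compounds[cid]
    return out, trace


def _useful_compounds(model: MetabolicModel) -> set[str]:
    useful = set(model.biomass)
    changed = True
    while changed:
        changed = False
        for rxn in model.reactions:
            if any(cid in useful for cid, _ in rxn.products):
                for cid, _ in rxn.reactants:
                    if cid not in useful:
                        useful.add(cid)
                        changed = True
    return useful


def remove_useless(
    model: MetabolicModel,
) -> tuple[MetabolicModel, SimplificationTrace]:
    """Eliminate compounds with no downstream biomass compound.

    Useless transportables/auxiliaries are pruned from reactions but stay in
    the compound table so |T| and its ordering remain stable.
    """
    _require_split(model)
    out = model.copy()
    trace = SimplificationTrace()
    trace.iterations = 1
    useful = _useful_compounds(out)

    keep_listed = set(out.transportables) | set(out.auxiliaries) | set(out.biomass)
    survivors = []
    for rxn in out.reactions:
        new_products = tuple((c, k) for c, k in rxn.products if c in useful)
        if not new_products:
            trace.deleted_reactions.append(rxn.id)
            continue
        if len(new_products) != len(rxn.products):
            rxn = replace(rxn, products=new_products)
            trace.modified_reactions.append(rxn.id)
        survivors.append(rxn)
    out.reactions = survivors

    for cid in list(out.compounds):
        if cid not in useful and cid not in keep_listed:
            trace.removed_useless.append(cid)
            del out.compounds[cid]
    return out, trace


def simplify(model: MetabolicModel) -> tuple[MetabolicModel, SimplificationTrace]:
    """Split → alternate impossible/useless removal to a joint fixed point →
    merge complementary pairs.  Raises if a biomass compound is eliminated
    (the model cannot produce it from any nutrient set)."""
    work = split_directions(model)
    total = SimplificationTrace()
    while True:
        work, t_imp = remove_impossible(work)
        missing = sorted(set(model.biomass) - work.compounds.keys())
        if missing:
            raise ModelError("biomass unproducible: " + ", ".join(missing))
        work, t_use = remove_useless(work)
        total.merge(t_imp)
        total.merge(t_use)
        if t_imp.removed_impossible == [] and t_use.is_empty():
            break
    merged = merge_directions(work)
    merged.validate()
    return merged, total
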