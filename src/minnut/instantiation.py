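"""Expansion of generic reactions over compound classes into instance reactions.

Pathway/genome databases describe broad-specificity enzymes with *generic
reactions* whose substrates are metabolite classes (e.g. "sugar phosphate" →
"sugar").  Before constraint construction each generic reaction is expanded by
substituting, independently for every class slot, every instance of that
class.  A substitution is kept only when the resulting instance-level equation
is mass balanced, and it is skipped as ambiguous when the chosen instance
shares its chemical formula with another instance of the same class (the
balance check then cannot discriminate between them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .model import Compound, MetabolicModel, ModelError, Reaction

__all__ = [
    "InstantiationReport",
    "IndeterminateBalanceError",
    "is_mass_balanced",
    "instantiate_generic_reactions",
]


class IndeterminateBalanceError(ModelError):
    """Mass balance cannot be decided because a formula is missing."""


@dataclass
class InstantiationReport:
    generic_reaction_id: str
    attempted: int = 0
    accepted: list[str] = field(default_factory=list)
    rejected_unbalanced: int = 0
    rejected_ambiguous: int = 0

    def accounted(self) -> bool:
        return self.attempted == (
            len(self.accepted) + self.rejected_unbalanced + self.rejected_ambiguous
        )


def is_mass_balanced(reaction: Reaction, compounds: dict[str, Compound]) -> bool:
    """True iff coefficient-weighted element counts agree on both sides."""
    totals: dict[str, object] = {}

    def tally(side, sign):
        for cid, coeff in side:
            comp = compounds.get(cid)
            if comp is None or comp.formula is None:
                raise IndeterminateBalanceError(
                    f"reaction {reaction.id!r}: no formula for compound {cid!r}"
                )
            for element, count in comp.formula.items():
                totals[element] = totals.get(element, 0) + sign * coeff * count

    tally(reaction.reactants, 1)
    tally(reaction.products, -1)
    return all(v == 0 for v in totals.values())


def _class_slots(rxn: Reaction, compounds: dict[str, Compound]):
    """Class mentions as (side, index) positions; substitution is per-slot."""
    slots = []
    for side_name, side in (("reactants", rxn.reactants), ("products", rxn.products)):
        for idx, (cid, _) in enumerate(side):
            comp = compounds.get(cid)
            if comp is not None and comp.is_class:
                slots.append((side_name, idx, cid))
    return slots


def instantiate_generic_reactions(
    model: MetabolicModel,
) -> tuple[MetabolicModel, list[InstantiationReport]]:
    """Replace every generic reaction by its accepted instantiations.

    Deterministic: slots are substituted in reaction order and instance lists
    are iterated as declared, so the accepted-reaction id set is a pure
    function of the model.
    """
    model.validate()
    out = model.copy()
    reports: list[InstantiationReport] = []
    new_reactions: list[Reaction] = []

    # Instances whose formula is shared within their class are ambiguous.
    ambiguous_instance: dict[tuple[str, str], bool] = {}
    for comp in model.compounds.values():
        if not comp.is_class:
            continue
        formula_count: dict[tuple, int] = {}
        for inst_id in comp.instance_ids:
            f = model.compounds[inst_id].formula
            key = tuple(sorted(f.items())) if f is not None else None
            if key is not None:
                formula_count[key] = formula_count.get(key, 0) + 1
        for inst_id in comp.instance_ids:
            f = model.compounds[inst_id].formula
            key = tuple(sorted(f.items())) if f is not None else None
            ambiguous_instance[(comp.id, inst_id)] = (
                key is not None and formula_count[key] > 1
            )

    for rxn in model.reactions:
        slots = _class_slots(rxn, model.compounds)
        if not slots:
            new_reactions.append(rxn)
            continue
        report = InstantiationReport(generic_reaction_id=rxn.id)
        reports.append(report)
        choice_lists = [
            model.compounds[class_id].instance_ids for _, _, class_id in slots
        ]
        if any(not choices for choices in choice_lists):
            # A class with zero instances: nothing to substitute, reaction dropped.
            continue
        seen_ids: set[str] = set()
        for combo in product(*choice_lists):
            report.attempted += 1
            if any(
                ambiguous_instance[(class_id, inst)]
                for (_, _, class_id), inst in zip(slots, combo)
            ):
                report.rejected_ambiguous += 1
                continue
            reactants = list(rxn.reactants)
            products = list(rxn.products)
            for (side_name, idx, _), inst in zip(slots, combo):
                side = reactants if side_name == "reactants" else products
                side[idx] = (inst, side[idx][1])
            new_id = f"{rxn.id}/{'-'.join(combo)}"
            candidate = Reaction(
                id=new_id,
                reactants=tuple(reactants),
                products=tuple(products),
                reversible=rxn.reversible,
                is_transport=rxn.is_transport,
                is_exchange=rxn.is_exchange,
            )
            try:
                balanced = is_mass_balanced(candidate, model.compounds)
            except IndeterminateBalanceError:
                balanced = False  # unverifiable substitutions are not added
            if balanced and new_id not in seen_ids:
                seen_ids.add(new_id)
                report.accepted.append(new_id)
                new_reactions.append(candidate)
            else:
                report.rejected_unbalanced += 1

    out.reactions = new_reactions
    out.validate()
    return out, reports
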