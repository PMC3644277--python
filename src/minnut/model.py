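"""Core domain types for stoichiometric metabolic models.

A model is a pair ⟨R, B⟩ of reactions and biomass compounds together with an
ordered list T of transportable metabolites (the candidate nutrients) and an
optional set of auxiliary compounds that are assumed to be unconditionally
available.  Stoichiometric coefficients are kept as exact rationals
(`fractions.Fraction`) so that all downstream feasibility reasoning is exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Compound",
    "Reaction",
    "MetabolicModel",
    "StoichiometricMatrix",
    "ModelError",
    "ParseError",
    "ValidationError",
    "parse_formula",
    "format_formula",
    "parse_equation",
    "format_equation",
    "load_model",
    "save_model",
    "build_stoich_matrix",
    "split_directions",
    "merge_directions",
]

REVERSE_SUFFIX = "__rev"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(Exception):
    """Base class for model-layer errors."""


class ParseError(ModelError):
    """A file or equation string could not be parsed."""


class ValidationError(ModelError):
    """A structurally well-formed model violates an invariant."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a chemical formula string such as ``C6H12O6`` into element counts."""
    text = text.strip()
    if not text:
        raise ParseError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ParseError(f"unparseable formula {text!r} at position {pos}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ParseError(f"unparseable formula {text!r} at position {pos}")
    return counts


def format_formula(formula: Mapping[str, int]) -> str:
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(formula.items())
    )


@dataclass(frozen=True)
class Compound:
    """A metabolite, or a metabolite class grouping several instances.

    ``formula`` maps element symbols to positive counts; it may be ``None``
    for macromolecule placeholders whose composition is not modelled.
    """

    id: str
    formula: Mapping[str, int] | None = None
    is_class: bool = False
    instance_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.formula is not None:
            bad = [el for el, n in self.formula.items() if n <= 0]
            if bad:
                raise ValidationError(
                    f"compound {self.id!r}: non-positive formula counts for {bad}"
                )
        if self.instance_ids and not self.is_class:
            raise ValidationError(
                f"compound {self.id!r} lists instances but is not a class"
            )
        object.__setattr__(self, "instance_ids", tuple(self.instance_ids))


def _merge_mentions(
    side: Iterable[tuple[str, Fraction | int]], what: str, rid: str
) -> tuple[tuple[str, Fraction], ...]:
    merged: dict[str, Fraction] = {}
    order: list[str] = []
    for cid, coeff in side:
        coeff = Fraction(coeff)
        if coeff <= 0:
            raise ValidationError(
                f"reaction {rid!r}: non-positive {what} coefficient for {cid!r}"
            )
        if cid not in merged:
            merged[cid] = Fraction(0)
            order.append(cid)
        merged[cid] += coeff
    return tuple((cid, merged[cid]) for cid in order)


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction.  Duplicate mentions on one side are summed."""

    id: str
    reactants: tuple[tuple[str, Fraction], ...]
    products: tuple[tuple[str, Fraction], ...]
    reversible: bool = False
    is_transport: bool = False
    is_exchange: bool = False
    pair_id: str | None = None  # links the two halves of a split reversible

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "reactants", _merge_mentions(self.reactants, "reactant", self.id)
        )
        object.__setattr__(
            self, "products", _merge_mentions(self.products, "product", self.id)
        )
        if not self.is_exchange and (not self.reactants or not self.products):
            raise ValidationError(
                f"reaction {self.id!r}: empty side on a non-exchange reaction"
            )

    def mentioned(self) -> set[str]:
        return {c for c, _ in self.reactants} | {c for c, _ in self.products}

    def net(self) -> dict[str, Fraction]:
        """Net production per compound (negative = net consumption)."""
        out: dict[str, Fraction] = {}
        for cid, k in self.reactants:
            out[cid] = out.get(cid, Fraction(0)) - k
        for cid, k in self.products:
            out[cid] = out.get(cid, Fraction(0)) + k
        return out

    def reversed(self, new_id: str | None = None) -> "Reaction":
        return replace(
            self,
            id=new_id or self.id,
            reactants=self.products,
            products=self.reactants,
        )


_ARROWS = ("<->", "<=>", "<>", "->", "=>", "→", "↔")


def parse_equation(rid: str, text: str, **kwargs) -> Reaction:
    """Parse a reaction-equation string such as ``2 A + B -> C + D``.

    ``<->`` (or ``<=>``) marks the reaction reversible unless overridden via
    keyword arguments.
    """
    arrow = None
    for cand in _ARROWS:
        if cand in text:
            arrow = cand
            break
    if arrow is None:
        raise ParseError(f"reaction {rid!r}: no arrow in equation {text!r}")
    reversible = kwargs.pop("reversible", arrow in ("<->", "<=>", "<>", "↔"))
    left, right = text.split(arrow, 1)

    def parse_side(side: str) -> list[tuple[str, Fraction]]:
        side = side.strip()
        if not side:
            return []
        terms = []
        for term in side.split("+"):
            parts = term.strip().split()
            if not parts:
                raise ParseError(f"reaction {rid!r}: empty term in {text!r}")
            if len(parts) == 2:
                try:
                    coeff = Fraction(parts[0])
                except ValueError as exc:
                    raise ParseError(
                        f"reaction {rid!r}: bad coefficient {parts[0]!r}"
                    ) from exc
                terms.append((parts[1], coeff))
            elif len(parts) == 1:
                terms.append((parts[0], Fraction(1)))
            else:
                raise ParseError(f"reaction {rid!r}: bad term {term!r}")
        return terms

    return Reaction(
        id=rid,
        reactants=tuple(parse_side(left)),
        products=tuple(parse_side(right)),
        reversible=reversible,
        **kwargs,
    )


def _coeff_str(k: Fraction) -> str:
    return "" if k == 1 else f"{k} "


def format_equation(rxn: Reaction) -> str:
    arrow = "<->" if rxn.reversible else "->"
    left = " + ".join(f"{_coeff_str(k)}{c}" for c, k in rxn.reactants)
    right = " + ".join(f"{_coeff_str(k)}{c}" for c, k in rxn.products)
    return f"{left} {arrow} {right}"


@dataclass
class MetabolicModel:
    """A metabolic model ⟨R, B⟩ with ordered transportables T and auxiliaries.

    The order of ``transportables`` is significant: it fixes the component
    positions of the Boolean vectors used by the enumeration machinery, and it
    is preserved by save/load round trips.
    """

    compounds: dict[str, Compound]
    reactions: list[Reaction]
    transportables: list[str]
    biomass: set[str]
    auxiliaries: set[str] = field(default_factory=set)

    def validate(self) -> None:
        seen_rids: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in seen_rids:
                raise ValidationError(f"duplicate reaction id {rxn.id!r}")
            seen_rids.add(rxn.id)
            dangling = sorted(rxn.mentioned() - self.compounds.keys())
            if dangling:
                raise ValidationError(
                    f"reaction {rxn.id!r} references undeclared compounds: "
                    + ", ".join(dangling)
                )
        for label, ids in (
            ("transportable", self.transportables),
            ("biomass", self.biomass),
            ("auxiliary", self.auxiliaries),
        ):
            for cid in ids:
                if cid not in self.compounds:
                    raise ValidationError(f"{label} {cid!r} is not a declared compound")
        if len(set(self.transportables)) != len(self.transportables):
            raise ValidationError("transportables list contains duplicates")
        for comp in self.compounds.values():
            for inst in comp.instance_ids:
                if inst not in self.compounds:
                    raise ValidationError(
                        f"class {comp.id!r} lists undeclared instance {inst!r}"
                    )
                if self.compounds[inst].is_class:
                    raise ValidationError(
                        f"class {comp.id!r} lists class {inst!r} as an instance"
                    )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            compounds=dict(self.compounds),
            reactions=list(self.reactions),
            transportables=list(self.transportables),
            biomass=set(self.biomass),
            auxiliaries=set(self.auxiliaries),
        )

    def reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise KeyError(rid)

    def producers(self, cid: str) -> list[Reaction]:
        """Reactions with cid among products (treating the model as written)."""
        return [r for r in self.reactions if any(c == cid for c, _ in r.products)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.compounds == other.compounds
            and self.reactions == other.reactions
            and self.transportables == other.transportables
            and self.biomass == other.biomass
            and self.auxiliaries == other.auxiliaries
        )


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------


@dataclass
class StoichiometricMatrix:
    """Sparse integer/rational matrix M with M[i,j] = net production of
    compound i by reaction j."""

    row_index: dict[str, int]
    col_index: dict[str, int]
    entries: dict[tuple[int, int], Fraction]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_index), len(self.col_index))

    def __getitem__(self, key: tuple[str, str]) -> Fraction:
        cid, rid = key
        return self.entries.get((self.row_index[cid], self.col_index[rid]), Fraction(0))

    def column(self, rid: str) -> dict[str, Fraction]:
        j = self.col_index[rid]
        rows = {i: cid for cid, i in self.row_index.items()}
        return {
            rows[i]: v for (i, jj), v in self.entries.items() if jj == j and v != 0
        }

    def to_dense(self) -> list[list[Fraction]]:
        n_rows, n_cols = self.shape
        dense = [[Fraction(0)] * n_cols for _ in range(n_rows)]
        for (i, j), v in self.entries.items():
            dense[i][j] = v
        return dense


def build_stoich_matrix(
    model: MetabolicModel, direction_mode: str = "free-variable"
) -> StoichiometricMatrix:
    """Build M.  In ``split-unidirectional`` mode every reversible reaction
    contributes two columns (forward and its exact negation); in
    ``free-variable`` mode one column whose flux variable is sign-free."""
    if direction_mode not in ("split-unidirectional", "free-variable"):
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    model.validate()
    row_index = {cid: i for i, cid in enumerate(model.compounds)}
    col_index: dict[str, int] = {}
    entries: dict[tuple[int, int], Fraction] = {}

    def add_column(rid: str, net: Mapping[str, Fraction], sign: int) -> None:
        j = len(col_index)
        col_index[rid] = j
        for cid, v in net.items():
            if v != 0:
                entries[(row_index[cid], j)] = sign * v

    for rxn in model.reactions:
        net = rxn.net()
        add_column(rxn.id, net, 1)
        if rxn.reversible and direction_mode == "split-unidirectional":
            add_column(rxn.id + REVERSE_SUFFIX, net, -1)
    return StoichiometricMatrix(row_index, col_index, entries)


# ---------------------------------------------------------------------------
# Direction splitting / merging
# ---------------------------------------------------------------------------


def split_directions(model: MetabolicModel) -> MetabolicModel:
    """Replace each reversible reaction by a complementary unidirectional pair
    linked through ``pair_id``; unidirectional reactions pass through."""
    out = model.copy()
    new_reactions: list[Reaction] = []
    for rxn in model.reactions:
        if rxn.reversible:
            fwd = replace(rxn, reversible=False, pair_id=rxn.id)
            rev = replace(
                rxn.reversed(rxn.id + REVERSE_SUFFIX),
                reversible=False,
                pair_id=rxn.id,
            )
            new_reactions.extend([fwd, rev])
        else:
            new_reactions.append(rxn)
    out.reactions = new_reactions
    return out


def merge_directions(model: MetabolicModel) -> MetabolicModel:
    """Recombine surviving complementary pairs into reversible reactions.

    If only one half of a pair survives it is kept as a unidirectional
    reaction (with its forward orientation restored when it is the reverse
    half)."""
    out = model.copy()
    by_pair: dict[str, list[Reaction]] = {}
    order: list[Reaction] = []
    for rxn in model.reactions:
        if rxn.pair_id is not None:
            by_pair.setdefault(rxn.pair_id, []).append(rxn)
        order.append(rxn)

    merged: list[Reaction] = []
    done_pairs: set[str] = set()
    for rxn in order:
        if rxn.pair_id is None:
            merged.append(rxn)
            continue
        if rxn.pair_id in done_pairs:
            continue
        done_pairs.add(rxn.pair_id)
        halves = by_pair[rxn.pair_id]
        if len(halves) == 2:
            fwd = next(h for h in halves if not h.id.endswith(REVERSE_SUFFIX))
            rev = next(h for h in halves if h.id.endswith(REVERSE_SUFFIX))
            if (rev.reactants, rev.products) == (fwd.products, fwd.reactants):
                merged.append(replace(fwd, reversible=True, pair_id=None))
            else:
                # Halves were edited asymmetrically; keep both unidirectional.
                merged.append(replace(fwd, pair_id=None))
                merged.append(replace(rev, pair_id=None))
        else:
            merged.append(replace(halves[0], pair_id=None))
    out.reactions = merged
    return out


# ---------------------------------------------------------------------------
# Canonical I/O
# ---------------------------------------------------------------------------


def _frac_to_json(k: Fraction):
    return int(k) if k.denominator == 1 else str(k)


def _formula_to_json(f: Mapping[str, int] | None):
    return dict(sorted(f.items())) if f is not None else None


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "compounds": [
            {
                "id": c.id,
                "formula": _formula_to_json(c.formula),
                "is_class": c.is_class,
                "instances": list(c.instance_ids),
            }
            for c in model.compounds.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": [[c, _frac_to_json(k)] for c, k in r.reactants],
                "products": [[c, _frac_to_json(k)] for c, k in r.products],
                "reversible": r.reversible,
                "transport": r.is_transport,
                "exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
        "transportables": list(model.transportables),
        "biomass": sorted(model.biomass),
        "auxiliaries": sorted(model.auxiliaries),
    }


def _reaction_from_dict(rec: dict) -> Reaction:
    rid = rec.get("id")
    if rid is None:
        raise ParseError(f"reaction record missing id: {rec!r}")
    common = dict(
        reversible=bool(rec.get("reversible", False)),
        is_transport=bool(rec.get("transport", False)),
        is_exchange=bool(rec.get("exchange", False)),
    )
    if "equation" in rec:
        return parse_equation(rid, rec["equation"], **common)
    try:
        reactants = tuple((c, Fraction(k)) for c, k in rec["reactants"])
        products = tuple((c, Fraction(k)) for c, k in rec["products"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed reaction record {rid!r}: {exc}") from exc
    return Reaction(id=rid, reactants=reactants, products=products, **common)


def model_from_dict(data: dict) -> MetabolicModel:
    compounds: dict[str, Compound] = {}
    for rec in data.get("compounds", []):
        cid = rec.get("id")
        if cid is None:
            raise ParseError(f"compound record missing id: {rec!r}")
        if cid in compounds:
            raise ValidationError(f"duplicate compound id {cid!r}")
        formula = rec.get("formula")
        if isinstance(formula, str):
            formula = parse_formula(formula)
        compounds[cid] = Compound(
            id=cid,
            formula=formula,
            is_class=bool(rec.get("is_class", False)),
            instance_ids=tuple(rec.get("instances", ())),
        )
    reactions = [_reaction_from_dict(rec) for rec in data.get("reactions", [])]
    model = MetabolicModel(
        compounds=compounds,
        reactions=reactions,
        transportables=list(data.get("transportables", [])),
        biomass=set(data.get("biomass", [])),
        auxiliaries=set(data.get("auxiliaries", [])),
    )
    model.validate()
    return model


def _model_to_tsv(model: MetabolicModel) -> str:
    lines = ["#type\tid\tfield1\tfield2\tfield3"]
    for c in model.compounds.values():
        formula = format_formula(c.formula) if c.formula else "-"
        kind = "class" if c.is_class else "instance"
        inst = ",".join(c.instance_ids) if c.instance_ids else "-"
        lines.append(f"compound\t{c.id}\t{formula}\t{kind}\t{inst}")
    for r in model.reactions:
        rev = "reversible" if r.reversible else "irreversible"
        flags = []
        if r.is_transport:
            flags.append("transport")
        if r.is_exchange:
            flags.append("exchange")
        lines.append(
            f"reaction\t{r.id}\t{format_equation(r)}\t{rev}\t{','.join(flags) or '-'}"
        )
    for cid in model.transportables:
        lines.append(f"transportable\t{cid}\t-\t-\t-")
    for cid in sorted(model.biomass):
        lines.append(f"biomass\t{cid}\t-\t-\t-")
    for cid in sorted(model.auxiliaries):
        lines.append(f"auxiliary\t{cid}\t-\t-\t-")
    return "\n".join(lines) + "\n"


def _model_from_tsv(text: str) -> MetabolicModel:
    compounds: dict[str, Compound] = {}
    reactions: list[Reaction] = []
    transportables: list[str] = []
    biomass: set[str] = set()
    auxiliaries: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        kind = parts[0]
        try:
            if kind == "compound":
                _, cid, formula_s, class_s, inst_s = parts
                formula = None if formula_s == "-" else parse_formula(formula_s)
                instances = tuple(inst_s.split(",")) if inst_s != "-" else ()
                compounds[cid] = Compound(
                    cid, formula, is_class=class_s == "class", instance_ids=instances
                )
            elif kind == "reaction":
                _, rid, equation, rev_s, flags_s = parts
                flags = set(flags_s.split(",")) if flags_s != "-" else set()
                reactions.append(
                    parse_equation(
                        rid,
                        equation,
                        reversible=rev_s == "reversible",
                        is_transport="transport" in flags,
                        is_exchange="exchange" in flags,
                    )
                )
            elif kind == "transportable":
                transportables.append(parts[1])
            elif kind == "biomass":
                biomass.add(parts[1])
            elif kind == "auxiliary":
                auxiliaries.add(parts[1])
            else:
                raise ParseError(f"unknown record type {kind!r}")
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    model = MetabolicModel(compounds, reactions, transportables, biomass, auxiliaries)
    model.validate()
    return model


def _model_from_sbml(
    path: Path,
    transportables: Sequence[str] = (),
    biomass: Iterable[str] = (),
    auxiliaries: Iterable[str] = (),
) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ParseError(f"SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError("SBML document contains no model")
    compounds: dict[str, Compound] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        compounds[sp.getId()] = Compound(sp.getId())
    reactions: list[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        reactants = tuple(
            (rxn.getReactant(j).getSpecies(), Fraction(rxn.getReactant(j).getStoichiometry()).limit_denominator(10**6))
            for j in range(rxn.getNumReactants())
        )
        products = tuple(
            (rxn.getProduct(j).getSpecies(), Fraction(rxn.getProduct(j).getStoichiometry()).limit_denominator(10**6))
            for j in range(rxn.getNumProducts())
        )
        reactions.append(
            Reaction(
                id=rxn.getId(),
                reactants=reactants,
                products=products,
                reversible=rxn.getReversible(),
                is_exchange=not reactants or not products,
            )
        )
    model = MetabolicModel(
        compounds,
        reactions,
        list(transportables),
        set(biomass),
        set(auxiliaries),
    )
    model.validate()
    return model


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".json",):
        return "canonical-json"
    if suffix in (".tsv", ".txt"):
        return "canonical-tsv"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ParseError(f"cannot guess model format from suffix {suffix!r}")


def load_model(path, format: str | None = None, **sbml_kwargs) -> MetabolicModel:
    """Load and validate a model from canonical JSON, canonical TSV, or SBML."""
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "canonical-json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        return model_from_dict(data)
    if fmt == "canonical-tsv":
        return _model_from_tsv(path.read_text())
    if fmt == "sbml":
        return _model_from_sbml(path, **sbml_kwargs)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt == "canonical-json":
        path.write_text(json.dumps(model_to_dict(model), indent=1) + "\n")
    elif fmt == "canonical-tsv":
        path.write_text(_model_to_tsv(model))
    else:
        raise ValueError(f"cannot write format {fmt!r}")
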