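"""Nutrient equivalence classes and lossless compression of set collections.

Two compounds c1, c2 are equivalent with respect to a collection 𝒩 of nutrient
sets when each can always substitute for the other: for every N ∈ 𝒩 containing
c1, (N∖{c1})∪{c2} ∈ 𝒩, and symmetrically.  Over a complete collection of
minimal nutrient sets this is an equivalence relation; the partition it
induces supports a *canonical form* (rewrite every compound to its class
representative) whose deduplicated image — the reduced collection — together
with the classes encodes the original collection with zero information loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from .model import MetabolicModel

__all__ = [
    "EquivalenceClassification",
    "ReducedCollection",
    "are_equivalent",
    "compute_classes",
    "reduce_collection",
    "expand",
]

Collection = list[frozenset[str]]


def _normalize(collection: Iterable[Iterable[str]]) -> Collection:
    return [frozenset(n) for n in collection]


def are_equivalent(c1: str, c2: str, collection: Iterable[Iterable[str]]) -> bool:
    """Definition check: c1 and c2 are mutually substitutable across the
    whole collection."""
    if c1 == c2:
        return True
    sets = set(_normalize(collection))
    for a, b in ((c1, c2), (c2, c1)):
        for n in sets:
            if a in n and (n - {a}) | {b} not in sets:
                return False
    return True


@dataclass
class EquivalenceClassification:
    classes: list[frozenset[str]]
    representatives: list[str]
    element_annotation: list[str | None] = field(default_factory=list)

    def representative_of(self, compound: str) -> str:
        for cls, rep in zip(self.classes, self.representatives):
            if compound in cls:
                return rep
        raise KeyError(compound)

    def class_of(self, compound: str) -> frozenset[str]:
        for cls in self.classes:
            if compound in cls:
                return cls
        raise KeyError(compound)


_ANNOTATED_ELEMENTS = ("C", "N", "P", "S")


def _annotate(cls: frozenset[str], model: MetabolicModel | None) -> str | None:
    if model is None:
        return None
    elements: set[str] = set()
    for cid in cls:
        comp = model.compounds.get(cid)
        if comp is None or comp.formula is None:
            return None
        elements.update(e for e in comp.formula if e in _ANNOTATED_ELEMENTS)
    return ",".join(e for e in _ANNOTATED_ELEMENTS if e in elements) or None


def compute_classes(
    collection: Iterable[Iterable[str]],
    model: MetabolicModel | None = None,
    preferred_representatives: Sequence[str] = (),
) -> EquivalenceClassification:
    """Partition the compounds occurring in the collection under mutual
    substitutability.

    Representatives default to the lexicographically smallest member;
    ``preferred_representatives`` overrides (first listed member wins).
    The relation is provably transitive on collections of minimal sets, but
    transitivity is re-verified and a violation raises (it would indicate a
    corrupted collection or an implementation bug).
    """
    sets = _normalize(collection)
    if len(set(sets)) != len(sets):
        raise ValueError("collection contains duplicate sets")
    occurring = sorted({c for n in sets for c in n})
    if not occurring:
        return EquivalenceClassification([], [], [])

    parent: dict[str, str] = {c: c for c in occurring}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pair_equivalent: dict[tuple[str, str], bool] = {}
    for i, c1 in enumerate(occurring):
        for c2 in occurring[i + 1 :]:
            eq = are_equivalent(c1, c2, sets)
            pair_equivalent[(c1, c2)] = eq
            if eq:
                parent[find(c1)] = find(c2)

    groups: dict[str, set[str]] = {}
    for c in occurring:
        groups.setdefault(find(c), set()).add(c)
    classes = sorted((frozenset(g) for g in groups.values()), key=min)

    # Transitivity audit: every intra-class pair must itself be equivalent.
    for cls in classes:
        members = sorted(cls)
        for i, c1 in enumerate(members):
            for c2 in members[i + 1 :]:
                if not pair_equivalent[(c1, c2)]:
                    raise ValueError(
                        f"substitutability is not transitive on this collection: "
                        f"{c1!r} and {c2!r} fall in one class but are not equivalent"
                    )

    prefs = {c: i for i, c in enumerate(preferred_representatives)}
    representatives = []
    for cls in classes:
        preferred = [c for c in cls if c in prefs]
        if preferred:
            representatives.append(min(preferred, key=prefs.__getitem__))
        else:
            representatives.append(min(cls))
    annotations = [_annotate(cls, model) for cls in classes]
    return EquivalenceClassification(classes, representatives, annotations)


@dataclass
class ReducedCollection:
    canonical_sets: Collection
    classification: EquivalenceClassification


def reduce_collection(
    collection: Iterable[Iterable[str]],
    classification: EquivalenceClassification,
) -> ReducedCollection:
    """Rewrite every set to its canonical form and deduplicate.  The number of
    canonical sets does not depend on which representatives were chosen."""
    canonical: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for n in _normalize(collection):
        canon = frozenset(classification.representative_of(c) for c in n)
        if canon not in seen:
            seen.add(canon)
            canonical.append(canon)
    return ReducedCollection(canonical, classification)


def expand(reduced: ReducedCollection) -> Collection:
    """Regenerate the full collection: substitute every class member for each
    representative, in all combinations."""
    out: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for canon in reduced.canonical_sets:
        members = sorted(canon)
        choices = [sorted(reduced.classification.class_of(c)) for c in members]
        for combo in product(*choices):
            n = frozenset(combo)
            if n not in seen:
                seen.add(n)
                out.append(n)
    return out


def classification_to_table(
    classification: EquivalenceClassification,
) -> list[dict[str, object]]:
    """Rows mirroring a class listing: id, element annotation, members."""
    return [
        {
            "class": i + 1,
            "elements": classification.element_annotation[i],
            "representative": classification.representatives[i],
            "compounds": sorted(cls),
        }
        for i, cls in enumerate(classification.classes)
    ]
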