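"""Scoring predicted minimal nutrient sets against growth experiments.

Phenotype-microarray style data assigns each tested well a nutrient set (one
source per essential element) and a growth call.  A prediction *matches* a
well when some predicted minimal set equals the well's set or is a proper
subset of it — subset matches are counted because a single predicted compound
may source several elements at once, making one of the well's fixed
supplements redundant.  Wells with growth and a match score a true positive,
growth without a match a false negative, no-growth without a match a true
negative, no-growth with a match a false positive; low-growth wells are
excluded as inconclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PMRecord",
    "ConfusionReport",
    "GROWTH_CALLS",
    "matches",
    "score",
    "read_pm_table",
    "write_report",
]

GROWTH_CALLS = ("growth", "no-growth", "low-growth")


@dataclass(frozen=True)
class PMRecord:
    well_id: str
    nutrient_set: frozenset[str]
    growth_call: str

    def __post_init__(self) -> None:
        if not self.nutrient_set:
            raise ValueError(f"well {self.well_id!r}: empty nutrient set")
        if self.growth_call not in GROWTH_CALLS:
            raise ValueError(
                f"well {self.well_id!r}: unknown growth call {self.growth_call!r}"
            )


@dataclass
class ConfusionReport:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0
    excluded_low_growth: int = 0
    verdicts: list[tuple[str, str]] = field(default_factory=list)

    @property
    def accuracy(self) -> Fraction | None:
        total = self.TP + self.TN + self.FP + self.FN
        if total == 0:
            return None
        return Fraction(self.TP + self.TN, total)

    @property
    def accuracy_percent(self) -> float | None:
        acc = self.accuracy
        return None if acc is None else float(acc) * 100.0


def matches(
    pm_set: Iterable[str], predicted_collection: Iterable[Iterable[str]]
) -> bool:
    """True iff some predicted set equals pm_set or is a proper subset of it."""
    pm = frozenset(pm_set)
    return any(frozenset(p) <= pm for p in predicted_collection)


def score(
    pm_records: Sequence[PMRecord],
    predicted_collection: Iterable[Iterable[str]],
) -> ConfusionReport:
    predicted = [frozenset(p) for p in predicted_collection]
    report = ConfusionReport()
    for record in pm_records:
        if record.growth_call == "low-growth":
            report.excluded_low_growth += 1
            report.verdicts.append((record.well_id, "excluded"))
            continue
        matched = matches(record.nutrient_set, predicted)
        if record.growth_call == "growth":
            verdict = "TP" if matched else "FN"
        else:
            verdict = "FP" if matched else "TN"
        setattr(report, verdict, getattr(report, verdict) + 1)
        report.verdicts.append((record.well_id, verdict))
    return report


def read_pm_table(path, synonyms: Mapping[str, str] | None = None) -> list[PMRecord]:
    """Read a PM table: TSV with columns well_id, compounds (comma-joined),
    growth_call.  ``synonyms`` maps assay compound names to model compound ids
    (explicit mapping only — silent fuzzy matching would corrupt the counts)."""
    synonyms = synonyms or {}
    records = []
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ValueError(f"PM table row has {len(row)} fields, expected 3: {row!r}")
            well_id, compounds_s, call = row
            compounds = frozenset(
                synonyms.get(c.strip(), c.strip())
                for c in compounds_s.split(",")
                if c.strip()
            )
            records.append(PMRecord(well_id, compounds, call.strip()))
    return records


def read_synonyms(path) -> dict[str, str]:
    """Two-column TSV: assay name → model compound id."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, cid = line.split("\t")
        mapping[name.strip()] = cid.strip()
    return mapping


def write_report(report: ConfusionReport, path) -> None:
    lines = ["#well_id\tverdict"]
    lines += [f"{well}\t{verdict}" for well, verdict in report.verdicts]
    lines.append(f"#TP\t{report.TP}")
    lines.append(f"#TN\t{report.TN}")
    lines.append(f"#FP\t{report.FP}")
    lines.append(f"#FN\t{report.FN}")
    lines.append(f"#excluded_low_growth\t{report.excluded_low_growth}")
    acc = report.accuracy_percent
    lines.append(f"#accuracy_percent\t{'NA' if acc is None else f'{acc:.1f}'}")
    Path(path).write_text("\n".join(lines) + "\n")
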