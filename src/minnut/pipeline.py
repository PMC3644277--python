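"""End-to-end pipeline: instantiate → simplify → enumerate → classes → reduce
→ evaluate, with a reproducibility manifest."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__
from .constraints import NutsetOracle
from .enumeration import enumerate_minimal_nutrient_sets
from .equivalence import classification_to_table, compute_classes, reduce_collection
from .evaluation import read_pm_table, read_synonyms, score, write_report
from .instantiation import instantiate_generic_reactions
from .model import load_model, model_to_dict
from .simplification import simplify

__all__ = ["read_config", "run_pipeline"]


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` file; '#' starts a comment line."""
    config: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config


def _model_hash(model) -> str:
    blob = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: dict[str, str] | str | Path) -> dict[str, Path]:
    """Run the full prediction pipeline and write the artifact bundle.

    Required config keys: ``model`` (path), ``outdir``.  Optional: ``mode``
    (default machinery), ``limit``, ``pm_table``, ``synonyms``,
    ``skip_simplify``.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    if "model" not in config:
        raise ValueError("config error: missing required key 'model'")
    if "outdir" not in config:
        raise ValueError("config error: missing required key 'outdir'")
    mode = config.get("mode", "machinery")
    limit = int(config["limit"]) if "limit" in config else None
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    model = load_model(config["model"])
    stage_counts: dict[str, int] = {
        "input_compounds": len(model.compounds),
        "input_reactions": len(model.reactions),
    }

    has_classes = any(c.is_class for c in model.compounds.values())
    if has_classes:
        model, reports = instantiate_generic_reactions(model)
        stage_counts["instantiated_reactions"] = sum(
            len(r.accepted) for r in reports
        )

    if config.get("skip_simplify", "").lower() not in ("1", "true", "yes"):
        model, trace = simplify(model)
        stage_counts["simplified_compounds"] = len(model.compounds)
        stage_counts["simplified_reactions"] = len(model.reactions)

    oracle = NutsetOracle(model, mode)
    result = enumerate_minimal_nutrient_sets(model, mode, limit=limit, oracle=oracle)
    sets = result.as_sorted_lists()
    stage_counts["minimal_nutrient_sets"] = len(sets)
    stage_counts["nutset_oracle_calls"] = oracle.n_calls
    stage_counts["nutset_solver_calls"] = oracle.n_solver_calls

    artifacts: dict[str, Path] = {}
    sets_path = outdir / "sets.json"
    sets_path.write_text(
        json.dumps(
            {
                "mode": mode,
                "transportable_order": list(model.transportables),
                "complete": result.complete,
                "sets": sets,
            },
            indent=1,
        )
        + "\n"
    )
    artifacts["sets"] = sets_path

    collection = [frozenset(s) for s in sets]
    classification = compute_classes(collection, model=model)
    classes_path = outdir / "classes.json"
    classes_path.write_text(
        json.dumps(classification_to_table(classification), indent=1) + "\n"
    )
    artifacts["classes"] = classes_path
    stage_counts["equivalence_classes"] = len(classification.classes)

    reduced = reduce_collection(collection, classification)
    reduced_path = outdir / "reduced.json"
    reduced_path.write_text(
        json.dumps([sorted(s) for s in reduced.canonical_sets], indent=1) + "\n"
    )
    artifacts["reduced"] = reduced_path
    stage_counts["reduced_sets"] = len(reduced.canonical_sets)

    if "pm_table" in config:
        synonyms = read_synonyms(config["synonyms"]) if "synonyms" in config else None
        records = read_pm_table(config["pm_table"], synonyms)
        report = score(records, collection)
        report_path = outdir / "report.tsv"
        write_report(report, report_path)
        artifacts["report"] = report_path
        stage_counts["pm_records"] = len(records)

    manifest = {
        "tool": "minnut",
        "version": __version__,
        "model_sha256": _model_hash(model),
        "mode": mode,
        "transportable_order": list(model.transportables),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "stage_counts": stage_counts,
        "complete": result.complete,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    artifacts["manifest"] = manifest_path
    return artifacts
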