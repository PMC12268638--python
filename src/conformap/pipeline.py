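"""Config-driven orchestration of the comparison pipeline.

A single YAML file names the input coordinate files, residue-range
selection presets, an optional PCA ensemble, pairwise conformational
comparisons and ion scans; ``run_pipeline`` executes every requested
task, records per-task errors without aborting the rest, and writes
CSV/JSON outputs that are byte-identical across reruns of the same
config (timestamps live only in the report's provenance block).

Accessions are resolved to local file paths only — the pipeline never
downloads; fetching coordinate files is the user's explicit step.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import interhelix_angle_change, interlobe_rotation, pair_distance
from .io import read_structure
from .ions import scan_solvent_sites
from .pca import (align_ensemble, build_ensemble_core, fit_pca,
                  projections_frame, significant_modes)
from .structure import Selection, Structure
from .superpose import match_core_by_alignment, match_core_by_number, superpose

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline",
           "DEFAULT_SELECTIONS"]

#: residue-range presets for the GRK5 comparisons this pipeline was built
#: around: kinase small lobe, large lobe, kinase domain, the interface
#: helices of the RH domain (alpha4) and kinase C-terminal region (alphaJ)
#: — configured as the helical windows around Glu91/Val92 and
#: Lys454/Arg455 — and the glycine-rich P-loop.
DEFAULT_SELECTIONS: dict[str, str] = {
    "grk5_small_lobe": "1-32,180-270,490-510",
    "grk5_large_lobe": "271-450",
    "grk5_kinase_domain": "180-510",
    "alpha4": "84-97",
    "alphaJ": "448-460",
    "p_loop": "190-200",
}


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid pipeline config:\n  - " + "\n  - ".join(self.errors))


@dataclass
class PipelineConfig:
    structures: list[dict]  # {id, path, chain}
    selections: dict[str, Selection]
    ensemble: dict | None
    comparisons: list[dict]
    ion_scan: list[str]
    output_dir: Path
    seed: int = 0
    warnings: list[str] = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    def structure_ids(self) -> list[str]:
        return [s["id"] for s in self.structures]


def _normalize_selection(name: str, value: str, warnings: list[str]) -> Selection:
    sel = Selection.parse(value)
    raw_tokens = value.split(":")[-1].split(",")
    if len(sel.ranges) < len([t for t in raw_tokens if t.strip()]):
        warnings.append(f"selection {name!r}: overlapping/adjacent intervals merged")
    return sel


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> PipelineConfig:
    """Parse, default-fill and cross-check a pipeline config.

    All problems are aggregated into one :class:`ConfigError` so a user
    can fix the file in a single pass.  Returns the normalized config;
    non-fatal issues (e.g. merged overlapping intervals) are collected
    as warnings.
    """
    if data is None:
        if path is None:
            raise ValueError("either path or data is required")
        with open(path) as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(["config root must be a mapping"])

    errors: list[str] = []
    warnings: list[str] = []

    structures = data.get("structures") or []
    ids = [s.get("id") for s in structures]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        errors.append(f"duplicate structure ids: {dupes}")
    for s in structures:
        if not s.get("id"):
            errors.append(f"structure entry missing id: {s}")
        if not s.get("path"):
            errors.append(f"structure {s.get('id')!r} missing path "
                          "(accessions must be resolved to local files)")
        s.setdefault("chain", None)

    selections: dict[str, Selection] = {}
    merged_sel = dict(DEFAULT_SELECTIONS)
    merged_sel.update(data.get("selections") or {})
    for name, value in merged_sel.items():
        try:
            selections[name] = _normalize_selection(name, str(value), warnings)
        except ValueError as exc:
            errors.append(f"selection {name!r}: {exc}")

    known = set(i for i in ids if i)

    ensemble = data.get("ensemble")
    if ensemble is not None:
        ensemble = dict(ensemble)
        ensemble.setdefault("correspondence", "by_number")
        ensemble.setdefault("selection", "grk5_kinase_domain")
        members = ensemble.get("members") or []
        ensemble.setdefault("reference", members[0] if members else None)
        for m in members:
            if m not in known:
                errors.append(f"ensemble member {m!r} is not a defined structure id")
        if ensemble["reference"] not in members:
            errors.append(f"ensemble reference {ensemble['reference']!r} not among members")
        if ensemble["selection"] not in selections:
            errors.append(f"ensemble selection {ensemble['selection']!r} undefined")
        if ensemble["correspondence"] not in ("by_number", "by_alignment"):
            errors.append(f"unknown correspondence {ensemble['correspondence']!r}")

    comparisons = []
    for i, comp in enumerate(data.get("comparisons") or []):
        comp = dict(comp)
        pair = comp.get("pair") or []
        if len(pair) != 2:
            errors.append(f"comparison #{i}: 'pair' must list exactly two structure ids")
        else:
            for sid in pair:
                if sid not in known:
                    errors.append(f"comparison #{i}: unknown structure id {sid!r}")
        comp.setdefault("align", "grk5_small_lobe")
        comp.setdefault("moving", "grk5_large_lobe")
        comp.setdefault("rmsd_selection", None)
        comp.setdefault("correspondence", "by_number")
        for key in ("align", "moving"):
            if comp[key] not in selections:
                errors.append(f"comparison #{i}: selection {comp[key]!r} undefined")
        if comp.get("rmsd_selection") and comp["rmsd_selection"] not in selections:
            errors.append(f"comparison #{i}: selection {comp['rmsd_selection']!r} undefined")
        for key in ("helix_1", "helix_2"):
            if comp.get(key) and comp[key] not in selections:
                errors.append(f"comparison #{i}: helix selection {comp[key]!r} undefined")
        comparisons.append(comp)

    ion_scan = list(data.get("ion_scan") or [])
    for sid in ion_scan:
        if sid not in known:
            errors.append(f"ion_scan: unknown structure id {sid!r}")

    if errors:
        raise ConfigError(errors)

    return PipelineConfig(
        structures=structures,
        selections=selections,
        ensemble=ensemble,
        comparisons=comparisons,
        ion_scan=ion_scan,
        output_dir=Path(data.get("output_dir", "conformap_out")),
        seed=int(data.get("seed", 0)),
        warnings=warnings,
        raw=data,
    )


def _selection_ranges(sel: Selection) -> tuple[int, int]:
    lo = min(r[0] for r in sel.ranges)
    hi = max(r[1] for r in sel.ranges)
    return lo, hi


def _run_comparison(comp: dict, by_id: dict[str, Structure],
                    selections: dict[str, Selection]) -> dict:
    id_a, id_b = comp["pair"]
    a, b = by_id[id_a], by_id[id_b]
    align_sel = selections[comp["align"]]
    moving_sel = selections[comp["moving"]]
    correspondence = comp["correspondence"]

    rmsd_sel = selections[comp["rmsd_selection"]] if comp.get("rmsd_selection") \
        else Selection()
    if correspondence == "by_number":
        core = match_core_by_number(a, b, rmsd_sel)
    else:
        core = match_core_by_alignment(a, b, rmsd_sel)
    fit, _ = superpose(a, b, core)

    rot = interlobe_rotation(a, b, align_sel, moving_sel, correspondence)
    record = {
        "pair": [id_a, id_b],
        "rmsd_global": round(fit.rmsd, 4),
        "n_atoms": fit.n_atoms,
        "interlobe_angle": round(rot.angle, 3),
        "axis": [round(x, 4) for x in rot.axis.tolist()],
        "n_align": rot.n_align,
        "n_moving": rot.n_moving,
    }
    if comp.get("helix_1") and comp.get("helix_2"):
        r1 = _selection_ranges(selections[comp["helix_1"]])
        r2 = _selection_ranges(selections[comp["helix_2"]])
        record["interhelix_delta"] = round(interhelix_angle_change(a, b, r1, r2), 3)
    deltas = {}
    for entry in comp.get("pairs") or []:
        (ch1, rn1), (ch2, rn2) = entry
        da = pair_distance(a, (ch1, int(rn1)), (ch2, int(rn2))).distance
        db = pair_distance(b, (ch1, int(rn1)), (ch2, int(rn2))).distance
        deltas[f"{ch1}{rn1}-{ch2}{rn2}"] = round(da - db, 3)
    if deltas:
        record["pair_distance_deltas"] = deltas
    return record


def run_pipeline(config: PipelineConfig,
                 structures: list[Structure] | None = None) -> dict:
    """Execute every configured task and write CSV/JSON outputs.

    ``structures`` may inject pre-loaded structures (ids must match the
    config); otherwise files are read from the configured paths.  Returns
    the run report (also written as ``report.json``).  Per-task failures
    are recorded in the report; remaining tasks still run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if structures is None:
        structures = []
        for entry in config.structures:
            s = read_structure(entry["path"])
            s.identifier = entry["id"]
            structures.append(s)
    by_id = {s.identifier: s for s in structures}
    missing = [i for i in config.structure_ids() if i not in by_id]
    if missing:
        raise KeyError(f"structures not provided: {missing}")

    config_text = yaml.safe_dump(config.raw, sort_keys=True)
    (out / "config_normalized.yaml").write_text(config_text)
    report: dict = {
        "provenance": {
            "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
            "conformap_version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        "warnings": list(config.warnings),
        "tasks": [],
    }

    if config.ensemble:
        task = {"task": "ensemble_pca"}
        try:
            members = [by_id[m] for m in config.ensemble["members"]]
            sel = config.selections[config.ensemble["selection"]]
            core = build_ensemble_core(members, sel,
                                       mode=config.ensemble["correspondence"],
                                       reference_id=config.ensemble["reference"])
            matrix, converged = align_ensemble(core, members)
            model = fit_pca(matrix)
            frame = projections_frame(model, matrix, list(core.members))
            frame.to_csv(out / "projections.csv", index=False, float_format="%.4f")
            pd.DataFrame({
                "component": np.arange(1, len(model.variances) + 1),
                "variance": model.variances,
            }).to_csv(out / "variances.csv", index=False, float_format="%.6f")
            (out / "pca_model.json").write_text(model.to_json())
            task.update({
                "status": "ok", "core_size": core.size,
                "n_members": model.n_members, "converged": converged,
                "significant_modes": significant_modes(model.variances),
                "top_variances": [round(v, 4) for v in model.variances[:5].tolist()],
            })
        except Exception as exc:  # noqa: BLE001 - per-task error capture
            task.update({"status": "error", "error": str(exc)})
        report["tasks"].append(task)

    comparison_rows = []
    for comp in config.comparisons:
        task = {"task": "comparison", "pair": comp.get("pair")}
        try:
            record = _run_comparison(comp, by_id, config.selections)
            task.update({"status": "ok", **record})
            comparison_rows.append(record)
        except Exception as exc:  # noqa: BLE001
            task.update({"status": "error", "error": str(exc)})
        report["tasks"].append(task)
    if comparison_rows:
        flat = [
            {k: (json.dumps(v) if isinstance(v, (list, dict)) else v)
             for k, v in r.items()}
            for r in comparison_rows
        ]
        pd.DataFrame(flat).to_csv(out / "comparisons.csv", index=False)

    for sid in config.ion_scan:
        task = {"task": "ion_scan", "structure": sid}
        try:
            results = scan_solvent_sites(by_id[sid])
            rows = [{"site": site, **cls.to_dict()} for site, cls in results]
            pd.DataFrame(rows).to_csv(out / f"ion_scan_{sid}.csv", index=False)
            calls = [cls.call for _, cls in results]
            task.update({
                "status": "ok", "n_sites": len(results),
                "calls": {c: calls.count(c) for c in sorted(set(calls))},
            })
        except Exception as exc:  # noqa: BLE001
            task.update({"status": "error", "error": str(exc)})
        report["tasks"].append(task)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
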