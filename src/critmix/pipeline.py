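"""End-to-end pipeline: simulate/load -> merge -> fit -> relabel -> assign -> report.

A single JSON or YAML config drives the whole analysis.  Every artifact is
written under the output directory together with a manifest recording the
seed and a hash of the resolved configuration, so re-running an identical
config reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .consistency import (assign_sessions, block_prevalence_summary,
                          build_consistency_report, build_group_change_report)
from .data import ResponseTable, read_responses, write_matrix
from .results import CriterionMixtureModel
from .simulate import SimulationConfig, generate_study

log = logging.getLogger("critmix")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``simulate`` holds per-category simulation settings, or
    ``new_data`` / ``archival_data`` point at long-format response CSVs.
    """

    output_dir: str = "critmix_output"
    seed: int = 0
    block_map: dict = field(default_factory=lambda: {"synthetic": "nominal"})
    n_groups: int = 2
    n_chains: int = 3
    n_iter: int = 10_000
    n_burnin: int = 4_000
    simulate: dict | None = None          # category -> SimulationConfig overrides
    new_data: str | None = None
    archival_data: str | None = None
    include_unknown_pairs: bool = True
    extra: dict = field(default_factory=dict)  # unknown keys, kept for forward compat

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("extra")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)} - {"extra"}


def parse_config(doc: dict) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a config mapping; returns (config, errors) with *all* violations."""
    errors: list[str] = []
    if not isinstance(doc, dict):
        return None, ["config document must be a mapping"]
    unknown = set(doc) - _KNOWN_KEYS
    kwargs = {k: v for k, v in doc.items() if k in _KNOWN_KEYS}
    cfg = PipelineConfig(**kwargs)
    cfg.extra = {k: doc[k] for k in unknown}
    for key in sorted(unknown):
        log.warning("ignoring unknown config key %r", key)

    for name in ("n_groups", "n_chains", "n_iter", "n_burnin"):
        if not isinstance(getattr(cfg, name), int) or getattr(cfg, name) <= 0:
            errors.append(f"{name} must be a positive integer")
    if isinstance(cfg.n_iter, int) and isinstance(cfg.n_burnin, int) \
            and cfg.n_iter <= cfg.n_burnin:
        errors.append("n_iter must exceed n_burnin")
    if not isinstance(cfg.block_map, dict) or not cfg.block_map:
        errors.append("block_map must be a non-empty mapping category -> block")
    if cfg.simulate is None and cfg.new_data is None:
        errors.append("either simulate or new_data must be given")
    if cfg.simulate is not None:
        if not isinstance(cfg.simulate, dict):
            errors.append("simulate must map category ids to simulation settings")
        else:
            for cat, overrides in cfg.simulate.items():
                try:
                    sim = _category_sim_config(cfg, cat, overrides or {})
                except TypeError as exc:
                    errors.append(f"simulate[{cat!r}]: {exc}")
                    continue
                errors.extend(f"simulate[{cat!r}]: {e}" for e in sim.validate())
    if cfg.new_data is not None and not Path(cfg.new_data).exists():
        errors.append(f"new_data path not found: {cfg.new_data}")
    if cfg.archival_data is not None and not Path(cfg.archival_data).exists():
        errors.append(f"archival_data path not found: {cfg.archival_data}")
    return (None if errors else cfg), errors


def validate_config(path) -> tuple[PipelineConfig | None, list[str]]:
    """Load and validate a JSON/YAML pipeline config file."""
    text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)  # YAML is a superset of JSON
    return parse_config(doc)


def _category_sim_config(cfg: PipelineConfig, category: str,
                         overrides: dict) -> SimulationConfig:
    base = dict(category_id=category, seed=cfg.seed + _stable_offset(category))
    base.update(overrides)
    return SimulationConfig(**base)


def _stable_offset(category: str) -> int:
    return int.from_bytes(hashlib.sha256(category.encode()).digest()[:3], "big")


def run_pipeline(cfg: PipelineConfig, progress: bool = False) -> dict:
    """Execute every stage per category; returns the artifact manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                      "categories": {}, "status": "ok"}
    try:
        new_tables, archival_tables, truths = _acquire_data(cfg, out)
        new_all = ResponseTable.concat(list(new_tables.values()))
        consistency = build_consistency_report(
            new_all, cfg.block_map, include_unknown_pairs=cfg.include_unknown_pairs)

        session_pairs = {}
        for cat in sorted(new_tables):
            log.info("category %s: merge + fit", cat)
            model = CriterionMixtureModel.from_tables(
                new_tables[cat], archival_tables.get(cat), cat, cfg.n_groups)
            matrix_path = out / f"merged_{cat}.csv"
            write_matrix(model.matrix, matrix_path)
            res = model.fit(n_chains=cfg.n_chains, n_iter=cfg.n_iter,
                            n_burnin=cfg.n_burnin, seed=cfg.seed,
                            progress=progress).relabel()
            samples_dir = out / f"samples_{cat}"
            res.save(samples_dir)
            diag = res.diagnostics()
            n_bad = int((diag["rhat"] > 1.1).sum())
            if n_bad:
                log.warning("category %s: %d parameter(s) with R-hat > 1.1", cat, n_bad)
            assignment = res.assignment_frame()
            if assignment["tie"].any():
                log.warning("category %s: assignment ties present", cat)
            assignment_path = out / f"assignments_{cat}.csv"
            assignment.to_csv(assignment_path, index=False)
            pairs = assign_sessions(res.assign_groups(), model.matrix.entry_index)
            session_pairs[cat] = pairs
            manifest["categories"][cat] = {
                "matrix": matrix_path.name, "samples": samples_dir.name,
                "assignments": assignment_path.name,
                "n_entries": model.matrix.n_entries,
                "n_items": model.matrix.n_items,
                "max_rhat": float(np.nanmax(diag["rhat"])),
            }

        changes = build_group_change_report(session_pairs, consistency)
        report = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "overall_inconsistency_proportion": consistency.overall_proportion,
            "block_inconsistency": block_prevalence_summary(
                consistency, cfg.block_map).to_dict(orient="records"),
            "block_group_change": block_prevalence_summary(
                changes, cfg.block_map).to_dict(orient="records"),
            "per_category_changes": changes.per_category.to_dict(orient="records"),
            "change_count_distribution": changes.change_count_distribution,
            "zero_inconsistency_items": [
                list(t) for t in consistency.zero_inconsistency_items],
        }
        if truths:
            report["true_switchers"] = {
                cat: sorted(t.switcher_ids) for cat, t in truths.items()}
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        consistency.per_participant.to_csv(out / "per_participant.csv", index=False)
        consistency.per_item.to_csv(out / "per_item.csv", index=False)
        manifest["report"] = "report.json"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _acquire_data(cfg: PipelineConfig, out: Path):
    new_tables: dict[str, ResponseTable] = {}
    archival_tables: dict[str, ResponseTable] = {}
    truths = {}
    if cfg.simulate is not None:
        for cat, overrides in cfg.simulate.items():
            sim = _category_sim_config(cfg, cat, overrides or {})
            study = generate_study(sim)
            new_tables[cat] = study.truth.table
            if sim.n_archival:
                archival_tables[cat] = study.archival
            truths[cat] = study.truth
            study.truth.table.to_csv(out / f"responses_{cat}.csv")
            truth_doc = {
                "switcher_ids": sorted(study.truth.switcher_ids),
                "z_session1": study.truth.params_session1.z.tolist(),
                "z_session2": study.truth.params_session2.z.tolist(),
                "beta": study.truth.params_session1.beta.tolist(),
                "mu": study.truth.params_session1.mu.tolist(),
                "alpha": study.truth.params_session1.alpha.tolist(),
                "participant_ids": study.truth.participant_ids,
            }
            (out / f"truth_{cat}.json").write_text(
                json.dumps(truth_doc, indent=2, sort_keys=True))
    else:
        table = read_responses(cfg.new_data)
        archival = (read_responses(cfg.archival_data, provenance="archival")
                    if cfg.archival_data else None)
        for cat in table.categories:
            new_tables[cat] = table.subset(cat)
            if archival is not None and cat in archival.categories:
                archival_tables[cat] = archival.subset(cat)
    return new_tables, archival_tables, truths
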