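"""Query orchestration and result serialization.

``run_query`` drives the full stack for one or more targets — enumeration,
optional verification, optional FBA yield ranking — and produces a plain
nested-dict report bundle with fully deterministic ordering, so the JSON
export is byte-identical for identical config and seed.  Exports are JSON
(machine-readable), a tab-separated pathway summary, and one DOT dependency
graph per target.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import flux_analysis as fa
from .enumeration import enumerate_pathways
from .milp_core import variable_is_forward, variable_reaction_id
from .netdb import (
    ChassisScope,
    MetabolicDatabase,
    load_database,
    load_scope,
    scope_from_sbml,
)
from .pathway_graph import build_dependency_graph, to_dot, verify_pathway

__all__ = ["QueryConfig", "run_query", "run_query_objects", "export_results"]

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_NO_PATHWAY = 3


@dataclass
class QueryConfig:
    db_path: str
    targets: list[str]
    scope_path: str | None = None
    sbml_path: str | None = None
    k: int = 0
    max_len: int = 10
    run_fba: bool = False
    carbon_source: str | None = None  # compound id of the carbon exchange
    basis_uptake: float = 10.0
    biomass_fraction: float = 0.0
    verify: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.k < 0 or self.max_len < 1:
            raise ValueError("require k >= 0 and max_len >= 1")
        if not (self.scope_path or self.sbml_path):
            raise ValueError("one of scope_path or sbml_path is required")


def _pathway_record(p, db: MetabolicDatabase) -> dict:
    steps = []
    for v in p.reactions:
        r = db.reactions[variable_reaction_id(v)]
        steps.append(
            {
                "variable": v,
                "reaction": r.id,
                "direction": "forward" if variable_is_forward(v) else "reverse",
                "equation": r.equation(),
                "enzyme": r.enzyme,
                "type": r.rxn_type.value,
            }
        )
    return {"length": p.length, "level": p.level, "steps": steps}


def run_query_objects(
    db: MetabolicDatabase,
    scope: ChassisScope,
    cfg: QueryConfig,
) -> dict:
    """Run enumeration (and optional verify/FBA) for every config target."""
    bundle: dict = {
        "config": {
            "targets": sorted(cfg.targets),
            "k": cfg.k,
            "max_len": cfg.max_len,
            "run_fba": cfg.run_fba,
            "verify": cfg.verify,
            "seed": cfg.seed,
            "organism": scope.organism,
        },
        "targets": {},
        "failures": {},
    }
    for target in sorted(cfg.targets):
        if target not in db.compounds:
            bundle["failures"][target] = "unknown target compound"
            continue
        state = enumerate_pathways(db, scope, target, k=cfg.k, max_len=cfg.max_len)
        levels = []
        for level, pathways in enumerate(state.found):
            recs = [
                _pathway_record(p, db)
                for p in sorted(pathways, key=lambda p: (p.length, p.reactions))
            ]
            levels.append(
                {
                    "level": level,
                    "objective": state.level_objectives[level],
                    "pathways": recs,
                }
            )
        entry: dict = {
            "status": "ok" if state.all_pathways else "no-pathway",
            "beta_star": state.beta_star,
            "total_pathways": len(state.all_pathways),
            "levels": levels,
        }
        if cfg.verify and state.all_pathways:
            entry["verified"] = all(
                verify_pathway(p, db, scope, target) for p in state.all_pathways
            )
        if cfg.run_fba and state.all_pathways and state.beta_star:
            chassis = fa.chassis_for_scope(db, scope, uptake=cfg.basis_uptake)
            carbon = cfg.carbon_source or sorted(scope.native_compounds)[0]
            results = []
            for i, p in enumerate(
                sorted(state.all_pathways, key=lambda p: (p.length, p.reactions))
            ):
                model = fa.integrate_pathway(chassis, p, db, target)
                results.append(
                    fa.compute_yield(
                        model,
                        target,
                        f"EX_{carbon}",
                        cfg.basis_uptake,
                        biomass_fraction=cfg.biomass_fraction,
                        pathway_id=f"{target}#{i}",
                        pathway_length=p.length,
                    )
                )
            entry["yields"] = [asdict(r) for r in fa.rank_pathways(results)]
        if state.all_pathways and state.beta_star:
            g = build_dependency_graph(state.union_variables, target, db, scope)
            entry["dot"] = to_dot(g, db, scope, title=target)
        bundle["targets"][target] = entry
    n_rows = []
    for target, entry in sorted(bundle["targets"].items()):
        n_rows.append((target, entry["beta_star"], entry["total_pathways"]))
    bundle["summary"] = [
        {"target": t, "beta_star": b, "pathways": n} for t, b, n in n_rows
    ]
    return bundle


def run_query(cfg: QueryConfig) -> tuple[dict, int]:
    """Load inputs, run the query, export if requested; returns (bundle, exit code)."""
    db = load_database(cfg.db_path)
    if cfg.sbml_path:
        scope, fragment = scope_from_sbml(cfg.sbml_path)
        from .netdb import merge_user_reactions

        db = merge_user_reactions(
            db, fragment.reactions.values(), fragment.compounds.values()
        )
    else:
        scope = load_scope(cfg.scope_path)
    scope.check_against(db)
    bundle = run_query_objects(db, scope, cfg)
    if cfg.out_dir:
        export_results(bundle, cfg.out_dir)
    if bundle["failures"] and not bundle["targets"]:
        return bundle, EXIT_ERROR
    if all(e["status"] == "no-pathway" for e in bundle["targets"].values()):
        return bundle, EXIT_NO_PATHWAY
    return bundle, EXIT_OK


def dumps_bundle(bundle: dict) -> str:
    """Canonical JSON: sorted keys, fixed separators — byte-stable."""
    return json.dumps(bundle, sort_keys=True, indent=1, separators=(",", ": ")) + "\n"


def summary_tsv(bundle: dict) -> str:
    lines = ["target\tlevel\tlength\treactions\tenzymes\ttypes"]
    for target, entry in sorted(bundle["targets"].items()):
        for level in entry["levels"]:
            for p in level["pathways"]:
                rxns = ",".join(s["variable"] for s in p["steps"])
                enz = ",".join(s["enzyme"] or "-" for s in p["steps"])
                typ = ",".join(s["type"] for s in p["steps"])
                lines.append(
                    f"{target}\t{level['level']}\t{p['length']}\t{rxns}\t{enz}\t{typ}"
                )
    return "\n".join(lines) + "\n"


def export_results(
    bundle: dict, out_dir: str | Path, formats: tuple[str, ...] = ("json", "tsv", "dot")
) -> list[Path]:
    """Write the bundle to disk; stable field order throughout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        p = out / "results.json"
        p.write_text(dumps_bundle(bundle))
        written.append(p)
    if "tsv" in formats:
        p = out / "summary.tsv"
        p.write_text(summary_tsv(bundle))
        written.append(p)
    if "dot" in formats:
        for target, entry in sorted(bundle["targets"].items()):
            if "dot" in entry:
                p = out / f"{target.replace('/', '_')}.dot"
                p.write_text(entry["dot"])
                written.append(p)
    return written
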