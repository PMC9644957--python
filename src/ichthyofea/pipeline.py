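"""Staged orchestration: geometry -> muscles -> FEA -> levers -> comparison.

Every stage is importable on its own; :func:`run` drives them from a YAML
config for the command-line interface.  All randomness flows through one
seeded generator and a config hash is embedded in the outputs, so identical
config + seed reproduces identical artifacts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ichthyofea import compare, dentition, fem, io as mesh_io, levers, muscles, skull

__all__ = [
    "RunConfig",
    "ConfigError",
    "run",
    "simulate_morphotype",
    "comparison_summaries",
    "truncation_sensitivity",
    "refinement_study",
    "tables_stage",
]

log = logging.getLogger("ichthyofea")

MORPHOTYPE_SPECIMENS = {"robust": "M1409", "gracile": "M1399"}
BITE_CASES = {"robust": ("posterior", "mid"), "gracile": ("posterior", "mid", "anterior")}
# The robust fossil's anterior rostrum is broken off: its model is truncated to
# the preserved share of the estimated total length, and its foremost preserved
# tooth position plays the role of the mid-tooth-row case in the comparison
# (the analog of the gracile mid bite).  Bite-case name -> node-set name:
BITE_SET_MAPS = {
    "robust": {"posterior": "bite_posterior", "mid": "bite_anterior"},
    "gracile": {"posterior": "bite_posterior", "mid": "bite_mid", "anterior": "bite_anterior"},
}


def morphotype_mesh(label: str, params: skull.MorphotypeParams | None = None):
    """Build the FE mesh for a morphotype, truncated to its preserved extent.

    Returns ``(mesh, bite_set_map)``.  The gracile skull is complete; the
    robust one is cut back to its preserved share (its estimated anterior
    rostrum carried no constraints or loads in the study).
    """
    params = params or skull.load_preset(label)
    mesh = skull.build_skull_mesh(params)
    meta = skull.preset_metadata(label) if label in MORPHOTYPE_SPECIMENS else {}
    study = meta.get("study", {})
    preserved = float(study.get("preserved_length_mm", params.total_skull_length))
    keep = preserved / params.total_skull_length
    if keep < 1.0:
        mesh = skull.truncate_rostrum(mesh, keep)
    return mesh, BITE_SET_MAPS.get(label, BITE_SET_MAPS["gracile"])


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (see ``ichthyofea --help`` for the CLI)."""

    morphotypes: list[str] = dc_field(default_factory=lambda: ["robust", "gracile"])
    load_cases: dict[str, list[str]] = dc_field(default_factory=dict)
    muscle_fixture: str | None = None
    lever_fixture: str | None = None
    tooth_fixture: str | None = None
    muscle_stress_MPa: float = muscles.DEFAULT_MUSCLE_STRESS
    youngs_E_MPa: float = 15_000.0
    poisson_nu: float = 0.29
    edge_length_mm: float | None = None  # granularity override for all presets
    include_depressors: bool = True
    load_insertions: bool = False
    truncation_sensitivity: bool = False
    out_dir: str = "results/run"
    seed: int = 0
    stages: list[str] = dc_field(default_factory=lambda: ["mesh", "tables", "solve", "compare", "report"])

    def __post_init__(self) -> None:
        for m in self.morphotypes:
            if m not in MORPHOTYPE_SPECIMENS:
                raise ConfigError(f"morphotypes: unknown morphotype {m!r} (expected robust/gracile)")
        for m, cases in self.load_cases.items():
            allowed = set(BITE_CASES.get(m, ()))
            bad = [c for c in cases if c not in allowed]
            if bad:
                hint = ""
                if m == "robust" and "anterior" in bad:
                    hint = (
                        " (the robust preset has no true anterior-tip case: its foremost "
                        "preserved bite point is analogous to the gracile mid case)"
                    )
                raise ConfigError(f"load_cases.{m}: invalid bite positions {bad}{hint}")
        for key in ("muscle_fixture", "lever_fixture", "tooth_fixture"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{key}: file not found: {path}")
        if not self.muscle_stress_MPa >= 0:
            raise ConfigError(f"muscle_stress_MPa must be >= 0, got {self.muscle_stress_MPa!r}")
        if self.edge_length_mm is not None and not self.edge_length_mm > 0:
            raise ConfigError(f"edge_length_mm must be > 0, got {self.edge_length_mm!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)} (expected a subset of {sorted(known)})")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def cases_for(self, morphotype: str) -> list[str]:
        return list(self.load_cases.get(morphotype, BITE_CASES[morphotype]))

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# computational stages (library API used by tests and the acceptance script)
# ---------------------------------------------------------------------------

def tables_stage(
    muscle_fixture: str | None = None,
    lever_fixture: str | None = None,
    tooth_fixture: str | None = None,
    muscle_stress: float = muscles.DEFAULT_MUSCLE_STRESS,
) -> dict:
    """Fixture-driven stage: muscle forces, totals, lever bite forces, dentition."""
    muscle_tables = {}
    totals_rows = []
    for specimen in ("M1409", "M1399"):
        ms = muscles.default_muscles(specimen, muscle_fixture)
        muscle_tables[specimen] = muscles.force_table(ms, muscle_stress)
        f_total = muscles.total_muscle_force(ms, muscle_stress)
        lever = levers.lever_from_fixture(specimen, lever_fixture)
        profile = levers.bite_profile(lever, f_total, specimen=specimen)
        rounded = profile.rounded()
        totals_rows.append(
            {
                "specimen": specimen,
                "total_muscle_volume_mm3": float(sum(m.volume_V for m in ms)),
                "mechanical_advantage": lever.advantage_tip,
                "total_muscle_force_N": int(muscles.round_half_away(f_total)),
                "bite_force_tip_N": rounded["tip_of_tooth_row"],
                "bite_force_back_N": rounded["back_of_tooth_row"],
            }
        )
    teeth = dentition.load_tooth_table(tooth_fixture)
    return {
        "muscle_tables": muscle_tables,
        "totals": pd.DataFrame(totals_rows),
        "dentition": dentition.dentition_summary(teeth),
        "dentition_per_tooth": dentition.dentition_table(teeth),
    }


def simulate_morphotype(
    params: skull.MorphotypeParams,
    specimen: str,
    positions: tuple[str, ...] | list[str],
    material: fem.Material | None = None,
    muscle_stress: float = muscles.DEFAULT_MUSCLE_STRESS,
    policy: muscles.NodeCountPolicy | None = None,
    muscle_fixture: str | None = None,
    include_depressors: bool = True,
    load_insertions: bool = False,
    seed: int = 0,
    mesh: skull.SkullMesh | None = None,
    bite_set_map: dict[str, str] | None = None,
) -> dict:
    """Build (or take) the mesh, apply the specimen's muscle loads and solve
    every requested bite case.  Returns mesh, load cases, fields, summaries."""
    material = material or fem.Material()
    if mesh is None:
        mesh = skull.build_skull_mesh(params)
    bite_set_map = bite_set_map or BITE_SET_MAPS["gracile"]
    ms = muscles.default_muscles(specimen, muscle_fixture)
    vectors = muscles.all_muscle_vectors(
        mesh,
        ms,
        muscle_stress,
        policy,
        load_insertions=load_insertions,
        include_depressors=include_depressors,
        seed=seed,
    )
    out = {"mesh": mesh, "cases": {}, "fields": {}, "summaries": {}}
    for pos in positions:
        case = fem.make_bite_load_case(mesh, vectors, bite_set_map[pos], label=f"{params.label}:{pos}")
        t0 = time.perf_counter()
        field = fem.solve(mesh, material, case)
        log.info(
            "solved %s (%d elements, %d fixed nodes) in %.2f s",
            case.label,
            mesh.n_elements,
            case.fixed_nodes.size,
            time.perf_counter() - t0,
        )
        out["cases"][pos] = case
        out["fields"][pos] = field
        out["summaries"][pos] = fem.region_summary(field, mesh, case)
    return out


def comparison_summaries(
    edge_scale: float = 1.0,
    seed: int = 0,
    config: RunConfig | None = None,
) -> tuple[dict, dict]:
    """Run both morphotypes at ``edge_scale`` x the preset granularity.

    Returns ``(summaries, results)`` where summaries maps
    ``(morphotype, position)`` to regional statistics.
    """
    config = config or RunConfig()
    summaries: dict[tuple[str, str], dict] = {}
    results: dict[str, dict] = {}
    for label in config.morphotypes:
        params = skull.load_preset(label)
        if config.edge_length_mm is not None:
            params = skull.MorphotypeParams(**{**params.__dict__, "target_edge_length": config.edge_length_mm})
        if edge_scale != 1.0:
            params = skull.MorphotypeParams(
                **{**params.__dict__, "target_edge_length": params.target_edge_length * edge_scale}
            )
        mesh, set_map = morphotype_mesh(label, params)
        res = simulate_morphotype(
            params,
            MORPHOTYPE_SPECIMENS[label],
            config.cases_for(label),
            material=fem.Material(config.youngs_E_MPa, config.poisson_nu),
            muscle_stress=config.muscle_stress_MPa,
            muscle_fixture=config.muscle_fixture,
            include_depressors=config.include_depressors,
            load_insertions=config.load_insertions,
            seed=seed,
            mesh=mesh,
            bite_set_map=set_map,
        )
        results[label] = res
        for pos, summary in res["summaries"].items():
            summaries[(label, pos)] = summary
    return summaries, results


def truncation_sensitivity(
    keep_fraction: float | None = None,
    seed: int = 0,
    config: RunConfig | None = None,
    gracile_result: dict | None = None,
) -> dict:
    """Gracile full vs rostrum-truncated posterior-bite comparison.

    The default truncation mirrors the robust specimen's preserved share of
    its estimated total length.  Returns the two posterior-cranium summaries
    and their relative difference in regional mean von Mises.
    """
    config = config or RunConfig()
    if keep_fraction is None:
        meta = skull.preset_metadata("robust")
        keep_fraction = meta["study"]["preserved_length_mm"] / meta["morphotype"]["total_skull_length"]
    params = skull.load_preset("gracile")
    if config.edge_length_mm is not None:
        params = skull.MorphotypeParams(**{**params.__dict__, "target_edge_length": config.edge_length_mm})

    if gracile_result is None:
        gracile_result = simulate_morphotype(
            params, MORPHOTYPE_SPECIMENS["gracile"], ("posterior",), seed=seed,
            muscle_stress=config.muscle_stress_MPa, muscle_fixture=config.muscle_fixture,
        )
    full_mesh = gracile_result["mesh"]
    truncated = skull.truncate_rostrum(full_mesh, keep_fraction)
    trunc_result = simulate_morphotype(
        params, MORPHOTYPE_SPECIMENS["gracile"], ("posterior",), seed=seed, mesh=truncated,
        muscle_stress=config.muscle_stress_MPa, muscle_fixture=config.muscle_fixture,
    )

    full_pc = gracile_result["summaries"]["posterior"]["posterior_cranium"]
    trunc_pc = trunc_result["summaries"]["posterior"]["posterior_cranium"]
    rel = abs(trunc_pc["mean"] - full_pc["mean"]) / full_pc["mean"]
    return {
        "keep_fraction": keep_fraction,
        "full": full_pc,
        "truncated": trunc_pc,
        "relative_difference": rel,
        "full_elements": full_mesh.n_elements,
        "truncated_elements": truncated.n_elements,
        "truncated_mesh": truncated,
        "truncated_result": trunc_result,
    }


def refinement_study(
    params: skull.MorphotypeParams,
    specimen: str,
    position: str = "mid",
    scales: tuple[float, ...] = (1.3, 1.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Regional mean von Mises across mesh-refinement levels (larger scale =
    coarser mesh); used to show regional summaries are stable under refinement."""
    rows = []
    for scale in scales:
        p = skull.MorphotypeParams(**{**params.__dict__, "target_edge_length": params.target_edge_length * scale})
        res = simulate_morphotype(p, specimen, (position,), seed=seed)
        summary = res["summaries"][position]
        row = {"edge_scale": scale, "n_elements": res["mesh"].n_elements}
        for region, s in summary.items():
            row[f"{region}_mean"] = np.nan if s is None else s["mean"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run (CLI backend)
# ---------------------------------------------------------------------------

def run(config: RunConfig) -> int:
    """Execute the requested stages; returns a process exit status."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    chash = compare.config_hash(config.as_dict())
    provenance = {"config_hash": chash, "seed": config.seed}
    log.info("run start: config hash %s, seed %d", chash, config.seed)

    status = 0
    tables = None
    summaries: dict[tuple[str, str], dict] = {}
    contrast = None
    mesh_stats: dict[str, dict] = {}
    try:
        if "tables" in config.stages:
            t0 = time.perf_counter()
            tables = tables_stage(
                config.muscle_fixture, config.lever_fixture, config.tooth_fixture, config.muscle_stress_MPa
            )
            log.info("tables stage done in %.2f s", time.perf_counter() - t0)

        results: dict[str, dict] = {}
        if "solve" in config.stages:
            summaries, results = comparison_summaries(seed=config.seed, config=config)
            for label, res in results.items():
                mesh = res["mesh"]
                mesh_stats[label] = dict(mesh.meta.get("quality", {}))
                if "mesh" in config.stages:
                    mesh_io.write_vtk(mesh, out / f"mesh_{label}.vtk")
                    mesh_io.write_stl(mesh, out / f"mesh_{label}.stl", name=label)
                for pos, field in res["fields"].items():
                    mesh_io.write_field_vtk(mesh, field, out / f"stress_{label}_{pos}.vtk")
        elif "mesh" in config.stages:
            for label in config.morphotypes:
                params = skull.load_preset(label)
                if config.edge_length_mm is not None:
                    params = skull.MorphotypeParams(
                        **{**params.__dict__, "target_edge_length": config.edge_length_mm}
                    )
                mesh = skull.build_skull_mesh(params)
                mesh_stats[label] = dict(mesh.meta.get("quality", {}))
                mesh_io.write_vtk(mesh, out / f"mesh_{label}.vtk")
                mesh_io.write_stl(mesh, out / f"mesh_{label}.stl", name=label)

        if "compare" in config.stages and summaries:
            contrast = compare.stress_contrast(summaries)
            log.info("contrast verdicts:\n%s", contrast.verdict_summary())

        if config.truncation_sensitivity and "solve" in config.stages:
            sens = truncation_sensitivity(
                seed=config.seed, config=config, gracile_result=results.get("gracile")
            )
            pd.DataFrame(
                [
                    {
                        "keep_fraction": sens["keep_fraction"],
                        "full_mean_MPa": sens["full"]["mean"],
                        "truncated_mean_MPa": sens["truncated"]["mean"],
                        "relative_difference": sens["relative_difference"],
                        "full_elements": sens["full_elements"],
                        "truncated_elements": sens["truncated_elements"],
                    }
                ]
            ).to_csv(out / "truncation_sensitivity.csv", index=False)
            log.info("truncation sensitivity: %.3f%% change", 100 * sens["relative_difference"])
    except Exception:
        log.exception("stage failed; partial artifacts preserved in %s", out)
        status = 1

    if "report" in config.stages:
        try:
            compare.generate_report(
                out,
                muscle_tables=tables["muscle_tables"] if tables else None,
                totals=tables["totals"] if tables else None,
                dentition=tables["dentition"] if tables else None,
                summaries=summaries or None,
                contrast=contrast,
                mesh_stats=mesh_stats or None,
                provenance=provenance,
                strict=False,
            )
        except Exception:
            log.exception("report generation failed")
            status = 1

    log.removeHandler(handler)
    handler.close()
    return status
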