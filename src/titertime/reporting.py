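"""Pipeline orchestration, run manifests and seed substreams.

A single top-level seed feeds every stage through named substreams
(``stage_seed``), so re-running one stage with the same label is
reproducible and independent of the other stages.
"""

from __future__ import annotations

import dataclasses
import graphlib
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .datamodel import (
    AnalyteConfig,
    write_cohort,
    write_json,
    write_panel,
)
from .errors import ConfigError, DataError
from .simulate import (
    cohort_config_from_dict,
    gen_cohort,
    gen_panel,
    panel_config_from_dict,
)

log = logging.getLogger("titertime")

#: built-in stage dependency DAG
STAGE_DEPS: dict[str, tuple[str, ...]] = {
    "simulate_panel": (),
    "simulate_cohort": (),
    "diurnal": ("simulate_panel",),
    "cosinor": ("simulate_panel",),
    "varcomp": ("simulate_panel",),
    "restrict": ("simulate_panel",),
    "subgroups": ("simulate_cohort",),
    "confounding": ("simulate_cohort",),
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    digest = hashlib.sha256(f"{seed}/{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    seed: int
    config_digest: str | None
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    package_version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def resolve_stages(
    requested: list[str] | None,
    deps: dict[str, tuple[str, ...]] | None = None,
) -> list[str]:
    """Topologically order the requested stages plus their dependencies.

    ``deps`` overrides the built-in DAG (used to validate user-declared
    dependency edits); a cycle raises :class:`ConfigError`.
    """
    graph = {k: set(v) for k, v in (deps or STAGE_DEPS).items()}
    for stage, parents in graph.items():
        for p in parents:
            if p not in graph:
                raise ConfigError(f"stage {stage!r} depends on unknown stage {p!r}")
    try:
        order = list(graphlib.TopologicalSorter(graph).static_order())
    except graphlib.CycleError as exc:
        raise ConfigError(f"cyclic stage dependencies: {exc.args[1]}") from exc
    if requested is None:
        return order
    unknown = [s for s in requested if s not in graph]
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    wanted: set[str] = set()
    frontier = list(requested)
    while frontier:
        s = frontier.pop()
        if s in wanted:
            continue
        wanted.add(s)
        frontier.extend(graph[s])
    return [s for s in order if s in wanted]


def run_pipeline(
    config: dict[str, Any],
    out_dir: str | Path,
    seed: int = 0,
    config_digest: str | None = None,
) -> RunManifest:
    """Simulate both datasets and run every requested analysis stage.

    Writes one file per stage into ``out_dir`` plus ``manifest.json``.
    """
    from . import cosinor as cos
    from . import diurnal as diu
    from . import restriction as res
    from . import subgroups as sub
    from . import varcomp as vc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    deps_override = config.get("stage_dependencies")
    if deps_override is not None:
        deps_override = {k: tuple(v) for k, v in deps_override.items()}
    stages = resolve_stages(config.get("stages"), deps_override)
    manifest = RunManifest(command="run", seed=seed, config_digest=config_digest)

    panel = None
    cohort = None
    panel_cfgs: dict[str, AnalyteConfig] = {}
    artifacts: dict[str, Path] = {}

    def emit(name: str, obj: Any) -> None:
        path = out / name
        write_json(obj, path)
        manifest.outputs.append(name)
        artifacts[name] = path

    for stage in stages:
        t0 = time.perf_counter()
        s_seed = stage_seed(seed, stage)
        if stage == "simulate_panel":
            pcfg = panel_config_from_dict(config.get("panel"), seed=s_seed)
            panel = gen_panel(pcfg)
            write_panel(panel, out / "panel.csv")
            manifest.outputs.append("panel.csv")
            panel_cfgs = {
                name: AnalyteConfig(
                    analyte=name,
                    detection_threshold=config.get("thresholds", {}).get(name, p.mesor),
                    interassay_cv_pct=config.get("interassay_cv_pct", {}).get(name, 15.0),
                )
                for name, p in pcfg.analytes.items()
            }
        elif stage == "simulate_cohort":
            ccfg = cohort_config_from_dict(config.get("cohort"), seed=s_seed)
            cohort = gen_cohort(ccfg)
            write_cohort(cohort, out / "cohort.csv")
            manifest.outputs.append("cohort.csv")
        elif stage == "diurnal":
            assert panel is not None
            emit("diurnal.json", diu.summarize_panel(panel, panel_cfgs))
        elif stage == "cosinor":
            assert panel is not None
            reports = {}
            for analyte in panel.analytes:
                obs = cos.panel_observations(panel, analyte, zscore=True)
                fit = cos.fit_cosinor(obs, analyte=analyte)
                ci = (
                    cos.acrophase_ci(fit)
                    if fit.amplitude > 0 and not fit.perfect_fit
                    else None
                )
                reports[analyte] = cos.fit_report(fit, ci)
            emit("cosinor.json", reports)
        elif stage == "varcomp":
            assert panel is not None
            emit(
                "varcomp.json",
                {a: vc.variance_components(panel, a) for a in panel.analytes},
            )
        elif stage == "restrict":
            assert panel is not None
            n_boot = int(config.get("n_boot", 10_000))
            reports = {}
            for analyte in panel.analytes:
                reports[analyte] = {
                    str(t): res.bootstrap_sd_ratio(
                        panel, analyte, t, n_boot=n_boot, seed=s_seed
                    )
                    for t in res.CLINICAL_TIMES
                }
            emit("restriction.json", reports)
        elif stage == "subgroups":
            assert cohort is not None
            reports = {}
            for analyte in cohort.analytes:
                rep = sub.subgroup_report(cohort, analyte)
                rep["comparisons"] = [
                    {**c, "comparison": dataclasses.asdict(c["comparison"])}
                    for c in rep["comparisons"]
                ]
                reports[analyte] = rep
            emit("subgroups.json", reports)
        elif stage == "confounding":
            assert cohort is not None
            first = cohort.analytes[0]
            df = cohort.for_analyte(first)
            rho, p = sub.spearman_check(df["age_years"], df["tod_hour"])
            emit(
                "confounding.json",
                {"spearman_age_vs_tod_hour": {"rho": rho, "p": p, "n": len(df)}},
            )
        else:  # pragma: no cover - resolve_stages rejects unknown stages
            raise ConfigError(f"unknown stage {stage!r}")
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    manifest.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
    write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
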