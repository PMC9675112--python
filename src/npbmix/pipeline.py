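"""End-to-end orchestration: simulate -> assign exposures -> design ->
fit NPB + baselines -> stratify -> sensitivity sweep -> report.

Each stage reads its inputs from, and writes its outputs to, a single run
directory, so stages can be run one at a time (CLI subcommands) or together
(:func:`run_pipeline`). Every stochastic stage derives its seed from the
master seed recorded in the manifest; identical config + seed reproduces
every table byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import run_all_single_exposure, stratified_run
from .design import build_design, exposure_summary
from .kriging import assign_pregnancy_exposure
from .npb import (
    NPBConfig,
    PosteriorSummary,
    npb_fit,
    sensitivity_sweep,
    summarize_posterior,
)
from .synthetic import (
    SimulationConfig,
    SpatialFieldSpec,
    read_cohort,
    simulate_cohort,
    simulate_monitors,
    write_cohort,
)

__all__ = ["RunManifest", "run_pipeline", "selection_report", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "krige", "design", "fit-npb", "fit-lm", "stratify", "sweep", "report")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)

    def write(self, outdir: Path) -> None:
        missing = [
            f for files in self.outputs.values() for f in files
            if not (outdir / f).exists()
        ]
        if missing:
            raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
        (outdir / "manifest.json").write_text(
            json.dumps(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "stage_seconds": self.stage_seconds,
                    "outputs": self.outputs,
                },
                indent=1,
                default=str,
            )
        )


def selection_report(summary: PosteriorSummary, threshold: float = 0.5) -> pd.DataFrame:
    """Terms with PIP strictly above the threshold.

    The ``interval_excludes_zero`` flag marks the dual criterion (PIP above
    threshold and a 95% credible interval not containing zero).
    """
    sel = summary[summary["pip"] > threshold].copy()
    sel["interval_excludes_zero"] = (sel["lo"] > 0) | (sel["hi"] < 0)
    return sel


def _sim_config(cfg: dict, seed: int) -> SimulationConfig:
    sim = dict(cfg.get("simulate", {}))
    sim.pop("enabled", None)
    return SimulationConfig(seed=seed, **sim)


def _npb_config(cfg: dict, seed: int) -> NPBConfig:
    npb = dict(cfg.get("npb", {}))
    npb.setdefault("seed", seed)
    return NPBConfig(**npb)


def _design_kwargs(cfg: dict) -> dict:
    d = dict(cfg.get("design", {}))
    d.setdefault("outcome_choice", "birth_weight")
    d.setdefault("interactions", "all")
    return d


def _require(outdir: Path, name: str, stage: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {name}; run its producing stage first"
        )
    return path


def stage_simulate(cfg: dict, outdir: Path, seed: int) -> list[str]:
    config = _sim_config(cfg, seed)
    cohort = simulate_cohort(config)
    write_cohort(cohort, outdir / "cohort.csv", config)
    return ["cohort.csv", "cohort.csv.meta.yaml"]


def stage_krige(cfg: dict, outdir: Path, seed: int) -> list[str]:
    """Demo exposure-assignment chain on simulated monitor data."""
    cohort = read_cohort(_require(outdir, "cohort.csv", "krige"))
    kcfg = dict(cfg.get("krige", {}))
    field_spec = SpatialFieldSpec(**kcfg.get("field", {"sill": 4.0, "range_km": 15.0}))
    n_days = int(kcfg.get("n_days", 0))
    if n_days == 0:
        span = (cohort["delivery_date"].max() - cohort["conception_date"].min()).days + 1
        n_days = span
    monitors = simulate_monitors(
        n_monitors=int(kcfg.get("n_monitors", 12)),
        region=tuple(kcfg.get("region", (0.0, 40.0, 0.0, 40.0))),
        field_spec=field_spec,
        n_days=n_days,
        seed=seed + 1000,
        start_date=cohort["conception_date"].min(),
    )
    monitors.to_csv(outdir / "monitors.csv", index=False)
    # project lon/lat to planar km within the monitor region
    lon, lat = cohort["lon"].to_numpy(), cohort["lat"].to_numpy()
    x = (lon - lon.min()) / max(np.ptp(lon), 1e-9) * 40.0
    y = (lat - lat.min()) / max(np.ptp(lat), 1e-9) * 40.0
    targets = pd.DataFrame(
        {
            "dyad_id": cohort["dyad_id"],
            "x_km": x,
            "y_km": y,
            "conception_date": cohort["conception_date"],
            "delivery_date": cohort["delivery_date"],
        }
    )
    n_targets = int(kcfg.get("n_targets", 50))
    assignments = assign_pregnancy_exposure(
        monitors, targets.head(n_targets), metric=kcfg.get("metric", "mean24h")
    )
    assignments.to_csv(outdir / "kriged_assignments.csv", index=False)
    return ["monitors.csv", "kriged_assignments.csv"]


def stage_design(cfg: dict, outdir: Path, seed: int) -> list[str]:
    cohort = read_cohort(_require(outdir, "cohort.csv", "design"))
    design = build_design(cohort, **_design_kwargs(cfg))
    design.to_dir(outdir / "design")
    exposure_summary(cohort).to_csv(outdir / "exposure_summary.csv", index=False)
    return [
        "design/y.csv", "design/X.csv", "design/Z.csv", "design/W.csv",
        "design/terms.csv", "exposure_summary.csv",
    ]


def stage_fit_npb(cfg: dict, outdir: Path, seed: int) -> list[str]:
    cohort = read_cohort(_require(outdir, "cohort.csv", "fit-npb"))
    design = build_design(cohort, **_design_kwargs(cfg))
    chain = npb_fit(design, _npb_config(cfg, seed + 2000))
    chain.to_dir(outdir / "npb_chain")
    summary = summarize_posterior(chain)
    summary.to_csv(outdir / "npb_summary.csv")
    threshold = float(cfg.get("report", {}).get("pip_threshold", 0.5))
    selection_report(summary, threshold).to_csv(outdir / "selection_report.csv")
    return [
        "npb_chain/draws.csv", "npb_chain/meta.json",
        "npb_summary.csv", "selection_report.csv",
    ]


def stage_fit_lm(cfg: dict, outdir: Path, seed: int) -> list[str]:
    cohort = read_cohort(_require(outdir, "cohort.csv", "fit-lm"))
    dkw = _design_kwargs(cfg)
    table = run_all_single_exposure(cohort, dkw["outcome_choice"])
    table.to_csv(outdir / "single_exposure.csv")
    return ["single_exposure.csv"]


def stage_stratify(cfg: dict, outdir: Path, seed: int) -> list[str]:
    cohort = read_cohort(_require(outdir, "cohort.csv", "stratify"))
    scfg = dict(cfg.get("stratify", {}))
    engine = scfg.get("engine", "single_exposure")
    dkw = _design_kwargs(cfg)
    kwargs = {}
    if engine == "npb":
        kwargs["npb_config"] = _npb_config(cfg, seed + 3000)
        kwargs["interactions"] = dkw["interactions"]
    results = stratified_run(
        cohort,
        stratifier=scfg.get("stratifier", "stratum"),
        engine=engine,
        outcome_choice=dkw["outcome_choice"],
        keep_geography=bool(scfg.get("keep_geography", True)),
        **kwargs,
    )
    files = []
    for label, table in results.items():
        safe = str(label).replace("/", "-").replace(" ", "_")
        name = f"stratified_{safe}.csv"
        table.to_csv(outdir / name)
        files.append(name)
    return files


def stage_sweep(cfg: dict, outdir: Path, seed: int) -> list[str]:
    cohort = read_cohort(_require(outdir, "cohort.csv", "sweep"))
    design = build_design(cohort, **_design_kwargs(cfg))
    grid = tuple(float(g) for g in cfg.get("sweep", {}).get("grid", (0.5, 1.0, 2.0, 4.0)))
    result = sensitivity_sweep(design, _npb_config(cfg, seed + 4000), grid=grid)
    result.pips.to_csv(outdir / "sweep_pips.csv")
    result.jaccard.to_csv(outdir / "sweep_jaccard.csv")
    pd.DataFrame(
        [{"setting": g, "selected": ";".join(result.selected[g])} for g in grid]
    ).to_csv(outdir / "sweep_selected.csv", index=False)
    return ["sweep_pips.csv", "sweep_jaccard.csv", "sweep_selected.csv"]


def stage_report(cfg: dict, outdir: Path, seed: int) -> list[str]:
    summary = pd.read_csv(_require(outdir, "npb_summary.csv", "report"), index_col="term")
    threshold = float(cfg.get("report", {}).get("pip_threshold", 0.5))
    report = selection_report(summary[summary["block"] != "covariate"], threshold)
    lm_path = outdir / "single_exposure.csv"
    if lm_path.exists():
        lm = pd.read_csv(lm_path, index_col="exposure")
        joined = summary[summary["block"] == "main"][["mean", "lo", "hi", "pip"]].join(
            lm[["estimate", "ci_lower", "ci_upper"]], how="left"
        )
        joined.columns = [
            "npb_mean", "npb_lo", "npb_hi", "npb_pip",
            "lm_estimate", "lm_lo", "lm_hi",
        ]
        joined.to_csv(outdir / "npb_vs_lm.csv")
        report.to_csv(outdir / "report.csv")
        return ["report.csv", "npb_vs_lm.csv"]
    report.to_csv(outdir / "report.csv")
    return ["report.csv"]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "krige": stage_krige,
    "design": stage_design,
    "fit-npb": stage_fit_npb,
    "fit-lm": stage_fit_lm,
    "stratify": stage_stratify,
    "sweep": stage_sweep,
    "report": stage_report,
}


def run_pipeline(config: dict | str | Path, stages: list[str] | None = None) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``config`` is a dict or a path to a YAML file with keys ``seed``,
    ``outdir``, optional ``stages``, and per-stage sections (``simulate``,
    ``design``, ``npb``, ``krige``, ``stratify``, ``sweep``, ``report``).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "npbmix_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    requested = stages if stages is not None else config.get("stages", list(STAGES))
    unknown = [s for s in requested if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid: {list(STAGES)}")
    manifest = RunManifest(config=config, seed=seed)
    for stage in STAGES:
        if stage not in requested:
            continue
        t0 = time.perf_counter()
        try:
            files = _STAGE_FUNCS[stage](config, outdir, seed)
        except Exception as err:
            log.error("stage %r failed: %s; partial outputs in %s", stage, err, outdir)
            (outdir / "manifest.json").write_text(
                json.dumps(
                    {
                        "version": manifest.version,
                        "seed": seed,
                        "failed_stage": stage,
                        "error": str(err),
                        "partial_outputs": manifest.outputs,
                        "stage_seconds": manifest.stage_seconds,
                    },
                    indent=1,
                    default=str,
                )
            )
            raise
        dt = time.perf_counter() - t0
        manifest.stage_seconds[stage] = round(dt, 3)
        manifest.outputs[stage] = files
        log.info("stage %-8s seed=%d n_outputs=%d %.2fs", stage, seed, len(files), dt)
    manifest.write(outdir)
    return manifest
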