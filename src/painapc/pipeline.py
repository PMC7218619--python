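"""End-to-end orchestration: rates -> candidate fits -> DIC selection -> projection.

`run_pipeline` ties the stages together per stratum, writes every numeric
output as CSV, and records a run log (seed, config hash, per-stage wall times,
DIC table, selected specification) so a run is reproducible from its artifact
directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .inference import MCMCConfig, compute_dic, select_model, summarize_effects
from .lexis import APCTable, observed_rates, read_table_csv, write_rates_csv, write_table_csv
from .model import APCModelSpec
from .projection import DEFAULT_BAND_LEVELS, project_rates, projection_delta, write_projection_csv
from .simulate import default_truth, generate_apc_table

__all__ = ["PipelineConfig", "run_pipeline", "default_candidates"]

logger = logging.getLogger(__name__)


def default_candidates() -> list[APCModelSpec]:
    """The comparison set: full APC with RW2 and RW1, and the two-effect models."""
    rw = lambda o, eff: {e: o for e in eff}  # noqa: E731
    full = ("age", "period", "cohort")
    return [
        APCModelSpec(effects=full, rw_order=rw(2, full)),
        APCModelSpec(effects=full, rw_order=rw(1, full)),
        APCModelSpec(effects=("age", "period"), rw_order=rw(2, ("age", "period"))),
        APCModelSpec(effects=("age", "cohort"), rw_order=rw(2, ("age", "cohort"))),
    ]


@dataclass
class PipelineConfig:
    """Full pipeline configuration; exactly one of input_csv / simulate."""

    out_dir: str | Path
    input_csv: str | Path | None = None
    simulate: bool = False
    candidates: Sequence[APCModelSpec] = field(default_factory=default_candidates)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    horizon: int = 2
    band_levels: Sequence[int] = DEFAULT_BAND_LEVELS
    at_risk_policy: str = "carry_forward"
    credible_level: float = 0.95
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if bool(self.input_csv) == bool(self.simulate):
            raise ValueError("exactly one input source: give input_csv or set simulate=True")
        if len(self.candidates) == 0:
            raise ValueError("candidate model list is empty")

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir),
            "input_csv": None if self.input_csv is None else str(self.input_csv),
            "simulate": self.simulate,
            "candidates": [c.to_dict() for c in self.candidates],
            "mcmc": {
                "n_iterations": self.mcmc.n_iterations,
                "n_burnin": self.mcmc.n_burnin,
                "thinning": self.mcmc.thinning,
                "n_chains": self.mcmc.n_chains,
                "seed": self.mcmc.seed,
            },
            "horizon": self.horizon,
            "band_levels": list(self.band_levels),
            "at_risk_policy": self.at_risk_policy,
            "credible_level": self.credible_level,
            "seed": self.seed,
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_tables(config: PipelineConfig, out: Path) -> list[APCTable]:
    if config.simulate:
        tables = [
            generate_apc_table(default_truth(s), seed=config.seed + i)
            for i, s in enumerate(("male", "female"))
        ]
        write_table_csv(tables, out / "simulated_input.csv")
        return tables
    return read_table_csv(config.input_csv)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the report manifest.

    Per stratum: marginal observed rates, candidate fits with DIC selection,
    effect summaries on log and rate-ratio scales, and rate projections with
    nested credible bands.  Raises with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_times: dict[str, float] = {}
    manifest: dict = {
        "painapc_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "strata": {},
    }

    def _stage(name: str, fn, *args, **kw):
        t0 = time.time()
        try:
            result = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stage_times[name] = round(time.time() - t0, 3)
        logger.info("stage %s finished in %.2fs", name, stage_times[name])
        return result

    tables = _stage("load", _load_tables, config, out)

    for table in tables:
        s = table.stratum
        files: dict[str, str] = {}

        def _write_rates(table=table, s=s, files=files):
            series = [observed_rates(table, m) for m in ("age", "period", "cohort", "total")]
            path = out / f"rates_{s}.csv"
            write_rates_csv(series, path)
            files["rates"] = path.name

        _stage(f"rates[{s}]", _write_rates)

        mcmc = MCMCConfig(
            n_iterations=config.mcmc.n_iterations,
            n_burnin=config.mcmc.n_burnin,
            thinning=config.mcmc.thinning,
            n_chains=config.mcmc.n_chains,
            seed=config.seed + config.mcmc.seed,
            proposal_scales=config.mcmc.proposal_scales,
            adapt=config.mcmc.adapt,
        )
        selection = _stage(f"select[{s}]", select_model, table, config.candidates, mcmc)
        dic_path = out / f"dic_{s}.csv"
        selection.dic_table.to_csv(dic_path, index=False)
        files["dic"] = dic_path.name

        fit = selection.fits[selection.chosen.label]
        summaries = _stage(
            f"summaries[{s}]", summarize_effects, fit, config.credible_level, table
        )
        sum_path = out / f"effects_{s}.csv"
        pd.concat([e.to_frame() for e in summaries], ignore_index=True).to_csv(sum_path, index=False)
        files["effects"] = sum_path.name

        results = _stage(
            f"project[{s}]",
            project_rates,
            fit,
            table,
            config.horizon,
            config.band_levels,
            config.at_risk_policy,
            True,
            config.seed,
        )
        proj_path = out / f"projection_{s}.csv"
        write_projection_csv(results, proj_path)
        files["projection"] = proj_path.name
        delta = projection_delta(results, table)
        delta_path = out / f"projection_delta_{s}.csv"
        delta.to_csv(delta_path, index=False)
        files["projection_delta"] = delta_path.name

        if config.make_plots:
            from .plotting import plot_projection_fan

            fig = plot_projection_fan(table, results)
            fig_path = out / f"projection_{s}.png"
            fig.savefig(fig_path, dpi=120)
            files["plot"] = fig_path.name

        manifest["strata"][s] = {
            "selected_model": selection.chosen.label,
            "dic": {
                row["spec_id"]: None if pd.isna(row["DIC"]) else float(row["DIC"])
                for _, row in selection.dic_table.iterrows()
            },
            "acceptance_rates": fit.acceptance_rates,
            "files": files,
        }

    manifest["stage_wall_times_s"] = stage_times
    manifest["total_wall_time_s"] = round(time.time() - t_start, 3)
    (out / "run_log.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    lines = [f"painapc {__version__} run (seed {config.seed}, config {manifest['config_hash']})"]
    for s, info in manifest["strata"].items():
        lines.append(f"stratum {s}: selected {info['selected_model']}; DIC " + ", ".join(
            f"{k}={v:.1f}" if v is not None else f"{k}=failed" for k, v in info["dic"].items()
        ))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return manifest
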