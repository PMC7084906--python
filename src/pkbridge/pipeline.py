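"""End-to-end pipeline: fit -> covariate search -> evaluation ->
extrapolation -> human scenario table, with file-based configuration.

Every randomized stage takes an explicit seed from the config, and the
report tables mirror the analysis outputs: covariate-search steps,
parameter estimates (with bootstrap CIs), the extrapolated human parameter
table, and the human scenario exposure grid.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .data import PKDataset
from .evaluation import bootstrap, gof, vpc
from .extrapolation import HUMAN, RAT, SpeciesContext, extrapolate
from .human import scenario_table
from .population import PopPKModel, covariate_search
from .presets import rat_base_model, rat_final_model
from .synthetic import generate_study

__all__ = ["PipelineConfig", "run_pipeline", "write_reports"]

log = logging.getLogger("pkbridge")


@dataclass
class PipelineConfig:
    """Explicit, serialisable settings for one pipeline run."""

    dataset: str | None = None  # CSV path; None -> synthetic preset
    out_dir: str = "pkbridge_out"
    preset: str = "final"  # initial-values preset: final | base
    synthetic_seed: int = 12345
    fit_seed: int = 0
    fit_maxfev: int = 2000
    fit_n_starts: int = 1
    run_covariate_search: bool = True
    bootstrap_n: int = 1000
    bootstrap_seed: int = 1
    vpc_n: int = 1000
    vpc_seed: int = 2
    rat_body_weight: float = RAT.body_weight
    rat_lbf: float = RAT.lbf
    human_body_weight: float = HUMAN.body_weight
    human_lbf: float = HUMAN.lbf
    tmax_post_dose: float = 6.0
    human_tlag: float = 2.0
    scenario_doses: tuple = (40.0, 60.0)
    scenario_ppl: tuple = (0.0, 5000.0, 15000.0)
    scenario_n: int = 1000
    scenario_seed: int = 3
    make_figures: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("scenario_doses", "scenario_ppl"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def write_reports(results: dict, out_dir) -> list:
    """Write every table in ``results`` as CSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tab in results.items():
        path = out / f"{name}.csv"
        tab.to_csv(path, index=False)
        written.append(path)
    return written


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the artifact tables.

    Stages run in analysis order; a failure halts with the stage name while
    completed artifacts stay on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict = {}
    stage = "setup"
    try:
        import pkbridge

        log.info("pkbridge %s | python %s", pkbridge.__version__, sys.version.split()[0])
        cfg.to_yaml(out / "config.yaml")

        stage = "data"
        if cfg.dataset:
            data = PKDataset.read_csv(cfg.dataset)
            log.info("loaded %s (%d rows)", cfg.dataset, len(data))
        else:
            data = generate_study(seed=cfg.synthetic_seed)
            data.to_csv(out / "synthetic_study.csv")
            log.info("generated synthetic study (seed %d)", cfg.synthetic_seed)

        stage = "fit"
        t0 = time.time()
        init = rat_final_model() if cfg.preset == "final" else rat_base_model()
        if cfg.run_covariate_search:
            base = rat_base_model()
            final_fit, steps = covariate_search(
                base, data,
                fit_kwargs=dict(maxfev=cfg.fit_maxfev, seed=cfg.fit_seed,
                                n_starts=cfg.fit_n_starts, presolve=True),
            )
            artifacts["table1_covariate_steps"] = steps
            # refit the selected model with standard errors
            result = PopPKModel(data, final_fit.params).fit(
                maxfev=cfg.fit_maxfev, seed=cfg.fit_seed,
                n_starts=cfg.fit_n_starts, compute_se=True,
            )
        else:
            result = PopPKModel(data, init).fit(
                maxfev=cfg.fit_maxfev, seed=cfg.fit_seed,
                n_starts=cfg.fit_n_starts, presolve=True,
            )
        log.info("fit done in %.1f s (OFV %.2f)", time.time() - t0, result.ofv)
        (out / "fit_summary.txt").write_text(result.summary() + "\n")

        stage = "bootstrap"
        t0 = time.time()
        boot = bootstrap(result, n=cfg.bootstrap_n, seed=cfg.bootstrap_seed)
        artifacts["table2_bootstrap"] = boot.table
        log.info("bootstrap %d reps in %.1f s (%d converged)",
                 cfg.bootstrap_n, time.time() - t0, boot.n_converged)

        stage = "estimates-table"
        import pandas as pd

        pop = result.params
        est_rows = []
        for nme in pop.estimated_names():
            est_rows.append({
                "parameter": nme,
                "estimate": pop.get_value(nme),
                "rse_pct": (result.rse or {}).get(nme),
            })
        est = pd.DataFrame(est_rows)
        merged = est.merge(boot.table, on="parameter", how="left")
        artifacts["table2_estimates"] = merged

        stage = "vpc"
        t0 = time.time()
        v = vpc(result, n=cfg.vpc_n, seed=cfg.vpc_seed)
        artifacts["vpc_bands"] = v.table
        log.info("vpc %d reps in %.1f s", cfg.vpc_n, time.time() - t0)

        stage = "gof"
        g = gof(result)
        artifacts["gof_residuals"] = g

        stage = "extrapolate"
        ctx_rat = SpeciesContext(cfg.rat_body_weight, cfg.rat_lbf)
        ctx_human = SpeciesContext(cfg.human_body_weight, cfg.human_lbf)
        hp = extrapolate(result, ctx_rat, ctx_human,
                         tmax_post_dose=cfg.tmax_post_dose, tlag=cfg.human_tlag)
        artifacts["table3_human_params"] = hp.to_frame()

        stage = "human-scenarios"
        t0 = time.time()
        artifacts["table4_scenarios"] = scenario_table(
            hp, doses=cfg.scenario_doses, ppl_daily=cfg.scenario_ppl,
            n_replicates=cfg.scenario_n, seed=cfg.scenario_seed,
            body_weight=cfg.human_body_weight,
        )
        log.info("scenario grid in %.1f s", time.time() - t0)

        stage = "reports"
        write_reports(artifacts, out)
        if cfg.make_figures:
            from .plots import plot_gof, plot_vpc

            plot_gof(g, out / "gof.png")
            plot_vpc(v.table, out / "vpc.png")
        log.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
        return artifacts
    except Exception:
        write_reports(artifacts, out)
        log.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}")
    finally:
        log.removeHandler(handler)
        handler.close()
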