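"""End-to-end analysis pipeline.

Stages: generate (or ingest) sessions -> stay-switch metrics and
repeated-measures tests -> hierarchical EM fit per condition -> paired
parameter tests -> AIC comparison of the condition factor -> parameter
recovery on surrogate data simulated from the fitted parameters. Every
output CSV carries the run-configuration hash; a plain-text append-only log
records seeds and stage completion with ISO timestamps.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Any, Dict, List

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort
from .fitting import HierarchicalEMFitter, compare_hunger_factor, parameter_tests
from .io import RunConfig, config_hash, read_sessions, write_csv, write_sessions
from .metrics import paired_t, rm_anova_2x2x2, stay_probabilities, stay_table_frame
from .recovery import generate_surrogate, recovery_analysis
from .task import TaskConfig

__all__ = ["PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


def _log(path: Path, message: str) -> None:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(f"{stamp} {message}\n")


def _index_tests(stay_df: pd.DataFrame, conditions: List[str]) -> pd.DataFrame:
    """Paired tests on the MF index, MB index, and points across conditions."""
    wide = stay_df.pivot(index="subject_id", columns="condition")
    rows = []
    for name in ("mf_index", "mb_index", "points"):
        a = wide[(name, conditions[0])].to_numpy(dtype=float)
        b = wide[(name, conditions[1])].to_numpy(dtype=float)
        keep = ~(np.isnan(a) | np.isnan(b))
        res = paired_t(a[keep], b[keep])
        rows.append(
            {
                "measure": name,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "d": res.d,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Run every stage and write all artifacts under ``config.outdir``.

    Returns the in-memory bundle (sessions, tables, fitter, recovery
    report). A stage failure aborts with a stage-named error; artifacts of
    completed stages are retained on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = outdir / "pipeline.log"
    chash = config_hash(config)
    _log(log, f"pipeline start (twostep {__version__}, seed={config.seed}, config_hash={chash})")
    bundle: Dict[str, Any] = {"config_hash": chash}

    stage = "sessions"
    try:
        if config.input_sessions:
            sessions = read_sessions(config.input_sessions)
            truth = None
        else:
            task_cfg = TaskConfig(**config.task)
            spec = CohortSpec(seed=config.seed, **config.cohort)
            sessions, truth = generate_cohort(spec, task_cfg)
            write_csv(truth, outdir / "ground_truth.csv", chash)
        write_sessions(sessions, outdir / "sessions.csv", chash)
        conditions: List[str] = []
        for s in sessions:
            if s.condition not in conditions:
                conditions.append(s.condition)
        bundle["sessions"] = sessions
        bundle["truth"] = truth
        _log(log, f"stage {stage}: {len(sessions)} sessions, conditions={conditions}")

        stage = "behavior"
        stay_df = stay_table_frame(sessions)
        write_csv(stay_df, outdir / "stay_tables.csv", chash)
        tables: Dict[str, Dict[str, Any]] = {}
        for s in sessions:
            tables.setdefault(s.subject_id, {})[s.condition] = stay_probabilities(s)
        anova = rm_anova_2x2x2(tables, conditions)
        write_csv(anova, outdir / "stay_anova.csv", chash)
        idx_tests = _index_tests(stay_df, conditions)
        write_csv(idx_tests, outdir / "index_tests.csv", chash)
        bundle.update(stay_tables=stay_df, anova=anova, index_tests=idx_tests)
        _log(log, f"stage {stage}: done")

        stage = "fit"
        fitter = HierarchicalEMFitter(seed=config.seed, **config.fit).fit(sessions)
        fits_df = fitter.results_frame()
        write_csv(fits_df, outdir / "fits.csv", chash)
        prior_txt = {
            cond: {"mean": p.mean.tolist(), "var": p.var.tolist()}
            for cond, p in fitter.priors_.items()
        }
        import yaml

        with open(outdir / "priors.yaml", "w", encoding="utf-8") as fh:
            fh.write(f"# config_hash={chash}\n")
            yaml.safe_dump(prior_txt, fh)
        bundle["fitter"] = fitter
        _log(log, f"stage {stage}: EM iterations {fitter.n_iter_}")

        stage = "parameter_tests"
        ptests = parameter_tests(
            fitter.fits_for(conditions[0]), fitter.fits_for(conditions[1])
        )
        write_csv(ptests, outdir / "parameter_tests.csv", chash)
        bundle["parameter_tests"] = ptests
        _log(log, f"stage {stage}: done")

        stage = "aic"
        aic = compare_hunger_factor(sessions, seed=config.seed, **config.fit)
        aic_df = pd.DataFrame([aic._asdict()])
        write_csv(aic_df, outdir / "aic.csv", chash)
        bundle["aic"] = aic
        _log(log, f"stage {stage}: delta_aic={aic.delta:.2f}")

        stage = "recovery"
        rec_opts = dict(config.recovery)
        if rec_opts.pop("enabled", True):
            n_sessions = int(rec_opts.pop("n_sessions", 1))
            gen_params = [f.params for f in fitter.fits_]
            surrogate = generate_surrogate(
                gen_params, sessions[0].config, seed=config.seed + 1, n_sessions=n_sessions
            )
            report = recovery_analysis(
                gen_params, surrogate, seed=config.seed + 1, **config.fit
            )
            corr_df = pd.DataFrame(
                report.correlation,
                index=[f"gen_{n}" for n in report.param_names],
                columns=[f"rec_{n}" for n in report.param_names],
            ).reset_index(names="parameter")
            write_csv(corr_df, outdir / "recovery.csv", chash)
            bundle["recovery"] = report
            _log(
                log,
                f"stage {stage}: min diag R={report.min_diagonal:.3f}, "
                f"max offdiag |R|={report.max_offdiagonal_abs:.3f}",
            )
        else:
            _log(log, f"stage {stage}: skipped (disabled)")
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        _log(log, f"stage {stage}: FAILED ({e})")
        raise PipelineStageError(f"stage '{stage}' failed: {e}") from e

    _log(log, "pipeline complete")
    return bundle
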