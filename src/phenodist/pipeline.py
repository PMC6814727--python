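"""End-to-end pipeline: simulate -> clean -> lsmeans -> fit -> predict -> evaluate.

Every stage writes its artifacts into the output directory and a manifest
records the configuration, the seed and a SHA-256 digest of every numeric
artifact, so a rerun with the same configuration and seed is byte-identical
and verifiably so.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import boosting, cleaning, evaluation, lsmeans as lsm, spatial, synthetic
from .cleaning import DEFAULT_PHASES
from .config import PipelineConfig
from .errors import PhenodistError
from .io import write_records
from .stack import EnvStack

__all__ = ["run_pipeline"]

log = logging.getLogger("phenodist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def simulate_stage(cfg: PipelineConfig, out: Path):
    s = cfg.simulate
    stack = synthetic.gen_env_stack(
        s.rows, s.cols, n_vars=s.n_vars, n_regions=s.n_regions, smoothness=s.smoothness,
        seed=cfg.seed, nodata_fraction=s.nodata_fraction,
    )
    households = synthetic.gen_households(stack, s.n_households, list(s.breeds), seed=cfg.seed + 1)
    spec = synthetic.default_surface_spec(
        stack, active_vars=tuple(s.active_vars), amplitudes=tuple(s.amplitudes),
        intercept=s.intercept, household_sd=s.household_sd, residual_sd=s.residual_sd,
        slope_mean=s.slope_mean, slope_sd=s.slope_sd, ref_week=s.ref_week,
    )
    cont = synthetic.Contamination(
        under50=s.contaminate_under50,
        over30_households=s.contaminate_over30_households,
        under6wk=s.contaminate_under6wk,
    )
    records, truth = synthetic.gen_weight_records(
        households, stack, spec,
        group_size_range=(s.group_size_min, s.group_size_max),
        contamination=cont, seed=cfg.seed + 2,
    )
    stack.save(out / "stack.npz")
    households.to_csv(out / "households.csv", index=False)
    write_records(records, out / "records.csv")
    truth.record_classes.to_csv(out / "truth_records.csv", index=False)
    truth.household_truth.to_csv(out / "truth_households.csv", index=False)
    log.info("simulate: %d households, %d records", len(households), len(records))
    return stack, households, records, truth


def clean_stage(cfg: PipelineConfig, records: pd.DataFrame, out: Path):
    avg = cleaning.to_average_weight(records)
    kept, removal_log = cleaning.apply_filters(
        avg,
        min_weight_g=cfg.filters.min_weight_g,
        max_birds=cfg.filters.max_birds,
        min_week=cfg.filters.min_week,
    )
    kept.to_csv(out / "cleaned.csv", index=False)
    removal_log.to_csv(out / "removal_log.csv", index=False)
    log.info("clean: kept %d of %d records", len(kept), len(records))
    return kept, removal_log


def lsmeans_stage(cfg: PipelineConfig, cleaned: pd.DataFrame, out: Path):
    """Per breed x phase: phase-average week, household fit, LSmeans."""
    breeds = sorted(cleaned["breed"].unique())
    all_entries = []
    phase_weeks = {}
    fits = {}
    for phase_name, phase in DEFAULT_PHASES.items():
        phase_records = cleaning.split_phase(cleaned, phase)
        if len(phase_records) == 0:
            continue
        eval_week = cleaning.phase_average_week(phase_records)
        phase_weeks[phase_name] = eval_week
        for breed in breeds:
            if (phase_records["breed"] == breed).sum() < 2:
                continue
            fit = lsm.fit_household_model(cleaned, breed, phase)
            entries = lsm.lsmeans_at_week(fit, eval_week)
            fits[(breed, phase_name)] = fit
            all_entries.append(entries)
    table = pd.concat(all_entries, ignore_index=True)
    table.to_csv(out / "lsmeans.csv", index=False)
    _write_json(out / "phase_weeks.json", phase_weeks)
    log.info("lsmeans: %d entries over %d models", len(table), len(fits))
    return table, phase_weeks


def model_stage(cfg: PipelineConfig, stack: EnvStack, ls_table: pd.DataFrame, out: Path):
    """Fit one boosted model per breed x phase; predict surfaces and rank regions."""
    b = cfg.boosting
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    results = []
    suit_rows = []
    eval_tables = []
    groups = sorted(ls_table.groupby(["breed", "phase"]).groups)
    for k, (breed, phase) in enumerate(groups):
        sub = ls_table[(ls_table["breed"] == breed) & (ls_table["phase"] == phase)].reset_index(drop=True)
        cells = [stack.cell_at(lo, la) for lo, la in zip(sub["lon"], sub["lat"])]
        rr = np.array([c[0] for c in cells])
        cc = np.array([c[1] for c in cells])
        X = pd.DataFrame({v: stack.layer(v)[rr, cc] for v in stack.var_names})
        y = sub["lsmean_g"].to_numpy()

        bases = boosting.make_bases(X, knot_count=b.knot_count, degree=b.degree,
                                    penalty_order=b.penalty_order, target_df=b.target_df)
        cv = boosting.cv_mstop(X, y, nu=b.nu, m_max=b.m_max, B=b.cv_B, scheme=b.cv_scheme,
                               seed=cfg.seed + 1000 + k, bases=bases)
        full = boosting.boost_fit(X, y, nu=b.nu, m_max=b.m_max, bases=bases)
        fit = boosting.truncate_fit(full, cv.m_stop)
        imp = boosting.variable_importance(fit)

        mask = spatial.env_range_mask(stack, X)
        sex = sub["sex"].iloc[0] if "sex" in sub.columns else ""
        surface = spatial.predict_surface(fit, stack, mask, breed=breed, sex=sex, phase=phase)
        suit = spatial.region_suitability(surface, stack, statistic=cfg.region_statistic)
        report = evaluation.predicted_vs_lsmeans(
            fit, sub.assign(row=rr, col=cc), stack,
            gate_n=cfg.evaluation.gate_n, method=cfg.evaluation.method,
        )

        mdir = models_dir / f"{breed}_{phase}"
        mdir.mkdir(exist_ok=True)
        (mdir / "model.json").write_text(boosting.fit_to_json(fit))
        pd.DataFrame({"iteration": range(len(fit.inbag_risk_path)),
                      "inbag_risk": fit.inbag_risk_path}).to_csv(mdir / "risk_path.csv", index=False)
        pd.DataFrame(cv.risk_matrix).to_csv(mdir / "cv_risk.csv", index=False)
        pd.DataFrame(imp.ranked(), columns=["variable", "risk_reduction"]).to_csv(
            mdir / "importance.csv", index=False)
        surface.to_frame(stack).to_csv(mdir / "surface.csv", index=False)
        np.savez_compressed(mdir / "surface.npz", values=surface.values, mask=surface.mask)

        suit_rows.append({
            "breed": breed, "sex": sex, "phase": phase, "statistic": suit.statistic,
            "best_region": suit.best_region, "tie": suit.tie,
            "m_stop": cv.m_stop, "top_variable": imp.best_var,
            "min_predicted_g": float(np.nanmin(surface.values)),
            "max_predicted_g": float(np.nanmax(surface.values)),
        })
        eval_tables.append(report.table)
        results.append({"breed": breed, "phase": phase, "fit": fit, "cv": cv,
                        "importance": imp, "surface": surface, "suitability": suit,
                        "report": report})
        log.info("model %s/%s: m_stop=%d top=%s best_region=%s",
                 breed, phase, cv.m_stop, imp.best_var, suit.best_region)

    pd.DataFrame(suit_rows).to_csv(out / "suitability.csv", index=False)
    eval_table = pd.concat(eval_tables, ignore_index=True)
    eval_table.to_csv(out / "evaluation.csv", index=False)
    _write_json(out / "evaluation_summary.json", evaluation.summarize_report(eval_table))
    return results, eval_table


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        stage = "simulate"
        stack, households, records, truth = simulate_stage(cfg, out)
        stage = "clean"
        cleaned, removal_log = clean_stage(cfg, records, out)
        stage = "lsmeans"
        ls_table, phase_weeks = lsmeans_stage(cfg, cleaned, out)
        stage = "model"
        results, eval_table = model_stage(cfg, stack, ls_table, out)
    except PhenodistError as err:
        log.error("stage %s failed: %s", stage, err)
        raise PhenodistError(f"pipeline failed in stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()

    cfg_text = json.dumps(cfg.to_dict(), sort_keys=True)
    artifacts = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name not in ("run.log", "manifest.json")
    )
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg.seed,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
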