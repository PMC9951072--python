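"""End-to-end pipeline: load/simulate -> score -> describe -> model -> report.

Given a config (YAML file or mapping) the pipeline scores a cohort, builds
the per-resident analysis table, produces the descriptive comparison table,
the stratified correlation table, the three propensity-model reports with
decile data, and a run manifest with input/output checksums.  Identical
config + seed reproduce byte-identical reports (no timestamps inside report
files; the manifest carries the only timestamp).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as cohort_io
from .braden import BradenError, summarize_braden
from .catalog import DIMENSIONS, default_catalog, load_catalog
from .cohort_stats import point_biserial_by_category, table1_report
from .records import MALE, ResidentRecord
from .risk_models import MODEL_SPECS, WORST_BRADEN, run_model_suite
from .scoring import SeverityScorer, bmi_category
from .simulate import SimulationConfig, export_cohort, simulate_cohort
from .windows import WindowError, compute_exposure_window

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_analysis_table(
    records: list[ResidentRecord],
    catalog=None,
    period_end: Optional[dt.date] = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """One analysis row per eligible resident.

    Columns: demographics (age, male 0/1, race), minimum in-window BMI and
    its four-category bin, Braden First/MEAN/Worst and Worst risk category,
    the four dimension scores, stay length, and the 0/1 PrI outcome.
    Residents without a computable window or without any Braden assessment
    are excluded and returned as (resident_id, reason) rejections.
    """
    scorer = SeverityScorer(catalog=catalog, period_end=period_end).fit(records)
    period_end = scorer.period_end or max(r.end_date for r in records)
    rows, rejections = [], []
    for rec in records:
        try:
            window = compute_exposure_window(rec, period_end)
        except WindowError as err:
            rejections.append((rec.resident_id, str(err)))
            continue
        try:
            summary = summarize_braden(
                rec.braden_assessments, (rec.admission_date, rec.end_date), window
            )
        except BradenError as err:
            rejections.append((rec.resident_id, str(err)))
            continue
        if summary.braden_worst is None:
            rejections.append(
                (rec.resident_id, "no Braden assessment in exposure window")
            )
            continue
        from .scoring import score_dimensions

        dss = score_dimensions(rec, window, scorer.catalog_)
        bmis = [v for d, v in rec.bmi_series() if window.contains(d)]
        bmi_min = min(bmis) if bmis else None
        rows.append(
            {
                "resident_id": rec.resident_id,
                "age": rec.age,
                "male": int(rec.sex == MALE),
                "race_ethnicity": rec.race_ethnicity,
                "bmi_min": bmi_min,
                "bmi_cat": bmi_category(bmi_min) if bmi_min else None,
                "braden_first": summary.braden_first,
                "braden_mean": summary.braden_mean,
                WORST_BRADEN: summary.braden_worst,
                "braden_worst_risk": summary.worst_risk_category,
                **dss.as_dict(),
                "stay_days": rec.stay_days,
                "pri": int(rec.has_pri),
            }
        )
    return pd.DataFrame(rows), rejections


def table2_report(analysis: pd.DataFrame) -> pd.DataFrame:
    """Point-biserial correlations of each predictor with the outcome,
    overall and within each Worst-Braden risk category."""
    rows = []
    predictors = [WORST_BRADEN, *DIMENSIONS]
    for pred in predictors:
        res = point_biserial_by_category(
            analysis["pri"], analysis[pred], analysis["braden_worst_risk"],
            variable=pred,
        )
        for stratum, cr in res.items():
            rows.append(
                {"predictor": pred, "stratum": stratum, "n": cr.n,
                 "r": cr.r, "p_value": cr.p_value}
            )
    return pd.DataFrame(rows)


def run_pipeline(config, out_dir=None) -> Path:
    """Run the whole workflow; returns the output directory.

    ``config`` is a mapping or a YAML file path with keys: ``data_dir`` (a
    cohort directory) or ``simulate`` (SimulationConfig overrides), optional
    ``catalog`` (path), ``seed`` (required), optional ``period_end`` and
    ``out_dir``.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        with open(config_path, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    if "seed" not in config:
        raise PipelineError("config stage: a seed is required")
    seed = int(config["seed"])
    out = Path(out_dir or config.get("out_dir") or "nhsi_output")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"seed": seed, "inputs": {}, "outputs": {}}
    try:
        manifest["software_version"] = metadata.version("nhsi")
    except metadata.PackageNotFoundError:  # pragma: no cover
        manifest["software_version"] = "unknown"

    # stage: catalog
    try:
        if config.get("catalog"):
            catalog = load_catalog(config["catalog"])
            manifest["inputs"]["catalog"] = _sha256(Path(config["catalog"]))
        else:
            catalog = default_catalog()
        manifest["catalog_version"] = catalog.version
    except Exception as err:
        raise PipelineError(f"catalog stage: {err}") from err

    # stage: load or simulate
    try:
        if config.get("data_dir"):
            data_dir = Path(config["data_dir"])
            records, reports = cohort_io.load_cohort(data_dir, catalog=catalog)
            for name, rep in reports.items():
                manifest["inputs"][name] = {
                    "sha256": _sha256(data_dir / name),
                    "rows_read": rep.rows_read,
                    "rows_used": rep.rows_used,
                    "rows_rejected": rep.rows_rejected,
                }
                log.info(
                    "%s: read %d used %d rejected %d",
                    name, rep.rows_read, rep.rows_used, rep.rows_rejected,
                )
        else:
            sim_over = dict(config.get("simulate") or {})
            sim_over.setdefault("seed", seed)
            sim_cfg = SimulationConfig(**sim_over)
            records, truth = simulate_cohort(sim_cfg, catalog=catalog)
            sim_dir = out / "simulated_cohort"
            export_cohort(records, sim_dir, ground_truth=truth, config=sim_cfg)
            manifest["inputs"]["simulated"] = {
                "seed": sim_cfg.seed, "n_residents": sim_cfg.n_residents
            }
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"load stage: {err}") from err

    period_end = None
    if config.get("period_end"):
        period_end = dt.date.fromisoformat(str(config["period_end"]))

    # stage: score + analysis table
    try:
        scorer = SeverityScorer(catalog=catalog, period_end=period_end)
        cohort_scores = scorer.fit(records).score(records)
        cohort_scores.scores.to_csv(out / "dimension_scores.csv")
        cohort_scores.audit.to_csv(out / "audit_trail.csv", index=False)
        analysis, rejections = build_analysis_table(
            records, catalog=catalog, period_end=period_end
        )
        analysis.to_csv(out / "analysis_table.csv", index=False)
        pd.DataFrame(
            rejections, columns=["resident_id", "reason"]
        ).to_csv(out / "rejected_residents.csv", index=False)
        log.info(
            "score stage: %d residents scored, %d rejected",
            len(analysis), len(rejections),
        )
    except Exception as err:
        raise PipelineError(f"score stage: {err}") from err

    # stage: descriptive tables
    try:
        t1 = table1_report(
            analysis,
            continuous=["age", "braden_first", "braden_mean", WORST_BRADEN,
                        *DIMENSIONS, "stay_days"],
            binary=["male"],
            categorical=["race_ethnicity", "bmi_cat", "braden_worst_risk"],
        )
        t1.to_csv(out / "table1.csv", index=False)
        t2 = table2_report(analysis)
        t2.to_csv(out / "table2_correlations.csv", index=False)
    except Exception as err:
        raise PipelineError(f"describe stage: {err}") from err

    # stage: propensity models
    try:
        suite = run_model_suite(analysis, seed=seed)
        coef_frames = []
        for mid, frame in suite.coefficient_tables().items():
            frame = frame.reset_index()
            frame.insert(0, "model", mid)
            coef_frames.append(frame)
        pd.concat(coef_frames, ignore_index=True).to_csv(
            out / "model_coefficients.csv", index=False
        )
        dec_rows = []
        for mid, strat in suite.deciles.items():
            t = strat.decile_table.copy()
            t.insert(0, "model", mid)
            dec_rows.append(t)
        pd.concat(dec_rows, ignore_index=True).to_csv(
            out / "deciles.csv", index=False
        )
        summary = {
            "c_statistics": suite.c_statistics,
            "lr_model3_vs_model1": {
                "chi_square": suite.lr_model3_vs_model1[0],
                "df": suite.lr_model3_vs_model1[1],
                "p_value": suite.lr_model3_vs_model1[2],
            },
            "delta_c_model2_vs_model1": suite.delta_c_model2_vs_model1,
            "delta_c_caveat": suite.delta_c_caveat,
            "pct_improvement_model2": suite.pct_improvement_model2,
            "pct_improvement_model3": suite.pct_improvement_model3,
            "top3_capture": {
                mid: {
                    "count": strat.top3_capture_count,
                    "percent": strat.top3_capture_percent,
                }
                for mid, strat in suite.deciles.items()
            },
            "split": {
                "sizes": suite.split_sizes,
                "c_statistics": suite.split_c_statistics,
            },
            "seed": seed,
        }
        (out / "model_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
        )
    except Exception as err:
        raise PipelineError(f"model stage: {err}") from err

    # stage: manifest
    for f in sorted(out.glob("*.csv")) + [out / "model_summary.json"]:
        manifest["outputs"][f.name] = _sha256(f)
    manifest["timestamp"] = dt.datetime.now(dt.timezone.utc).isoformat()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return out
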