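"""End-to-end orchestration: simulate -> harmonize -> label -> train -> audit.

One master seed fans out to per-stage seeds through a seed sequence, so the
whole run is reproducible while each stage's randomness stays independent.
Every stage writes its artifact (CSV/JSON) plus a manifest recording config
hashes, seeds, package version and file digests; rerunning with the same
config and seed reproduces identical artifacts (timestamps live only in the
manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .classifier import (
    TrainingProtocol,
    cross_fit_probabilities,
    evaluate,
    feature_attribution,
    split_patient_stratified,
    tune_and_fit,
)
from .cohort import CohortConfig, generate_cohort, read_cohort_csv, write_cohort_csv
from .equity import AuditConfig, build_intersectional_groups, decisions_from_probs, run_full_audit
from .errors import StageError
from .harmonize import harmonize_table
from .labeling import CodeLists, label_table

log = logging.getLogger("utiaudit")


class MasterConfig(BaseModel):
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    protocol: TrainingProtocol = Field(default_factory=TrainingProtocol)
    audit: AuditConfig = Field(default_factory=AuditConfig)
    seed: int = 0


def demo_config(seed: int = 1) -> MasterConfig:
    """Scaled-down demonstration run (~30k encounters, small tuning budget).

    The audit group-size floor scales with the cohort so the intersectional
    structure (about twenty audit cells, dominated by larger cells and
    excluding the smallest intersections) matches what a full-size cohort
    produces at a floor of 2000.
    """
    cfg = MasterConfig(seed=seed)
    cfg.protocol = TrainingProtocol(
        n_trials=8,
        search_space={
            "max_depth": (2, 6),
            "n_estimators": (50, 300),
        },
    )
    cfg.audit = AuditConfig(min_group_size=400)
    return cfg


def derive_stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from the master seed (all < 2**31)."""
    state = np.random.SeedSequence(master_seed).generate_state(3)
    names = ("cohort", "protocol", "evaluation")
    return {name: int(s & 0x7FFFFFFF) for name, s in zip(names, state)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonify(obj):
    """Make numpy scalars JSON-clean and map NaN to null."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(float(obj)) else float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(_jsonify(payload), indent=1, sort_keys=True) + "\n")


def threshold_scan_table(probs, truth, thresholds) -> pd.DataFrame:
    """Overall model FPR/FNR at each candidate integer-percent threshold."""
    t_arr = np.asarray(truth, dtype=bool)
    rows = []
    for t in sorted(thresholds):
        d = decisions_from_probs(np.asarray(probs, float), t / 100.0)
        rows.append({
            "threshold_pct": t,
            "fpr": float(d[~t_arr].mean()),
            "fnr": float((~d[t_arr]).mean()),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: MasterConfig, outdir: str | Path) -> dict:
    """Run every stage and write artifacts + manifest under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    manifest = {
        "package_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "artifacts": {},
    }

    def _record(name: str, path: Path):
        manifest["artifacts"][name] = {"path": path.name, "sha256": _sha256(path)}

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        cohort_cfg = config.cohort.model_copy(update={"seed": seeds["cohort"]})
        log.info("stage=%s seed=%d n=%d", stage, cohort_cfg.seed, cohort_cfg.n_encounters)
        cohort = generate_cohort(cohort_cfg)
        cohort_path = outdir / "cohort.csv"
        write_cohort_csv(cohort, cohort_path)
        _record("cohort", cohort_path)
    except Exception as err:  # noqa: BLE001 - stage context is the contract
        raise StageError(stage, str(err)) from err

    # ---- harmonize + label ---------------------------------------------
    stage = "harmonize_label"
    try:
        labeled = label_table(harmonize_table(cohort, log=log), CodeLists.default())
        labeled_path = outdir / "labeled.csv"
        labeled.to_csv(labeled_path, index=False)
        _record("labeled", labeled_path)
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err

    # ---- train ----------------------------------------------------------
    stage = "train"
    try:
        protocol = config.protocol.model_copy(update={"seed": seeds["protocol"]})
        train_df, test_df = split_patient_stratified(labeled, protocol)
        fitted = tune_and_fit(train_df, protocol, log=log)
        test_metrics = evaluate(fitted.predict_proba(test_df), test_df, seed=seeds["evaluation"])
        probs = cross_fit_probabilities(labeled, fitted.params, protocol)
        groups = build_intersectional_groups(labeled, config.audit)
        cohort_metrics = evaluate(
            probs, labeled,
            groups=[(g.label, g.indices) for g in groups],
            seed=seeds["evaluation"],
        )
        attribution = feature_attribution(fitted, labeled)
        metrics = {
            "tuned": fitted.tuned,
            "best_params": fitted.params,
            "best_cv_auroc": fitted.best_cv_auroc,
            "trials": fitted.trials,
            "test": {k: v for k, v in test_metrics.items() if k != "calibration"},
            "cohort_cross_fit": {
                k: v for k, v in cohort_metrics.items() if k != "calibration"
            },
            "attribution_ranking": attribution.summary.to_dict(orient="records"),
        }
        write_json(metrics, outdir / "model_metrics.json")
        cohort_metrics["calibration"].to_csv(outdir / "calibration.csv", index=False)
        pd.DataFrame({"encounter_id": labeled["encounter_id"], "prob": probs}).to_csv(
            outdir / "probabilities.csv", index=False
        )
        _record("model_metrics", outdir / "model_metrics.json")
        _record("calibration", outdir / "calibration.csv")
        _record("probabilities", outdir / "probabilities.csv")
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err

    # ---- audit ----------------------------------------------------------
    stage = "audit"
    try:
        report = run_full_audit(labeled, probs, config.audit)
        report["model"] = {
            "auroc": cohort_metrics["auroc"],
            "pr_auc": cohort_metrics["pr_auc"],
        }
        write_json(report, outdir / "report.json")
        _record("report", outdir / "report.json")
        scan = threshold_scan_table(
            probs, labeled["liberal_uti"], config.audit.candidate_thresholds
        )
        scan.to_csv(outdir / "threshold_scan.csv", index=False)
        _record("threshold_scan", outdir / "threshold_scan.csv")
        per_group_rows = []
        for definition, section in report["definitions"].items():
            for source, payload in section["sources"].items():
                for row in payload["per_group"]:
                    per_group_rows.append({"definition": definition, "source": source, **row})
        pd.DataFrame(per_group_rows).to_csv(outdir / "per_group_metrics.csv", index=False)
        pd.DataFrame(report["decile_table"]).to_csv(outdir / "deciles.csv", index=False)
        _record("per_group_metrics", outdir / "per_group_metrics.csv")
        _record("deciles", outdir / "deciles.csv")
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    write_json(manifest, outdir / "manifest.json")
    return manifest
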