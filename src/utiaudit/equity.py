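"""Intersectional equity audit of model and physician UTI diagnosis.

Encounters are crossed into intersectional demographic cells (age bin x sex
x race x ethnicity); cells meeting a minimum size enter the audit.  For the
model (at several decision thresholds) and the rule-based physician proxy,
the audit computes per-group confusion metrics — overdiagnosis (false
positives among true negatives), underdiagnosis (false negatives among true
positives), accuracy and the diagnostic odds ratio — and summarizes equity
as the coefficient of variation of accuracy and DOR across groups, with
normal-approximation confidence intervals.

Three thresholds are examined: a *policy-constrained* operating point (the
highest integer-percent threshold at which the model's underdiagnosis rate
is below the physician's in every audit group — so no group would see more
missed diagnoses if the model replaced human judgment), an externally
reported clinician treatment threshold (42.3%), and the Youden-optimal
threshold maximizing TPR - FPR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .cohort import GROUP_AXES
from .errors import ConfigurationError, InfeasibleThresholdError


class AuditConfig(BaseModel):
    group_axes: tuple[str, ...] = GROUP_AXES
    min_group_size: int = Field(default=2000, ge=1)
    candidate_thresholds: list[int] = Field(default_factory=lambda: list(range(1, 100)))
    fixed_clinician_threshold: float = Field(default=0.423, gt=0, lt=1)
    z_quantile: float = Field(default=1.96, gt=0)
    decile_count: int = Field(default=10, ge=2)
    definitions: tuple[str, ...] = ("strict", "liberal")


@dataclass(frozen=True)
class IntersectionalGroup:
    """One demographic cell and the positional row indices of its members."""

    key: tuple
    indices: np.ndarray
    n: int

    @property
    def label(self) -> str:
        return "|".join(str(k) for k in self.key)


def build_intersectional_groups(
    encounters: pd.DataFrame, config: AuditConfig
) -> list[IntersectionalGroup]:
    """Exhaustive cross of the demographic axes, filtered to audit size.

    Cells below ``min_group_size`` are excluded from the audit (their
    encounters still count in overall metrics).  Deterministic order: size
    descending, then key lexicographically.
    """
    if len(encounters) == 0:
        return []
    axes = list(config.group_axes)
    codes = encounters.reset_index(drop=True).groupby(axes, sort=False, observed=True)
    groups = []
    for key, idx in codes.groups.items():
        key = key if isinstance(key, tuple) else (key,)
        arr = np.asarray(idx, dtype=int)
        if len(arr) >= config.min_group_size:
            groups.append(IntersectionalGroup(key=key, indices=arr, n=len(arr)))
    groups.sort(key=lambda g: (-g.n, g.key))
    return groups


def _dor(tp: int, fp: int, fn: int, tn: int) -> tuple[float, bool]:
    if tp + fp + fn + tn == 0:
        raise ConfigurationError("all-zero confusion table has no diagnostic odds ratio")
    if min(tp, fp, fn, tn) == 0:
        tp, fp, fn, tn = (x + 0.5 for x in (tp, fp, fn, tn))
        return (tp / fn) / (fp / tn), True
    return (tp / fn) / (fp / tn), False


def diagnostic_odds_ratio(tp: int, fp: int, fn: int, tn: int) -> float:
    """(TP/FN)/(FP/TN); Haldane-Anscombe 0.5 correction when any cell is 0."""
    return _dor(tp, fp, fn, tn)[0]


@dataclass(frozen=True)
class GroupMetrics:
    """Confusion-cell metrics for one group at one operating point."""

    key: tuple
    n: int
    tp: int
    fp: int
    fn: int
    tn: int
    overdiagnosis: float  # FP / (FP + TN); NaN when no true negatives
    underdiagnosis: float  # FN / (TP + FN); NaN when no true positives
    accuracy: float
    dor: float
    dor_corrected: bool

    @classmethod
    def from_decisions(cls, key, decisions, truth) -> "GroupMetrics":
        d = np.asarray(decisions, dtype=bool)
        t = np.asarray(truth, dtype=bool)
        tp = int((d & t).sum())
        fp = int((d & ~t).sum())
        fn = int((~d & t).sum())
        tn = int((~d & ~t).sum())
        n = tp + fp + fn + tn
        over = fp / (fp + tn) if fp + tn > 0 else float("nan")
        under = fn / (tp + fn) if tp + fn > 0 else float("nan")
        dor, corrected = _dor(tp, fp, fn, tn) if n > 0 else (float("nan"), False)
        return cls(
            key=tuple(key), n=n, tp=tp, fp=fp, fn=fn, tn=tn,
            overdiagnosis=over, underdiagnosis=under,
            accuracy=(tp + tn) / n if n else float("nan"),
            dor=dor, dor_corrected=corrected,
        )

    def to_dict(self) -> dict:
        return {
            "group": "|".join(str(k) for k in self.key),
            "n": self.n, "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "overdiagnosis": self.overdiagnosis, "underdiagnosis": self.underdiagnosis,
            "accuracy": self.accuracy, "dor": self.dor,
            "dor_corrected": self.dor_corrected,
        }


def decisions_from_probs(probs, threshold: float) -> np.ndarray:
    """Classification rule: probability >= threshold => positive."""
    return np.asarray(probs, dtype=float) >= threshold


def confusion_at_threshold(
    predictions,
    truth,
    threshold: Optional[float] = None,
    groups: Optional[Sequence[IntersectionalGroup]] = None,
) -> dict:
    """Per-group and overall confusion metrics at one operating point.

    ``predictions`` is either a probability vector (then ``threshold`` is
    applied as ``p >= threshold``) or already-binary decisions (physician
    proxy; ``threshold`` ignored).  Overall metrics cover *all* rows,
    including encounters in sub-threshold cells.
    """
    pred = np.asarray(predictions)
    if threshold is not None and pred.dtype != bool:
        decisions = decisions_from_probs(pred, threshold)
    else:
        decisions = pred.astype(bool)
    t = np.asarray(truth, dtype=bool)
    result = {"overall": GroupMetrics.from_decisions(("overall",), decisions, t)}
    if groups is not None:
        result["groups"] = {
            g.key: GroupMetrics.from_decisions(g.key, decisions[g.indices], t[g.indices])
            for g in groups
        }
    return result


def select_policy_constrained_threshold(
    model_probs,
    truth,
    physician_decisions,
    groups: Sequence[IntersectionalGroup],
    config: AuditConfig,
) -> int:
    """Highest integer-percent threshold with model FNR below the physician's
    in every audit group.

    Scans the candidate grid downward from the top; returns the first
    (highest) threshold satisfying the strict inequality in all groups.
    Groups where the physician FNR is undefined (no positives) are vacuous.
    Raises :class:`InfeasibleThresholdError` if even the lowest candidate
    fails, listing the violating groups there.
    """
    if not groups:
        raise ConfigurationError("policy threshold needs at least one audit group")
    probs = np.asarray(model_probs, dtype=float)
    t_arr = np.asarray(truth, dtype=bool)
    phys = np.asarray(physician_decisions, dtype=bool)

    phys_fnr = {}
    for g in groups:
        tg = t_arr[g.indices]
        if tg.any():
            phys_fnr[g.key] = float((~phys[g.indices][tg]).mean())
    candidates = sorted(config.candidate_thresholds, reverse=True)
    violating: list = []
    for t in candidates:
        decisions = decisions_from_probs(probs, t / 100.0)
        violating = []
        for g in groups:
            if g.key not in phys_fnr:
                continue
            tg = t_arr[g.indices]
            model_fnr = float((~decisions[g.indices][tg]).mean())
            if not model_fnr < phys_fnr[g.key]:
                violating.append(g.key)
        if not violating:
            return int(t)
    raise InfeasibleThresholdError(
        f"no candidate threshold keeps model underdiagnosis below the "
        f"physician's in every audit group; at threshold {candidates[-1]} the "
        f"violating groups are {violating}",
        violating_groups=violating,
    )


def youden_optimal_threshold(model_probs, truth, candidate_thresholds) -> int:
    """Integer-percent threshold maximizing Youden's J = TPR - FPR.

    Ties are broken toward the lowest threshold (favoring sensitivity).
    """
    probs = np.asarray(model_probs, dtype=float)
    t_arr = np.asarray(truth, dtype=bool)
    if not t_arr.any() or t_arr.all():
        raise ConfigurationError("both classes must be present to pick a Youden threshold")
    best_t, best_j = None, -np.inf
    for t in sorted(candidate_thresholds):
        d = decisions_from_probs(probs, t / 100.0)
        tpr = float(d[t_arr].mean())
        fpr = float(d[~t_arr].mean())
        j = tpr - fpr
        if j > best_j:
            best_t, best_j = int(t), j
    return best_t


@dataclass(frozen=True)
class CvEstimate:
    """Coefficient of variation across groups, with its normal-approx CI."""

    metric: str
    cv: float
    n_groups: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "metric": self.metric, "cv": self.cv, "n_groups": self.n_groups,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


def coefficient_of_variation(values, metric: str = "") -> CvEstimate:
    """Sample SD (n-1 denominator) over mean, across group metric values."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ConfigurationError("coefficient of variation needs at least 2 values")
    mean = float(vals.mean())
    if mean <= 0:
        raise ConfigurationError(f"coefficient of variation undefined for mean {mean} <= 0")
    return CvEstimate(metric=metric, cv=float(vals.std(ddof=1)) / mean, n_groups=len(vals))


def cv_confidence_interval(cv: float, n_groups: int, z_quantile: float = 1.96) -> tuple[float, float]:
    """Normal-approximation CI: cv +/- z / sqrt(2(k-1)), floored at 0."""
    if n_groups < 2:
        raise ConfigurationError("CV confidence interval needs >=2 groups")
    half = z_quantile * math.sqrt(1.0 / (2.0 * (n_groups - 1)))
    return max(0.0, cv - half), cv + half


def cv_with_ci(values, metric: str, z_quantile: float = 1.96) -> CvEstimate:
    point = coefficient_of_variation(values, metric)
    lo, hi = cv_confidence_interval(point.cv, point.n_groups, z_quantile)
    return CvEstimate(metric=metric, cv=point.cv, n_groups=point.n_groups,
                      ci_low=lo, ci_high=hi)


def decile_diagnosis_table(
    model_probs, physician_decisions, truth=None, n_deciles: int = 10
) -> pd.DataFrame:
    """Physician diagnosis rate per decile of model-predicted probability.

    Deciles are equal-count bins by rank of the predicted probability.  The
    physician's effective decision threshold shows up as the decile at which
    the diagnosis rate ramps; observed culture positivity per decile (when
    ``truth`` is given) reads as an empirical calibration check.
    """
    probs = np.asarray(model_probs, dtype=float)
    if len(probs) < n_deciles:
        raise ConfigurationError(f"need at least {n_deciles} observations for deciles")
    phys = np.asarray(physician_decisions, dtype=bool)
    order = np.argsort(probs, kind="stable")
    rank = np.empty(len(probs), dtype=int)
    rank[order] = np.arange(len(probs))
    decile = (rank * n_deciles) // len(probs)
    rows = []
    for d in range(n_deciles):
        mask = decile == d
        row = {
            "decile": d + 1,
            "n": int(mask.sum()),
            "prob_min": float(probs[mask].min()),
            "prob_max": float(probs[mask].max()),
            "physician_dx_rate": float(phys[mask].mean()),
        }
        if truth is not None:
            row["culture_positive_rate"] = float(np.asarray(truth, dtype=bool)[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _source_report(decisions, truth, groups, config: AuditConfig, threshold=None) -> dict:
    res = confusion_at_threshold(decisions, truth, threshold=threshold, groups=groups)
    per_group = [m.to_dict() for m in res["groups"].values()]
    acc = [m["accuracy"] for m in per_group]
    dor = [m["dor"] for m in per_group]
    out = {
        "threshold": threshold,
        "overall": res["overall"].to_dict(),
        "per_group": per_group,
    }
    if len(per_group) >= 2:
        out["cv"] = {
            "accuracy": cv_with_ci(acc, "accuracy", config.z_quantile).to_dict(),
            "dor": cv_with_ci(dor, "dor", config.z_quantile).to_dict(),
        }
    return out


def run_full_audit(
    encounters: pd.DataFrame,
    model_probs,
    config: AuditConfig | None = None,
) -> dict:
    """Assemble the full equity report for model and physician.

    For each requested UTI definition the report carries per-group and
    overall metrics for the model at the policy-constrained, fixed-clinician
    (42.3%) and Youden thresholds and for the physician proxy, plus CV
    estimates for accuracy and DOR, the selected thresholds, and the decile
    table of physician diagnosis rates by model-predicted probability.

    Under the strict definition the model's diagnosis combines the
    culture-positivity probability with the binary symptom rule (an
    encounter without any UTI sign or symptom is never called UTI); this is
    applied by zeroing the probability for asymptomatic encounters before
    thresholding.
    """
    config = config or AuditConfig()
    probs = np.asarray(model_probs, dtype=float)
    if len(probs) != len(encounters):
        raise ConfigurationError("model_probs length must match encounter table")
    groups = build_intersectional_groups(encounters, config)
    phys = encounters["physician_diagnosed"].to_numpy(dtype=bool)
    report: dict = {
        "metadata": {
            "cv_ci_formula": "cv +/- z*sqrt(1/(2*(n_groups-1))), lower bound floored at 0",
            "youden_tie_break": "ties broken toward the lowest threshold",
            "attribution": "tree-path additive contributions (TreeSHAP)",
            "min_group_size": config.min_group_size,
            "fixed_clinician_threshold": config.fixed_clinician_threshold,
            "definitions_included": list(config.definitions),
            "definitions_omitted": [d for d in ("strict", "liberal")
                                    if d not in config.definitions],
        },
        "n_encounters": int(len(encounters)),
        "n_audit_groups": len(groups),
        "audit_groups": [{"group": g.label, "n": g.n} for g in groups],
        "definitions": {},
    }
    for definition in config.definitions:
        truth = encounters[f"{definition}_uti"].to_numpy(dtype=bool)
        if definition == "strict":
            eff_probs = probs * encounters["any_symptom"].to_numpy(dtype=bool)
        else:
            eff_probs = probs
        policy_t = select_policy_constrained_threshold(eff_probs, truth, phys, groups, config)
        youden_t = youden_optimal_threshold(eff_probs, truth, config.candidate_thresholds)
        section = {
            "thresholds": {
                "policy_constrained_pct": policy_t,
                "youden_pct": youden_t,
                "fixed_clinician": config.fixed_clinician_threshold,
            },
            "sources": {
                "model_policy": _source_report(eff_probs, truth, groups, config, policy_t / 100.0),
                "model_fixed_clinician": _source_report(
                    eff_probs, truth, groups, config, config.fixed_clinician_threshold),
                "model_youden": _source_report(eff_probs, truth, groups, config, youden_t / 100.0),
                "physician": _source_report(phys, truth, groups, config, None),
            },
        }
        report["definitions"][definition] = section
    report["decile_table"] = decile_diagnosis_table(
        probs, phys,
        truth=encounters["liberal_uti"].to_numpy(dtype=bool),
        n_deciles=config.decile_count,
    ).to_dict(orient="records")
    return report
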