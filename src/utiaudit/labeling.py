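"""Outcome labels: culture positivity, strict/liberal UTI, physician proxy.

Three labels drive every downstream analysis:

* **culture_positive** — the urine culture grew >=10,000 CFU/mL of a
  pathogenic organism (the laboratory reporting cutoff used here; growth of
  skin or vaginal flora at any count does not qualify).
* **strict_uti / liberal_uti** — strict requires culture positivity AND at
  least one documented UTI sign or symptom, distinguishing true infection
  from asymptomatic bacteriuria; liberal is culture positivity alone.
* **physician_diagnosed** — a rule-based composite proxy for the treating
  physician's diagnosis: an explicit UTI diagnosis code, or else a
  UTI-relevant antibiotic prescription together with a nonspecific
  UTI-attributable diagnosis and no alternative infectious diagnosis that
  would explain the antibiotic.

Code lists (organisms, diagnoses, antibiotics) ship as a JSON resource and
are override-able; matching is exact on case-folded, trimmed labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import ConfigurationError

CFU_THRESHOLD = 10_000

SYMPTOM_COLUMNS = (
    "sym_likely_uti_symptom",
    "sym_uti_exam_finding",
    "sym_systemic",
)

ProxyBranch = Literal["explicit", "inferred", "none"]


def _norm(label: str) -> str:
    return " ".join(str(label).casefold().split())


def _norm_set(labels: Iterable[str]) -> frozenset[str]:
    return frozenset(_norm(x) for x in labels)


@dataclass(frozen=True)
class CodeLists:
    """Normalized code sets used by the labeling rules."""

    pathogenic_organisms: frozenset[str]
    uti_explicit_dx: frozenset[str]
    uti_relevant_antibiotics: frozenset[str]
    nonspecific_uti_attributable_dx: frozenset[str]
    alternative_infectious_dx: frozenset[str]
    version: str = "?"

    def __post_init__(self) -> None:
        for name in (
            "pathogenic_organisms",
            "uti_explicit_dx",
            "uti_relevant_antibiotics",
            "nonspecific_uti_attributable_dx",
            "alternative_infectious_dx",
        ):
            if not getattr(self, name):
                raise ConfigurationError(f"code list {name!r} is empty")
        overlap = self.uti_explicit_dx & self.alternative_infectious_dx
        if overlap:
            raise ConfigurationError(
                f"uti_explicit_dx and alternative_infectious_dx overlap: {sorted(overlap)}"
            )

    @classmethod
    def from_dict(cls, payload: dict) -> "CodeLists":
        return cls(
            pathogenic_organisms=_norm_set(payload["pathogenic_organisms"]),
            uti_explicit_dx=_norm_set(payload["uti_explicit_dx"]),
            uti_relevant_antibiotics=_norm_set(payload["uti_relevant_antibiotics"]),
            nonspecific_uti_attributable_dx=_norm_set(
                payload["nonspecific_uti_attributable_dx"]
            ),
            alternative_infectious_dx=_norm_set(payload["alternative_infectious_dx"]),
            version=str(payload.get("version", "?")),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CodeLists":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "CodeLists":
        ref = _ilres.files("utiaudit.resources").joinpath("code_lists.json")
        return cls.from_dict(json.loads(ref.read_text()))


def call_culture_positive(
    organism, cfu_per_ml, code_lists: CodeLists
) -> bool:
    """True iff the culture grew >=10,000 CFU/mL of a pathogenic organism."""
    if organism is None or (isinstance(organism, float)) or str(organism).strip() == "":
        return False
    if cfu_per_ml < 0:
        raise ConfigurationError(f"cfu_per_ml must be non-negative, got {cfu_per_ml}")
    return _norm(organism) in code_lists.pathogenic_organisms and cfu_per_ml >= CFU_THRESHOLD


def label_uti(
    culture_positive: bool,
    symptom_flags: Iterable[bool],
    definition: Literal["strict", "liberal"],
) -> bool:
    """Apply the strict (culture + symptom) or liberal (culture-only) rule."""
    if definition == "strict":
        return bool(culture_positive) and any(bool(f) for f in symptom_flags)
    if definition == "liberal":
        return bool(culture_positive)
    raise ConfigurationError(f"unknown UTI definition {definition!r}")


def infer_physician_diagnosis(
    explicit_dx_codes: Iterable[str],
    antibiotic_rx: Iterable[str],
    other_dx_codes: Iterable[str],
    code_lists: CodeLists,
) -> tuple[bool, ProxyBranch]:
    """Composite proxy for the physician's UTI diagnosis.

    Branch ``explicit``: any explicit UTI diagnosis code.  Branch
    ``inferred``: a UTI-relevant antibiotic AND a nonspecific UTI-attributable
    diagnosis AND no alternative infectious diagnosis.  Otherwise ``none``.
    """
    explicit = _norm_set(explicit_dx_codes)
    if explicit & code_lists.uti_explicit_dx:
        return True, "explicit"
    abx = _norm_set(antibiotic_rx)
    other = _norm_set(other_dx_codes)
    if (
        abx & code_lists.uti_relevant_antibiotics
        and other & code_lists.nonspecific_uti_attributable_dx
        and not other & code_lists.alternative_infectious_dx
    ):
        return True, "inferred"
    return False, "none"


def split_codes(cell) -> list[str]:
    """Parse a semicolon-joined code cell from CSV into a list."""
    if cell is None or (isinstance(cell, float)) or str(cell).strip() == "":
        return []
    return [part.strip() for part in str(cell).split(";") if part.strip()]


def label_table(
    encounters: pd.DataFrame, code_lists: CodeLists | None = None
) -> pd.DataFrame:
    """Append the outcome label columns to an encounter table.

    Adds ``culture_positive``, ``strict_uti``, ``liberal_uti``,
    ``any_symptom``, ``physician_diagnosed`` and ``proxy_branch``.  Code-list
    columns may hold either python lists or semicolon-joined strings (the
    CSV round-trip form).
    """
    code_lists = code_lists or CodeLists.default()
    out = encounters.copy()

    def _as_list(cell):
        return cell if isinstance(cell, (list, tuple)) else split_codes(cell)

    organisms = out["culture_organism"]
    cfus = out["culture_cfu_per_ml"]
    out["culture_positive"] = [
        call_culture_positive(org, int(cfu), code_lists)
        for org, cfu in zip(organisms, cfus)
    ]
    present = [c for c in SYMPTOM_COLUMNS if c in out.columns]
    if not present:
        raise ConfigurationError("no symptom flag columns found")
    flags = out[present].astype(bool)
    out["any_symptom"] = flags.any(axis=1)
    out["strict_uti"] = out["culture_positive"] & out["any_symptom"]
    out["liberal_uti"] = out["culture_positive"]

    diagnosed, branch = [], []
    for exp, abx, other in zip(
        out["explicit_dx_codes"], out["antibiotic_rx"], out["other_dx_codes"]
    ):
        d, b = infer_physician_diagnosis(
            _as_list(exp), _as_list(abx), _as_list(other), code_lists
        )
        diagnosed.append(d)
        branch.append(b)
    out["physician_diagnosed"] = diagnosed
    out["proxy_branch"] = branch
    return out
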