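"""Synthetic ED encounter cohort with known ground truth.

Real urinalysis/urine-culture cohorts are not publicly shareable, so every
downstream stage here is exercised on simulated encounters whose generative
truth is recorded per row.  The generator emulates the structure of a large
multi-site ED cohort: ~15% urine-culture positivity, UTI symptoms common in
both culture-positive (~89%) and culture-negative (~86%) visits, urinalysis
components statistically coupled to culture status through a latent
infection intensity, demographics drawn from a configurable mix of
intersectional cells with unequal sizes, and a simulated physician whose
diagnostic sensitivity and false-positive rate are configurable per group.

The latent-intensity model: each encounter draws a culture status
``C ~ Bernoulli(p)`` and an intensity ``z = mu*C + N(0,1)``.  Component
``c`` with signal strength ``s_c`` observes ``x_c = s_c*z +
sqrt(1-s_c^2)*N(0,1)`` and bins it through fixed monotone cutpoints into its
ordinal levels, so stronger signal means cleaner monotone coupling (and a
monotone model response).  The simulated physician acts on the latent strict
truth with the configured sensitivity/FPR and then *emits* either an
explicit UTI diagnosis code or an antibiotic-plus-nonspecific-diagnosis
combination, so both branches of the diagnosis proxy rule are exercised and
the proxy recovers the physician's intent exactly.

Four independent RNG streams (demographics, biology, physician, reporting)
are derived from the single seed, so perturbing one block of parameters
leaves the other draws unchanged.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import harmonize
from .errors import ConfigurationError
from .harmonize import COMPONENTS, DIALECTS, ScaleMap, default_scale_map

AGE_BINS = ("18-44", "45-64", "65-84", "85+")
AGE_RANGES = {"18-44": (18, 45), "45-64": (45, 65), "65-84": (65, 85), "85+": (85, 100)}
SEXES = ("female", "male")
RACES = (
    "white",
    "black",
    "other or not listed",
    "asian",
    "american indian or alaska native",
    "native hawaiian or pacific islander",
    "unknown or declined",
)
ETHNICITIES = ("hispanic", "non-hispanic", "unknown")

GROUP_AXES = ("age_bin", "sex", "race", "ethnicity")

_PATHOGENS = (
    ("escherichia coli", 0.62),
    ("klebsiella pneumoniae", 0.12),
    ("enterococcus faecalis", 0.08),
    ("proteus mirabilis", 0.06),
    ("streptococcus agalactiae", 0.04),
    ("pseudomonas aeruginosa", 0.03),
    ("citrobacter freundii", 0.02),
    ("staphylococcus saprophyticus", 0.02),
    ("serratia marcescens", 0.01),
)
_CONTAMINANTS = (
    "lactobacillus species",
    "corynebacterium species",
    "staphylococcus epidermidis",
    "mixed skin flora",
)
_EXPLICIT_DX = ("urinary tract infection", "cystitis", "pyelonephritis")
_UTI_ABX = ("nitrofurantoin", "cephalexin", "ciprofloxacin", "trimethoprim-sulfamethoxazole")
_NONSPECIFIC_DX = ("dysuria", "urinary frequency", "abdominal pain", "flank pain")
_ALTERNATIVE_DX = ("pneumonia", "cellulitis", "pharyngitis")

#: monotone cutpoints binning the latent component score into 4 ordinal levels
_CUTPOINTS_4 = (0.75, 1.5, 2.25)
#: single cutpoint for the binary nitrite assay
_CUTPOINT_NITRITE = 1.6

DEFAULT_URINALYSIS_SIGNAL = {
    "blood": 0.35,
    "glucose": 0.05,
    "ketones": 0.05,
    "leukocyte_esterase": 0.80,
    "nitrites": 0.80,
    "protein": 0.30,
    "bacteria": 0.85,
    "epithelial_cells": 0.25,
    "white_blood_cells": 0.80,
}


def group_key(age_bin: str, sex: str, race: str, ethnicity: str) -> str:
    """Canonical string key for an intersectional demographic cell."""
    return f"{age_bin}|{sex}|{race}|{ethnicity}"


class DemographicCell(BaseModel):
    age_bin: str
    sex: str
    race: str
    ethnicity: str
    weight: float = Field(gt=0)

    @field_validator("age_bin")
    @classmethod
    def _age(cls, v):
        if v not in AGE_BINS:
            raise ValueError(f"age_bin must be one of {AGE_BINS}")
        return v

    @field_validator("sex")
    @classmethod
    def _sex(cls, v):
        if v not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        return v


def default_demographic_mix() -> list[DemographicCell]:
    """Independent product of realistic ED marginals (age x sex x race x ethnicity)."""
    age_w = dict(zip(AGE_BINS, (0.463, 0.257, 0.197, 0.084)))
    sex_w = {"female": 0.712, "male": 0.288}
    race_w = dict(zip(RACES, (0.562, 0.221, 0.185, 0.015, 0.003, 0.003, 0.010)))
    eth_w = dict(zip(ETHNICITIES, (0.256, 0.739, 0.005)))
    cells = []
    for a, wa in age_w.items():
        for s, ws in sex_w.items():
            for r, wr in race_w.items():
                for e, we in eth_w.items():
                    cells.append(
                        DemographicCell(
                            age_bin=a, sex=s, race=r, ethnicity=e,
                            weight=wa * ws * wr * we,
                        )
                    )
    return cells


class PhysicianBehavior(BaseModel):
    """Simulated physician decision model, configurable per demographic cell.

    ``sensitivity`` and ``false_positive_rate`` act on the latent strict-UTI
    truth; ``group_overrides`` maps :func:`group_key` strings to
    ``(sensitivity, false_positive_rate)`` pairs.  ``explicit_share`` is the
    fraction of diagnoses emitted as an explicit UTI code (the rest go out as
    antibiotic + nonspecific diagnosis, the proxy's inferred branch).
    """

    sensitivity: float = Field(default=0.634, ge=0, le=1)
    false_positive_rate: float = Field(default=0.091, ge=0, le=1)
    explicit_share: float = Field(default=0.92, ge=0, le=1)
    group_overrides: dict[str, tuple[float, float]] = Field(default_factory=dict)

    @field_validator("group_overrides")
    @classmethod
    def _overrides(cls, v):
        for key, (sens, fpr) in v.items():
            if not (0 <= sens <= 1 and 0 <= fpr <= 1):
                raise ValueError(f"group_overrides[{key!r}] rates must be in [0,1]")
        return v


class CohortConfig(BaseModel):
    """Generative conditions for one synthetic cohort."""

    n_encounters: int = Field(default=30_000, gt=0)
    n_patients: int = Field(default=24_000, gt=0)
    culture_positive_prevalence: float = Field(default=0.151, ge=0, le=1)
    symptom_rate_given_positive: float = Field(default=0.892, ge=0, le=1)
    symptom_rate_given_negative: float = Field(default=0.863, ge=0, le=1)
    demographic_mix: Optional[list[DemographicCell]] = None
    n_sites: int = Field(default=9, gt=0)
    physician_behavior: PhysicianBehavior = Field(default_factory=PhysicianBehavior)
    urinalysis_signal: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_URINALYSIS_SIGNAL)
    )
    latent_separation: float = Field(default=2.2, ge=0)
    missing_rate: float = Field(default=0.02, ge=0, le=1)
    dialect_mix: dict[str, float] = Field(
        default_factory=lambda: {"qualitative": 0.4, "semiquantitative": 0.4, "quantitative": 0.2}
    )
    seed: int = 0

    @field_validator("urinalysis_signal")
    @classmethod
    def _signal(cls, v):
        unknown = set(v) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"urinalysis_signal has unknown components {sorted(unknown)}")
        for comp, s in v.items():
            if not 0 <= s <= 1:
                raise ValueError(f"urinalysis_signal[{comp!r}] must be in [0,1]")
        full = dict(DEFAULT_URINALYSIS_SIGNAL)
        full.update(v)
        return full

    @field_validator("dialect_mix")
    @classmethod
    def _dialects(cls, v):
        unknown = set(v) - set(DIALECTS)
        if unknown:
            raise ValueError(f"dialect_mix has unknown dialects {sorted(unknown)}")
        total = sum(v.values())
        if total <= 0 or any(p < 0 for p in v.values()):
            raise ValueError("dialect_mix proportions must be non-negative with positive sum")
        return {d: p / total for d, p in v.items()}

    @model_validator(mode="after")
    def _consistent(self):
        if self.n_patients > self.n_encounters:
            raise ValueError("n_patients must not exceed n_encounters")
        return self

    def normalized_mix(self) -> list[DemographicCell]:
        mix = self.demographic_mix or default_demographic_mix()
        total = sum(c.weight for c in mix)
        return [c.model_copy(update={"weight": c.weight / total}) for c in mix]


def _streams(seed: int):
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.Generator(np.random.PCG64(c)) for c in children)


def render_raw_urinalysis(
    ordinal_level: int, dialect: str, component: str, scale_map: ScaleMap | None = None
) -> str:
    """Render an ordinal level into a raw reporting-dialect string."""
    return harmonize.render_raw_urinalysis(ordinal_level, dialect, component, scale_map)


def _weighted_choice(rng, options, weights, size):
    w = np.asarray(weights, dtype=float)
    return rng.choice(len(options), size=size, p=w / w.sum())


def generate_cohort(config: CohortConfig, scale_map: ScaleMap | None = None) -> pd.DataFrame:
    """Generate one encounter table under the configured conditions.

    Returns a DataFrame with one row per encounter: demographics, site and
    reporting dialect, raw urinalysis strings, culture result, symptom
    flags, physician actions (codes/prescriptions) and the latent ground
    truth columns (``latent_*``, ``physician_intent``) that only a synthetic
    cohort can provide.  Identical config and seed give byte-identical
    tables.
    """
    scale_map = scale_map or default_scale_map()
    rng_demo, rng_bio, rng_phys, rng_rep = _streams(config.seed)
    n = config.n_encounters
    n_pat = config.n_patients

    # ---- demographics (patient level) ----------------------------------
    mix = config.normalized_mix()
    cell_idx = _weighted_choice(rng_demo, mix, [c.weight for c in mix], n_pat)
    pat_age_bin = np.array([mix[i].age_bin for i in cell_idx])
    pat_sex = np.array([mix[i].sex for i in cell_idx])
    pat_race = np.array([mix[i].race for i in cell_idx])
    pat_eth = np.array([mix[i].ethnicity for i in cell_idx])
    lo = np.array([AGE_RANGES[b][0] for b in pat_age_bin])
    hi = np.array([AGE_RANGES[b][1] for b in pat_age_bin])
    pat_age = rng_demo.integers(lo, hi)

    # every patient owns >=1 encounter; extras are assigned uniformly
    patient_of = np.concatenate([np.arange(n_pat), rng_demo.integers(0, n_pat, n - n_pat)])
    rng_demo.shuffle(patient_of)
    site_id = rng_demo.integers(0, config.n_sites, n)
    dialect_names = sorted(config.dialect_mix)
    site_dialect = np.array(dialect_names)[
        _weighted_choice(
            rng_demo, dialect_names, [config.dialect_mix[d] for d in dialect_names],
            config.n_sites,
        )
    ]
    dialect = site_dialect[site_id]

    # ---- biology: culture, latent intensity, urinalysis, symptoms ------
    positive = rng_bio.random(n) < config.culture_positive_prevalence
    z = config.latent_separation * positive + rng_bio.standard_normal(n)

    levels: dict[str, np.ndarray] = {}
    for comp in COMPONENTS:
        s = config.urinalysis_signal[comp]
        x = s * z + np.sqrt(max(0.0, 1 - s * s)) * rng_bio.standard_normal(n)
        if scale_map[comp].n_levels == 2:
            lv = (x > _CUTPOINT_NITRITE).astype(int)
        else:
            lv = np.digitize(x, _CUTPOINTS_4)
        levels[comp] = lv

    sym_rate = np.where(
        positive, config.symptom_rate_given_positive, config.symptom_rate_given_negative
    )
    any_symptom = rng_bio.random(n) < sym_rate
    likely = (rng_bio.random(n) < 0.85) & any_symptom
    exam = (rng_bio.random(n) < 0.20) & any_symptom
    systemic = (rng_bio.random(n) < 0.45) & any_symptom
    none_drawn = any_symptom & ~(likely | exam | systemic)
    likely = likely | none_drawn  # at least one flag when any_symptom holds

    # culture report: organism + CFU/mL consistent with positivity
    organism = np.full(n, "", dtype=object)
    cfu = np.zeros(n, dtype=np.int64)
    pos_idx = np.flatnonzero(positive)
    names, pw = zip(*_PATHOGENS)
    organism[pos_idx] = np.array(names)[_weighted_choice(rng_bio, names, pw, len(pos_idx))]
    cfu[pos_idx] = np.maximum(
        10_000, (10 ** rng_bio.uniform(4, 6, len(pos_idx))).astype(np.int64)
    )
    neg_idx = np.flatnonzero(~positive)
    kind = _weighted_choice(rng_bio, ("none", "contaminant", "low_count"), (0.70, 0.15, 0.15), len(neg_idx))
    contam = neg_idx[kind == 1]
    organism[contam] = rng_bio.choice(_CONTAMINANTS, len(contam))
    cfu[contam] = (10 ** rng_bio.uniform(3, 5, len(contam))).astype(np.int64)
    low = neg_idx[kind == 2]
    organism[low] = np.array(names)[_weighted_choice(rng_bio, names, pw, len(low))]
    cfu[low] = np.minimum(9_999, (10 ** rng_bio.uniform(2, 4, len(low))).astype(np.int64))

    latent_strict = positive & any_symptom

    # ---- physician behaviour -------------------------------------------
    beh = config.physician_behavior
    sens = np.full(n, beh.sensitivity)
    fpr = np.full(n, beh.false_positive_rate)
    if beh.group_overrides:
        keys = np.array([
            group_key(pat_age_bin[p], pat_sex[p], pat_race[p], pat_eth[p])
            for p in patient_of
        ])
        for key, (s_, f_) in beh.group_overrides.items():
            mask = keys == key
            sens[mask] = s_
            fpr[mask] = f_
    intent = np.where(latent_strict, rng_phys.random(n) < sens, rng_phys.random(n) < fpr)

    explicit_dx = np.full(n, "", dtype=object)
    abx = np.full(n, "", dtype=object)
    other_dx = np.full(n, "", dtype=object)
    dx_idx = np.flatnonzero(intent)
    explicit_branch = rng_phys.random(len(dx_idx)) < beh.explicit_share
    exp_rows = dx_idx[explicit_branch]
    inf_rows = dx_idx[~explicit_branch]
    explicit_dx[exp_rows] = rng_phys.choice(_EXPLICIT_DX, len(exp_rows))
    with_abx = exp_rows[rng_phys.random(len(exp_rows)) < 0.8]
    abx[with_abx] = rng_phys.choice(_UTI_ABX, len(with_abx))
    abx[inf_rows] = rng_phys.choice(_UTI_ABX, len(inf_rows))
    other_dx[inf_rows] = rng_phys.choice(_NONSPECIFIC_DX, len(inf_rows))

    no_dx = np.flatnonzero(~intent)
    # emissions for undiagnosed visits never satisfy the proxy rule:
    # nothing / nonspecific code without antibiotic / antibiotic explained
    # by an alternative infectious diagnosis / antibiotic alone
    emis = _weighted_choice(rng_phys, ("nothing", "nonspecific", "alt_abx", "abx_only"),
                            (0.60, 0.20, 0.15, 0.05), len(no_dx))
    ns_rows = no_dx[emis == 1]
    other_dx[ns_rows] = rng_phys.choice(_NONSPECIFIC_DX, len(ns_rows))
    alt_rows = no_dx[emis == 2]
    alt = rng_phys.choice(_ALTERNATIVE_DX, len(alt_rows))
    ns = rng_phys.choice(_NONSPECIFIC_DX, len(alt_rows))
    other_dx[alt_rows] = [f"{a};{b}" for a, b in zip(alt, ns)]
    abx[alt_rows] = rng_phys.choice(_UTI_ABX, len(alt_rows))
    abx_rows = no_dx[emis == 3]
    abx[abx_rows] = rng_phys.choice(_UTI_ABX, len(abx_rows))

    # ---- reporting: raw strings per site dialect, with missingness -----
    raw_cols = {}
    for comp in COMPONENTS:
        raw = np.empty(n, dtype=object)
        render = scale_map[comp].render_tables
        for d in DIALECTS:
            mask = dialect == d
            if mask.any():
                raw[mask] = np.array(render[d], dtype=object)[levels[comp][mask]]
        missing = rng_rep.random(n) < config.missing_rate
        raw[missing] = ""
        raw_cols[harmonize.raw_column(comp)] = raw

    table = pd.DataFrame(
        {
            "encounter_id": [f"E{i:06d}" for i in range(n)],
            "patient_id": [f"P{p:06d}" for p in patient_of],
            "site_id": site_id,
            "dialect": dialect,
            "age_years": pat_age[patient_of],
            "age_bin": pat_age_bin[patient_of],
            "sex": pat_sex[patient_of],
            "race": pat_race[patient_of],
            "ethnicity": pat_eth[patient_of],
            **raw_cols,
            "culture_organism": organism,
            "culture_cfu_per_ml": cfu,
            "sym_likely_uti_symptom": likely,
            "sym_uti_exam_finding": exam,
            "sym_systemic": systemic,
            "explicit_dx_codes": explicit_dx,
            "antibiotic_rx": abx,
            "other_dx_codes": other_dx,
            "latent_culture_positive": positive,
            "latent_any_symptom": any_symptom,
            "latent_strict_uti": latent_strict,
            "physician_intent": intent,
        }
    )
    return table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


_BOOL_COLUMNS = (
    "sym_likely_uti_symptom", "sym_uti_exam_finding", "sym_systemic",
    "latent_culture_positive", "latent_any_symptom", "latent_strict_uti",
    "physician_intent", "culture_positive", "any_symptom", "strict_uti",
    "liberal_uti", "physician_diagnosed",
)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV back with string/bool dtypes intact (empty = missing)."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    for col in _BOOL_COLUMNS:
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col] == "True"
    return df
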