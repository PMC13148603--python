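"""Harmonize heterogeneous urinalysis reporting dialects onto one ordinal scale.

Emergency departments report urinalysis components on different scales —
qualitative words ("negative" … "large"), semiquantitative pluses ("1+" …
"3+"), or quantitative bins ("11-50/hpf", "100 mg/dl").  Downstream modelling
needs a single ordered level per component.  This module ships a versioned,
override-able mapping table (``resources/scale_map.json``) and functions to
apply it to single values or whole encounter tables.

Level 0 is always negative/none.  Dipstick chemistries and microscopy counts
use four levels; nitrites are reported qualitatively by clinical assays and
use two (negative/positive).  Unknown vocabulary raises
:class:`~utiaudit.errors.HarmonizationError` rather than being coerced to
missing: only true missingness may pass through as missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources as _ilres
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, HarmonizationError

#: canonical component keys, in panel order (dipstick then microscopy)
COMPONENTS = (
    "blood",
    "glucose",
    "ketones",
    "leukocyte_esterase",
    "nitrites",
    "protein",
    "bacteria",
    "epithelial_cells",
    "white_blood_cells",
)

DIALECTS = ("qualitative", "semiquantitative", "quantitative")

#: raw-string column name for a component in an encounter table
def raw_column(component: str) -> str:
    return f"ua_{component}_raw"


#: harmonized ordinal column name for a component
def level_column(component: str) -> str:
    return f"ua_{component}"


def _norm(raw: str) -> str:
    return " ".join(str(raw).casefold().split())


@dataclass(frozen=True)
class ComponentScale:
    """Unified ordinal scale for one urinalysis component.

    ``levels`` are the canonical labels (index = ordinal level, 0 =
    negative/none).  ``dialect_maps`` take a normalized raw string to a level
    index; ``render_tables`` give one canonical raw string per (dialect,
    level) and are used by the synthetic cohort generator, so render followed
    by harmonize is the identity on levels.
    """

    component: str
    levels: tuple[str, ...]
    dialect_maps: Mapping[str, Mapping[str, int]]
    render_tables: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        n = len(self.levels)
        for dialect, table in self.dialect_maps.items():
            seen = set(table.values())
            if seen != set(range(n)):
                raise ConfigurationError(
                    f"{self.component}/{dialect}: dialect map must be "
                    f"surjective onto levels 0..{n - 1}, got {sorted(seen)}"
                )
        for dialect, rendered in self.render_tables.items():
            if len(rendered) != n:
                raise ConfigurationError(
                    f"{self.component}/{dialect}: render table must list "
                    f"exactly one string per level"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def lookup(self, raw: str, dialect: str) -> int:
        if dialect not in self.dialect_maps:
            raise HarmonizationError(
                f"unknown dialect {dialect!r} for component {self.component!r}"
            )
        table = self.dialect_maps[dialect]
        key = _norm(raw)
        if key not in table:
            raise HarmonizationError(
                f"unmappable value {raw!r} for component "
                f"{self.component!r} in dialect {dialect!r}"
            )
        return table[key]

    def render(self, level: int, dialect: str) -> str:
        if dialect not in self.render_tables:
            raise HarmonizationError(
                f"unknown dialect {dialect!r} for component {self.component!r}"
            )
        if not 0 <= int(level) < self.n_levels:
            raise ConfigurationError(
                f"{self.component}: level {level} outside 0..{self.n_levels - 1}"
            )
        return self.render_tables[dialect][int(level)]


class ScaleMap:
    """Collection of :class:`ComponentScale` objects for the full panel."""

    def __init__(self, scales: Mapping[str, ComponentScale], version: str = "?"):
        missing = set(COMPONENTS) - set(scales)
        if missing:
            raise ConfigurationError(f"scale map missing components: {sorted(missing)}")
        self.scales = dict(scales)
        self.version = version

    def __getitem__(self, component: str) -> ComponentScale:
        try:
            return self.scales[component]
        except KeyError:
            raise HarmonizationError(f"unregistered component {component!r}") from None

    @classmethod
    def from_dict(cls, payload: dict) -> "ScaleMap":
        scales = {}
        for comp, entry in payload["components"].items():
            scales[comp] = ComponentScale(
                component=comp,
                levels=tuple(entry["levels"]),
                dialect_maps={
                    d: {_norm(k): int(v) for k, v in m.items()}
                    for d, m in entry["dialects"].items()
                },
                render_tables={d: tuple(r) for d, r in entry["render"].items()},
            )
        return cls(scales, version=str(payload.get("version", "?")))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaleMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "ScaleMap":
        ref = _ilres.files("utiaudit.resources").joinpath("scale_map.json")
        return cls.from_dict(json.loads(ref.read_text()))


_DEFAULT: ScaleMap | None = None


def default_scale_map() -> ScaleMap:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ScaleMap.default()
    return _DEFAULT


def _is_missing(raw) -> bool:
    if raw is None:
        return True
    if isinstance(raw, float) and np.isnan(raw):
        return True
    if isinstance(raw, str) and raw.strip() == "":
        return True
    return raw is pd.NA


def harmonize_component(
    raw,
    component: str,
    dialect: str,
    scale_map: ScaleMap | None = None,
):
    """Map one raw component result to its unified ordinal level.

    Missing input (None/NaN/empty string) passes through as ``None``.  An
    already-ordinal integer within the component's range is returned
    unchanged (idempotence).  Anything else must be in the dialect's declared
    vocabulary, case- and whitespace-insensitively; unknown strings raise.
    """
    scale_map = scale_map or default_scale_map()
    scale = scale_map[component]
    if _is_missing(raw):
        return None
    if isinstance(raw, (int, np.integer)) or (
        isinstance(raw, float) and float(raw).is_integer()
    ):
        level = int(raw)
        if 0 <= level < scale.n_levels:
            return level
        raise HarmonizationError(
            f"ordinal value {raw!r} outside range 0..{scale.n_levels - 1} "
            f"for component {component!r}"
        )
    return scale.lookup(raw, dialect)


def render_raw_urinalysis(
    level: int,
    dialect: str,
    component: str,
    scale_map: ScaleMap | None = None,
) -> str:
    """Render an ordinal level as a raw string in the given reporting dialect.

    Inverse of :func:`harmonize_component` on non-missing levels; used by the
    synthetic cohort generator to emit realistic mixed-dialect tables.
    """
    scale_map = scale_map or default_scale_map()
    return scale_map[component].render(level, dialect)


def harmonize_table(
    encounters: pd.DataFrame,
    scale_map: ScaleMap | None = None,
    dialect_col: str = "dialect",
    log=None,
) -> pd.DataFrame:
    """Append a harmonized ordinal column ``ua_<component>`` per component.

    Expects raw strings in ``ua_<component>_raw`` and the reporting dialect of
    each row in ``dialect_col``.  Row count and order are preserved; raised
    mapping errors carry the offending row's encounter id.
    """
    scale_map = scale_map or default_scale_map()
    if len(encounters) == 0:
        out = encounters.copy()
        for comp in COMPONENTS:
            out[level_column(comp)] = pd.Series(dtype="float64")
        return out
    if dialect_col not in encounters.columns:
        raise ConfigurationError(f"missing dialect column {dialect_col!r}")
    out = encounters.copy()
    positions = pd.Series(np.arange(len(out)), index=out.index)
    # lookups are done once per unique (dialect, raw string) pair, then
    # broadcast — the loop cost is vocabulary-sized, not table-sized
    for comp in COMPONENTS:
        col = raw_column(comp)
        if col not in out.columns:
            raise ConfigurationError(f"missing raw column {col!r}")
        levels = np.full(len(out), np.nan)
        for dialect, idx in out.groupby(dialect_col, sort=False).groups.items():
            sub = out.loc[idx, col]
            lut: dict = {}
            for raw in pd.unique(sub):
                try:
                    lvl = harmonize_component(raw, comp, str(dialect), scale_map)
                except HarmonizationError as err:
                    bad = sub[sub == raw].index[0]
                    enc = out.loc[bad].get("encounter_id", bad)
                    raise HarmonizationError(f"encounter {enc}: {err}") from err
                lut[raw] = np.nan if lvl is None else float(lvl)
            levels[positions[idx].to_numpy()] = sub.map(lut).to_numpy(dtype=float)
        out[level_column(comp)] = levels
        if log is not None:
            counts = pd.Series(levels).value_counts(dropna=False).sort_index()
            log.info("harmonized %s: %s", comp, counts.to_dict())
    return out
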