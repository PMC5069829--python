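"""On-disk schema and validation for disaggregated health-indicator data.

The data model mirrors the shape of national health-inequality databases:
one row per (setting, survey source, year, indicator, inequality dimension,
population subgroup), carrying the subgroup estimate ``y_j``, its standard
error, and the subgroup's population share ``p_j``.  Files are plain
delimited text (comma or tab) with a fixed lower-case header.

Required columns
----------------
``setting, source, year, indicator_id, dimension, subgroup, estimate,
population_share``

Optional columns
----------------
``se`` (standard error; empty = unknown, CIs are then suppressed),
``subgroup_order`` (integer rank, 1 = most disadvantaged; required for
ordered dimensions), ``is_reference`` (boolean flag for the reference
subgroup of a binary dimension), ``income_group`` and ``region``
(setting-level benchmarking metadata, repeated per row).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "setting",
    "source",
    "year",
    "indicator_id",
    "dimension",
    "subgroup",
    "estimate",
    "population_share",
)
OPTIONAL_COLUMNS = ("se", "subgroup_order", "is_reference", "income_group", "region")

#: dimension kinds
ORDERED = "ordered"
BINARY = "binary"
UNORDERED_MANY = "unordered_many"
DIMENSION_KINDS = (ORDERED, BINARY, UNORDERED_MANY)

_SEPARATORS = {"comma": ",", "tab": "\t"}


class SchemaError(ValueError):
    """A structural problem with an input file (e.g. a missing column)."""


class DataParseError(ValueError):
    """One or more rows could not be parsed; carries row numbers."""

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        lines = "; ".join(f"row {n}: {msg}" for n, msg in row_errors[:10])
        more = "" if len(row_errors) <= 10 else f" (+{len(row_errors) - 10} more)"
        super().__init__(f"{len(row_errors)} unparseable row(s): {lines}{more}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubgroupRecord:
    """One disaggregated observation: a subgroup's estimate within a stratum."""

    setting: str
    source: str
    year: int
    indicator_id: str
    dimension: str
    subgroup: str
    estimate: float
    population_share: float
    se: Optional[float] = None
    subgroup_order: Optional[int] = None
    is_reference: Optional[bool] = None


@dataclass(frozen=True)
class IndicatorSpec:
    """Indicator metadata.

    ``favourable`` is True for health-intervention indicators where higher
    values are better (e.g. coverage) and False for adverse outcomes where
    lower is better (e.g. mortality).  ``scale`` is the natural display
    multiplier (e.g. 100 for a proportion reported per 100).
    """

    indicator_id: str
    name: str = ""
    favourable: bool = True
    scale: float = 1.0


@dataclass(frozen=True)
class DimensionSpec:
    """An inequality dimension: its kind, subgroup order and reference.

    kind is one of ``ordered`` (e.g. wealth quintiles, 1 = most
    disadvantaged), ``binary`` (e.g. urban/rural) or ``unordered_many``
    (e.g. subnational regions).
    """

    dimension: str
    kind: str
    subgroup_names: tuple[str, ...] = ()
    reference_subgroup: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in DIMENSION_KINDS:
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == BINARY and self.subgroup_names and len(self.subgroup_names) != 2:
            raise ValueError("binary dimension needs exactly 2 subgroups")


@dataclass(frozen=True)
class SettingMeta:
    """Benchmarking metadata for a setting (country or area)."""

    setting: str
    income_group: str = "unknown"
    region: str = "unknown"


@dataclass(frozen=True)
class StratumSlice:
    """All subgroup records for one (setting, source, year, indicator, dimension).

    This is the unit on which summary measures are computed.  For ordered
    dimensions subgroups are sorted by ``subgroup_order`` (ascending, i.e.
    most disadvantaged first) and population shares are renormalised to sum
    exactly to one.
    """

    key: tuple[str, str, int, str, str]
    subgroups: tuple[SubgroupRecord, ...]
    indicator: IndicatorSpec
    dimension_spec: DimensionSpec

    @property
    def n(self) -> int:
        return len(self.subgroups)

    @property
    def estimates(self) -> list[float]:
        return [r.estimate for r in self.subgroups]

    @property
    def shares(self) -> list[float]:
        return [r.population_share for r in self.subgroups]

    @property
    def ses(self) -> list[Optional[float]]:
        return [r.se for r in self.subgroups]

    @property
    def has_se(self) -> bool:
        return all(r.se is not None for r in self.subgroups)


@dataclass
class Dataset:
    """A validated collection of records plus indicator/dimension/setting metadata."""

    records: list[SubgroupRecord] = field(default_factory=list)
    indicators: dict[str, IndicatorSpec] = field(default_factory=dict)
    dimensions: dict[str, DimensionSpec] = field(default_factory=dict)
    settings: dict[str, SettingMeta] = field(default_factory=dict)

    # -- slicing ------------------------------------------------------------

    def slice_keys(self) -> list[tuple[str, str, int, str, str]]:
        seen: dict[tuple, None] = {}
        for r in self.records:
            seen.setdefault((r.setting, r.source, r.year, r.indicator_id, r.dimension), None)
        return list(seen)

    def get_slice(self, key: tuple[str, str, int, str, str]) -> StratumSlice:
        setting, source, year, indicator_id, dimension = key
        rows = [
            r
            for r in self.records
            if (r.setting, r.source, r.year, r.indicator_id, r.dimension) == key
        ]
        if not rows:
            raise KeyError(f"no records for slice {key}")
        return build_slice(
            rows,
            self.indicators.get(indicator_id, IndicatorSpec(indicator_id)),
            self.dimensions.get(dimension, DimensionSpec(dimension, UNORDERED_MANY)),
        )

    def iter_slices(self) -> Iterator[StratumSlice]:
        for key in self.slice_keys():
            yield self.get_slice(key)

    # -- tabular views ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            meta = self.settings.get(r.setting, SettingMeta(r.setting))
            rows.append(
                {
                    "setting": r.setting,
                    "source": r.source,
                    "year": r.year,
                    "indicator_id": r.indicator_id,
                    "dimension": r.dimension,
                    "subgroup": r.subgroup,
                    "estimate": r.estimate,
                    "se": r.se,
                    "population_share": r.population_share,
                    "subgroup_order": r.subgroup_order,
                    "is_reference": r.is_reference,
                    "income_group": meta.income_group,
                    "region": meta.region,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ValidationFinding:
    """One data-quality finding for a slice (never an exception)."""

    slice_key: tuple
    code: str
    message: str


# ---------------------------------------------------------------------------
# slice construction
# ---------------------------------------------------------------------------


def build_slice(
    rows: Sequence[SubgroupRecord],
    indicator: IndicatorSpec,
    dimension_spec: DimensionSpec,
) -> StratumSlice:
    """Assemble a StratumSlice: order subgroups and renormalise shares.

    Shares are renormalised to sum exactly to one (survey-derived shares are
    rounded); a renormalisation larger than 1e-9 is logged.
    """
    rows = list(rows)
    if dimension_spec.kind == ORDERED:
        if any(r.subgroup_order is None for r in rows):
            raise SchemaError(
                f"ordered dimension {dimension_spec.dimension!r} requires subgroup_order"
            )
        rows.sort(key=lambda r: r.subgroup_order)
    total = sum(r.population_share for r in rows)
    if total <= 0:
        raise SchemaError("population shares must sum to a positive value")
    if abs(total - 1.0) > 1e-9:
        logger.info(
            "renormalising shares for %s (sum=%.6f)",
            (rows[0].setting, rows[0].year, rows[0].indicator_id, rows[0].dimension),
            total,
        )
    rows = [replace(r, population_share=r.population_share / total) for r in rows]
    first = rows[0]
    key = (first.setting, first.source, first.year, first.indicator_id, first.dimension)
    return StratumSlice(key=key, subgroups=tuple(rows), indicator=indicator, dimension_spec=dimension_spec)


# ---------------------------------------------------------------------------
# year parsing
# ---------------------------------------------------------------------------

_YEAR_RANGE = re.compile(r"^(\d{4})\s*[-/]\s*(\d{2}|\d{4})$")


def parse_year(value) -> int:
    """Parse a survey year label to a single integer (end year of a range).

    Accepts plain integers ("2007"), full ranges ("2005-2006") and
    abbreviated ranges ("2005-06", "1999-00" -> 2000).
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if float(value) != int(value):
            raise ValueError(f"non-integer year {value!r}")
        return int(value)
    text = str(value).strip()
    m = _YEAR_RANGE.match(text)
    if m:
        start, end = m.group(1), m.group(2)
        if len(end) == 4:
            return int(end)
        century = int(start) - int(start) % 100
        end_year = century + int(end)
        if end_year < int(start):  # wrapped a century boundary, e.g. 1999-00
            end_year += 100
        return end_year
    return int(text)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n", ""}


def _parse_bool(text: str) -> Optional[bool]:
    t = text.strip().lower()
    if t == "":
        return None
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def read_dataset(
    path,
    dialect: str = "comma",
    indicators: Optional[dict[str, IndicatorSpec]] = None,
    dimensions: Optional[dict[str, DimensionSpec]] = None,
    header_map: Optional[dict[str, str]] = None,
) -> Dataset:
    """Read a delimited-text dataset into a :class:`Dataset`.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row.
    dialect:
        ``"comma"`` or ``"tab"``.
    indicators, dimensions:
        Metadata overriding the shipped defaults (see :func:`default_config`).
        Indicators or dimensions present in the file but absent from the
        metadata are auto-registered with inferred properties.
    header_map:
        Optional mapping from the file's column names (synonyms) to the
        canonical lower-case schema names.
    """
    sep = _separator(dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    if header_map:
        raw = raw.rename(columns={k.strip().lower(): v for k, v in header_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    defaults = default_config()
    indicator_map = dict(defaults["indicators"]) if indicators is None else dict(indicators)
    dimension_map = dict(defaults["dimensions"]) if dimensions is None else dict(dimensions)

    records: list[SubgroupRecord] = []
    setting_meta: dict[str, SettingMeta] = {}
    row_errors: list[tuple[int, str]] = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # 1-based + header
        d = dict(zip(raw.columns, row))
        try:
            estimate = float(d["estimate"])
            share = float(d["population_share"])
            se_text = d.get("se", "").strip()
            order_text = d.get("subgroup_order", "").strip()
            rec = SubgroupRecord(
                setting=d["setting"].strip(),
                source=d["source"].strip(),
                year=parse_year(d["year"]),
                indicator_id=d["indicator_id"].strip(),
                dimension=d["dimension"].strip(),
                subgroup=d["subgroup"].strip(),
                estimate=estimate,
                population_share=share,
                se=float(se_text) if se_text else None,
                subgroup_order=int(float(order_text)) if order_text else None,
                is_reference=_parse_bool(d.get("is_reference", "")),
            )
        except (ValueError, KeyError) as exc:
            row_errors.append((i, str(exc)))
            continue
        records.append(rec)
        income = d.get("income_group", "").strip() or "unknown"
        region = d.get("region", "").strip() or "unknown"
        if rec.setting not in setting_meta or (
            setting_meta[rec.setting].income_group == "unknown" and income != "unknown"
        ):
            setting_meta[rec.setting] = SettingMeta(rec.setting, income, region)
    if row_errors:
        raise DataParseError(row_errors)

    _register_unknowns(records, indicator_map, dimension_map)
    return Dataset(
        records=records,
        indicators=indicator_map,
        dimensions=dimension_map,
        settings=setting_meta,
    )


def _register_unknowns(
    records: Iterable[SubgroupRecord],
    indicator_map: dict[str, IndicatorSpec],
    dimension_map: dict[str, DimensionSpec],
) -> None:
    """Auto-register indicators/dimensions seen in data but absent from config.

    Unknown indicators default to favourable with scale 1.  Unknown
    dimensions are inferred: ordered if subgroup_order is populated, binary
    if exactly two subgroups appear, otherwise unordered_many.
    """
    by_dim: dict[str, list[SubgroupRecord]] = {}
    for r in records:
        if r.indicator_id not in indicator_map:
            logger.info("auto-registering indicator %r (favourable, scale 1)", r.indicator_id)
            indicator_map[r.indicator_id] = IndicatorSpec(r.indicator_id, name=r.indicator_id)
        by_dim.setdefault(r.dimension, []).append(r)
    for dim, rows in by_dim.items():
        if dim in dimension_map:
            continue
        subgroups = sorted({r.subgroup for r in rows})
        if all(r.subgroup_order is not None for r in rows):
            kind = ORDERED
        elif len(subgroups) == 2:
            kind = BINARY
        else:
            kind = UNORDERED_MANY
        logger.info("auto-registering dimension %r as %s", dim, kind)
        dimension_map[dim] = DimensionSpec(dim, kind, tuple(subgroups))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_dataset(ds: Dataset, share_tolerance: float = 0.01) -> list[ValidationFinding]:
    """Enumerate data-quality findings per stratum slice.

    Checks: population shares summing to 1 within ``share_tolerance``;
    duplicate subgroup labels; broken ordered-rank sequences; negative
    estimates; ordered dimensions missing subgroup_order.  Findings are
    returned, never raised.
    """
    findings: list[ValidationFinding] = []
    grouped: dict[tuple, list[SubgroupRecord]] = {}
    for r in ds.records:
        grouped.setdefault((r.setting, r.source, r.year, r.indicator_id, r.dimension), []).append(r)
    for key, rows in grouped.items():
        dim = ds.dimensions.get(key[4], DimensionSpec(key[4], UNORDERED_MANY))
        total = sum(r.population_share for r in rows)
        if abs(total - 1.0) > share_tolerance:
            findings.append(
                ValidationFinding(key, "share_sum", f"population shares sum to {total:.4f}, not 1")
            )
        labels = [r.subgroup for r in rows]
        for dup in sorted({s for s in labels if labels.count(s) > 1}):
            findings.append(ValidationFinding(key, "duplicate_subgroup", f"duplicate subgroup {dup!r}"))
        for r in rows:
            if r.estimate < 0:
                findings.append(
                    ValidationFinding(key, "negative_estimate", f"negative estimate for {r.subgroup!r}")
                )
        if dim.kind == ORDERED:
            orders = [r.subgroup_order for r in rows]
            if any(o is None for o in orders):
                findings.append(
                    ValidationFinding(key, "missing_order", "ordered dimension lacks subgroup_order")
                )
            elif sorted(orders) != list(range(1, len(rows) + 1)):
                findings.append(
                    ValidationFinding(
                        key, "rank_sequence", f"subgroup_order {sorted(orders)} is not 1..{len(rows)}"
                    )
                )
    return findings


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _separator(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValueError(f"dialect must be one of {sorted(_SEPARATORS)}, got {dialect!r}") from None


def write_table(table: pd.DataFrame, path, separator: str = "comma") -> None:
    """Write a result table as delimited text with the chosen field separator.

    Fields containing the separator are quoted so the round trip is lossless.
    """
    sep = _separator(separator)
    table.to_csv(path, sep=sep, index=False, quoting=csv.QUOTE_MINIMAL)


def write_dataset(ds: Dataset, path, separator: str = "comma") -> None:
    """Export a full Dataset in the on-disk schema (round-trips via read_dataset)."""
    write_table(ds.to_frame(), path, separator=separator)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_DEFAULT_DIMENSIONS: tuple[DimensionSpec, ...] = (
    DimensionSpec(
        "economic status",
        ORDERED,
        ("quintile 1 (poorest)", "quintile 2", "quintile 3", "quintile 4", "quintile 5 (richest)"),
    ),
    DimensionSpec(
        "education",
        ORDERED,
        ("no education", "primary education", "secondary or higher education"),
    ),
    DimensionSpec("place of residence", BINARY, ("rural", "urban"), reference_subgroup="urban"),
    DimensionSpec("sex", BINARY, ("female", "male"), reference_subgroup="male"),
    DimensionSpec("subnational region", UNORDERED_MANY),
)


def default_config() -> dict:
    """Shipped defaults: the five standard dimensions; no indicator presets."""
    return {
        "dimensions": {d.dimension: d for d in _DEFAULT_DIMENSIONS},
        "indicators": {},
    }


def load_config(path) -> dict:
    """Load dimension/indicator metadata from a YAML config file.

    The file may declare ``dimensions`` (list of mappings with keys
    ``dimension``, ``kind``, ``subgroup_names``, ``reference_subgroup``) and
    ``indicators`` (keys ``indicator_id``, ``name``, ``favourable``,
    ``scale``).  Entries merge over the shipped defaults.
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    cfg = default_config()
    for d in data.get("dimensions", []) or []:
        spec = DimensionSpec(
            dimension=d["dimension"],
            kind=d["kind"],
            subgroup_names=tuple(d.get("subgroup_names", ()) or ()),
            reference_subgroup=d.get("reference_subgroup"),
        )
        cfg["dimensions"][spec.dimension] = spec
    for ind in data.get("indicators", []) or []:
        spec = IndicatorSpec(
            indicator_id=ind["indicator_id"],
            name=ind.get("name", ind["indicator_id"]),
            favourable=bool(ind.get("favourable", True)),
            scale=float(ind.get("scale", 1.0)),
        )
        cfg["indicators"][spec.indicator_id] = spec
    return cfg
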