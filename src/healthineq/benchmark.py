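"""Between-setting benchmarking: comparator shortlists and comparison tables.

A setting is compared against others filtered by income group and region,
restricted to settings that have data for the chosen indicator and
dimension inside an inclusive year window around the reference survey year
(a range of 5 around 2007 admits surveys from 2002 through 2012; a range
of 0 admits 2007 only).  When a comparator has several eligible surveys,
the one closest to the reference year is used, with ties broken towards
the later year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import measures as m
from .schema_io import Dataset, StratumSlice
from .uncertainty import BootstrapConfig, with_ci

logger = logging.getLogger(__name__)


class BenchmarkQueryError(ValueError):
    """The benchmark query cannot be answered (bad reference or measure)."""


@dataclass(frozen=True)
class BenchmarkQuery:
    """A between-setting comparison request.

    Empty ``income_groups`` / ``regions`` mean no filter on that attribute.
    ``manual_includes`` adds settings to the shortlist regardless of income
    group and region (they still need eligible data); ``manual_excludes``
    removes settings and is applied last.
    """

    setting: str
    reference_year: int
    indicator_id: str
    dimension: str
    year_range: int = 5
    income_groups: frozenset[str] = frozenset()
    regions: frozenset[str] = frozenset()
    measure_id: Optional[str] = None
    manual_includes: frozenset[str] = frozenset()
    manual_excludes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.year_range <= 5:
            raise ValueError("year_range must be between 0 and 5")


def year_window(reference_year: int, year_range: int) -> tuple[int, int]:
    """Inclusive year window [reference_year - range, reference_year + range]."""
    if year_range < 0:
        raise ValueError("year_range must be non-negative")
    return reference_year - year_range, reference_year + year_range


def _eligible_years(ds: Dataset, setting: str, query: BenchmarkQuery) -> list[int]:
    low, high = year_window(query.reference_year, query.year_range)
    return sorted(
        {
            r.year
            for r in ds.records
            if r.setting == setting
            and r.indicator_id == query.indicator_id
            and r.dimension == query.dimension
            and low <= r.year <= high
        }
    )


def _choose_year(years: list[int], reference_year: int) -> int:
    # closest to the reference year; ties break to the later year
    return max(years, key=lambda y: (-abs(y - reference_year), y))


def select_comparators(ds: Dataset, query: BenchmarkQuery) -> list[tuple[str, int]]:
    """Comparator settings with their chosen survey years.

    Settings pass if their income group / region match the (possibly empty)
    filters and they have data for the indicator and dimension inside the
    year window.  Manual includes are added even when the metadata filters
    would drop them; manual excludes are applied last.  The reference
    setting itself is never part of the comparator list.
    """
    if query.setting not in {r.setting for r in ds.records}:
        raise BenchmarkQueryError(f"reference setting {query.setting!r} absent from dataset")
    chosen: list[tuple[str, int]] = []
    for setting in sorted({r.setting for r in ds.records}):
        if setting == query.setting or setting in query.manual_excludes:
            continue
        meta = ds.settings.get(setting)
        matches_meta = (
            (not query.income_groups or (meta and meta.income_group in query.income_groups))
            and (not query.regions or (meta and meta.region in query.regions))
        )
        if not matches_meta and setting not in query.manual_includes:
            continue
        years = _eligible_years(ds, setting, query)
        if not years:
            continue
        year = _choose_year(years, query.reference_year)
        if len(years) > 1:
            logger.info("comparator %r: chose survey year %d from %s", setting, year, years)
        chosen.append((setting, year))
    return chosen


def _setting_slice(ds: Dataset, setting: str, year: int, query: BenchmarkQuery) -> Optional[StratumSlice]:
    for key in ds.slice_keys():
        if key[0] == setting and key[2] == year and key[3] == query.indicator_id and key[4] == query.dimension:
            return ds.get_slice(key)
    return None


def benchmark_table(
    ds: Dataset,
    query: BenchmarkQuery,
    cfg: Optional[BootstrapConfig] = None,
) -> pd.DataFrame:
    """Comparison table: reference setting first, then comparators.

    Each row carries the chosen survey year, the setting mean (share-
    weighted), and — when ``measure_id`` is set — the summary measure with
    its CI.  An inapplicable measure/dimension pair raises
    :class:`BenchmarkQueryError` before any computation.
    """
    measure_id = None
    if query.measure_id is not None:
        measure_id = m.normalise_measure_id(query.measure_id)
        dim_spec = ds.dimensions.get(query.dimension)
        if dim_spec is None:
            raise BenchmarkQueryError(f"unknown dimension {query.dimension!r}")
        if measure_id not in m.applicable_measures(dim_spec):
            raise BenchmarkQueryError(
                f"{measure_id} is not applicable to {dim_spec.kind} dimension {query.dimension!r}"
            )
    comparators = select_comparators(ds, query)
    ref_years = _eligible_years(ds, query.setting, query)
    # the reference setting is always shown, even with no data in the window
    ref_year = _choose_year(ref_years, query.reference_year) if ref_years else None
    rows = []
    for setting, year, role in [(query.setting, ref_year, "reference")] + [
        (s, y, "comparator") for s, y in comparators
    ]:
        meta = ds.settings.get(setting)
        row = {
            "setting": setting,
            "role": role,
            "income_group": meta.income_group if meta else "unknown",
            "region": meta.region if meta else "unknown",
            "year": year,
            "setting_average": None,
        }
        sl = _setting_slice(ds, setting, year, query) if year is not None else None
        if sl is not None:
            row["setting_average"] = m.weighted_mean(sl)
            if measure_id is not None:
                res = with_ci(sl, measure_id, cfg) if cfg is not None else m.compute_measure(sl, measure_id)
                row["measure"] = measure_id
                row["estimate"] = res.estimate
                row["ci_lower"] = res.ci_lower
                row["ci_upper"] = res.ci_upper
        elif measure_id is not None:
            row["measure"] = measure_id
            row["estimate"] = None
            row["ci_lower"] = None
            row["ci_upper"] = None
        rows.append(row)
    return pd.DataFrame(rows)
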