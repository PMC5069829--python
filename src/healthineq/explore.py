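"""Within-setting table views: disaggregated data and summary measures.

These functions reproduce the two tabular views an analyst works with when
assessing inequality inside one setting: a disaggregated-data table (one
row per subgroup estimate) and a summary-measure table (one row per stratum
and measure), either for the latest available survey or across a chosen set
of years.  Rounding and display multipliers are presentation-only — the
underlying values keep full precision and can always be recovered by
re-querying with more decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import measures as m
from .schema_io import Dataset, StratumSlice
from .uncertainty import BootstrapConfig, with_ci


@dataclass(frozen=True)
class ViewQuery:
    """A table query: what to show and how to display it.

    ``years`` is either the string ``"latest"`` (default: the most recent
    survey per setting/source/indicator/dimension) or an explicit set of
    calendar years.  ``measure_ids`` applies to summary views only; None
    means every applicable measure.
    """

    setting: str
    indicator_ids: frozenset[str]
    dimensions: frozenset[str]
    sources: Optional[frozenset[str]] = None
    years: Union[str, frozenset[int]] = "latest"
    measure_ids: Optional[tuple[str, ...]] = None
    decimals: int = 1
    display_multiplier: float = 1.0
    include_ci: bool = False

    def __post_init__(self) -> None:
        if not self.indicator_ids or not self.dimensions:
            raise ValueError("select at least one indicator and one dimension")
        if not 0 <= self.decimals <= 10:
            raise ValueError("decimals must be between 0 and 10")
        if self.display_multiplier <= 0:
            raise ValueError("display_multiplier must be positive")


def _matching_keys(ds: Dataset, query: ViewQuery) -> list[tuple]:
    keys = []
    for key in ds.slice_keys():
        setting, source, year, indicator_id, dimension = key
        if setting != query.setting:
            continue
        if query.sources is not None and source not in query.sources:
            continue
        if indicator_id not in query.indicator_ids or dimension not in query.dimensions:
            continue
        if query.years != "latest" and year not in query.years:
            continue
        keys.append(key)
    return keys


def latest_slices(ds: Dataset, query: ViewQuery) -> list[StratumSlice]:
    """The most recent slice per (setting, source, indicator, dimension).

    Ties between sources in the same year are both returned (sources are
    never merged).  An empty result is returned, not raised, when nothing
    matches.
    """
    keys = _matching_keys(ds, query)
    latest: dict[tuple, tuple] = {}
    for key in keys:
        setting, source, year, indicator_id, dimension = key
        group = (setting, source, indicator_id, dimension)
        if group not in latest or year > latest[group][2]:
            latest[group] = key
    return [ds.get_slice(k) for k in sorted(latest.values())]


def resolve_slices(ds: Dataset, query: ViewQuery) -> list[StratumSlice]:
    """Slices matching the query: latest-per-group or explicit years."""
    if query.years == "latest":
        return latest_slices(ds, query)
    return [ds.get_slice(k) for k in sorted(_matching_keys(ds, query))]


def disaggregated_table(ds: Dataset, query: ViewQuery) -> pd.DataFrame:
    """Disaggregated-data view: one row per subgroup record matching the query.

    Estimates (and, with ``include_ci``, normal-approximation 95% bounds
    y +/- 1.96 se) are rounded to ``query.decimals``; the rounding is
    display-only.
    """
    z = float(stats.norm.ppf(0.975))
    rows = []
    for sl in resolve_slices(ds, query):
        for r in sl.subgroups:
            row = {
                "setting": r.setting,
                "source": r.source,
                "year": r.year,
                "indicator_id": r.indicator_id,
                "indicator_name": sl.indicator.name or sl.indicator.indicator_id,
                "dimension": r.dimension,
                "subgroup": r.subgroup,
                "population_share": r.population_share,
                "estimate": round(r.estimate, query.decimals),
            }
            if query.include_ci:
                if r.se is not None:
                    row["ci_lower"] = round(r.estimate - z * r.se, query.decimals)
                    row["ci_upper"] = round(r.estimate + z * r.se, query.decimals)
                else:
                    row["ci_lower"] = np.nan
                    row["ci_upper"] = np.nan
            rows.append(row)
    columns = [
        "setting", "source", "year", "indicator_id", "indicator_name",
        "dimension", "subgroup", "population_share", "estimate",
    ] + (["ci_lower", "ci_upper"] if query.include_ci else [])
    return pd.DataFrame(rows, columns=columns)


def summary_table(
    ds: Dataset,
    query: ViewQuery,
    cfg: Optional[BootstrapConfig] = None,
) -> pd.DataFrame:
    """Summary-measure view: one row per (stratum slice, measure).

    Requested measures that do not apply to a slice's dimension produce a
    blank estimate with an explanatory note, never an error.  Estimates and
    CI bounds are multiplied by ``display_multiplier`` and rounded to
    ``decimals`` (display-only).  CIs require ``include_ci`` and use the
    analytic/bootstrap routing of the uncertainty module.
    """
    rows = []
    for sl in resolve_slices(ds, query):
        admissible = m.applicable_measures(sl.dimension_spec)
        requested = (
            [m.normalise_measure_id(mid) for mid in query.measure_ids]
            if query.measure_ids is not None
            else [mid for mid in m.MEASURE_ORDER if mid in admissible]
        )
        for mid in requested:
            row = {
                "setting": sl.key[0],
                "source": sl.key[1],
                "year": sl.key[2],
                "indicator_id": sl.key[3],
                "dimension": sl.key[4],
                "measure": mid,
                "estimate": np.nan,
                "note": "",
            }
            if query.include_ci:
                row["ci_lower"] = np.nan
                row["ci_upper"] = np.nan
            if mid not in admissible:
                row["note"] = f"not applicable to {sl.dimension_spec.kind} dimension"
                rows.append(row)
                continue
            res = with_ci(sl, mid, cfg) if query.include_ci else m.compute_measure(sl, mid)
            row["note"] = res.notes
            if res.estimate is not None:
                row["estimate"] = round(res.estimate * query.display_multiplier, query.decimals)
            if query.include_ci and res.ci_lower is not None:
                row["ci_lower"] = round(res.ci_lower * query.display_multiplier, query.decimals)
                row["ci_upper"] = round(res.ci_upper * query.display_multiplier, query.decimals)
            rows.append(row)
    columns = ["setting", "source", "year", "indicator_id", "dimension", "measure", "estimate"]
    if query.include_ci:
        columns += ["ci_lower", "ci_upper"]
    columns.append("note")
    return pd.DataFrame(rows, columns=columns)
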