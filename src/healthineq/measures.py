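"""The 15 summary measures of health inequality.

Given a stratum slice — subgroup estimates :math:`y_j` with population
shares :math:`p_j` — this module computes seven absolute and eight relative
summary measures, each applicable to particular kinds of inequality
dimension:

===========  =============================================  ==========
id           measure                                        scale
===========  =============================================  ==========
ACI          absolute concentration index                   absolute
BGV          between-group variance                         absolute
D            difference (high vs low subgroup)              absolute
MDB          mean difference from best-performing subgroup  absolute
MDM          mean difference from mean                      absolute
PAR          population attributable risk                   absolute
SII          slope index of inequality                      absolute
IDIS         index of disparity                             relative
KMI          Kunst-Mackenbach index                         relative
MLD          mean log deviation (x1000)                     relative
PAF          population attributable fraction               relative
R            ratio (high vs low subgroup)                   relative
RCI          relative concentration index                   relative
RII          relative index of inequality                   relative
TI           Theil index (x1000)                            relative
===========  =============================================  ==========

The national average is the share-weighted mean
:math:`\\mu = \\sum_j p_j y_j`.  Rank-based measures (ACI, RCI, SII, RII,
KMI) use the relative rank :math:`X_j`, the midpoint of subgroup j's
cumulative population-share interval with subgroups ordered from most
disadvantaged to most advantaged.  Direction conventions depend on whether
the indicator is favourable (higher is better) or adverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .schema_io import BINARY, ORDERED, UNORDERED_MANY, DimensionSpec, StratumSlice, SubgroupRecord

__all__ = [
    "MEASURE_ORDER",
    "MEASURES",
    "MeasureInfo",
    "MeasureResult",
    "RankedSlice",
    "RegressionFit",
    "ApplicabilityError",
    "DegenerateFitError",
    "EmptySliceError",
    "applicable_measures",
    "weighted_mean",
    "relative_ranks",
    "compute_pairwise",
    "compute_dispersion",
    "compute_entropy",
    "compute_concentration",
    "fit_rank_regression",
    "compute_regression_measure",
    "compute_attributable",
    "compute_measure",
    "compute_all_measures",
]


class ApplicabilityError(ValueError):
    """A measure was requested for a dimension kind it does not apply to."""


class DegenerateFitError(ValueError):
    """The rank regression cannot be fitted (all ranks identical)."""


class EmptySliceError(ValueError):
    """A slice with no subgroups was passed to a measure."""


@dataclass(frozen=True)
class MeasureInfo:
    measure_id: str
    name: str
    scale: str  # "absolute" | "relative"
    kinds: frozenset[str]  # dimension kinds the measure applies to


_ALL_KINDS = frozenset({ORDERED, BINARY, UNORDERED_MANY})
_ORD = frozenset({ORDERED})
_UNO = frozenset({UNORDERED_MANY})

#: registry in the fixed documented output order (absolute then relative,
#: alphabetical within scale)
MEASURES: dict[str, MeasureInfo] = {
    m.measure_id: m
    for m in (
        MeasureInfo("ACI", "absolute concentration index", "absolute", _ORD),
        MeasureInfo("BGV", "between-group variance", "absolute", _UNO),
        MeasureInfo("D", "difference", "absolute", _ALL_KINDS),
        MeasureInfo("MDB", "mean difference from best performing subgroup", "absolute", _UNO),
        MeasureInfo("MDM", "mean difference from mean", "absolute", _UNO),
        MeasureInfo("PAR", "population attributable risk", "absolute", _ALL_KINDS),
        MeasureInfo("SII", "slope index of inequality", "absolute", _ORD),
        MeasureInfo("IDIS", "index of disparity", "relative", _UNO),
        MeasureInfo("KMI", "Kunst-Mackenbach index", "relative", _ORD),
        MeasureInfo("MLD", "mean log deviation", "relative", _UNO),
        MeasureInfo("PAF", "population attributable fraction", "relative", _ALL_KINDS),
        MeasureInfo("R", "ratio", "relative", _ALL_KINDS),
        MeasureInfo("RCI", "relative concentration index", "relative", _ORD),
        MeasureInfo("RII", "relative index of inequality", "relative", _ORD),
        MeasureInfo("TI", "Theil index", "relative", _UNO),
    )
}

MEASURE_ORDER: tuple[str, ...] = tuple(MEASURES)


def normalise_measure_id(measure_id: str) -> str:
    """Measure ids are case-insensitive on input, upper-case canonically."""
    mid = measure_id.strip().upper()
    if mid not in MEASURES:
        raise KeyError(f"unknown measure id {measure_id!r}; known: {', '.join(MEASURE_ORDER)}")
    return mid


def applicable_measures(dimension_spec: DimensionSpec) -> set[str]:
    """The set of measure ids admissible for a dimension's kind.

    Ordered dimensions admit 9 measures, binary 4, unordered-many 10.
    """
    if dimension_spec.kind not in (ORDERED, BINARY, UNORDERED_MANY):
        raise ValueError(f"unknown dimension kind {dimension_spec.kind!r}")
    return {mid for mid, info in MEASURES.items() if dimension_spec.kind in info.kinds}


@dataclass(frozen=True)
class MeasureResult:
    """One summary-measure value, optionally with a 95% confidence interval.

    ``estimate`` is None for undefined results (e.g. a ratio with a zero
    denominator); ``notes`` then explains why the cell is blank.
    """

    measure_id: str
    slice_key: tuple
    estimate: Optional[float]
    se: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    ci_method: str = "none"  # "analytic" | "bootstrap" | "none"
    notes: str = ""

    def with_note(self, note: str) -> "MeasureResult":
        joined = f"{self.notes}; {note}" if self.notes else note
        return MeasureResult(
            self.measure_id, self.slice_key, self.estimate, self.se,
            self.ci_lower, self.ci_upper, self.ci_method, joined,
        )


@dataclass(frozen=True)
class RankedSlice:
    """A slice of an ordered dimension together with relative ranks X_j."""

    slice: StratumSlice
    ranks: tuple[float, ...]


@dataclass(frozen=True)
class RegressionFit:
    """A rank regression: predicted values at the extremes of the social scale.

    v0 is the predicted value for a hypothetical person at rank 0 (bottom of
    the social-group distribution), v1 at rank 1 (top).
    """

    v0: float
    v1: float
    slope: float
    intercept: float
    model: str = "wls"


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def weighted_mean(slice: StratumSlice) -> float:
    """National average mu = sum_j p_j y_j (population-share-weighted mean)."""
    if slice.n == 0:
        raise EmptySliceError("cannot average an empty slice")
    return float(np.dot(slice.shares, slice.estimates))


def relative_ranks(slice: StratumSlice) -> RankedSlice:
    """Relative rank X_j = (cumulative share through j) - p_j / 2.

    Subgroups must belong to an ordered dimension and already be sorted from
    most disadvantaged (order 1) to most advantaged.
    """
    if slice.dimension_spec.kind != ORDERED:
        raise ApplicabilityError(
            f"relative ranks require an ordered dimension, got {slice.dimension_spec.kind}"
        )
    p = np.asarray(slice.shares, dtype=float)
    x = np.cumsum(p) - 0.5 * p
    return RankedSlice(slice=slice, ranks=tuple(float(v) for v in x))


def _undefined(slice: StratumSlice, measure_id: str, note: str) -> MeasureResult:
    return MeasureResult(measure_id, slice.key, None, notes=note)


def _result(slice: StratumSlice, measure_id: str, value: float, note: str = "") -> MeasureResult:
    return MeasureResult(measure_id, slice.key, float(value), notes=note)


def _check_applicable(slice: StratumSlice, measure_id: str) -> None:
    if slice.dimension_spec.kind not in MEASURES[measure_id].kinds:
        raise ApplicabilityError(
            f"{measure_id} does not apply to {slice.dimension_spec.kind} dimension "
            f"{slice.dimension_spec.dimension!r}"
        )


def _binary_reference(slice: StratumSlice) -> tuple[SubgroupRecord, SubgroupRecord]:
    """(reference, other) for a binary dimension.

    The reference comes from per-record ``is_reference`` flags if present,
    else from the dimension config (defaults: urban, male).
    """
    a, b = slice.subgroups
    flagged = [r for r in slice.subgroups if r.is_reference]
    if len(flagged) == 1:
        ref = flagged[0]
    else:
        ref_name = slice.dimension_spec.reference_subgroup
        if ref_name is None or ref_name not in (a.subgroup, b.subgroup):
            raise ApplicabilityError(
                f"no reference subgroup configured for binary dimension "
                f"{slice.dimension_spec.dimension!r}"
            )
        ref = a if a.subgroup == ref_name else b
    other = b if ref is a else a
    return ref, other


def _best_performing(slice: StratumSlice) -> SubgroupRecord:
    """Best-performing subgroup: max estimate if favourable, min if adverse.

    Ties break to the larger population share, then lexicographic label.
    """
    sign = 1.0 if slice.indicator.favourable else -1.0
    return max(
        slice.subgroups,
        key=lambda r: (sign * r.estimate, r.population_share, _ReversedLabel(r.subgroup)),
    )


class _ReversedLabel(str):
    """Sort key helper: max() with this picks the lexicographically smaller label."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def _high_low(slice: StratumSlice) -> tuple[SubgroupRecord, SubgroupRecord]:
    """Comparison subgroups (y_high, y_low) for D and R.

    ordered: most advantaged vs most disadvantaged (by rank, regardless of
    which estimate is larger); binary: reference subgroup vs the other;
    unordered: max vs min estimate.
    """
    kind = slice.dimension_spec.kind
    if kind == ORDERED:
        return slice.subgroups[-1], slice.subgroups[0]
    if kind == BINARY:
        return _binary_reference(slice)
    hi = max(slice.subgroups, key=lambda r: (r.estimate, r.population_share, _ReversedLabel(r.subgroup)))
    lo = min(slice.subgroups, key=lambda r: (r.estimate, -r.population_share, r.subgroup))
    return hi, lo


def _reference_subgroup(slice: StratumSlice) -> SubgroupRecord:
    """Reference subgroup for PAR/PAF.

    ordered: most advantaged; binary: configured reference;
    unordered: best-performing subgroup.
    """
    kind = slice.dimension_spec.kind
    if kind == ORDERED:
        return slice.subgroups[-1]
    if kind == BINARY:
        return _binary_reference(slice)[0]
    return _best_performing(slice)


# ---------------------------------------------------------------------------
# measure families
# ---------------------------------------------------------------------------


def compute_pairwise(slice: StratumSlice, kind: str) -> MeasureResult:
    """Difference D = y_high - y_low or ratio R = y_high / y_low."""
    mid = normalise_measure_id(kind)
    if mid not in ("D", "R"):
        raise ValueError("pairwise measures are D and R")
    _check_applicable(slice, mid)
    hi, lo = _high_low(slice)
    if mid == "D":
        return _result(slice, "D", hi.estimate - lo.estimate)
    if lo.estimate == 0:
        return _undefined(slice, "R", f"ratio undefined: y_low = 0 for subgroup {lo.subgroup!r}")
    return _result(slice, "R", hi.estimate / lo.estimate)


def compute_dispersion(slice: StratumSlice, kind: str) -> MeasureResult:
    """Spread measures for unordered dimensions.

    BGV = sum p_j (y_j - mu)^2; MDM = sum p_j |y_j - mu|;
    MDB = sum p_j |y_j - y_best|; IDIS = (1/n) * sum_j |y_j - mu| / mu * 100
    (unweighted sum over subgroups).
    """
    mid = normalise_measure_id(kind)
    if mid not in ("BGV", "MDM", "MDB", "IDIS"):
        raise ValueError("dispersion measures are BGV, MDM, MDB, IDIS")
    _check_applicable(slice, mid)
    p = np.asarray(slice.shares, dtype=float)
    y = np.asarray(slice.estimates, dtype=float)
    mu = weighted_mean(slice)
    if mid == "BGV":
        return _result(slice, "BGV", float(np.sum(p * (y - mu) ** 2)))
    if mid == "MDM":
        return _result(slice, "MDM", float(np.sum(p * np.abs(y - mu))))
    if mid == "MDB":
        ref = _best_performing(slice)
        return _result(
            slice, "MDB", float(np.sum(p * np.abs(y - ref.estimate))),
            note=f"best-performing subgroup: {ref.subgroup}",
        )
    if mu == 0:
        return _undefined(slice, "IDIS", "index of disparity undefined: mean is 0")
    return _result(slice, "IDIS", float(np.sum(np.abs(y - mu)) / mu * 100.0 / slice.n))


def compute_entropy(slice: StratumSlice, kind: str) -> MeasureResult:
    """Entropy-family measures (reported x1000).

    MLD = sum p_j (-ln(y_j/mu)) * 1000; TI = sum p_j (y_j/mu) ln(y_j/mu) * 1000.
    """
    mid = normalise_measure_id(kind)
    if mid not in ("MLD", "TI"):
        raise ValueError("entropy measures are MLD and TI")
    _check_applicable(slice, mid)
    p = np.asarray(slice.shares, dtype=float)
    y = np.asarray(slice.estimates, dtype=float)
    mu = weighted_mean(slice)
    if mu <= 0 or np.any(y <= 0):
        return _undefined(slice, mid, "entropy measure undefined: non-positive estimate or mean")
    ratio = y / mu
    if mid == "MLD":
        return _result(slice, "MLD", float(np.sum(p * (-np.log(ratio))) * 1000.0))
    return _result(slice, "TI", float(np.sum(p * ratio * np.log(ratio)) * 1000.0))


def compute_concentration(ranked: RankedSlice, kind: str) -> MeasureResult:
    """Concentration indices on the ordered social-group distribution.

    ACI = sum p_j (2 X_j - 1) y_j; RCI = ACI / mu * 100.  Positive values
    mean the indicator is concentrated among the advantaged.
    """
    mid = normalise_measure_id(kind)
    if mid not in ("ACI", "RCI"):
        raise ValueError("concentration measures are ACI and RCI")
    slice = ranked.slice
    _check_applicable(slice, mid)
    p = np.asarray(slice.shares, dtype=float)
    y = np.asarray(slice.estimates, dtype=float)
    x = np.asarray(ranked.ranks, dtype=float)
    aci = float(np.sum(p * (2.0 * x - 1.0) * y))
    if mid == "ACI":
        return _result(slice, "ACI", aci)
    mu = weighted_mean(slice)
    if mu == 0:
        return _undefined(slice, "RCI", "relative concentration index undefined: mean is 0")
    return _result(slice, "RCI", aci / mu * 100.0)


def fit_rank_regression(ranked: RankedSlice) -> RegressionFit:
    """Weighted least-squares fit of y_j on the relative rank X_j.

    Weights are the population shares p_j.  Returns predicted values at the
    extremes of the social scale (v0 at rank 0, v1 at rank 1).
    """
    slice = ranked.slice
    x = np.asarray(ranked.ranks, dtype=float)
    y = np.asarray(slice.estimates, dtype=float)
    p = np.asarray(slice.shares, dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("all relative ranks identical; rank regression is degenerate")
    fit = sm.WLS(y, sm.add_constant(x), weights=p).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    return RegressionFit(v0=intercept, v1=intercept + slope, slope=slope, intercept=intercept)


def compute_regression_measure(fit: RegressionFit, slice: StratumSlice, kind: str) -> MeasureResult:
    """Slope/relative index of inequality and Kunst-Mackenbach index.

    SII = v1 - v0 for favourable indicators, v0 - v1 for adverse;
    RII = SII / mu; KMI = v1/v0 for favourable, v0/v1 for adverse.
    """
    mid = normalise_measure_id(kind)
    if mid not in ("SII", "RII", "KMI"):
        raise ValueError("regression measures are SII, RII, KMI")
    _check_applicable(slice, mid)
    fav = slice.indicator.favourable
    sii = fit.v1 - fit.v0 if fav else fit.v0 - fit.v1
    if mid == "SII":
        return _result(slice, "SII", sii)
    if mid == "RII":
        mu = weighted_mean(slice)
        if mu == 0:
            return _undefined(slice, "RII", "relative index of inequality undefined: mean is 0")
        return _result(slice, "RII", sii / mu)
    num, den = (fit.v1, fit.v0) if fav else (fit.v0, fit.v1)
    if den == 0:
        return _undefined(slice, "KMI", "Kunst-Mackenbach index undefined: predicted value at rank 0 is 0")
    return _result(slice, "KMI", num / den)


def compute_attributable(slice: StratumSlice, kind: str) -> MeasureResult:
    """Population attributable risk / fraction.

    PAR = y_ref - mu: the improvement in the national average if every
    subgroup matched the reference subgroup.  PAF = PAR / mu * 100.
    Negative PAR is reported as computed (no flooring at 0 by default;
    pass ``floor_par=True`` to :func:`compute_measure` to clamp).
    """
    mid = normalise_measure_id(kind)
    if mid not in ("PAR", "PAF"):
        raise ValueError("attributable measures are PAR and PAF")
    _check_applicable(slice, mid)
    ref = _reference_subgroup(slice)
    mu = weighted_mean(slice)
    par = ref.estimate - mu
    note = f"reference subgroup: {ref.subgroup}"
    if mid == "PAR":
        return _result(slice, "PAR", par, note=note)
    if mu == 0:
        return _undefined(slice, "PAF", "population attributable fraction undefined: mean is 0")
    return _result(slice, "PAF", par / mu * 100.0, note=note)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_PAIRWISE = {"D", "R"}
_DISPERSION = {"BGV", "MDM", "MDB", "IDIS"}
_ENTROPY = {"MLD", "TI"}
_CONCENTRATION = {"ACI", "RCI"}
_REGRESSION = {"SII", "RII", "KMI"}
_ATTRIBUTABLE = {"PAR", "PAF"}


def compute_measure(slice: StratumSlice, measure_id: str, floor_par: bool = False) -> MeasureResult:
    """Compute one summary measure on a slice.

    Raises :class:`ApplicabilityError` if the measure does not apply to the
    slice's dimension kind; returns an undefined result (estimate None, note
    set) for in-domain degeneracies such as division by zero.
    """
    mid = normalise_measure_id(measure_id)
    if slice.n < 2:
        raise EmptySliceError(f"need at least 2 subgroups to compute {mid}, got {slice.n}")
    if mid in _PAIRWISE:
        return compute_pairwise(slice, mid)
    if mid in _DISPERSION:
        return compute_dispersion(slice, mid)
    if mid in _ENTROPY:
        return compute_entropy(slice, mid)
    if mid in _CONCENTRATION:
        return compute_concentration(relative_ranks(slice), mid)
    if mid in _REGRESSION:
        _check_applicable(slice, mid)
        fit = fit_rank_regression(relative_ranks(slice))
        return compute_regression_measure(fit, slice, mid)
    result = compute_attributable(slice, mid)
    if floor_par and result.estimate is not None and result.estimate < 0:
        floored = MeasureResult(result.measure_id, result.slice_key, 0.0, notes=result.notes)
        return floored.with_note("floored negative value at 0")
    return result


def compute_all_measures(slice: StratumSlice, floor_par: bool = False) -> list[MeasureResult]:
    """All applicable measures for the slice, in the fixed documented order.

    Inapplicable measures are absent (not null-valued); per-measure
    degeneracies yield undefined results with notes, never abort the slice.
    """
    admissible = applicable_measures(slice.dimension_spec)
    return [compute_measure(slice, mid, floor_par=floor_par) for mid in MEASURE_ORDER if mid in admissible]
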