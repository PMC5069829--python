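"""95% confidence intervals for summary measures.

Two routes, mirroring common practice for inequality measures computed from
pre-aggregated subgroup tables:

* **analytic** for the two simple pairwise measures — the difference D uses
  the usual normal interval on a difference of independent estimates, and
  the ratio R a log-delta-method interval;
* **parametric bootstrap** for everything else — per draw, each subgroup
  estimate is resampled from Normal(y_j, se_j) independently (clamped at 0,
  since the indicators are non-negative), the measure is recomputed, and a
  percentile interval is taken.

The bootstrap never sees microdata: it resamples the published subgroup
estimates using their stated standard errors, which is the correctly
specified model for the synthetic fixtures this package generates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .schema_io import BINARY, ORDERED, StratumSlice
from . import measures as m

logger = logging.getLogger(__name__)

#: measures with closed-form intervals; the other 13 are bootstrapped
ANALYTIC_MEASURES = frozenset({"D", "R"})


@dataclass(frozen=True)
class BootstrapConfig:
    """Parametric-bootstrap settings.

    draws: number of bootstrap replicates (>= 100 for a reported CI);
    seed: RNG seed (required for reproducible output);
    interval: only "percentile" is implemented;
    level: CI level in (0, 1).
    """

    draws: int = 2000
    seed: int = 0
    interval: str = "percentile"
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.draws < 100:
            raise ValueError("draws must be >= 100 for a reported CI")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.interval != "percentile":
            raise ValueError("only the percentile interval is implemented")


# ---------------------------------------------------------------------------
# analytic intervals
# ---------------------------------------------------------------------------


def analytic_ci(result: m.MeasureResult, slice: StratumSlice, level: float = 0.95) -> m.MeasureResult:
    """Closed-form CI for D or R.

    D: D +/- z * sqrt(se_high^2 + se_low^2).
    R: R * exp(+/- z * sqrt((se_high/y_high)^2 + (se_low/y_low)^2)).
    """
    if result.measure_id not in ANALYTIC_MEASURES:
        raise ValueError(f"no analytic CI for {result.measure_id}")
    if result.estimate is None:
        return result
    hi, lo = m._high_low(slice)
    if hi.se is None or lo.se is None:
        return result.with_note("CI suppressed: standard error missing")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    if result.measure_id == "D":
        se = float(np.hypot(hi.se, lo.se))
        return m.MeasureResult(
            "D", result.slice_key, result.estimate, se=se,
            ci_lower=result.estimate - z * se, ci_upper=result.estimate + z * se,
            ci_method="analytic", notes=result.notes,
        )
    if hi.estimate == 0 or lo.estimate == 0:
        return result.with_note("CI suppressed: zero estimate in log-scale interval")
    log_se = float(np.sqrt((hi.se / hi.estimate) ** 2 + (lo.se / lo.estimate) ** 2))
    return m.MeasureResult(
        "R", result.slice_key, result.estimate, se=result.estimate * log_se,
        ci_lower=result.estimate * float(np.exp(-z * log_se)),
        ci_upper=result.estimate * float(np.exp(z * log_se)),
        ci_method="analytic", notes=result.notes,
    )


# ---------------------------------------------------------------------------
# vectorised measure kernels (one row of Y per bootstrap draw)
# ---------------------------------------------------------------------------


def _wls_line(Y: np.ndarray, x: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row weighted least squares of y on x with weights p; returns (v0, v1)."""
    xbar = float(np.dot(p, x))
    ybar = Y @ p
    sxx = float(np.dot(p, (x - xbar) ** 2))
    sxy = Y @ (p * (x - xbar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    return intercept, intercept + slope


def _measure_draws(measure_id: str, Y: np.ndarray, slice: StratumSlice) -> np.ndarray:
    """Evaluate one measure on each row of the draw matrix Y (B x n).

    Returns an array of length B with NaN where the measure is undefined for
    a draw.  Subgroup selection that depends on the estimates themselves
    (best-performing subgroup, max/min for unordered D and R) is re-resolved
    per draw, so the bootstrap reflects selection uncertainty too.
    """
    p = np.asarray(slice.shares, dtype=float)
    n = slice.n
    mu = Y @ p
    kind = slice.dimension_spec.kind
    fav = slice.indicator.favourable

    if measure_id in ("D", "R"):
        if kind == ORDERED:
            hi_v, lo_v = Y[:, -1], Y[:, 0]
        elif kind == BINARY:
            ref, other = m._binary_reference(slice)
            ref_idx = slice.subgroups.index(ref)
            hi_v, lo_v = Y[:, ref_idx], Y[:, 1 - ref_idx]
        else:
            hi_v, lo_v = Y.max(axis=1), Y.min(axis=1)
        if measure_id == "D":
            return hi_v - lo_v
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(lo_v != 0, hi_v / lo_v, np.nan)

    if measure_id == "BGV":
        return ((Y - mu[:, None]) ** 2) @ p
    if measure_id == "MDM":
        return np.abs(Y - mu[:, None]) @ p
    if measure_id == "MDB":
        best = Y.max(axis=1) if fav else Y.min(axis=1)
        return np.abs(Y - best[:, None]) @ p
    if measure_id == "IDIS":
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mu != 0, np.abs(Y - mu[:, None]).sum(axis=1) / mu * 100.0 / n, np.nan)

    if measure_id in ("MLD", "TI"):
        out = np.full(Y.shape[0], np.nan)
        ok = (mu > 0) & np.all(Y > 0, axis=1)
        if ok.any():
            ratio = Y[ok] / mu[ok, None]
            if measure_id == "MLD":
                out[ok] = (-np.log(ratio) * p).sum(axis=1) * 1000.0
            else:
                out[ok] = (ratio * np.log(ratio) * p).sum(axis=1) * 1000.0
        return out

    if measure_id in ("ACI", "RCI"):
        x = np.asarray(m.relative_ranks(slice).ranks, dtype=float)
        aci = Y @ (p * (2.0 * x - 1.0))
        if measure_id == "ACI":
            return aci
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mu != 0, aci / mu * 100.0, np.nan)

    if measure_id in ("SII", "RII", "KMI"):
        x = np.asarray(m.relative_ranks(slice).ranks, dtype=float)
        v0, v1 = _wls_line(Y, x, p)
        sii = v1 - v0 if fav else v0 - v1
        if measure_id == "SII":
            return sii
        if measure_id == "RII":
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(mu != 0, sii / mu, np.nan)
        num, den = (v1, v0) if fav else (v0, v1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den != 0, num / den, np.nan)

    if measure_id in ("PAR", "PAF"):
        if kind == ORDERED:
            ref_v = Y[:, -1]
        elif kind == BINARY:
            ref = m._binary_reference(slice)[0]
            ref_v = Y[:, slice.subgroups.index(ref)]
        else:
            ref_v = Y.max(axis=1) if fav else Y.min(axis=1)
        par = ref_v - mu
        if measure_id == "PAR":
            return par
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mu != 0, par / mu * 100.0, np.nan)

    raise KeyError(f"unknown measure id {measure_id!r}")


# ---------------------------------------------------------------------------
# bootstrap interval
# ---------------------------------------------------------------------------


def bootstrap_ci(slice: StratumSlice, measure_id: str, cfg: BootstrapConfig) -> m.MeasureResult:
    """Percentile parametric-bootstrap CI for one measure on one slice.

    Per-subgroup estimates are drawn independently from Normal(y_j, se_j),
    clamped at 0 (indicators are non-negative); the measure is recomputed on
    each draw.  If more than half of the draws are undefined (e.g. a log of
    zero), the CI is suppressed with a note.  Deterministic for a given seed.
    """
    mid = m.normalise_measure_id(measure_id)
    point = m.compute_measure(slice, mid)
    if point.estimate is None:
        return point
    if not slice.has_se:
        return point.with_note("CI suppressed: standard error missing")

    y = np.asarray(slice.estimates, dtype=float)
    se = np.asarray([r.se for r in slice.subgroups], dtype=float)
    rng = np.random.default_rng(cfg.seed)
    Y = rng.normal(y, se, size=(cfg.draws, slice.n))
    clamped = Y < 0
    if clamped.any():
        logger.info(
            "clamped %.2f%% of bootstrap draws at 0 for %s on %s",
            100.0 * clamped.mean(), mid, slice.key,
        )
        Y = np.where(clamped, 0.0, Y)

    values = _measure_draws(mid, Y, slice)
    ok = np.isfinite(values)
    if ok.sum() < cfg.draws / 2:
        return point.with_note(
            f"CI suppressed: {cfg.draws - int(ok.sum())}/{cfg.draws} bootstrap draws undefined"
        )
    values = values[ok]
    alpha = (1.0 - cfg.level) / 2.0
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    return m.MeasureResult(
        mid, slice.key, point.estimate, se=float(values.std(ddof=1)),
        ci_lower=float(lower), ci_upper=float(upper),
        ci_method="bootstrap", notes=point.notes,
    )


def with_ci(slice: StratumSlice, measure_id: str, cfg: BootstrapConfig | None = None) -> m.MeasureResult:
    """One measure with its CI, routed analytic (D, R) or bootstrap (rest)."""
    mid = m.normalise_measure_id(measure_id)
    cfg = cfg or BootstrapConfig()
    if mid in ANALYTIC_MEASURES:
        return analytic_ci(m.compute_measure(slice, mid), slice, level=cfg.level)
    return bootstrap_ci(slice, mid, cfg)


def all_measures_with_ci(slice: StratumSlice, cfg: BootstrapConfig | None = None) -> list[m.MeasureResult]:
    """Every applicable measure with a CI, in the fixed documented order."""
    admissible = m.applicable_measures(slice.dimension_spec)
    return [with_ci(slice, mid, cfg) for mid in m.MEASURE_ORDER if mid in admissible]
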