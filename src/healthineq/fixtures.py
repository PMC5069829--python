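"""Synthetic disaggregated datasets with known inequality structure.

The generator emulates the shape of a health-inequality monitoring
database — settings x survey sources x years x indicators x dimensions,
each stratum split into subgroups with estimates, standard errors and
population shares — while keeping the true inequality parameters known, so
measures, confidence intervals and table views are all testable without any
external data.

A stratum is generated from a linear social gradient: subgroup j at
relative rank X_j receives

    y_j = base + slope * X_j + Normal(0, noise_sd),   truncated at 0,

with the reported standard error set equal to ``noise_sd``.  The slope of
the generating line is therefore the true slope index of inequality (SII)
of the stratum, which makes parameter-recovery and CI-coverage experiments
exact in expectation.  Real survey data differ in ways this deliberately
ignores: sampling designs, clustering, non-normal estimate errors and
share uncertainty are not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .schema_io import (
    BINARY,
    ORDERED,
    UNORDERED_MANY,
    Dataset,
    DimensionSpec,
    IndicatorSpec,
    SettingMeta,
    StratumSlice,
    SubgroupRecord,
    build_slice,
)

#: round-robin benchmarking metadata for generated settings
INCOME_GROUPS = ("low income", "lower middle income", "upper middle income", "high income")
REGIONS = (
    "african region",
    "region of the americas",
    "south-east asia region",
    "european region",
    "eastern mediterranean region",
    "western pacific region",
)

#: a generated spec is rejected if any subgroup's draw would be truncated
#: at zero with probability above this
MAX_TRUNCATION_PROB = 0.01


@dataclass(frozen=True)
class GradientSpec:
    """Parameters of one synthetic stratum with a linear social gradient."""

    base: float
    slope: float
    n_subgroups: int = 5
    shares: Union[str, Sequence[float]] = "equal"
    noise_sd: float = 0.0
    favourable: bool = True
    seed: int = 0

    def share_vector(self) -> np.ndarray:
        if isinstance(self.shares, str):
            if self.shares != "equal":
                raise ValueError(f"shares must be 'equal' or a list, got {self.shares!r}")
            p = np.full(self.n_subgroups, 1.0 / self.n_subgroups)
        else:
            p = np.asarray(self.shares, dtype=float)
            if len(p) != self.n_subgroups:
                raise ValueError(f"expected {self.n_subgroups} shares, got {len(p)}")
            if np.any(p <= 0):
                raise ValueError("shares must be positive")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"shares must sum to 1, got {p.sum():.6f}")
        return p

    def ranks(self) -> np.ndarray:
        p = self.share_vector()
        return np.cumsum(p) - 0.5 * p

    def true_estimates(self) -> np.ndarray:
        """Noiseless subgroup estimates base + slope * X_j."""
        return self.base + self.slope * self.ranks()


def _check_truncation(spec: GradientSpec) -> None:
    means = spec.true_estimates()
    if np.any(means < 0):
        raise ValueError("spec implies negative noiseless estimates")
    if spec.noise_sd > 0:
        p_neg = stats.norm.cdf(-means / spec.noise_sd)
        if np.any(p_neg > MAX_TRUNCATION_PROB):
            raise ValueError(
                f"truncation probability {p_neg.max():.3f} exceeds {MAX_TRUNCATION_PROB}; "
                "raise base or lower noise_sd"
            )


def generate_gradient_slice(
    spec: GradientSpec,
    setting: str = "synthetic setting",
    source: str = "SIM",
    year: int = 2010,
    indicator: Optional[IndicatorSpec] = None,
    dimension: Optional[DimensionSpec] = None,
) -> StratumSlice:
    """Generate one stratum slice from a gradient spec.

    By default the dimension is an ordered one with subgroups ``q1..qn``
    (1 = most disadvantaged).  Pass a binary or unordered ``dimension`` to
    generate the same gradient structure without rank ordering (useful for
    dispersion- and entropy-measure experiments).
    """
    _check_truncation(spec)
    p = spec.share_vector()
    n = spec.n_subgroups
    rng = np.random.default_rng(spec.seed)
    y = spec.true_estimates()
    if spec.noise_sd > 0:
        y = np.maximum(0.0, y + rng.normal(0.0, spec.noise_sd, size=n))
    indicator = indicator or IndicatorSpec(
        "synth", name="synthetic indicator", favourable=spec.favourable, scale=1.0
    )
    if dimension is None:
        names = tuple(f"q{j + 1}" for j in range(n))
        dimension = DimensionSpec("economic status", ORDERED, names)
    else:
        names = dimension.subgroup_names or tuple(f"g{j + 1}" for j in range(n))
        if len(names) != n:
            raise ValueError("dimension subgroup_names must match n_subgroups")
    ordered = dimension.kind == ORDERED
    records = [
        SubgroupRecord(
            setting=setting,
            source=source,
            year=year,
            indicator_id=indicator.indicator_id,
            dimension=dimension.dimension,
            subgroup=names[j],
            estimate=float(y[j]),
            population_share=float(p[j]),
            se=float(spec.noise_sd),
            subgroup_order=j + 1 if ordered else None,
            is_reference=(names[j] == dimension.reference_subgroup) if dimension.reference_subgroup else None,
        )
        for j in range(n)
    ]
    return build_slice(records, indicator, dimension)


@dataclass(frozen=True)
class SliceTruth:
    """True generating parameters of one synthetic stratum (for manifests)."""

    key: tuple
    base: float
    slope: float
    noise_sd: float


def _default_indicators() -> list[IndicatorSpec]:
    return [
        IndicatorSpec("cov_a", name="synthetic intervention coverage A", favourable=True, scale=100.0),
        IndicatorSpec("cov_b", name="synthetic intervention coverage B", favourable=True, scale=100.0),
    ]


def _default_dimensions() -> list[DimensionSpec]:
    return [
        DimensionSpec(
            "economic status",
            ORDERED,
            ("quintile 1 (poorest)", "quintile 2", "quintile 3", "quintile 4", "quintile 5 (richest)"),
        ),
        DimensionSpec("place of residence", BINARY, ("rural", "urban"), reference_subgroup="urban"),
        DimensionSpec(
            "subnational region",
            UNORDERED_MANY,
            ("region alpha", "region beta", "region gamma", "region delta", "region epsilon"),
        ),
    ]


def generate_dataset(
    n_settings: int = 5,
    years: Sequence[int] = (2007, 2012),
    dimensions: Optional[Sequence[DimensionSpec]] = None,
    indicators: Optional[Sequence[IndicatorSpec]] = None,
    seed: int = 0,
    return_truth: bool = False,
):
    """Generate a full synthetic dataset: settings x years x indicators x dimensions.

    Per-stratum gradient parameters are drawn from a seeded hyperprior
    (base ~ U(30, 70), slope ~ U(-25, 25), noise_sd ~ U(0.5, 2), Dirichlet
    shares), chosen so estimates behave like coverage percentages and zero
    truncation is effectively impossible.  Settings receive round-robin
    income groups and regions and alternate survey sources.  The output
    passes :func:`healthineq.schema_io.validate_dataset` with no findings.

    Returns the :class:`Dataset`, or ``(Dataset, list[SliceTruth])`` when
    ``return_truth`` is true.
    """
    if n_settings < 1 or not years:
        raise ValueError("need at least one setting and one year")
    dimensions = list(dimensions) if dimensions is not None else _default_dimensions()
    indicators = list(indicators) if indicators is not None else _default_indicators()
    if not dimensions or not indicators:
        raise ValueError("need at least one dimension and one indicator")
    rng = np.random.default_rng(seed)
    records: list[SubgroupRecord] = []
    truths: list[SliceTruth] = []
    settings = {}
    for i in range(n_settings):
        name = f"setting {i + 1:02d}"
        settings[name] = SettingMeta(
            name, INCOME_GROUPS[i % len(INCOME_GROUPS)], REGIONS[i % len(REGIONS)]
        )
    for i, setting in enumerate(settings):
        source = "DHS" if i % 2 == 0 else "MICS"
        for year in years:
            for ind in indicators:
                for dim in dimensions:
                    n = len(dim.subgroup_names) if dim.subgroup_names else 5
                    shares = rng.dirichlet(np.full(n, 8.0))
                    shares = shares / shares.sum()
                    spec = GradientSpec(
                        base=float(rng.uniform(30.0, 70.0)),
                        slope=float(rng.uniform(-25.0, 25.0)),
                        n_subgroups=n,
                        shares=shares.tolist(),
                        noise_sd=float(rng.uniform(0.5, 2.0)),
                        favourable=ind.favourable,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    sl = generate_gradient_slice(
                        spec, setting=setting, source=source, year=int(year),
                        indicator=ind, dimension=dim,
                    )
                    records.extend(sl.subgroups)
                    truths.append(SliceTruth(sl.key, spec.base, spec.slope, spec.noise_sd))
    ds = Dataset(
        records=records,
        indicators={ind.indicator_id: ind for ind in indicators},
        dimensions={d.dimension: d for d in dimensions},
        settings=settings,
    )
    if return_truth:
        return ds, truths
    return ds


def truth_manifest(truths: Sequence[SliceTruth]) -> pd.DataFrame:
    """Tabulate true generating parameters per stratum (for the fixtures CLI)."""
    return pd.DataFrame(
        [
            {
                "setting": t.key[0],
                "source": t.key[1],
                "year": t.key[2],
                "indicator_id": t.key[3],
                "dimension": t.key[4],
                "base": t.base,
                "slope": t.slope,
                "noise_sd": t.noise_sd,
            }
            for t in truths
        ]
    )
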