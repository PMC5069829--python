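import numpy as np
import pytest

from healthineq.schema_io import (
    BINARY,
    ORDERED,
    UNORDERED_MANY,
    DimensionSpec,
    IndicatorSpec,
    SubgroupRecord,
    build_slice,
)

DIM_NAMES = {ORDERED: "economic status", BINARY: "place of residence", UNORDERED_MANY: "subnational region"}


def make_slice(
    p,
    y,
    kind=ORDERED,
    favourable=True,
    se=None,
    reference_subgroup=None,
    setting="testland",
    source="DHS",
    year=2010,
    indicator_id="ind",
):
    """Build a StratumSlice from raw shares/estimates for tests."""
    n = len(p)
    names = [f"g{j + 1}" for j in range(n)]
    if kind == BINARY:
        assert n == 2
        names = ["rural", "urban"]
        reference_subgroup = reference_subgroup or "urban"
    dim = DimensionSpec(DIM_NAMES[kind], kind, tuple(names), reference_subgroup=reference_subgroup)
    ses = se if se is not None else [None] * n
    if np.isscalar(ses):
        ses = [float(ses)] * n
    records = [
        SubgroupRecord(
            setting=setting,
            source=source,
            year=year,
            indicator_id=indicator_id,
            dimension=dim.dimension,
            subgroup=names[j],
            estimate=float(y[j]),
            population_share=float(p[j]),
            se=None if ses[j] is None else float(ses[j]),
            subgroup_order=j + 1 if kind == ORDERED else None,
        )
        for j in range(n)
    ]
    return build_slice(records, IndicatorSpec(indicator_id, favourable=favourable), dim)


@pytest.fixture
def slice_a():
    """Two wealth quintile halves: p=[.5,.5], y=[20,40], ordered, favourable."""
    return make_slice([0.5, 0.5], [20.0, 40.0], kind=ORDERED, se=1.0)


@pytest.fixture
def slice_b():
    """Three regions: p=[.25,.25,.5], y=[10,20,30], unordered."""
    return make_slice([0.25, 0.25, 0.5], [10.0, 20.0, 30.0], kind=UNORDERED_MANY, se=1.0)


@pytest.fixture
def binary_slice():
    """Rural/urban split with urban as the reference subgroup."""
    return make_slice([0.6, 0.4], [30.0, 50.0], kind=BINARY, se=1.0)


def random_slice(rng, kind=None, favourable=None, with_se=True):
    """A random valid slice for property/oracle tests."""
    kind = kind or rng.choice([ORDERED, BINARY, UNORDERED_MANY])
    n = 2 if kind == BINARY else int(rng.integers(2, 9))
    p = rng.dirichlet(np.full(n, 2.0))
    y = rng.uniform(0.5, 100.0, size=n)
    fav = bool(rng.integers(0, 2)) if favourable is None else favourable
    se = rng.uniform(0.1, 3.0) if with_se else None
    return make_slice(p, y, kind=kind, favourable=fav, se=se)
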