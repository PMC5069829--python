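import pytest

from conftest import make_slice
from healthineq import measures as m
from healthineq.schema_io import BINARY, ORDERED, UNORDERED_MANY, DimensionSpec


class TestBuildingBlocks:
    def test_weighted_mean_examples(self, slice_a, slice_b):
        assert m.weighted_mean(slice_a) == pytest.approx(30.0)
        assert m.weighted_mean(slice_b) == pytest.approx(22.5)

    def test_weighted_mean_single_subgroup_identity(self):
        sl = make_slice([1.0], [17.0], kind=UNORDERED_MANY)
        assert m.weighted_mean(sl) == pytest.approx(17.0)

    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.5, 0.5], [0.25, 0.75]),
            ([0.25, 0.25, 0.25, 0.25], [0.125, 0.375, 0.625, 0.875]),
        ],
    )
    def test_relative_ranks(self, p, expected):
        sl = make_slice(p, list(range(len(p))), kind=ORDERED)
        assert m.relative_ranks(sl).ranks == pytest.approx(expected)

    def test_relative_ranks_require_ordered_dimension(self, slice_b):
        with pytest.raises(m.ApplicabilityError):
            m.relative_ranks(slice_b)


class TestGoldenSlices:
    """Hand-derived values on the two reference slices."""

    @pytest.mark.parametrize(
        "measure_id,expected",
        [
            ("D", 20.0),
            ("R", 2.0),
            ("ACI", 5.0),
            ("RCI", 100.0 / 6.0),
            ("SII", 40.0),
            ("RII", 4.0 / 3.0),
            ("KMI", 5.0),
            ("PAR", 10.0),
            ("PAF", 100.0 / 3.0),
        ],
    )
    def test_ordered_slice_measures(self, slice_a, measure_id, expected):
        assert m.compute_measure(slice_a, measure_id).estimate == pytest.approx(expected)

    @pytest.mark.parametrize(
        "measure_id,expected",
        [
            ("BGV", 68.75),
            ("MDM", 7.5),
            ("MDB", 7.5),
            ("IDIS", 100.0 / 3.0),
            ("MLD", 88.3373),
            ("TI", 75.5107),
            ("PAR", 7.5),
            ("D", 20.0),
            ("R", 3.0),
        ],
    )
    def test_region_slice_measures(self, slice_b, measure_id, expected):
        assert m.compute_measure(slice_b, measure_id).estimate == pytest.approx(expected, rel=1e-4)

    def test_rank_regression_two_points(self, slice_a):
        fit = m.fit_rank_regression(m.relative_ranks(slice_a))
        assert fit.v0 == pytest.approx(10.0)
        assert fit.v1 == pytest.approx(50.0)

    def test_rank_regression_recovers_exact_line(self):
        sl = make_slice([0.25] * 4, [10.0, 20.0, 30.0, 40.0], kind=ORDERED)
        fit = m.fit_rank_regression(m.relative_ranks(sl))
        assert fit.v0 == pytest.approx(5.0)
        assert fit.v1 == pytest.approx(45.0)

    def test_adverse_indicator_swaps_direction(self):
        sl = make_slice([0.5, 0.5], [20.0, 40.0], kind=ORDERED, favourable=False)
        assert m.compute_measure(sl, "SII").estimate == pytest.approx(-40.0)
        assert m.compute_measure(sl, "KMI").estimate == pytest.approx(0.2)


class TestSubgroupResolution:
    def test_ordered_d_uses_rank_not_value(self):
        # most advantaged minus most disadvantaged even when the value is lower
        sl = make_slice([0.5, 0.5], [40.0, 20.0], kind=ORDERED)
        assert m.compute_measure(sl, "D").estimate == pytest.approx(-20.0)

    def test_binary_reference_subgroup(self, binary_slice):
        # urban (reference, 50) minus rural (30)
        assert m.compute_measure(binary_slice, "D").estimate == pytest.approx(20.0)
        assert m.compute_measure(binary_slice, "R").estimate == pytest.approx(50.0 / 30.0)
        assert m.compute_measure(binary_slice, "PAR").estimate == pytest.approx(50.0 - 38.0)

    def test_unordered_extremes(self, slice_b):
        assert m.compute_measure(slice_b, "D").estimate == pytest.approx(20.0)

    def test_adverse_region_reference_is_minimum(self):
        sl = make_slice([0.25, 0.25, 0.5], [10.0, 20.0, 30.0], kind=UNORDERED_MANY, favourable=False)
        # best-performing subgroup for an adverse outcome has the lowest rate
        assert m.compute_measure(sl, "PAR").estimate == pytest.approx(10.0 - 22.5)
        assert m.compute_measure(sl, "MDB").estimate == pytest.approx(
            0.25 * 0 + 0.25 * 10 + 0.5 * 20
        )

    def test_best_performer_tie_breaks_to_larger_share_then_label(self):
        sl = make_slice([0.2, 0.5, 0.3], [30.0, 30.0, 10.0], kind=UNORDERED_MANY)
        res = m.compute_measure(sl, "MDB")
        assert "g2" in res.notes  # larger share wins the tie
        sl2 = make_slice([0.25, 0.25, 0.5], [30.0, 30.0, 10.0], kind=UNORDERED_MANY)
        assert "g1" in m.compute_measure(sl2, "MDB").notes  # equal shares: lexicographic


class TestApplicability:
    def test_ordered_dimension_has_nine_measures(self):
        spec = DimensionSpec("economic status", ORDERED)
        assert m.applicable_measures(spec) == {"D", "R", "PAR", "PAF", "ACI", "RCI", "SII", "RII", "KMI"}

    def test_binary_dimension_has_four_measures(self):
        spec = DimensionSpec("sex", BINARY)
        assert m.applicable_measures(spec) == {"D", "R", "PAR", "PAF"}

    def test_unordered_dimension_has_ten_measures(self):
        spec = DimensionSpec("subnational region", UNORDERED_MANY)
        assert m.applicable_measures(spec) == {
            "D", "R", "PAR", "PAF", "BGV", "MDB", "MDM", "IDIS", "MLD", "TI",
        }

    def test_census_fifteen_measures_seven_absolute_eight_relative(self):
        assert len(m.MEASURES) == 15
        scales = [info.scale for info in m.MEASURES.values()]
        assert scales.count("absolute") == 7
        assert scales.count("relative") == 8
        union = set().union(*(m.applicable_measures(DimensionSpec("d", k)) for k in (ORDERED, BINARY, UNORDERED_MANY)))
        assert union == set(m.MEASURES)

    @pytest.mark.parametrize(
        "kind,count", [(ORDERED, 9), (BINARY, 4), (UNORDERED_MANY, 10)]
    )
    def test_compute_all_measures_counts(self, kind, count):
        n = 2 if kind == BINARY else 4
        sl = make_slice([1.0 / n] * n, [10.0 * (j + 1) for j in range(n)], kind=kind)
        results = m.compute_all_measures(sl)
        assert len(results) == count
        # fixed documented order
        ids = [r.measure_id for r in results]
        assert ids == [mid for mid in m.MEASURE_ORDER if mid in set(ids)]

    def test_inapplicable_measure_raises(self, slice_a, slice_b):
        with pytest.raises(m.ApplicabilityError):
            m.compute_measure(slice_a, "BGV")
        with pytest.raises(m.ApplicabilityError):
            m.compute_measure(slice_b, "SII")

    def test_measure_ids_case_insensitive(self, slice_a):
        assert m.compute_measure(slice_a, "sii").measure_id == "SII"
        with pytest.raises(KeyError):
            m.normalise_measure_id("XYZ")


class TestDegenerateInputs:
    def test_ratio_with_zero_denominator_is_undefined_not_raised(self):
        sl = make_slice([0.5, 0.5], [0.0, 40.0], kind=ORDERED)
        res = m.compute_measure(sl, "R")
        assert res.estimate is None and "y_low" in res.notes

    def test_entropy_with_zero_estimate_is_undefined(self):
        sl = make_slice([0.5, 0.25, 0.25], [0.0, 10.0, 20.0], kind=UNORDERED_MANY)
        for mid in ("MLD", "TI"):
            res = m.compute_measure(sl, mid)
            assert res.estimate is None and res.notes

    def test_all_zero_slice_relative_measures_undefined(self):
        sl = make_slice([0.5, 0.5], [0.0, 0.0], kind=ORDERED)
        assert m.compute_measure(sl, "RCI").estimate is None
        assert m.compute_measure(sl, "RII").estimate is None
        assert m.compute_measure(sl, "PAF").estimate is None

    def test_single_subgroup_slice_rejected(self):
        sl = make_slice([1.0], [10.0], kind=UNORDERED_MANY)
        with pytest.raises(m.EmptySliceError):
            m.compute_measure(sl, "D")

    def test_compute_all_never_aborts_on_undefined_cells(self):
        sl = make_slice([0.5, 0.25, 0.25], [0.0, 10.0, 20.0], kind=UNORDERED_MANY)
        results = m.compute_all_measures(sl)
        assert len(results) == 10
        by_id = {r.measure_id: r for r in results}
        assert by_id["MLD"].estimate is None
        assert by_id["BGV"].estimate is not None

    def test_par_floor_option(self):
        # reference below the mean: PAR negative unless floored
        sl = make_slice([0.5, 0.5], [10.0, 30.0], kind=BINARY, reference_subgroup="rural")
        assert m.compute_measure(sl, "PAR").estimate == pytest.approx(-10.0)
        floored = m.compute_measure(sl, "PAR", floor_par=True)
        assert floored.estimate == 0.0 and "floored" in floored.notes
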