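import pandas as pd
import pytest

from healthineq import fixtures, schema_io
from healthineq.schema_io import (
    DataParseError,
    Dataset,
    DimensionSpec,
    IndicatorSpec,
    SchemaError,
    SettingMeta,
    SubgroupRecord,
    parse_year,
    read_dataset,
    validate_dataset,
    write_dataset,
    write_table,
)

HEADER = "setting,source,year,indicator_id,dimension,subgroup,estimate,se,population_share,subgroup_order"


def _csv_lines(rows):
    return HEADER + "\n" + "\n".join(rows) + "\n"


@pytest.fixture
def ten_row_csv(tmp_path):
    rows = [
        f"aland,DHS,2010,anc4,economic status,q{j},{20 + 5 * j},1.0,0.2,{j}" for j in range(1, 6)
    ] + [
        f"aland,DHS,2012,anc4,economic status,q{j},{25 + 5 * j},1.0,0.2,{j}" for j in range(1, 6)
    ]
    path = tmp_path / "data.csv"
    path.write_text(_csv_lines(rows))
    return path


def test_read_well_formed_csv(ten_row_csv):
    ds = read_dataset(ten_row_csv)
    assert len(ds.records) == 10
    assert len(ds.slice_keys()) == 2
    rec = ds.records[0]
    assert rec.setting == "aland" and rec.estimate == 25.0 and rec.subgroup_order == 1


def test_tab_dialect_gives_identical_dataset(ten_row_csv, tmp_path):
    tab_path = tmp_path / "data.tsv"
    tab_path.write_text(ten_row_csv.read_text().replace(",", "\t"))
    assert read_dataset(tab_path, dialect="tab").records == read_dataset(ten_row_csv).records


def test_missing_column_names_the_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("setting,source,year\nx,DHS,2010\n")
    with pytest.raises(SchemaError, match="population_share"):
        read_dataset(path)


def test_unparseable_row_reported_with_row_number(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        _csv_lines(
            [
                "x,DHS,2010,ind,sex,female,10,1,0.5,",
                "x,DHS,2010,ind,sex,male,not-a-number,1,0.5,",
            ]
        )
    )
    with pytest.raises(DataParseError) as err:
        read_dataset(path)
    assert err.value.row_errors[0][0] == 3  # header is line 1


def test_header_map_handles_synonyms(tmp_path):
    path = tmp_path / "syn.csv"
    path.write_text(
        "country,source,year,indicator_id,dimension,subgroup,value,se,population_share,subgroup_order\n"
        "x,DHS,2010,ind,sex,female,10,1,0.5,\n"
        "x,DHS,2010,ind,sex,male,20,1,0.5,\n"
    )
    ds = read_dataset(path, header_map={"country": "setting", "value": "estimate"})
    assert ds.records[0].setting == "x" and ds.records[0].estimate == 10.0


@pytest.mark.parametrize(
    "raw,expected",
    [("2007", 2007), (2012, 2012), ("2005-06", 2006), ("2005-2006", 2006), ("1999-00", 2000)],
)
def test_parse_year(raw, expected):
    assert parse_year(raw) == expected


def test_shares_not_summing_to_one_loads_but_is_flagged(tmp_path):
    path = tmp_path / "short.csv"
    path.write_text(
        _csv_lines(
            [
                "x,DHS,2010,ind,sex,female,10,1,0.4,",
                "x,DHS,2010,ind,sex,male,20,1,0.4,",
            ]
        )
    )
    ds = read_dataset(path)
    assert len(ds.records) == 2
    findings = validate_dataset(ds, share_tolerance=0.01)
    assert [f.code for f in findings] == ["share_sum"]


def _two_row_dataset(share=0.5, orders=(1, 2), estimates=(10.0, 20.0), dimension="sex"):
    dim_kind = "ordered" if dimension == "economic status" else "binary"
    records = [
        SubgroupRecord("x", "DHS", 2010, "ind", dimension, f"s{i}", estimates[i], share,
                       subgroup_order=orders[i] if orders else None)
        for i in range(2)
    ]
    return Dataset(
        records=records,
        indicators={"ind": IndicatorSpec("ind")},
        dimensions={dimension: DimensionSpec(dimension, dim_kind)},
        settings={"x": SettingMeta("x")},
    )


def test_validate_clean_shares_no_finding():
    assert validate_dataset(_two_row_dataset(share=0.5)) == []


def test_validate_share_sum_finding():
    findings = validate_dataset(_two_row_dataset(share=0.6), share_tolerance=0.01)
    assert len(findings) == 1 and findings[0].code == "share_sum"


def test_validate_rank_gap_finding():
    findings = validate_dataset(_two_row_dataset(orders=(1, 3), dimension="economic status"))
    assert [f.code for f in findings] == ["rank_sequence"]


def test_validate_missing_order_finding():
    findings = validate_dataset(_two_row_dataset(orders=None, dimension="economic status"))
    assert [f.code for f in findings] == ["missing_order"]


def test_validate_negative_estimate_and_duplicate_subgroup():
    ds = _two_row_dataset(estimates=(-1.0, 20.0))
    ds.records[1] = SubgroupRecord("x", "DHS", 2010, "ind", "sex", "s0", 20.0, 0.5)
    codes = sorted(f.code for f in validate_dataset(ds))
    assert codes == ["duplicate_subgroup", "negative_estimate"]


@pytest.mark.parametrize("separator", ["comma", "tab"])
def test_dataset_round_trip_is_lossless(tmp_path, separator):
    ds = fixtures.generate_dataset(n_settings=2, years=[2007], seed=3)
    path = tmp_path / "ds.txt"
    write_dataset(ds, path, separator=separator)
    back = read_dataset(
        path, dialect=separator, indicators=ds.indicators, dimensions=ds.dimensions
    )
    assert back.records == ds.records
    assert back.settings == ds.settings


def test_fixture_datasets_validate_clean():
    ds = fixtures.generate_dataset(n_settings=3, years=[2007, 2012], seed=11)
    assert validate_dataset(ds) == []


@pytest.mark.parametrize("separator,sep", [("comma", ","), ("tab", "\t")])
def test_write_table_structure(tmp_path, separator, sep):
    table = pd.DataFrame({"a": [1, 2], "b": [3.5, 4.5], "c": ["x", "y"]})
    path = tmp_path / "t.txt"
    write_table(table, path, separator=separator)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 3
    assert all(line.count(sep) == 2 for line in lines)
    back = pd.read_csv(path, sep=sep)
    pd.testing.assert_frame_equal(back, table)


def test_write_table_quotes_embedded_separator(tmp_path):
    table = pd.DataFrame({"label": ["a, annotated", "plain"], "v": [1.25, 2.5]})
    path = tmp_path / "q.csv"
    write_table(table, path, separator="comma")
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(back, table)


def test_load_config_merges_over_defaults(tmp_path):
    cfg_path = tmp_path / "cfg.yaml"
    cfg_path.write_text(
        "dimensions:\n"
        "  - dimension: wealth decile\n"
        "    kind: ordered\n"
        "indicators:\n"
        "  - indicator_id: u5mr\n"
        "    favourable: false\n"
        "    scale: 1000\n"
    )
    cfg = schema_io.load_config(cfg_path)
    assert cfg["dimensions"]["wealth decile"].kind == "ordered"
    assert "economic status" in cfg["dimensions"]  # shipped default retained
    assert cfg["indicators"]["u5mr"].favourable is False
    assert cfg["indicators"]["u5mr"].scale == 1000.0


def test_unknown_dimension_kind_is_inferred(tmp_path):
    path = tmp_path / "inf.csv"
    path.write_text(
        _csv_lines(
            [
                "x,DHS,2010,ind,province,north,10,1,0.3,",
                "x,DHS,2010,ind,province,south,20,1,0.3,",
                "x,DHS,2010,ind,province,east,30,1,0.4,",
            ]
        )
    )
    ds = read_dataset(path)
    assert ds.dimensions["province"].kind == "unordered_many"
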