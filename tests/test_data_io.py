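"""LIS CSV reading, filtering, drop accounting and round trips."""

import numpy as np
import pytest

from indirect_ri import (
    ADULT_FILTER,
    MeasurementSeries,
    RecordFilter,
    read_lis_csv,
    write_lis_csv,
)
from indirect_ri.errors import ConfigurationError, DomainError, EmptyInputError
from indirect_ri.synthetic import SyntheticSpec, generate
from .conftest import gaussian_spec, make_series


def write_csv(path, rows, header="analyte,value,age"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadLisCsv:
    def test_age_bounds_inclusive(self, tmp_path):
        p = tmp_path / "lis.csv"
        write_csv(p, [f"TSH,1.{i},{age}" for i, age in
                      enumerate([17, 18, 50, 87, 88])])
        series, log = read_lis_csv(p, "TSH")
        assert series.n == 3
        assert log.age_filtered == 2

    def test_non_positive_dropped_and_counted(self, tmp_path):
        p = tmp_path / "lis.csv"
        write_csv(p, ["TSH,-0.5,40", "TSH,2.5,40", "TSH,0,40"])
        series, log = read_lis_csv(p, "TSH")
        assert series.n == 1
        assert log.non_positive == 2

    def test_non_numeric_dropped(self, tmp_path):
        p = tmp_path / "lis.csv"
        write_csv(p, ["TSH,<0.01,40", "TSH,1.2,40"])
        series, log = read_lis_csv(p, "TSH")
        assert series.n == 1 and log.non_numeric == 1

    def test_other_analytes_excluded(self, tmp_path):
        p = tmp_path / "lis.csv"
        write_csv(p, ["TSH,1.2,40", "FT4,0.9,40"])
        series, log = read_lis_csv(p, "TSH")
        assert series.n == 1 and log.wrong_analyte == 1

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "lis.csv"
        write_csv(p, ["TSH,1.2"], header="analyte,value")
        with pytest.raises(ConfigurationError):
            read_lis_csv(p, "TSH")

    def test_empty_result_raises(self, tmp_path):
        p = tmp_path / "lis.csv"
        write_csv(p, ["TSH,1.2,40"])
        with pytest.raises(EmptyInputError):
            read_lis_csv(p, "FT4")

    def test_decimals_inferred_from_text(self, tmp_path):
        p = tmp_path / "lis.csv"
        write_csv(p, ["TSH,1.25,40", "TSH,2.1,41"])
        series, _ = read_lis_csv(p, "TSH")
        assert series.decimals == 2

    def test_column_mapping(self, tmp_path):
        p = tmp_path / "lis.csv"
        p.write_text("test,result,years\nTSH,1.2,40\n")
        series, _ = read_lis_csv(
            p, "TSH",
            columns={"analyte": "test", "value": "result", "age": "years"},
        )
        assert series.n == 1

    def test_value_filter(self, tmp_path):
        p = tmp_path / "lis.csv"
        write_csv(p, ["TSH,0.5,40", "TSH,5.0,40", "TSH,120.0,40"])
        flt = RecordFilter(age_min=18, age_max=87, value_min=1.0, value_max=100.0)
        series, log = read_lis_csv(p, "TSH", flt)
        assert series.n == 1 and log.value_filtered == 2


class TestRoundTrip:
    def test_synthetic_round_trip(self, tmp_path):
        spec = gaussian_spec(n=1000, seed=5)
        series, _ = generate(spec)
        p = tmp_path / "out.csv"
        write_lis_csv(p, series)
        back, _ = read_lis_csv(p, series.analyte_name, decimals=series.decimals)
        assert back.n == 1000
        assert back.analyte_name == series.analyte_name
        np.testing.assert_allclose(back.values, series.values, rtol=0, atol=1e-9)

    def test_filter_idempotent(self, tmp_path):
        p = tmp_path / "lis.csv"
        rng = np.random.default_rng(0)
        rows = [f"TSH,{v:.1f},{a}" for v, a in
                zip(rng.uniform(0.1, 10, 200), rng.integers(0, 100, 200))]
        write_csv(p, rows)
        first, _ = read_lis_csv(p, "TSH")
        q = tmp_path / "again.csv"
        write_lis_csv(q, first, ages=np.full(first.n, 50))
        second, log = read_lis_csv(q, "TSH")
        np.testing.assert_array_equal(np.sort(first.values), np.sort(second.values))
        assert log.kept == first.n


class TestMeasurementSeries:
    def test_rejects_non_positive(self):
        with pytest.raises(DomainError):
            make_series([1.0, 0.0])

    def test_rejects_wrong_resolution(self):
        with pytest.raises(DomainError):
            make_series([1.25], decimals=1)

    def test_resolution_property(self):
        assert make_series([1.2], decimals=1).resolution == pytest.approx(0.1)

    def test_filter_validation(self):
        with pytest.raises(ConfigurationError):
            RecordFilter(age_min=50, age_max=18)
        with pytest.raises(ConfigurationError):
            RecordFilter(age_min=18, age_max=87, value_min=5.0, value_max=1.0)
        assert ADULT_FILTER.age_min == 18 and ADULT_FILTER.age_max == 87
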