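"""Tissue table reading, elemental ratios, grouping and comparisons."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gulfweed import (
    EmptyInputError,
    SchemaError,
    TissueGenConfig,
    compare_groups,
    elemental_ratios,
    gen_tissue_dataset,
    read_tissue_table,
    summarize_by_group,
)
from gulfweed.tissue import ATOMIC_MASS

HEADER = ("sample_id,cruise,station_id,latitude,longitude,date,species,replicate,"
          "pct_C,pct_N,pct_P,d15N,as_ug_g,era")


def _csv(rows):
    return io.StringIO(HEADER + "\n" + "\n".join(rows) + "\n")


_ROW = "S{i},A20,ST1,{lat},{lon},2021-04-01,S_fluitans_III,1,{c},{n},{p},{d},{a},y2021"


class TestReadTissueTable:
    def test_valid_rows_pass_through(self):
        rows = [_ROW.format(i=i, lat=25, lon=-66, c=30, n=1, p=0.05, d=0.5, a=80)
                for i in range(3)]
        table = read_tissue_table(_csv(rows))
        assert table.n_accepted == 3 and table.n_rejected == 0
        assert table.frame["longitude"].iloc[0] == -66.0

    def test_missing_chemistry_retained_as_nan(self):
        rows = [_ROW.format(i=0, lat=25, lon=-66, c=30, n=1, p="NA", d=0.5, a=80)]
        table = read_tissue_table(_csv(rows))
        assert table.n_accepted == 1
        assert np.isnan(table.frame["pct_P"].iloc[0])
        assert table.frame["pct_C"].iloc[0] == 30.0

    def test_out_of_range_latitude_rejected(self):
        rows = [
            _ROW.format(i=0, lat=95, lon=-66, c=30, n=1, p=0.05, d=0.5, a=80),
            _ROW.format(i=1, lat=25, lon=-66, c=30, n=1, p=0.05, d=0.5, a=80),
        ]
        table = read_tissue_table(_csv(rows))
        assert table.n_rejected == 1 and table.n_accepted == 1
        assert "latitude" in table.rejections[0][1]

    def test_all_missing_chemistry_rejected(self):
        rows = [_ROW.format(i=0, lat=25, lon=-66, c="", n="", p="", d="", a="")]
        with pytest.raises(EmptyInputError):
            read_tissue_table(_csv(rows))  # only row rejected -> empty table

    def test_longitudes_normalized_to_half_open_interval(self):
        rows = [_ROW.format(i=0, lat=25, lon=294, c=30, n=1, p=0.05, d=0.5, a=80)]
        table = read_tissue_table(_csv(rows))
        assert table.frame["longitude"].iloc[0] == pytest.approx(-66.0)

    def test_missing_column_names_the_column(self):
        bad = io.StringIO("sample_id,latitude\nS1,25\n")
        with pytest.raises(SchemaError, match="longitude"):
            read_tissue_table(bad)

    def test_empty_file_is_explicit(self):
        with pytest.raises(EmptyInputError):
            read_tissue_table(io.StringIO(HEADER + "\n"))


class TestElementalRatios:
    def test_weight_basis_direct_ratio(self):
        r = elemental_ratios(30.0, 1.0, 0.05, 100.0, basis="weight")
        assert r.c_to_n == pytest.approx(30.0)
        assert r.as_to_p == pytest.approx(0.2)  # (100/1e4)/0.05

    def test_molar_basis_uses_atomic_masses(self):
        r = elemental_ratios(30.0, 1.0, 0.05, 100.0, basis="molar")
        assert r.c_to_n == pytest.approx((30 / 12.011) / (1 / 14.007), rel=1e-9)

    def test_zero_denominator_flags_not_raises(self):
        r = elemental_ratios(30.0, 0.0, 0.05, 100.0)
        assert np.isnan(r.c_to_n)
        assert "c_to_n" in r.undefined
        assert np.isfinite(r.c_to_p)

    @given(
        c=st.floats(1, 50), n=st.floats(0.1, 5), p=st.floats(0.01, 1),
        a=st.floats(1, 500),
    )
    def test_molar_weight_conversion_round_trips(self, c, n, p, a):
        w = elemental_ratios(c, n, p, a, basis="weight")
        m = elemental_ratios(c, n, p, a, basis="molar")
        assert m.c_to_n * ATOMIC_MASS["C"] / ATOMIC_MASS["N"] == pytest.approx(
            w.c_to_n, abs=1e-12 * abs(w.c_to_n)
        )
        assert m.as_to_p * ATOMIC_MASS["As"] / ATOMIC_MASS["P"] == pytest.approx(
            w.as_to_p, abs=1e-12 * max(abs(w.as_to_p), 1)
        )


class TestSummarize:
    def test_constant_groups(self):
        frame = pd.DataFrame({
            "region": ["SS"] * 3 + ["CAR"] * 3,
            "pct_N": [1.0] * 3 + [1.0] * 3,
        })
        out = summarize_by_group(frame, ("region",), ("pct_N",))
        assert set(out["mean"]) == {1.0}
        assert set(out["sd"]) == {0.0}

    def test_single_group_single_row(self):
        frame = pd.DataFrame({"region": ["SS"] * 4, "pct_N": [1, 2, 3, 4.0]})
        out = summarize_by_group(frame, ("region",), ("pct_N",))
        assert len(out) == 1 and out["n"].iloc[0] == 4

    def test_generator_group_means_recovered_within_3_se(self):
        cfg = TissueGenConfig(n_2021=400, n_1983_1987=0, n_2015_2018=0, seed=21)
        frame = gen_tissue_dataset(cfg)
        from gulfweed import assign_regions

        frame = assign_regions(frame)
        out = summarize_by_group(frame, ("region",), ("pct_N",))
        for _, row in out.iterrows():
            if row["n"] < 30:
                continue
            truth = cfg.n_base + cfg.n_offsets[row["region"]]
            se = row["sd"] / np.sqrt(row["n"])
            # truncation at 0.05 barely moves these means; 3 SE covers it
            assert abs(row["mean"] - truth) < 3 * se + 0.01


class TestCompareGroups:
    def test_identical_distributions_rarely_reject(self):
        rejections = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame({
                "region": ["A"] * 40 + ["B"] * 40,
                "v": rng.normal(0, 1, 80),
            })
            res = compare_groups(frame, "v", "region")
            rejections += res.p_value < 0.05
        assert rejections <= 8  # ~5% expected; binomial slack

    def test_extreme_separation_rejects(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({
            "region": ["A"] * 30 + ["B"] * 30,
            "v": np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)]),
        })
        res = compare_groups(frame, "v", "region")
        assert res.p_value < 1e-6
        assert (res.pairwise["p_holm"] < 0.001).all()

    def test_constant_equal_groups_zero_effect(self):
        frame = pd.DataFrame({"region": ["A"] * 5 + ["B"] * 5, "v": [2.0] * 10})
        res = compare_groups(frame, "v", "region")
        assert res.pairwise["cohens_d"].iloc[0] == 0.0

    def test_insufficient_data_is_not_testable(self):
        frame = pd.DataFrame({"region": ["A", "A", "B"], "v": [1.0, 2.0, 3.0]})
        res = compare_groups(frame, "v", "region")
        assert not res.testable and res.reason
        assert res.method  # the method label travels even when untestable
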