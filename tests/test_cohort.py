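"""Data model, readers/writers and normalization primitives."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centomics.cohort import (
    CohortTable,
    SampleMetadata,
    log_autoscale,
    prevalence_filter,
    read_cohort,
    read_gmt,
    tss_normalize,
    write_cohort,
    write_gmt,
    write_metadata,
)
from centomics.config import AnalysisConfig


def _toy_table(values, kind="metabolite"):
    values = np.asarray(values, dtype=float)
    return CohortTable(
        feature_ids=[f"f{j}" for j in range(values.shape[1])],
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        values=values,
        kind=kind,
    )


class TestSampleMetadata:
    def test_centenarian_requires_frailty_index(self):
        with pytest.raises(ValueError, match="frailty_index"):
            SampleMetadata("s1", "CE")

    def test_non_centenarian_rejects_frailty_index(self):
        with pytest.raises(ValueError, match="frailty_index"):
            SampleMetadata("s1", "YNG", frailty_index=3)

    def test_bad_group(self):
        with pytest.raises(ValueError, match="group"):
            SampleMetadata("s1", "OLD")


class TestReadWrite:
    def test_roundtrip_is_byte_identical(self, tmp_path):
        table = _toy_table([[1.0, 2.5], [0.0, 3.0], [4.0, 0.5]])
        meta = [
            SampleMetadata("s0", "CE", age=101, frailty_index=5),
            SampleMetadata("s1", "ELD", age=70),
            SampleMetadata("s2", "YNG", age=30),
        ]
        tpath, mpath = tmp_path / "t.tsv", tmp_path / "m.tsv"
        write_cohort(table, tpath)
        write_metadata(meta, mpath)
        first = tpath.read_bytes()
        table2, meta2 = read_cohort(tpath, mpath, "metabolite")
        assert table2.values.shape == (3, 2)
        np.testing.assert_array_equal(table2.values, table.values)
        write_cohort(table2, tpath)
        assert tpath.read_bytes() == first

    def test_sample_intersection_drops_extras(self, tmp_path, caplog):
        table = _toy_table([[1.0], [2.0], [3.0]])
        meta = [
            SampleMetadata("s0", "CE", frailty_index=1),
            SampleMetadata("s1", "ELD"),
            SampleMetadata("s2", "YNG"),
            SampleMetadata("s9", "YNG"),  # absent from the table
        ]
        write_cohort(table, tmp_path / "t.tsv")
        write_metadata(meta, tmp_path / "m.tsv")
        with caplog.at_level("INFO"):
            table2, meta2 = read_cohort(tmp_path / "t.tsv", tmp_path / "m.tsv", "metabolite")
        assert table2.n_samples == 3
        assert [m.sample_id for m in meta2] == ["s0", "s1", "s2"]
        assert "s9" in caplog.text

    def test_negative_abundance_names_cell(self, tmp_path):
        (tmp_path / "t.tsv").write_text("feature_id\ts0\ts1\nf0\t1.0\t-1.0\n")
        write_metadata([SampleMetadata("s0", "YNG"), SampleMetadata("s1", "YNG")],
                       tmp_path / "m.tsv")
        with pytest.raises(ValueError, match="s1"):
            read_cohort(tmp_path / "t.tsv", tmp_path / "m.tsv", "metabolite")

    def test_non_numeric_cell_named(self, tmp_path):
        (tmp_path / "t.tsv").write_text("feature_id\ts0\nf0\t1.0\nf1\tabc\n")
        write_metadata([SampleMetadata("s0", "YNG")], tmp_path / "m.tsv")
        with pytest.raises(ValueError, match="f1"):
            read_cohort(tmp_path / "t.tsv", tmp_path / "m.tsv", "metabolite")

    def test_duplicate_feature_id_rejected(self, tmp_path):
        (tmp_path / "t.tsv").write_text("feature_id\ts0\nf0\t1.0\nf0\t2.0\n")
        write_metadata([SampleMetadata("s0", "YNG")], tmp_path / "m.tsv")
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(tmp_path / "t.tsv", tmp_path / "m.tsv", "metabolite")

    def test_gmt_roundtrip(self, tmp_path):
        from centomics.cohort import PathwayMap

        pm = PathwayMap(members={"p1": {"a", "b"}, "p2": {"c"}},
                        names={"p1": "one", "p2": "two"})
        write_gmt(pm, tmp_path / "p.gmt")
        pm2 = read_gmt(tmp_path / "p.gmt")
        assert pm2.members == pm.members
        assert pm2.names == pm.names


class TestTssNormalize:
    @pytest.mark.parametrize(
        "row, scale, expected",
        [
            ([2.0, 2.0], 1e6, [5e5, 5e5]),
            ([1.0, 0.0, 3.0], 1.0, [0.25, 0.0, 0.75]),
        ],
    )
    def test_examples(self, row, scale, expected):
        table = _toy_table([row])
        out = tss_normalize(table, scale)
        np.testing.assert_allclose(out.values[0], expected)
        assert out.is_relative

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="s0"):
            tss_normalize(_toy_table([[0.0, 0.0]]))

    def test_idempotent(self, rng):
        table = _toy_table(rng.gamma(2.0, size=(5, 7)))
        once = tss_normalize(table)
        twice = tss_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)


class TestPrevalenceFilter:
    def test_detection_fraction_strictly_above_threshold(self):
        # 2/10 nonzero -> kept at 0.10; 1/10 -> removed (boundary not >)
        vals = np.zeros((10, 2))
        vals[:2, 0] = 1.0
        vals[0, 1] = 1.0
        out, removed = prevalence_filter(_toy_table(vals), 0.10)
        assert out.feature_ids == ["f0"]
        assert removed == ["f1"]

    def test_zero_threshold_keeps_everything_detected(self):
        vals = np.array([[1.0, 0.0], [0.0, 0.0]])
        out, removed = prevalence_filter(_toy_table(vals), 0.0)
        assert out.feature_ids == ["f0"]

    @given(frac=st.floats(0.05, 0.9))
    @settings(max_examples=25, deadline=None)
    def test_monotone_shrinkage(self, frac):
        rng = np.random.default_rng(1)
        vals = (rng.random((12, 9)) > 0.5) * rng.gamma(1.0, size=(12, 9))
        base, _ = prevalence_filter(_toy_table(vals), 0.0)
        sub, _ = prevalence_filter(_toy_table(vals), frac)
        assert set(sub.feature_ids) <= set(base.feature_ids)


class TestLogAutoscale:
    def test_constant_feature_dropped(self):
        vals = np.array([[1.0, 2.0], [1.0, 5.0], [1.0, 9.0]])
        z, kept = log_autoscale(_toy_table(vals), pseudocount=1.0)
        assert kept == ["f1"]

    def test_columns_standardized(self, rng):
        vals = rng.lognormal(size=(20, 4))
        z, kept = log_autoscale(_toy_table(vals), pseudocount=0.5)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_two_point_feature_centered(self):
        z, kept = log_autoscale(_toy_table([[1.0], [10.0]]), pseudocount=1e-12)
        np.testing.assert_allclose(z.sum(axis=0), 0.0, atol=1e-12)


class TestConfig:
    def test_yaml_roundtrip_unchanged(self, tmp_path):
        cfg = AnalysisConfig(alpha=0.01, fi_cut=12, seed=42)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert AnalysisConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_unknown_key_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("alpha: 0.05\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            AnalysisConfig.from_yaml(tmp_path / "c.yaml")

    @pytest.mark.parametrize("field, value", [
        ("alpha", 1.5), ("prevalence_min", 1.0), ("fi_cut", -1),
        ("two_group_test", "anova"), ("n_permutations", 5),
    ])
    def test_threshold_ranges_enforced(self, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(AnalysisConfig(), **{field: value})
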