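import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from berryplast.core_data import (
    MatrixLoadError,
    SampleNameError,
    average_replicates,
    normalize_to_veraison,
    parse_sample_name,
    read_expression_table,
    write_expression_table,
)
from conftest import build_matrix


class TestSampleNameCodec:
    def test_replicate_averaged_name(self):
        d = parse_sample_name("FA081")
        assert (d.vineyard, d.year, d.stage, d.replicate) == ("FA", "08", 1, None)

    def test_round_trip(self):
        d = parse_sample_name("AM062B")
        assert (d.vineyard, d.year, d.stage, d.replicate) == ("AM", "06", 2, "B")
        assert d.encode() == "AM062B"

    @pytest.mark.parametrize("bad,field", [
        ("AM084A", "stage"),        # stage 4 out of range
        ("AM08", "stage"),          # missing stage digit entirely
        ("A081", "vineyard"),       # 1-letter vineyard code
        ("AMCD081", "vineyard"),    # 4-letter vineyard code
        ("am081", "vineyard"),      # lowercase
        ("AM0812D", "replicate"),   # replicate D invalid
        ("AM8A1", "year"),          # year not two digits
    ])
    def test_malformed_names_name_the_field(self, bad, field):
        with pytest.raises(SampleNameError):
            parse_sample_name(bad)

    @given(
        vineyard=st.text(alphabet=st.characters(min_codepoint=65, max_codepoint=90),
                         min_size=2, max_size=3),
        year=st.integers(0, 99),
        stage=st.integers(1, 3),
        rep=st.sampled_from(["A", "B", "C", None]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_codec_is_a_bijection(self, vineyard, year, stage, rep):
        name = f"{vineyard}{year:02d}{stage}{rep or ''}"
        d = parse_sample_name(name)
        assert d.encode() == name
        assert (d.vineyard, d.year, d.stage, d.replicate) == (vineyard, f"{year:02d}", stage, rep)


class TestTableIO:
    def test_tsv_round_trip(self, tmp_path, six_sample_names):
        m = build_matrix(np.arange(18).reshape(3, 6), six_sample_names)
        path = tmp_path / "m.tsv"
        write_expression_table(m, path)
        back = read_expression_table(path)
        assert back.gene_ids == m.gene_ids
        assert back.sample_names == m.sample_names
        np.testing.assert_allclose(back.values, m.values)
        assert (path.with_suffix(".tsv.json")).exists()

    def test_linear_values_log2_transformed(self, tmp_path):
        path = tmp_path / "lin.tsv"
        path.write_text("gene_id\tAM081A\tAM081B\ng0\t8.0\t4.0\n")
        m = read_expression_table(path, scale="linear")
        np.testing.assert_allclose(m.values, [[3.0, 2.0]])
        assert m.scale_tag == "log2"

    def test_nonpositive_linear_value_rejected(self, tmp_path):
        path = tmp_path / "lin.tsv"
        path.write_text("gene_id\tAM081A\ng0\t-1.0\n")
        with pytest.raises(MatrixLoadError, match="non-positive"):
            read_expression_table(path, scale="linear")

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\tAM081A\ngX\t1.0\ngX\t2.0\n")
        with pytest.raises(MatrixLoadError, match="gX"):
            read_expression_table(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tAM081A\tAM081B\ng0\t1.0\toops\n")
        with pytest.raises(MatrixLoadError, match="AM081B"):
            read_expression_table(path)

    def test_annotation_table_overrides_names(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ng0\t1.0\t2.0\n")
        ann = tmp_path / "ann.tsv"
        ann.write_text("sample\tvineyard\tyear\tstage\treplicate\n"
                       "s1\tAM\t08\t1\tA\ns2\tAM\t08\t2\tA\n")
        m = read_expression_table(path, annotation=ann)
        assert [s.stage for s in m.samples] == [1, 2]


class TestAverageReplicates:
    def test_mean_of_three(self):
        m = build_matrix([[4.0, 6.0, 8.0]], ["AM081A", "AM081B", "AM081C"])
        out = average_replicates(m)
        assert out.n_samples == 1
        assert out.sample_names == ["AM081"]
        np.testing.assert_allclose(out.values, [[6.0]])
        assert out.samples[0].replicate is None

    def test_single_replicate_unchanged(self):
        m = build_matrix([[5.5]], ["AM081B"])
        np.testing.assert_allclose(average_replicates(m).values, [[5.5]])

    def test_matches_brute_force_group_means(self):
        rng = np.random.default_rng(3)
        names = [f"{v}081{r}" for v in ("AM", "CS", "MN") for r in "ABC"]
        vals = rng.normal(size=(5, 9))
        out = average_replicates(build_matrix(vals, names))
        assert out.n_samples == 3
        for j, v in enumerate(("AM", "CS", "MN")):
            expected = vals[:, 3 * j:3 * j + 3].mean(axis=1)
            np.testing.assert_allclose(out.data[f"{v}081"].to_numpy(), expected)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        names = [f"AM08{t}{r}" for t in (1, 2) for r in "AB"]
        m = build_matrix(rng.normal(size=(4, 4)), names)
        once = average_replicates(m)
        twice = average_replicates(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.sample_names == twice.sample_names


class TestVeraisonNormalization:
    def test_self_ratio_is_zero_and_four_fold_is_two(self):
        names = ["AM081A", "AM082A", "AM083A"]
        m = build_matrix([[5.0, 7.0, 5.0], [10.0, 10.0, 10.0]], names)
        out = normalize_to_veraison(m)
        assert out.scale_tag == "log2ratio"
        assert out.sample_names == ["AM082A", "AM083A"]
        np.testing.assert_allclose(out.values, [[2.0, 0.0], [0.0, 0.0]])

    def test_matches_brute_force_subtraction(self):
        rng = np.random.default_rng(9)
        names = [f"{v}08{t}{r}" for v in ("AM", "CS") for t in (1, 2, 3) for r in "ABC"]
        vals = rng.normal(size=(4, 18))
        m = build_matrix(vals, names)
        out = normalize_to_veraison(m)
        # independent loop-based oracle
        for g in range(4):
            for s, name in zip(out.samples, out.sample_names):
                base = [
                    m.values[g, i] for i, d in enumerate(m.samples)
                    if d.vineyard == s.vineyard and d.year == s.year and d.stage == 1
                ]
                expect = m.data.loc[m.gene_ids[g], name] - sum(base) / len(base)
                assert abs(out.data.loc[out.gene_ids[g], name] - expect) < 1e-12

    def test_missing_veraison_group_is_an_error(self):
        m = build_matrix([[1.0, 2.0]], ["AM082A", "AM083A"])
        with pytest.raises(ValueError, match="AM"):
            normalize_to_veraison(m)
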