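import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socmicro.abundance import (
    AbundanceTable,
    AmbiguousSampleError,
    SampleRecord,
    bat_similarity_matrix,
    bray_curtis_similarity,
    normalize,
    read_abundance_table,
    read_sample_metadata,
    select_gut,
    select_latest_faecal,
    simpson_diversity,
    write_abundance_table,
    write_sample_metadata,
)


def table(values, taxa=None, samples=None, tag="raw"):
    values = np.asarray(values, float)
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceTable(taxa, samples, values, tag)


class TestAbundanceTable:
    def test_rejects_negative_value_naming_location(self):
        with pytest.raises(ValueError, match="t1.*s0"):
            table([[1, 2], [-3, 4]])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="duplicate taxon"):
            table([[1, 2], [3, 4]], taxa=["a", "a"])
        with pytest.raises(ValueError, match="duplicate sample"):
            table([[1, 2], [3, 4]], samples=["x", "x"])

    def test_rejects_all_zero_sample_column(self):
        with pytest.raises(ValueError, match="s1.*zero"):
            table([[1, 0], [2, 0]])

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="empty"):
            AbundanceTable([], [], np.empty((0, 0)))


class TestIO:
    def test_plain_tsv_round_trip(self, tmp_path):
        t = table([[1.5, 2], [0, 4], [3, 0]])
        path = tmp_path / "abund.tsv"
        write_abundance_table(t, path)
        back = read_abundance_table(path)
        assert back.taxon_ids == t.taxon_ids
        assert back.sample_ids == t.sample_ids
        np.testing.assert_array_equal(back.values, t.values)

    def test_comment_lines_skipped(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("# a comment\ntaxon_id\ts1\ts2\nt1\t1\t2\nt2\t3\t4\n")
        t = read_abundance_table(path)
        assert t.values.shape == (2, 2)

    def test_negative_entry_rejected_at_read(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("taxon_id\ts1\nt1\t-1\nt2\t2\n")
        with pytest.raises(ValueError, match="t1"):
            read_abundance_table(path)

    def test_metaphlan_dialect_keeps_species_rows_only(self, tmp_path):
        # 5 lineage rows: 2 species-level survive, names stripped
        path = tmp_path / "mp.tsv"
        path.write_text(
            "clade_name\tNCBI_tax_id\tsampleA\tsampleB\n"
            "k__Bacteria\t2\t90.0\t80.0\n"
            "k__Bacteria|p__Firmicutes\t1239\t60.0\t50.0\n"
            "k__Bacteria|p__Firmicutes|g__Lactobacillus\t1578\t40.0\t30.0\n"
            "k__Bacteria|p__Firmicutes|g__Lactobacillus|s__Lactobacillus_reuteri"
            "\t1598\t25.0\t20.0\n"
            "k__Bacteria|p__Proteobacteria|g__Escherichia|s__Escherichia_coli"
            "\t562\t15.0\t10.0\n"
        )
        t = read_abundance_table(path, dialect="metaphlan_merged")
        assert t.taxon_ids == ["Lactobacillus_reuteri", "Escherichia_coli"]
        assert t.normalization_tag == "relative"
        np.testing.assert_array_equal(t.values, [[25, 20], [15, 10]])

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_abundance_table(tmp_path / "x.tsv", dialect="biom")

    def test_sample_metadata_round_trip(self, tmp_path):
        recs = [
            SampleRecord("s1", "A01", "A", 0, "faecal", "pre_merge"),
            SampleRecord("s2", "A01", "A", 30, "gut", "post_merge"),
        ]
        path = tmp_path / "meta.csv"
        write_sample_metadata(recs, path)
        assert read_sample_metadata(path) == recs


class TestNormalize:
    def test_relative_columns_sum_to_one(self):
        t = normalize(table([[2], [2], [6]]), "relative")
        np.testing.assert_allclose(t.values[:, 0], [0.2, 0.2, 0.6])
        assert t.normalization_tag == "relative"

    def test_relative_is_idempotent(self):
        t = normalize(table([[2, 1], [2, 2], [6, 7]]), "relative")
        again = normalize(t, "relative")
        np.testing.assert_allclose(again.values, t.values)

    def test_median_of_ratios_proportional_columns(self):
        # columns (10,20,30) and (20,40,60): size factors in ratio 1:2,
        # normalized columns identical
        t = normalize(table([[10, 20], [20, 40], [30, 60]]),
                      "median_of_ratios")
        np.testing.assert_allclose(t.values[:, 0], t.values[:, 1])
        # hand computation: geomeans (sqrt(200), sqrt(800), sqrt(1800));
        # ratios col0 = (10/14.142.., ...) = 1/sqrt(2) for every taxon
        np.testing.assert_allclose(
            t.values[:, 0], np.array([10, 20, 30]) * np.sqrt(2)
        )

    def test_median_of_ratios_requires_common_taxon(self):
        with pytest.raises(ValueError, match="pseudo-count|relative"):
            normalize(table([[1, 0], [0, 1]]), "median_of_ratios")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_median_of_ratios_equalizes_proportional_pairs(self, seed):
        r = np.random.default_rng(seed)
        col = r.uniform(0.5, 10, size=8)
        factor = r.uniform(0.1, 10)
        t = normalize(table(np.column_stack([col, col * factor])),
                      "median_of_ratios")
        np.testing.assert_allclose(t.values[:, 0], t.values[:, 1])


class TestBrayCurtis:
    def test_identical_columns_give_similarity_one(self):
        s = bray_curtis_similarity(table([[3, 3], [1, 1]]))
        assert s["s0", "s1"] == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        s = bray_curtis_similarity(table([[1, 0], [0, 1]]))
        assert s["s0", "s1"] == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # BC((6,2,0),(2,6,0)) = 8/16 = 0.5
        s = bray_curtis_similarity(table([[6, 2], [2, 6], [0, 0.0001]],
                                         taxa=["a", "b", "c"]))
        assert s["s0", "s1"] == pytest.approx((1 - 8 / 16.0001), abs=1e-3)

    def test_subset_selection(self):
        t = table([[1, 2, 3], [4, 5, 6]])
        s = bray_curtis_similarity(t, sample_subset=["s2", "s0"])
        assert s.ids == ["s2", "s0"]

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            bray_curtis_similarity(table([[1], [2]]))

    def test_matches_scikit_bio(self, rng):
        skbio_div = pytest.importorskip("skbio.diversity")
        vals = rng.uniform(0, 10, size=(12, 5))
        t = table(vals)
        s = bray_curtis_similarity(t)
        dm = skbio_div.beta_diversity("braycurtis", vals.T, ids=t.sample_ids)
        np.testing.assert_allclose(
            1.0 - s.values, dm.data, atol=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_hand_formula_and_scale_invariance(self, seed):
        r = np.random.default_rng(seed)
        vals = r.uniform(0, 5, size=(6, 3)) + 0.01
        s = bray_curtis_similarity(table(vals))
        u, v = vals[:, 0], vals[:, 1]
        expected = 1 - np.abs(u - v).sum() / (u + v).sum()
        assert s["s0", "s1"] == pytest.approx(expected, abs=1e-12)
        # common rescaling of all columns leaves similarity unchanged
        s2 = bray_curtis_similarity(table(vals * 7.3))
        np.testing.assert_allclose(s2.values, s.values, atol=1e-12)
        # symmetry and range
        assert np.array_equal(s.values, s.values.T)
        assert (s.values >= 0).all() and (s.values <= 1).all()


class TestSimpson:
    def test_single_taxon_zero_diversity(self):
        t = table([[5], [0]])
        assert simpson_diversity(t, "s0") == pytest.approx(0.0)

    def test_uniform_four_taxa(self):
        t = table([[1], [1], [1], [1]])
        assert simpson_diversity(t, "s0") == pytest.approx(0.75)

    def test_hand_computed(self):
        t = table([[0.5], [0.3], [0.2]])
        assert simpson_diversity(t, "s0") == pytest.approx(0.62, abs=1e-12)

    def test_unknown_sample(self):
        with pytest.raises(KeyError, match="nope"):
            simpson_diversity(table([[1]]), "nope")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_uniform_composition_maximizes(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(2, 10))
        p = r.dirichlet(np.ones(k))
        vals = np.column_stack([p, np.full(k, 1.0 / k)])
        t = table(vals)
        assert simpson_diversity(t, "s0") <= simpson_diversity(t, "s1") + 1e-12


class TestBatSimilarityMatrix:
    def _setup(self):
        t = table([[5, 5, 1, 5], [1, 1, 5, 1]],
                  samples=["g1", "g2", "g3", "f1"])
        sim = bray_curtis_similarity(t)
        recs = [
            SampleRecord("g1", "batA", "A", 30, "gut", "post_merge"),
            SampleRecord("g2", "batB", "A", 30, "gut", "post_merge"),
            SampleRecord("g3", "batC", "B", 30, "gut", "post_merge"),
            SampleRecord("f1", "batD", "B", 10, "faecal", "post_merge"),
        ]
        return sim, recs

    def test_gut_selection_is_a_relabeling(self):
        sim, recs = self._setup()
        bats, prov = bat_similarity_matrix(sim, recs, select_gut)
        assert bats.ids == ["batA", "batB", "batC"]
        assert bats["batA", "batC"] == sim["g1", "g3"]
        assert prov["selected"]["batB"] == "g2"

    def test_bat_without_gut_sample_dropped_with_provenance(self):
        sim, recs = self._setup()
        _, prov = bat_similarity_matrix(sim, recs, select_gut)
        assert prov["dropped"] == ["batD"]

    def test_multiple_gut_samples_is_ambiguous(self):
        sim, recs = self._setup()
        recs.append(SampleRecord("g2b", "batB", "A", 31, "gut", "post_merge"))
        sim2 = type(sim)(sim.ids + ["g2b"],
                         np.pad(sim.values, ((0, 1), (0, 1))))
        with pytest.raises(AmbiguousSampleError, match="batB"):
            bat_similarity_matrix(sim2, recs, select_gut)

    def test_latest_faecal_before_cutoff_picks_later_sample(self):
        t = table([[5, 4, 1], [1, 2, 5]], samples=["f1", "f2", "x"])
        sim = bray_curtis_similarity(t)
        recs = [
            SampleRecord("f1", "batA", "A", 10, "faecal", "post_merge"),
            SampleRecord("f2", "batA", "A", 40, "faecal", "post_merge"),
            SampleRecord("x", "batB", "B", 5, "faecal", "pre_merge"),
        ]
        bats, prov = bat_similarity_matrix(sim, recs,
                                           select_latest_faecal(60))
        assert prov["selected"]["batA"] == "f2"
        bats2, prov2 = bat_similarity_matrix(sim, recs,
                                             select_latest_faecal(20))
        assert prov2["selected"]["batA"] == "f1"
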