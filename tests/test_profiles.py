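"""OTU table I/O, the correction formula, qPCR division and rarefaction."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from copynorm.profiles import (CommunityProfile, CorrectionError, OtuRecord,
                               ProfileParseError, community_average_gcn,
                               correct_profile, correct_qpcr, lookup_gcn,
                               rarefy, read_profile, read_qpcr, write_profile)
from copynorm.trait import GcnLookup

TABULAR = ("OTU ID\tS1\tS2\ttaxonomy\n"
           "otu1\t10\t5\tk__B; p__X\n"
           "otu2\t10\t15\tk__B; p__Y\n")

QIIME = ("# Constructed from biom file\n"
         "#OTU ID\tS1\tS2\ttaxonomy\n"
         "otu1\t10\t5\tk__B; p__X\n"
         "otu2\t10\t15\tk__B; p__Y\n")


def biom_doc(sparse: bool) -> str:
    doc = {
        "id": None, "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org", "type": "OTU table",
        "generated_by": "t", "date": "",
        "matrix_type": "sparse" if sparse else "dense",
        "matrix_element_type": "float", "shape": [2, 2],
        "rows": [{"id": "otu1", "metadata": {"taxonomy": ["k__B", "p__X"]}},
                 {"id": "otu2", "metadata": {"taxonomy": ["k__B", "p__Y"]}}],
        "columns": [{"id": "S1", "metadata": None},
                    {"id": "S2", "metadata": None}],
    }
    dense = [[10.0, 5.0], [10.0, 15.0]]
    doc["data"] = ([[r, c, dense[r][c]] for r in range(2) for c in range(2)
                    if dense[r][c]] if sparse else dense)
    return json.dumps(doc)


def simple_lookup():
    return GcnLookup(id_map={"otu1": 2.0, "otu2": 1.0},
                     string_map={"k__B; p__X": 2.0, "k__B; p__Y": 1.0})


class TestReaders:
    def test_tabular_with_taxonomy(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(TABULAR)
        prof = read_profile(p)
        assert prof.samples == ["S1", "S2"]
        assert prof.otu_ids == ["otu1", "otu2"]
        np.testing.assert_allclose(prof.counts, [[10, 10], [5, 15]])
        assert prof.otus[0].taxonomy == "k__B; p__X"

    def test_qiime_classic_autodetected(self, tmp_path):
        p = tmp_path / "q.txt"
        p.write_text(QIIME)
        prof = read_profile(p)
        assert prof.source_format == "qiime_classic"
        assert prof.otus[1].taxonomy == "k__B; p__Y"

    @pytest.mark.parametrize("sparse", [True, False])
    def test_biom_sparse_equals_dense(self, tmp_path, sparse):
        p = tmp_path / "b.biom"
        p.write_text(biom_doc(sparse))
        prof = read_profile(p)
        np.testing.assert_allclose(prof.counts, [[10, 10], [5, 15]])
        assert prof.otus[0].taxonomy == "k__B; p__X"

    def test_ragged_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("OTU ID\tS1\tS2\notu1\t10\n")
        with pytest.raises(ProfileParseError, match="line 2"):
            read_profile(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("OTU ID\tS1\notu1\t-3\n")
        with pytest.raises(ProfileParseError, match="negative"):
            read_profile(p)


class TestLookupGcn:
    def test_phylogenetic_mode_keys_on_taxon_id(self):
        otu = OtuRecord("otu1", taxon_id="otu1", taxonomy=None)
        assert lookup_gcn(otu, simple_lookup(), "phylogenetic") == 2.0

    def test_taxonomic_mode_falls_back_to_parent_rank(self):
        lookup = GcnLookup(string_map={"k__A; p__B": 5.0})
        otu = OtuRecord("x", taxonomy="k__A; p__B; g__C")
        assert lookup_gcn(otu, lookup, "taxonomic") == 5.0

    def test_unassigned_is_absent(self):
        assert lookup_gcn(OtuRecord("x"), simple_lookup(), "phylogenetic") is None
        assert lookup_gcn(OtuRecord("x"), simple_lookup(), "taxonomic") is None


class TestAverageGcn:
    def test_uniform_gcn(self):
        assert community_average_gcn([5, 5], [2, 2]) == pytest.approx(2.0)

    def test_read_weighted_mean(self):
        assert community_average_gcn([10, 10], [2, 1]) == pytest.approx(20 / 15)

    def test_single_otu(self):
        assert community_average_gcn([7], [3.0]) == pytest.approx(3.0)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            community_average_gcn([0, 0], [1, 2])


class TestCorrection:
    def test_uniform_gcn_is_count_normalization(self):
        prof = CommunityProfile(["S"], [OtuRecord("a", "a"), OtuRecord("b", "b")],
                                np.array([[30.0, 70.0]]))
        lookup = GcnLookup(id_map={"a": 1.0, "b": 1.0})
        corr = correct_profile(prof, lookup)
        np.testing.assert_allclose(corr.abundance[0], [30, 70])

    def test_printed_formula(self):
        prof = CommunityProfile(["S"], [OtuRecord("a", "a"), OtuRecord("b", "b")],
                                np.array([[10.0, 10.0]]))
        lookup = GcnLookup(id_map={"a": 2.0, "b": 1.0})
        corr = correct_profile(prof, lookup)
        np.testing.assert_allclose(corr.abundance[0], [100 / 3, 200 / 3])
        assert corr.average_gcn["S"] == pytest.approx(20 / 15)

    def test_unassigned_rule_preserves_assigned_ratios(self):
        otus = [OtuRecord("a", "a"), OtuRecord("b", "b"), OtuRecord("u")]
        prof = CommunityProfile(["S"], otus, np.array([[10.0, 10.0, 30.0]]))
        lookup = GcnLookup(id_map={"a": 2.0, "b": 1.0})
        corr = correct_profile(prof, lookup)
        np.testing.assert_allclose(corr.abundance[0],
                                   [13.3333333, 26.6666667, 60.0], rtol=1e-6)
        # the 1:2 ratio among assigned OTUs is preserved
        assert corr.abundance[0][1] / corr.abundance[0][0] == pytest.approx(2.0)
        # the unassigned OTU received the community average
        assert corr.applied_gcn[0][2] == pytest.approx(20 / 15)

    def test_no_resolvable_otu_names_sample(self):
        prof = CommunityProfile(["bad"], [OtuRecord("u")], np.array([[5.0]]))
        with pytest.raises(CorrectionError, match="bad"):
            correct_profile(prof, GcnLookup())

    @given(counts=st.lists(st.integers(1, 1000), min_size=2, max_size=6),
           gcns=st.lists(st.integers(1, 15), min_size=6, max_size=6),
           scale=st.floats(0.1, 100.0))
    @settings(max_examples=60, deadline=None)
    def test_sum_100_and_count_scaling_invariance(self, counts, gcns, scale):
        n = len(counts)
        otus = [OtuRecord(f"o{i}", f"o{i}") for i in range(n)]
        lookup = GcnLookup(id_map={f"o{i}": float(g)
                                   for i, g in enumerate(gcns[:n])})
        c = np.array([counts], dtype=float)
        corr1 = correct_profile(CommunityProfile(["S"], otus, c), lookup)
        corr2 = correct_profile(CommunityProfile(["S"], otus, c * scale), lookup)
        assert corr1.abundance[0].sum() == pytest.approx(100.0, abs=1e-6)
        np.testing.assert_allclose(corr1.abundance, corr2.abundance, rtol=1e-9)
        assert corr1.average_gcn["S"] == pytest.approx(corr2.average_gcn["S"])

    @given(genomes=st.lists(st.integers(1, 500), min_size=2, max_size=6),
           gcns=st.lists(st.integers(1, 15), min_size=6, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_exact_recovery_identity(self, genomes, gcns):
        """Counts proportional to genomes x GCN recover cell fractions and
        genome totals exactly."""
        n = len(genomes)
        g = np.array(gcns[:n], dtype=float)
        ncells = np.array(genomes, dtype=float)
        otus = [OtuRecord(f"o{i}", f"o{i}") for i in range(n)]
        lookup = GcnLookup(id_map={f"o{i}": float(v) for i, v in enumerate(g)})
        prof = CommunityProfile(["S"], otus, (ncells * g)[None, :])
        corr = correct_profile(prof, lookup)
        np.testing.assert_allclose(corr.abundance[0],
                                   ncells / ncells.sum() * 100, rtol=1e-9)
        templates = float((ncells * g).sum())
        recovered = correct_qpcr({"S": templates}, corr.average_gcn)["S"]
        assert recovered == pytest.approx(ncells.sum(), rel=1e-9)


class TestQpcr:
    def test_division_by_average(self):
        out = correct_qpcr({"a": 10.0, "b": 0.0}, {"a": 2.0, "b": 1.5})
        assert out == {"a": 5.0, "b": 0.0}

    def test_missing_average_names_sample(self):
        with pytest.raises(CorrectionError, match="orphan"):
            correct_qpcr({"orphan": 1.0}, {})

    def test_read_qpcr(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("#sample\ttemplates\nS1\t13.3e9\nS2\t7.72e9\n")
        assert read_qpcr(p) == {"S1": 13.3e9, "S2": 7.72e9}


class TestRarefy:
    def make(self, counts):
        otus = [OtuRecord(f"o{i}") for i in range(len(counts[0]))]
        return CommunityProfile([f"S{i}" for i in range(len(counts))], otus,
                                np.array(counts, dtype=float))

    def test_sample_at_depth_unchanged(self):
        prof = self.make([[60, 40]])
        out = rarefy(prof, depth=100, repetitions=10, seed=0)
        np.testing.assert_allclose(out.counts, prof.counts)

    def test_deterministic_under_seed(self):
        prof = self.make([[900, 100]])
        a = rarefy(prof, 100, repetitions=50, seed=42)
        b = rarefy(prof, 100, repetitions=50, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_hypergeometric_expectation(self):
        prof = self.make([[900, 100]])
        out = rarefy(prof, 100, repetitions=1000, seed=7)
        # E = 90; SE of the mean over 1000 hypergeometric draws
        se = np.sqrt(100 * 0.9 * 0.1 * (1000 - 100) / 999) / np.sqrt(1000)
        assert abs(out.counts[0, 0] - 90) < 3 * se

    def test_shallow_sample_passes_through_with_warning(self):
        prof = self.make([[3, 4]])
        with pytest.warns(UserWarning, match="left unrarefied"):
            out = rarefy(prof, 100, repetitions=10, seed=0)
        np.testing.assert_allclose(out.counts, prof.counts)

    def test_non_integer_counts_rejected(self):
        prof = self.make([[1.5, 2.5]])
        with pytest.raises(ValueError, match="integer"):
            rarefy(prof, 2, seed=0)


class TestWriters:
    @pytest.mark.parametrize("text,fmt", [(TABULAR, "tabular"),
                                          (QIIME, "qiime_classic")])
    def test_round_trip_identity_with_uniform_gcn(self, tmp_path, text, fmt):
        src = tmp_path / "in.txt"
        src.write_text(text)
        prof = read_profile(src)
        lookup = GcnLookup(id_map={"otu1": 1.0, "otu2": 1.0})
        corr = correct_profile(prof, lookup)
        dst = tmp_path / "out.txt"
        write_profile(corr, dst)
        back = read_profile(dst)
        assert back.source_format == fmt
        assert back.otu_ids == prof.otu_ids  # order preserved
        norm = prof.counts / prof.counts.sum(axis=1, keepdims=True) * 100
        np.testing.assert_allclose(back.counts, norm, rtol=1e-12)

    def test_biom_in_biom_out(self, tmp_path):
        src = tmp_path / "in.biom"
        src.write_text(biom_doc(sparse=True))
        prof = read_profile(src)
        corr = correct_profile(prof, simple_lookup())
        dst = tmp_path / "out.biom"
        write_profile(corr, dst)
        assert json.loads(dst.read_text())["format"].startswith("Biological")
        back = read_profile(dst)
        np.testing.assert_allclose(back.counts, corr.abundance, rtol=1e-12)
        sidecar = (tmp_path / "out.biom.avg_gcn.tsv").read_text()
        assert "S1" in sidecar and "average_gcn" in sidecar
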