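"""Interval-based gene mapping, exact hypergeometric enrichment and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import comb

from paretognome.annotate import (
    GeneInterval,
    bh_fdr,
    hypergeometric_enrichment,
    intersect_gene_lists,
    map_snps_to_genes,
    read_bed,
    read_gff3,
    read_gmt,
)


def _markers(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "id"])


INTERVALS = [
    GeneInterval("1", 100, 200, "GENEA"),
    GeneInterval("1", 300, 400, "GENEB"),
]


class TestMapping:
    def test_containment_is_genic(self):
        ann = map_snps_to_genes(_markers([("1", 150, "m1")]), INTERVALS)
        assert ann[0].category == "genic"
        assert ann[0].genes == ("GENEA",)

    def test_boundary_position_inclusive(self):
        ann = map_snps_to_genes(_markers([("1", 200, "m1"), ("1", 100, "m2")]), INTERVALS)
        assert all(a.category == "genic" for a in ann)

    def test_equidistant_marker_reports_both_flanks(self):
        ann = map_snps_to_genes(_markers([("1", 250, "m1")]), INTERVALS)
        assert ann[0].category == "intergenic"
        assert set(ann[0].genes) == {"GENEA", "GENEB"}
        assert ann[0].distances == (50, 50)

    def test_one_sided_flank_at_chromosome_end(self):
        ann = map_snps_to_genes(_markers([("1", 500, "m1")]), INTERVALS)
        assert ann[0].genes == ("GENEB",)
        assert ann[0].distances == (100,)

    def test_overlapping_intervals_report_all_symbols(self):
        ivs = INTERVALS + [GeneInterval("1", 120, 180, "GENEC")]
        ann = map_snps_to_genes(_markers([("1", 150, "m1")]), ivs)
        assert set(ann[0].genes) == {"GENEA", "GENEC"}

    def test_unknown_chromosome_warned_and_flankless(self):
        with pytest.warns(UserWarning, match="absent"):
            ann = map_snps_to_genes(_markers([("2", 10, "m1")]), INTERVALS)
        assert ann[0].category == "intergenic"
        assert ann[0].genes == ()

    def test_every_marker_annotated_exactly_once(self):
        rng = np.random.default_rng(0)
        markers = _markers([("1", int(p), f"m{i}") for i, p in
                            enumerate(rng.integers(1, 600, size=50))])
        ann = map_snps_to_genes(markers, INTERVALS)
        assert [a.marker_id for a in ann] == list(markers["id"])


class TestReaders:
    def test_bed_is_converted_to_one_based_inclusive(self, tmp_path):
        (tmp_path / "g.bed").write_text("1\t99\t200\tGENEA\t0\t+\n")
        iv = read_bed(tmp_path / "g.bed")[0]
        assert (iv.start, iv.end, iv.strand) == (100, 200, "+")

    def test_gff3_gene_records(self, tmp_path):
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;Name=GENEA\n"
            "1\tsrc\texon\t100\t150\t.\t+\t.\tID=e1\n"
        )
        ivs = read_gff3(tmp_path / "g.gff3")
        assert len(ivs) == 1
        assert ivs[0].symbol == "GENEA"
        assert (ivs[0].start, ivs[0].end) == (100, 200)

    def test_gmt_sets(self, tmp_path):
        (tmp_path / "c.gmt").write_text("setA\tdesc\tg1\tg2\nsetB\tdesc\tg3\n")
        sets = read_gmt(tmp_path / "c.gmt")
        assert sets == {"setA": {"G1", "G2"}, "setB": {"G3"}}


class TestHypergeometric:
    def test_full_overlap_exact_probability(self):
        """All 5 query genes inside a 5-gene set from a 10-gene universe:
        only 1 of C(10,5)=252 draws achieves it, so p = 1/252."""
        universe = [f"g{i}" for i in range(10)]
        collection = {"S": set(universe[:5])}
        result = hypergeometric_enrichment(universe[:5], collection, universe)
        assert result.loc[0, "p"] == pytest.approx(1 / comb(10, 5, exact=True), abs=1e-12)
        assert result.loc[0, "k"] == 5

    def test_zero_overlap_certain_event(self):
        universe = [f"g{i}" for i in range(10)]
        result = hypergeometric_enrichment(
            universe[5:], {"S": set(universe[:5])}, universe
        )
        assert result.loc[0, "p"] == pytest.approx(1.0)
        assert not result["significant"].any()

    def test_matches_exact_pmf_summation(self):
        """Upper-tail p equals the direct sum of hypergeometric pmf terms."""
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(200)]
        for _ in range(20):
            K, n = rng.integers(5, 100, size=2)
            genes = list(rng.choice(universe, size=K, replace=False))
            query = list(rng.choice(universe, size=n, replace=False))
            result = hypergeometric_enrichment(query, {"S": set(genes)}, universe)
            k = int(result.loc[0, "k"])
            N = 200
            exact = sum(
                comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
                for x in range(k, min(K, n) + 1)
            ) / comb(N, n, exact=True)
            assert result.loc[0, "p"] == pytest.approx(exact, rel=1e-12)

    def test_empty_universe_rejected_and_empty_query_warns(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["g1"], {"S": {"g1"}}, [])
        with pytest.warns(UserWarning, match="empty"):
            out = hypergeometric_enrichment(["zz"], {"S": {"g1"}}, ["g1", "g2"])
        assert out.empty


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_on_hand_computed_triple(self):
        # p*m/rank = (0.03, 0.03, 0.03) after the step-up minimum
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        # a second hand-worked triple
        assert np.allclose(bh_fdr([0.01, 0.04, 0.9]), [0.03, 0.06, 0.9])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_never_below_raw_and_order_preserved(self, p):
        adj = bh_fdr(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        # monotone in the sorted order
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_idempotent_on_adjusted_monotone_input(self):
        adj = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(bh_fdr(adj), adj)


class TestIntersections:
    def test_overlap_semantics(self):
        out = intersect_gene_lists(["a", "b", "B"], ["b", "c"], "ref")
        assert out["overlap"] == ["B"]
        assert out["query_size"] == 2  # deduplicated, case-insensitive
        assert out["overlap_count"] == 1

    def test_query_subset_of_reference(self):
        out = intersect_gene_lists(["x", "y"], ["x", "y", "z"])
        assert out["overlap"] == ["X", "Y"]

    def test_empty_reference_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = intersect_gene_lists(["a"], [])
        assert out["overlap_count"] == 0
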