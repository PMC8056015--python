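import numpy as np
import pytest

from svmatac import (
    BinLinkMap,
    CoAccessLinkTable,
    impute,
    impute_group,
    make_fixed_bins,
    map_links_to_bins,
    read_links,
    score_coaccessibility,
)
from svmatac.genome import GenomicInterval
from svmatac.impute import parse_peak_string

from conftest import groups_for, matrix_from_dense


def impute_oracle(dense, labels, pairs, c_int):
    """Independent triple-loop (groups x pairs x cells) reference."""
    dense = np.asarray(dense)
    out = dense.copy()
    for g in set(labels):
        rows = [j for j, lab in enumerate(labels) if lab == g]
        for i, k, score in pairs:
            if score < c_int:
                continue
            for a, b in ((i, k), (k, i)):
                if all(dense[j, b] == 1 for j in rows):  # partner saturated
                    for j in rows:
                        out[j, a] = 1
    return out


class TestReadLinks:
    def test_underscore_dialect(self, tmp_path):
        p = tmp_path / "links.csv"
        p.write_text("Peak1,Peak2,coaccess\nchr1_100_600,chr1_9000_9500,0.41\n")
        table = read_links(p)
        a, b, s = table.links[0]
        assert (a.chrom, a.start, a.end) == ("chr1", 100, 600)
        assert (b.start, b.end) == (9000, 9500) and s == 0.41

    def test_colon_dash_dialect_equivalent(self, tmp_path):
        p = tmp_path / "links.csv"
        p.write_text("Peak1,Peak2,coaccess\nchr1:100-600,chr1:9000-9500,0.41\n")
        assert read_links(p).links[0][0] == GenomicInterval("chr1", 100, 600)

    def test_na_rows_dropped(self, tmp_path):
        p = tmp_path / "links.csv"
        p.write_text(
            "Peak1,Peak2,coaccess\n"
            "chr1_0_100,chr1_200_300,NA\n"
            "chr1_0_100,chr1_400_500,0.5\n"
        )
        assert len(read_links(p)) == 1

    def test_tsv_accepted(self, tmp_path):
        p = tmp_path / "links.tsv"
        p.write_text("Peak1\tPeak2\tcoaccess\nchr1_0_100\tchr1_200_300\t0.9\n")
        assert len(read_links(p)) == 1

    def test_unparseable_peak_string_quoted(self):
        with pytest.raises(ValueError, match="wat"):
            parse_peak_string("wat")


class TestMapLinksToBins:
    bins = make_fixed_bins({"chr1": 50000}, 5000)

    def test_leftmost_bin_wins(self):
        table = CoAccessLinkTable(
            [(GenomicInterval("chr1", 4900, 5200), GenomicInterval("chr1", 20000, 20100), 0.5)]
        )
        lm = map_links_to_bins(table, self.bins)
        assert dict(lm.items()) == {(0, 4): 0.5}

    def test_same_bin_link_dropped(self):
        table = CoAccessLinkTable(
            [(GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400), 0.9)]
        )
        assert len(map_links_to_bins(table, self.bins)) == 0

    def test_reciprocal_pairs_keep_max_score(self):
        A = GenomicInterval("chr1", 100, 200)
        B = GenomicInterval("chr1", 9000, 9100)
        table = CoAccessLinkTable([(A, B, 0.3), (B, A, 0.5)])
        lm = map_links_to_bins(table, self.bins)
        assert dict(lm.items()) == {(0, 1): 0.5}

    def test_unknown_chromosome_dropped_not_error(self):
        table = CoAccessLinkTable(
            [(GenomicInterval("chrZ", 0, 100), GenomicInterval("chr1", 0, 100), 0.9)]
        )
        assert len(map_links_to_bins(table, self.bins)) == 0

    def test_order_independent(self, rng):
        links = []
        for _ in range(50):
            s1 = int(rng.integers(0, 45000))
            s2 = int(rng.integers(0, 45000))
            links.append(
                (GenomicInterval("chr1", s1, s1 + 300),
                 GenomicInterval("chr1", s2, s2 + 300),
                 float(rng.random()))
            )
        lm1 = map_links_to_bins(CoAccessLinkTable(links), self.bins)
        shuffled = [links[i] for i in rng.permutation(len(links))]
        lm2 = map_links_to_bins(CoAccessLinkTable(shuffled), self.bins)
        assert dict(lm1.items()) == dict(lm2.items())

    def test_called_bins_rejected(self):
        called = make_fixed_bins({"chr1": 10000}, 5000)
        called.kind = "called"
        with pytest.raises(ValueError, match="fixed_bin"):
            map_links_to_bins(CoAccessLinkTable([]), called)


class TestImputeGroup:
    def test_saturated_partner_propagates(self):
        dense = np.zeros((5, 3), dtype=int)
        dense[:, 1] = 1          # column k saturated
        dense[0, 0] = 1          # column i one of five
        lm = BinLinkMap({(0, 1): 0.3})
        out = impute_group(matrix_from_dense(dense), lm, c_int=0.25)
        assert out.values.toarray()[:, 0].min() == 1

    def test_below_cutoff_no_change(self):
        dense = np.zeros((5, 2), dtype=int)
        dense[:, 1] = 1
        lm = BinLinkMap({(0, 1): 0.2})
        out = impute_group(matrix_from_dense(dense), lm, c_int=0.25)
        np.testing.assert_array_equal(out.values.toarray(), dense)

    def test_unsaturated_partner_no_change(self):
        dense = np.ones((5, 2), dtype=int)
        dense[3, 1] = 0  # one zero: sum != n
        dense[:, 0] = 0
        lm = BinLinkMap({(0, 1): 0.9})
        out = impute_group(matrix_from_dense(dense), lm, c_int=0.25)
        np.testing.assert_array_equal(out.values.toarray(), dense)

    def test_single_pass_does_not_cascade(self):
        # chain 0-1-2: col 2 saturated; single pass lifts col 1 but not col 0
        dense = np.zeros((4, 3), dtype=int)
        dense[:, 2] = 1
        lm = BinLinkMap({(0, 1): 0.9, (1, 2): 0.9})
        out = impute_group(matrix_from_dense(dense), lm).values.toarray()
        assert out[:, 1].min() == 1 and out[:, 0].max() == 0
        cascaded = impute_group(
            matrix_from_dense(dense), lm, cascade=True
        ).values.toarray()
        assert cascaded[:, 0].min() == 1

    def test_fixed_point_mode_is_idempotent(self, rng):
        # Single-pass imputation is deliberately NOT idempotent when links
        # chain through a newly saturated column (see
        # test_single_pass_does_not_cascade); the fixed-point variant is.
        for _ in range(20):
            dense = (rng.random((6, 20)) < 0.6).astype(np.int8)
            pairs = {
                (int(a), int(b)): float(rng.random())
                for a, b in rng.integers(0, 20, size=(15, 2))
                if a < b
            }
            lm = BinLinkMap(pairs)
            once = impute_group(matrix_from_dense(dense), lm, cascade=True)
            twice = impute_group(once, lm, cascade=True)
            assert once.equals(twice)

    def test_single_pass_rerun_identity_without_chains(self, rng):
        # with a single link, re-application cannot find new work
        for _ in range(10):
            dense = (rng.random((5, 6)) < 0.5).astype(np.int8)
            dense[:, 3] = 1
            lm = BinLinkMap({(0, 3): 0.9})
            once = impute_group(matrix_from_dense(dense), lm)
            assert impute_group(once, lm).equals(once)


class TestImputeGrouped:
    def test_propagation_stays_within_group(self):
        dense = np.zeros((8, 2), dtype=int)
        dense[0:4, 1] = 1  # saturated in group A only
        m = matrix_from_dense(dense)
        g = groups_for(m, ["A"] * 4 + ["B"] * 4)
        out = impute(m, g, BinLinkMap({(0, 1): 0.5})).values.toarray()
        assert out[:4, 0].min() == 1 and out[4:, 0].max() == 0

    def test_empty_linkmap_is_identity(self, small_matrix):
        g = groups_for(small_matrix, ["A", "A", "A"])
        out = impute(small_matrix, g, BinLinkMap({}))
        assert out.equals(small_matrix)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 30))
            m_peaks = int(rng.integers(2, 60))
            dense = (rng.random((n, m_peaks)) < rng.uniform(0.1, 0.6)).astype(np.int8)
            labels = [f"g{rng.integers(3)}" for _ in range(n)]
            raw_pairs = [
                (int(a), int(b), float(rng.random()))
                for a, b in rng.integers(0, m_peaks, size=(25, 2))
                if a != b
            ]
            lm = BinLinkMap.from_pairs(raw_pairs)
            mat = matrix_from_dense(dense)
            got = impute(mat, groups_for(mat, labels), lm).values.toarray()
            dedup = [(i, k, s) for (i, k), s in lm.items()]
            np.testing.assert_array_equal(
                got, impute_oracle(dense, labels, dedup, 0.25)
            )


class TestScoreCoaccessibility:
    def test_identical_columns_score_one(self, rng):
        col = (rng.random(40) < 0.5).astype(int)
        col[0] = 1
        dense = np.stack([col, col], axis=1)
        table = score_coaccessibility(matrix_from_dense(dense), min_cells=1)
        assert table.links[0][2] == pytest.approx(1.0)

    def test_independent_columns_score_near_zero(self, rng):
        dense = (rng.random((500, 2)) < 0.5).astype(int)
        table = score_coaccessibility(matrix_from_dense(dense), min_cells=1)
        assert abs(table.links[0][2]) < 0.2

    def test_distance_gate(self):
        dense = np.ones((4, 2), dtype=int)
        dense[0, 0] = 0
        dense[1, 1] = 0
        m = matrix_from_dense(dense, bin_size=1_000_000)
        table = score_coaccessibility(m, max_distance=500_000, min_cells=1)
        assert len(table) == 0

    def test_constant_column_scores_zero(self):
        dense = np.ones((6, 2), dtype=int)
        dense[:3, 0] = 0
        table = score_coaccessibility(matrix_from_dense(dense), min_cells=1)
        assert table.links[0][2] == 0.0

    def test_negative_correlation_clamped(self):
        dense = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        table = score_coaccessibility(matrix_from_dense(dense), min_cells=1)
        assert table.links[0][2] == 0.0
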