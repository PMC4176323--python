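import numpy as np
import pandas as pd
import pytest

from endmate import pair_analysis as pa
from endmate.end_clustering import Cluster
from endmate.gene_annotation import ClusterGeneLink
from endmate.io_models import ENDPAIR_COLUMNS, GeneModel
from oracles import crosstab_oracle, hypergeom_sf_oracle, jaccard_oracle, poisson_sf_oracle


def _matrix(o, gene="G1"):
    o = np.asarray(o, dtype=np.int64)
    return pa.PairMatrix(
        gene_id=gene,
        tsc_ids=[f"T{i}" for i in range(o.shape[0])],
        pac_ids=[f"P{j}" for j in range(o.shape[1])],
        o=o,
    )


def _pairs_frame(rows):
    """rows: (lib, pos5, pos3, count) on chr1 '+'."""
    recs = []
    for lib, pos5, pos3, n in rows:
        for _ in range(n):
            recs.append(
                (lib, "chr1", pos5, "+", 60, "chr1", pos3, "+", 60, "PAS", "", "")
            )
    return pd.DataFrame(recs, columns=ENDPAIR_COLUMNS)


def _cluster(kind, start, rep=None):
    return Cluster(
        cluster_id=f"{kind}:chr1:+:{start}", kind=kind, chrom="chr1", strand="+",
        start=start, rep_pos=start if rep is None else rep,
    )


class TestBuildMatrix:
    def test_two_by_two_tabulation(self):
        tscs = [_cluster("TSC", 0), _cluster("TSC", 1000)]
        pacs = [_cluster("PAC", 10_000), _cluster("PAC", 12_000)]
        rows = [
            ("l1", 10, 10_010, 90), ("l1", 1010, 12_010, 90),
            ("l1", 10, 12_010, 10), ("l1", 1010, 10_010, 10),
        ]
        assigned = pa.assign_pairs_to_clusters(_pairs_frame(rows), tscs, pacs)
        m = pa.build_pair_matrix(
            assigned, [c.cluster_id for c in tscs], [c.cluster_id for c in pacs], "G"
        )
        assert m.o.tolist() == [[90, 10], [10, 90]]
        assert m.N == 200
        assert m.T.tolist() == [100, 100] and m.P.tolist() == [100, 100]

    def test_single_cell_matrix(self):
        tscs, pacs = [_cluster("TSC", 0)], [_cluster("PAC", 5000)]
        assigned = pa.assign_pairs_to_clusters(
            _pairs_frame([("l1", 10, 5010, 30)]), tscs, pacs
        )
        m = pa.build_pair_matrix(assigned, [tscs[0].cluster_id], [pacs[0].cluster_id], "G")
        assert m.o.tolist() == [[30]] and m.N == 30

    def test_matches_crosstab_oracle(self, rng):
        tsc_starts = [0, 1000, 2000]
        pac_starts = [50_000, 52_000]
        tscs = [_cluster("TSC", s) for s in tsc_starts]
        pacs = [_cluster("PAC", s) for s in pac_starts]
        rows = []
        obs = []
        for _ in range(500):
            i = int(rng.integers(0, 3))
            j = int(rng.integers(0, 2))
            lib = str(rng.choice(["a", "b"]))
            rows.append((lib, tsc_starts[i] + 5, pac_starts[j] + 5, 1))
            obs.append((tscs[i].cluster_id, pacs[j].cluster_id))
        assigned = pa.assign_pairs_to_clusters(_pairs_frame(rows), tscs, pacs)
        m = pa.build_pair_matrix(
            assigned, [c.cluster_id for c in tscs], [c.cluster_id for c in pacs], "G"
        )
        exp = crosstab_oracle(obs, [c.cluster_id for c in tscs], [c.cluster_id for c in pacs])
        for i, t in enumerate(m.tsc_ids):
            for j, p in enumerate(m.pac_ids):
                assert m.o[i, j] == exp[(t, p)]
        assert m.o_by_lib.sum() == m.N


class TestIndependencePvalue:
    def test_diagonal_cell_matches_summation_oracle(self):
        m = _matrix([[90, 10], [10, 90]])
        link = pa.pair_independence_pvalue(m, 0, 0)
        assert link.e == pytest.approx(50.0)
        assert link.p_value == pytest.approx(poisson_sf_oracle(90, 50.0), rel=1e-9)

    def test_zero_observed_gives_one(self):
        m = _matrix([[0, 10], [10, 90]])
        assert pa.pair_independence_pvalue(m, 0, 0).p_value == 1.0

    def test_one_by_one_convention(self):
        assert pa.pair_independence_pvalue(_matrix([[42]]), 0, 0).p_value == 1.0

    def test_observed_at_expectation_is_not_significant(self):
        # o exactly proportional to marginals: survival at the mean >= 0.4
        m = _matrix([[100, 100], [100, 100]])
        for i in range(2):
            for j in range(2):
                assert pa.pair_independence_pvalue(m, i, j).p_value >= 0.4

    def test_expectations_sum_to_N(self, rng):
        o = rng.integers(0, 40, size=(3, 3))
        m = _matrix(o)
        if m.N == 0:
            return
        total = sum(
            pa.pair_independence_pvalue(m, i, j).e for i in range(3) for j in range(3)
        )
        assert total == pytest.approx(m.N, rel=1e-12)


class TestSelectPreferred:
    totals = {"l1": 1_000_000}

    def test_exactly_ten_tags_fails_strict_threshold(self):
        # cell (0,0) meets every other criterion (mutual max, share 10/12,
        # e = 0.67 so p << 0.05, 10 ppm) but has exactly 10 tags
        m = _matrix([[10, 2], [2, 200]])
        by = {(l.tsc_id, l.pac_id): l for l in pa.select_preferred(m, self.totals)}
        assert by[("T0", "P0")].p_value < 1e-6
        assert not by[("T0", "P0")].preferred  # o = 10 is not > 10
        m11 = _matrix([[11, 2], [2, 200]])
        by11 = {(l.tsc_id, l.pac_id): l for l in pa.select_preferred(m11, self.totals)}
        assert by11[("T0", "P0")].preferred

    def test_mutual_diagonal_preferred(self):
        m = _matrix([[90, 10], [10, 90]])
        links = pa.select_preferred(m, self.totals)
        flags = {(l.tsc_id, l.pac_id): l.preferred for l in links}
        assert flags == {
            ("T0", "P0"): True, ("T0", "P1"): False,
            ("T1", "P0"): False, ("T1", "P1"): True,
        }

    def test_tied_maxima_disqualify(self):
        m = _matrix([[90, 90], [10, 90]])
        links = pa.select_preferred(m, self.totals)
        assert not any(l.preferred for l in links)

    def test_row_max_not_column_max_fails(self):
        m = _matrix([[60, 40], [100, 20]])
        by = {(l.tsc_id, l.pac_id): l for l in pa.select_preferred(m, self.totals)}
        assert not by[("T0", "P0")].preferred

    def test_low_ppm_fails(self):
        m = _matrix([[90, 10], [10, 90]])
        links = pa.select_preferred(m, {"l1": 100_000_000})
        assert not any(l.preferred for l in links)


class TestUnitOverlap:
    def test_examples(self):
        assert pa.unit_overlap_fraction((0, 100), (0, 100)) == 1.0
        assert pa.unit_overlap_fraction((0, 100), (200, 300)) == 0.0
        assert pa.unit_overlap_fraction((0, 100), (50, 150)) == pytest.approx(1 / 3)
        with pytest.raises(ValueError):
            pa.unit_overlap_fraction((5, 5), (0, 10))

    def test_matches_jaccard_oracle(self, rng):
        for _ in range(300):
            a = sorted(rng.integers(0, 1000, 2))
            b = sorted(rng.integers(0, 1000, 2))
            if a[0] == a[1] or b[0] == b[1]:
                continue
            assert pa.unit_overlap_fraction(tuple(a), tuple(b)) == pytest.approx(
                jaccard_oracle(a, b)
            )

    def test_shorter_denominator_variant(self):
        assert pa.unit_overlap_fraction((0, 100), (0, 50), method="shorter") == 1.0


class TestTissueZScores:
    def test_constant_expression_gives_zero(self):
        z = pa.tissue_zscores({f"t{i}": 3.0 for i in range(18)})
        assert np.all(z.z == 0.0) and z.sigma == 0.0

    def test_standardization_identities(self, rng):
        for _ in range(50):
            vals = rng.lognormal(2, 1, size=18)
            z = pa.tissue_zscores(vals)
            assert z.z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.z.std() == pytest.approx(1.0, abs=1e-12)

    def test_single_outlier_library_hand_computed(self):
        ppm = [3.0] * 17 + [300.0]
        z = pa.tissue_zscores(ppm, pseudocount=1.0)
        x = np.log2(np.array(ppm) + 1.0)
        mu, sd = x.mean(), x.std()
        assert z.z[-1] == pytest.approx((np.log2(301.0) - mu) / sd, rel=1e-12)

    def test_single_library_errors(self):
        with pytest.raises(ValueError):
            pa.tissue_zscores({"only": 1.0})


class TestSwitchingPairs:
    def _z(self, peaks, libs=("brain", "heart", "testis", "liver")):
        z = np.full(len(libs), -0.5)
        for lib, v in peaks.items():
            z[libs.index(lib)] = v
        return pa.TissueZScore("u", list(libs), z, 0.0, 1.0, z)

    def test_opposed_peaks_detected(self):
        za = self._z({"brain": 3.3})
        zb = self._z({"testis": 2.8})
        assert pa.detect_switching_pairs(za, zb) == [("brain", "testis")]

    def test_flat_units_and_infinite_cut(self):
        flat = self._z({})
        assert pa.detect_switching_pairs(flat, flat) == []
        za = self._z({"brain": 5.0})
        zb = self._z({"testis": 5.0})
        assert pa.detect_switching_pairs(za, zb, z_cut=np.inf) == []

    def test_same_tissue_not_a_switch(self):
        za = self._z({"brain": 3.0})
        zb = self._z({"brain": 4.0})
        assert pa.detect_switching_pairs(za, zb) == []


class TestConnectedUnits:
    def _setup(self, gap=40_000, strand_b="+", count=8, total=1_000_000):
        ga_model = GeneModel("A", "chr1", "+", 100_000, 150_000,
                             ((100_000, 150_000),))
        b_start = 150_000 + gap
        gb_model = GeneModel("B", "chr1", strand_b, b_start, b_start + 30_000,
                             ((b_start, b_start + 30_000),))
        tsc = _cluster("TSC", 100_000)
        pac = _cluster("PAC", (b_start + 29_990) // 500 * 500)
        rows = [("l1", 100_010, b_start + 29_990, count)]
        assigned = pa.assign_pairs_to_clusters(_pairs_frame(rows), [tsc], [pac])
        tsc_links = [ClusterGeneLink(tsc.cluster_id, "A", "first_exon", 0)]
        pac_links = [ClusterGeneLink(pac.cluster_id, "B", "last_exon", 0)]
        return assigned, [ga_model, gb_model], tsc_links, pac_links, {"l1": total}

    def test_adjacent_bridge_reported(self):
        args = self._setup()
        (unit,) = pa.find_connected_units(*args)
        assert (unit.gene5, unit.gene3) == ("A", "B")
        assert unit.gap == 40_000 and unit.ppm == pytest.approx(8.0)

    def test_low_ppm_not_reported(self):
        args = self._setup(count=4)
        assert pa.find_connected_units(*args) == []

    def test_opposite_strand_not_reported(self):
        args = self._setup(strand_b="-")
        assert pa.find_connected_units(*args) == []

    def test_gap_beyond_limit_deferred_to_fusions(self):
        args = self._setup(gap=3_500_000)
        assert pa.find_connected_units(*args) == []


class TestEnrichment:
    def test_undersized_term_skipped(self):
        bg = {f"g{i}" for i in range(1000)}
        fg = {f"g{i}" for i in range(50)}
        term_map = {"small": [f"g{i}" for i in range(99)],
                    "ok": [f"g{i}" for i in range(100)]}
        res = pa.geneset_enrichment(fg, bg, term_map)
        assert [r.term_id for r in res] == ["ok"]

    def test_zero_hits_give_one(self):
        bg = {f"g{i}" for i in range(500)}
        fg = {f"g{i}" for i in range(400, 420)}
        term = {"t": [f"g{i}" for i in range(150)]}
        (r,) = pa.geneset_enrichment(fg, bg, term)
        assert r.k == 0 and r.p == 1.0

    def test_matches_exact_hypergeometric_oracle(self, rng):
        bg = [f"g{i}" for i in range(400)]
        for _ in range(25):
            fg = list(rng.choice(bg, size=40, replace=False))
            term = list(rng.choice(bg, size=150, replace=False))
            (r,) = pa.geneset_enrichment(fg, bg, {"t": term}, size_min=100, size_max=500)
            assert r.p == pytest.approx(
                hypergeom_sf_oracle(r.k, 400, 150, 40), rel=1e-12, abs=1e-300
            )

    def test_foreground_outside_background_errors(self):
        with pytest.raises(ValueError):
            pa.geneset_enrichment({"x"}, {"y"}, {})
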