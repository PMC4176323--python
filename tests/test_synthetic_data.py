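import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from endmate import gene_annotation as ga
from endmate import io_models as io
from endmate import synthetic_data as sd
from endmate.end_clustering import Cluster
from endmate.pipeline import run_pipeline


def cluster_id_of(truth, g, idx, kind):
    """Cluster id the pipeline will assign to a planted unit position."""
    model = truth.genes[g]
    pos = truth.tss_pos[g, idx] if kind == "TSC" else truth.pas_pos[g, idx]
    return f"{kind}:{model.chrom}:{model.strand}:{int(pos) // 500 * 500}"


def _rep_cluster(truth, g, idx, kind):
    model = truth.genes[g]
    pos = int(truth.tss_pos[g, idx] if kind == "TSC" else truth.pas_pos[g, idx])
    return Cluster(cluster_id="x", kind=kind, chrom=model.chrom,
                   strand=model.strand, start=pos // 500 * 500, rep_pos=pos)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_outputs(self):
        cfg = sd.SimConfig(seed=11, n_genes=30, depth=3000, n_libraries=4,
                           dr_depth=500)
        outs = []
        for _ in range(2):
            truth = sd.simulate_annotation(cfg)
            tags, truth = sd.simulate_tags(cfg, truth)
            dr = sd.simulate_random_tags(cfg, truth)
            genome = sd.simulate_genome(truth)
            outs.append(
                (
                    tags.to_csv(index=False),
                    dr.to_csv(index=False),
                    truth.tag_truth.to_csv(index=False),
                    "".join(genome.values()),
                    tuple(truth.genes),
                )
            )
        assert outs[0] == outs[1]

    def test_different_seeds_differ(self):
        t1 = sd.simulate_annotation(sd.SimConfig(seed=1, n_genes=10))
        t2 = sd.simulate_annotation(sd.SimConfig(seed=2, n_genes=10))
        assert t1.genes != t2.genes


class TestAnnotation:
    def test_no_alternatives_when_probability_zero(self):
        cfg = sd.SimConfig(seed=3, n_genes=40, alt_tsc_prob=0.0, alt_pac_prob=0.0)
        truth = sd.simulate_annotation(cfg)
        assert (truth.k5 == 1).all() and (truth.k3 == 1).all()

    def test_models_round_trip_through_bed12(self, tmp_path):
        cfg = sd.SimConfig(seed=4, n_genes=200)
        truth = sd.simulate_annotation(cfg)
        p = tmp_path / "ann.bed"
        io.write_gene_models(truth.genes, p)
        back = io.read_gene_models(p)
        assert len(back) == 200
        assert [m.exons for m in back] == [m.exons for m in truth.genes]

    def test_genes_do_not_overlap(self):
        truth = sd.simulate_annotation(sd.SimConfig(seed=5, n_genes=60))
        by_chrom = {}
        for m in truth.genes:
            by_chrom.setdefault(m.chrom, []).append((m.tx_start, m.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))


class TestTagSampling:
    def test_noiseless_limit_places_all_tags_at_truth(self):
        cfg = sd.SimConfig(seed=6, n_genes=20, n_libraries=3, depth=2000,
                           truncation_rate=0.0, internal_priming_rate=0.0,
                           chimera_rate=0.0)
        truth = sd.simulate_annotation(cfg)
        tags, truth = sd.simulate_tags(cfg, truth)
        tt = truth.tag_truth
        assert (tt["noise"] == "none").all()
        exp5 = truth.tss_pos[tt["gene"], tt["tss_idx"]]
        exp3 = truth.pas_pos[tt["gene3"], tt["pac_idx"]]
        assert (tags["pos5"].to_numpy() == exp5).all()
        assert (tags["pos3"].to_numpy() == exp3).all()

    def test_every_tag_has_exactly_one_truth_record(self):
        cfg = sd.SimConfig(seed=6, n_genes=10, n_libraries=2, depth=1000,
                           fusions=((0, 1, 50.0),))
        truth = sd.simulate_annotation(cfg)
        tags, truth = sd.simulate_tags(cfg, truth)
        assert len(tags) == len(truth.tag_truth)
        assert (tags["library_id"].to_numpy()
                == truth.tag_truth["library_id"].to_numpy()).all()

    def test_full_chimerism_decouples_gene_ends(self):
        cfg = sd.SimConfig(seed=8, n_genes=10, n_libraries=1, depth=100_000,
                           alt_tsc_prob=0.0, alt_pac_prob=0.0,
                           truncation_rate=0.0, internal_priming_rate=0.0,
                           chimera_rate=1.0, gene_log2_sd=1.0,
                           tissue_log2_sd=0.0, specific_frac=0.0)
        truth = sd.simulate_annotation(cfg)
        tags, truth = sd.simulate_tags(cfg, truth)
        tab = pd.crosstab(truth.tag_truth["gene"], truth.tag_truth["gene3"])
        chi2, p, dof, _ = sps.chi2_contingency(tab)
        assert p > 0.01

    def test_planted_fusion_support_has_poisson_scale(self):
        cfg = sd.SimConfig(seed=9, n_genes=20, n_libraries=1, depth=1_000_000,
                           fusions=((0, 1, 20.0),))
        truth = sd.simulate_annotation(cfg)
        tags, truth = sd.simulate_tags(cfg, truth)
        n_fus = int((truth.tag_truth["noise"] == "fusion").sum())
        assert abs(n_fus - 20) <= 2 * np.sqrt(20)

    def test_marginal_ppm_calibration(self):
        cfg = sd.SimConfig(seed=10, n_genes=200, n_libraries=1, depth=100_000)
        truth = sd.simulate_annotation(cfg)
        tags, truth = sd.simulate_tags(cfg, truth)
        counts = np.bincount(truth.tag_truth["gene"], minlength=200)
        expected = truth.gene_probs(0) * cfg.depth
        ok = np.abs(counts - expected) <= 3 * np.sqrt(np.maximum(expected, 1.0))
        assert ok.mean() >= 0.985

    def test_internal_priming_lands_on_planted_a_runs(self):
        cfg = sd.SimConfig(seed=12, n_genes=15, n_libraries=2, depth=4000,
                           internal_priming_rate=0.3, truncation_rate=0.0,
                           chimera_rate=0.0)
        truth = sd.simulate_annotation(cfg)
        tags, truth = sd.simulate_tags(cfg, truth)
        genome = sd.simulate_genome(truth)
        tt = truth.tag_truth
        primed = tags[(tt["noise"] == "internal_priming").to_numpy()]
        assert len(primed) > 0
        sub = primed.sample(n=min(50, len(primed)), random_state=0)
        for row in sub.itertuples(index=False):
            pac = Cluster(cluster_id="x", kind="PAC", chrom=row.chrom3,
                          strand=row.strand3, start=row.pos3 // 500 * 500,
                          rep_pos=row.pos3)
            assert ga.scan_polya_stretch(genome, pac) is True


@pytest.fixture(scope="module")
def small_world():
    cfg = sd.SimConfig(seed=13, n_genes=30)
    truth = sd.simulate_annotation(cfg)
    return truth, sd.simulate_genome(truth)


class TestGenomePlanting:
    def test_polya_signals_planted_where_flagged(self, small_world):
        truth, genome = small_world
        for g in range(30):
            for a in range(truth.k3[g]):
                if truth.polya_signal[g, a]:
                    pac = _rep_cluster(truth, g, a, "PAC")
                    present, offsets = ga.scan_polya_signal(genome, pac)
                    assert present and -21 in offsets

    def test_tata_boxes_planted_where_flagged(self, small_world):
        truth, genome = small_world
        flagged = [g for g in range(30) if truth.tata[g]]
        assert flagged  # seed chosen world contains TATA genes
        for g in flagged:
            tsc = _rep_cluster(truth, g, 0, "TSC")
            assert ga.scan_tata(genome, tsc) is True


@pytest.fixture(scope="module")
def world():
    cfg = sd.SimConfig(seed=14, n_genes=100, depth=20_000,
                       alt_tsc_prob=1.0, alt_pac_prob=1.0,
                       preferred_frac=1.0, gene_log2_sd=1.0)
    truth = sd.simulate_annotation(cfg)
    tags, truth = sd.simulate_tags(cfg, truth)
    return truth, run_pipeline(tags, truth.genes)


class TestEndToEndRecovery:
    """Planted signal recovered by the full pipeline.

    Alternative-unit and coupling probabilities are raised to 1 so the
    planted populations are large enough to measure recall; depth gives
    every unit >= ~50 pooled pairs as the selection logic assumes.
    """

    def test_planted_clusters_pass_ppm_filter(self, world):
        truth, res = world
        tsc_ids = {c.cluster_id for c in res.tscs}
        planted = [
            cluster_id_of(truth, g, i, "TSC")
            for g in range(100)
            for i in range(truth.k5[g])
        ]
        assert np.mean([p in tsc_ids for p in planted]) >= 0.95

    def test_planted_preferred_pairs_recovered(self, world):
        truth, res = world
        got = {(lk.tsc_id, lk.pac_id) for lk in res.preferred}
        planted = {
            (cluster_id_of(truth, g, i, "TSC"), cluster_id_of(truth, g, j, "PAC"))
            for g, i, j in truth.preferred_units()
        }
        assert planted
        recall = np.mean([p in got for p in planted])
        assert recall >= 0.95

    def test_switch_plantings_detected(self, world):
        from endmate import pair_analysis as pa

        truth, res = world
        assert truth.switch_info
        found = 0
        for g, la, lb in truth.switch_info:
            gene_id = truth.genes[g].gene_id
            m = res.matrices.get(gene_id)
            if m is None:
                continue
            ids = (cluster_id_of(truth, g, 0, "TSC"), cluster_id_of(truth, g, 0, "PAC"),
                   cluster_id_of(truth, g, 1, "TSC"), cluster_id_of(truth, g, 1, "PAC"))
            try:
                i0, j0 = m.tsc_ids.index(ids[0]), m.pac_ids.index(ids[1])
                i1, j1 = m.tsc_ids.index(ids[2]), m.pac_ids.index(ids[3])
            except ValueError:
                continue
            totals = np.array([res.lib_totals[l] for l in m.lib_ids], float)
            za = pa.tissue_zscores(dict(zip(m.lib_ids, m.o_by_lib[i0, j0] / totals * 1e6)))
            zb = pa.tissue_zscores(dict(zip(m.lib_ids, m.o_by_lib[i1, j1] / totals * 1e6)))
            pairs = pa.detect_switching_pairs(za, zb)
            if (truth.lib_ids[la], truth.lib_ids[lb]) in pairs:
                found += 1
        assert found / len(truth.switch_info) >= 0.7
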