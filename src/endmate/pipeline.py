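"""End-to-end driver tying the analysis stages together.

Takes an ENDPAIR v1 frame plus gene models and runs: end clustering (500-bp
bins), ppm quantification and the 5-ppm screen, gene association with the
50-kb windows, per-gene TSC x PAC matrices with Poisson independence
statistics and preferred-pair selection, connected adjacent-gene units, and
fusion candidates.  Each stage remains individually importable; this module
only sequences them with shared defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import end_clustering as ec
from . import fusion_detection as fd
from . import gene_annotation as ga
from . import pair_analysis as pa
from .io_models import GeneModel, LibraryStats, library_stats_from_frame

__all__ = ["PipelineResult", "run_pipeline", "tss_table", "pas_table"]


def tss_table(pairs: pd.DataFrame) -> pd.DataFrame:
    return pairs.rename(
        columns={"chrom5": "chrom", "pos5": "pos", "strand5": "strand"}
    )[["chrom", "pos", "strand", "library_id"]]


def pas_table(pairs: pd.DataFrame) -> pd.DataFrame:
    sub = pairs[pairs["end3_kind"] == "PAS"]
    return sub.rename(
        columns={"chrom3": "chrom", "pos3": "pos", "strand3": "strand"}
    )[["chrom", "pos", "strand", "library_id"]]


@dataclass
class PipelineResult:
    stats: dict
    tscs: list = field(default_factory=list)
    pacs: list = field(default_factory=list)
    tsc_links: list = field(default_factory=list)
    pac_links: list = field(default_factory=list)
    matrices: dict = field(default_factory=dict)
    pair_links: dict = field(default_factory=dict)  # gene_id -> list[PairLink]
    preferred: list = field(default_factory=list)
    connected: list = field(default_factory=list)
    fusions: list = field(default_factory=list)

    @property
    def lib_totals(self) -> dict[str, int]:
        return {k: v.total_pairs for k, v in self.stats.items()}


def run_pipeline(
    pairs: pd.DataFrame,
    genes: list[GeneModel],
    stats: dict[str, LibraryStats] | None = None,
    bin_width: int = ec.DEFAULT_BIN,
    min_ppm: float = 5.0,
    max_dist: int = 50_000,
    min_tags: int = 10,
    alpha: float = 0.05,
    min_share: float = 0.5,
    fusion_ppm: float = 5.0,
    fusion_dist: int = 3_000_000,
    fusion_mapq: int = 37,
) -> PipelineResult:
    """Run the full dT-library analysis over an ENDPAIR frame."""
    if stats is None:
        stats = library_stats_from_frame(pairs)
    res = PipelineResult(stats=stats)

    dt_pairs = pairs[pairs["end3_kind"] == "PAS"]
    res.tscs = ec.cluster_tag_table(tss_table(dt_pairs), "TSC", bin_width)
    res.pacs = ec.cluster_tag_table(pas_table(dt_pairs), "PAC", bin_width)
    for c in res.tscs + res.pacs:
        ec.compute_ppm(c, stats)
    res.tscs = ec.filter_clusters(res.tscs, min_ppm)
    res.pacs = ec.filter_clusters(res.pacs, min_ppm)

    res.tsc_links = ga.associate_clusters(res.tscs, genes, max_dist)
    res.pac_links = ga.associate_clusters(res.pacs, genes, max_dist)

    assigned = pa.assign_pairs_to_clusters(dt_pairs, res.tscs, res.pacs)
    res.matrices = pa.build_pair_matrices(assigned, res.tsc_links, res.pac_links)
    totals = res.lib_totals
    for gene_id, m in res.matrices.items():
        if m.N == 0:
            res.pair_links[gene_id] = []
            continue
        links = pa.select_preferred(
            m, totals, min_ppm=min_ppm, min_tags=min_tags,
            alpha=alpha, min_share=min_share,
        )
        res.pair_links[gene_id] = links
        res.preferred.extend(lk for lk in links if lk.preferred)

    res.connected = pa.find_connected_units(
        assigned, genes, res.tsc_links, res.pac_links, totals,
        min_ppm=min_ppm, max_gap=fusion_dist,
    )
    res.fusions = fd.detect_fusions(
        assigned, genes, res.tsc_links, res.pac_links, totals,
        ppm_thr=fusion_ppm, dist_thr=fusion_dist, mapq_thr=fusion_mapq,
    )
    return res
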