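"""Fusion transcript candidates from distant or inter-chromosomal end pairs.

A fusion candidate is a (gene5, gene3) pair whose TSC-PAC tags span two
genic regions separated by more than 3 Mb on the same chromosome or lying on
different chromosomes, supported by more than 5 ppm of pooled tags, all with
mapping quality above 37.  Same-chromosome opposite-strand gene pairs are
candidates at any separation: producing such a transcript requires a genomic
rearrangement.  Same-strand pairs within 3 Mb are read-through ("connected")
units and are never reported here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gene_annotation import ClusterGeneLink
from .io_models import GeneModel

__all__ = ["FusionCandidate", "detect_fusions"]


@dataclass
class FusionCandidate:
    gene5: str
    gene3: str
    chrom5: str
    chrom3: str
    count: int
    ppm: float
    min_mapq: int
    distance: int | None  # bp between genic regions if same chromosome


def _gene_distance(a: GeneModel, b: GeneModel) -> int:
    """Gap between two genic intervals on one chromosome (0 if overlapping)."""
    return max(0, max(a.tx_start, b.tx_start) - min(a.tx_end, b.tx_end))


def detect_fusions(assigned: pd.DataFrame, genes: list[GeneModel],
                   tsc_links: list[ClusterGeneLink],
                   pac_links: list[ClusterGeneLink],
                   lib_totals: dict, ppm_thr: float = 5.0,
                   dist_thr: int = 3_000_000,
                   mapq_thr: int = 37) -> list[FusionCandidate]:
    """Candidate fusions from an ENDPAIR frame with tsc_id/pac_id columns.

    Supporting tags with mapq <= ``mapq_thr`` on either end are discarded
    before counting; all remaining thresholds are strict.  Output order is
    deterministic (sorted by gene pair) and independent of input row order.
    """
    totals = {
        k: (v.total_pairs if hasattr(v, "total_pairs") else int(v))
        for k, v in lib_totals.items()
    }
    pooled_total = sum(totals.values())
    gene_by_id = {g.gene_id: g for g in genes}
    tsc_genes: dict[str, set[str]] = {}
    for lk in tsc_links:
        if not lk.excluded:
            tsc_genes.setdefault(lk.cluster_id, set()).add(lk.gene_id)
    pac_genes: dict[str, set[str]] = {}
    for lk in pac_links:
        if not lk.excluded:
            pac_genes.setdefault(lk.cluster_id, set()).add(lk.gene_id)

    sub = assigned[
        (assigned["mapq5"] > mapq_thr)
        & (assigned["mapq3"] > mapq_thr)
        & (assigned["tsc_id"] != "")
        & (assigned["pac_id"] != "")
    ]
    support: dict[tuple[str, str], list[int]] = {}
    for row in sub.itertuples(index=False):
        for ga in tsc_genes.get(row.tsc_id, ()):
            for gb in pac_genes.get(row.pac_id, ()):
                if ga == gb:
                    continue
                support.setdefault((ga, gb), []).append(
                    min(int(row.mapq5), int(row.mapq3))
                )
    out = []
    for (ga_id, gb_id) in sorted(support):
        ga, gb = gene_by_id[ga_id], gene_by_id[gb_id]
        if ga.chrom == gb.chrom:
            distance = _gene_distance(ga, gb)
            if ga.strand == gb.strand and distance <= dist_thr:
                continue  # read-through territory, handled by connected units
        else:
            distance = None
        mapqs = support[(ga_id, gb_id)]
        ppm = len(mapqs) * 1e6 / pooled_total if pooled_total else 0.0
        if ppm <= ppm_thr:
            continue
        out.append(
            FusionCandidate(
                gene5=ga_id, gene3=gb_id, chrom5=ga.chrom, chrom3=gb.chrom,
                count=len(mapqs), ppm=float(ppm), min_mapq=int(min(mapqs)),
                distance=distance,
            )
        )
    return out
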