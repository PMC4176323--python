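"""Associating clusters with gene models and scanning cis-sequence features.

A TSC is attached to a gene when its bin overlaps the 50-kb window upstream
of the annotated 5' end or the first exon; a PAC when it overlaps the 50-kb
window downstream of the 3' end or the last exon.  Hits inside internal
exons are reported but flagged excluded.  Sequence scans (TATA consensus,
AATAAA poly(A) signal, genomic A-stretches marking internal-priming risk)
operate on the transcript (sense) strand around the cluster's representative
position; windows are expressed in transcript orientation with 0 at rep_pos
and negative offsets upstream.

TATA boxes are detected with the IUPAC consensus TATAWAWR rather than the
proprietary TRANSFAC position-weight matrices; a user PWM hook can be passed
via ``matcher``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

from .end_clustering import Cluster
from .io_models import GeneModel, revcomp

__all__ = [
    "ClusterGeneLink",
    "CisFeatureReport",
    "associate_clusters",
    "classify_tag_positions",
    "scan_polya_signal",
    "scan_polya_stretch",
    "scan_tata",
    "annotate_cpg",
    "compare_cluster_sets",
    "first_base_composition",
    "build_cis_report",
    "TAG_CATEGORIES",
]

TAG_CATEGORIES = (
    "first_exon",
    "last_exon",
    "internal_exon",
    "intron",
    "upstream_50kb",
    "downstream_50kb",
    "intergenic",
)

TATA_CONSENSUS = re.compile("TATA[AT]A[AT][AG]")


@dataclass
class ClusterGeneLink:
    cluster_id: str
    gene_id: str
    relation: str  # upstream_50kb | first_exon | internal | last_exon | downstream_50kb
    distance: int  # signed bp of rep_pos from the relevant gene terminus
    excluded: bool = False


@dataclass
class CisFeatureReport:
    """Presence flags for promoter/terminator sequence features of a cluster."""

    cluster_id: str
    tata: bool | None = None
    cpg: bool | None = None
    polya_signal: bool | None = None
    polya_stretch: bool | None = None
    first_base: dict | None = None


# ---------------------------------------------------------------------------
# cluster-gene association
# ---------------------------------------------------------------------------


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def associate_clusters(
    clusters: list[Cluster],
    genes: list[GeneModel],
    max_dist: int = 50_000,
) -> list[ClusterGeneLink]:
    """Link TSCs/PACs to genes via terminal windows and terminal exons.

    Any bin overlap with the window or exon qualifies; the signed distance is
    measured from rep_pos to the relevant transcript terminus (negative =
    upstream of the 5' end for TSCs; positive = downstream of the 3' end for
    PACs).  A cluster may link to several genes.  Internal-exon hits are
    returned with ``excluded=True`` and the relation ``internal``.
    """
    by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_loc.setdefault((g.chrom, g.strand), []).append(g)
    links: list[ClusterGeneLink] = []
    for c in clusters:
        for g in by_loc.get((c.chrom, c.strand), []):
            link = _link_one(c, g, max_dist)
            if link is not None:
                links.append(link)
    return links


def _link_one(c: Cluster, g: GeneModel, max_dist: int) -> ClusterGeneLink | None:
    plus = g.strand == "+"
    first_exon = g.exons[0] if plus else g.exons[-1]
    last_exon = g.exons[-1] if plus else g.exons[0]
    if plus:
        up_win = (g.tx_start - max_dist, g.tx_start)
        down_win = (g.tx_end, g.tx_end + max_dist)
        d5 = c.rep_pos - g.five_prime_pos
        d3 = c.rep_pos - g.three_prime_pos
    else:
        up_win = (g.tx_end, g.tx_end + max_dist)
        down_win = (g.tx_start - max_dist, g.tx_start)
        d5 = g.five_prime_pos - c.rep_pos
        d3 = g.three_prime_pos - c.rep_pos
    internal = g.exons[1:-1]

    if c.kind == "TSC":
        if _overlaps(c.start, c.end, *first_exon):
            return ClusterGeneLink(c.cluster_id, g.gene_id, "first_exon", int(d5))
        if _overlaps(c.start, c.end, *up_win):
            return ClusterGeneLink(c.cluster_id, g.gene_id, "upstream_50kb", int(d5))
    else:
        if _overlaps(c.start, c.end, *last_exon):
            return ClusterGeneLink(c.cluster_id, g.gene_id, "last_exon", int(d3))
        if _overlaps(c.start, c.end, *down_win):
            return ClusterGeneLink(c.cluster_id, g.gene_id, "downstream_50kb", int(d3))
    for s, e in internal:
        if _overlaps(c.start, c.end, s, e):
            ref = d5 if c.kind == "TSC" else d3
            return ClusterGeneLink(
                c.cluster_id, g.gene_id, "internal", int(ref), excluded=True
            )
    return None


# ---------------------------------------------------------------------------
# tag position classification
# ---------------------------------------------------------------------------


class _MergedIntervals:
    """Stabbing queries against a merged, sorted interval set."""

    def __init__(self, intervals):
        merged = []
        for s, e in sorted(intervals):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.starts = np.array([m[0] for m in merged], dtype=np.int64)
        self.ends = np.array([m[1] for m in merged], dtype=np.int64)

    def contains(self, pos: np.ndarray) -> np.ndarray:
        if len(self.starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(pos), dtype=bool)
        hit[ok] = pos[ok] < self.ends[idx[ok]]
        return hit

    def overlaps(self, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Vectorised any-overlap test for [start,end) query intervals."""
        if len(self.starts) == 0:
            return np.zeros(len(start), dtype=bool)
        # first merged interval ending after query start
        idx = np.searchsorted(self.ends, start, side="right")
        ok = idx < len(self.starts)
        hit = np.zeros(len(start), dtype=bool)
        hit[ok] = self.starts[idx[ok]] < end[ok]
        return hit


def _category_index(genes, max_dist):
    """Per (chrom,strand) merged intervals for every positional category."""
    raw: dict[tuple[str, str], dict[str, list]] = {}
    for g in genes:
        d = raw.setdefault((g.chrom, g.strand), {c: [] for c in TAG_CATEGORIES[:-1]})
        plus = g.strand == "+"
        first = g.exons[0] if plus else g.exons[-1]
        last = g.exons[-1] if plus else g.exons[0]
        d["first_exon"].append(first)
        if last != first:
            d["last_exon"].append(last)
        inner = [e for e in g.exons if e != first and e != last]
        d["internal_exon"].extend(inner)
        for (s0, e0), (s1, e1) in zip(g.exons, g.exons[1:]):
            d["intron"].append((e0, s1))
        if plus:
            d["upstream_50kb"].append((g.tx_start - max_dist, g.tx_start))
            d["downstream_50kb"].append((g.tx_end, g.tx_end + max_dist))
        else:
            d["upstream_50kb"].append((g.tx_end, g.tx_end + max_dist))
            d["downstream_50kb"].append((g.tx_start - max_dist, g.tx_start))
    return {
        key: {cat: _MergedIntervals(iv) for cat, iv in cats.items()}
        for key, cats in raw.items()
    }


def classify_tag_positions(tags, genes, max_dist: int = 50_000):
    """Assign each tag one positional category relative to the gene models.

    ``tags`` is a list of EndTag or a DataFrame with chrom/pos/strand.
    Overlapping annotations are resolved by precedence first_exon > last_exon
    > internal_exon > intron > upstream > downstream; everything else is
    intergenic.  Returns (categories array, fractions dict); the fractions
    sum to 1.
    """
    if hasattr(tags, "columns"):
        chroms = tags["chrom"].to_numpy()
        pos = tags["pos"].to_numpy()
        strands = tags["strand"].to_numpy()
    else:
        chroms = np.array([t.chrom for t in tags])
        pos = np.array([t.pos for t in tags], dtype=np.int64)
        strands = np.array([t.strand for t in tags])
    n = len(pos)
    index = _category_index(genes, max_dist)
    cats = np.full(n, "intergenic", dtype=object)
    for (chrom, strand), cat_ivs in index.items():
        sel = np.flatnonzero((chroms == chrom) & (strands == strand))
        if len(sel) == 0:
            continue
        remaining = sel
        for cat in TAG_CATEGORIES[:-1]:
            if len(remaining) == 0:
                break
            hit = cat_ivs[cat].contains(pos[remaining])
            cats[remaining[hit]] = cat
            remaining = remaining[~hit]
    fractions = {c: 0.0 for c in TAG_CATEGORIES}
    if n:
        uniq, counts = np.unique(cats, return_counts=True)
        for c, k in zip(uniq, counts):
            fractions[str(c)] = k / n
    return cats, fractions


# ---------------------------------------------------------------------------
# sequence scans
# ---------------------------------------------------------------------------


def _fetch(genome, chrom: str, start: int, end: int) -> tuple[str, int, int]:
    """Fetch genome[start:end) clipped to the chromosome (with a warning)."""
    seq = genome[chrom]
    length = len(seq)
    c0, c1 = max(0, start), min(length, end)
    if (c0, c1) != (start, end):
        warnings.warn(f"window [{start},{end}) clipped to [{c0},{c1}) on {chrom}")
    if c0 >= c1:
        return "", c0, c0
    return str(seq[c0:c1]).upper(), c0, c1


def _sense_window(genome, chrom: str, strand: str, rep_pos: int,
                  rel: tuple[int, int]) -> tuple[str, int]:
    """Sense-strand sequence of transcript-relative window [rel0, rel1).

    Returns (sequence, rel0_actual) where index i of the sequence is
    transcript offset rel0_actual + i from rep_pos (negative = upstream).
    """
    r0, r1 = rel
    if strand == "+":
        seq, c0, _ = _fetch(genome, chrom, rep_pos + r0, rep_pos + r1)
        return seq, c0 - rep_pos
    raw, _, c1 = _fetch(genome, chrom, rep_pos - r1 + 1, rep_pos - r0 + 1)
    return revcomp(raw), rep_pos - c1 + 1


def scan_polya_signal(genome, pac: Cluster, window: tuple[int, int] = (-40, 0)):
    """Scan for perfect AATAAA hexamers upstream of a PAC's representative end.

    Returns (present, offsets) with offsets of hexamer starts in transcript
    coordinates, reported 5'->3'.
    """
    seq, r0 = _sense_window(genome, pac.chrom, pac.strand, pac.rep_pos, window)
    offsets = [r0 + m.start() for m in re.finditer("(?=AATAAA)", seq)]
    return (len(offsets) > 0), offsets


def scan_polya_stretch(genome, pac: Cluster, window: tuple[int, int] = (1, 21),
                       min_run: int = 6) -> bool:
    """Internal-priming risk: genomic A-run of >= min_run just downstream."""
    seq, _ = _sense_window(genome, pac.chrom, pac.strand, pac.rep_pos, window)
    return bool(re.search("A{%d,}" % min_run, seq))


def scan_tata(genome, tsc: Cluster, window: tuple[int, int] = (-40, -20),
              matcher=None) -> bool:
    """TATA box upstream of a TSC (consensus TATAWAWR, fully inside window).

    ``matcher`` may be any callable str -> bool to substitute a PWM scan.
    """
    seq, _ = _sense_window(genome, tsc.chrom, tsc.strand, tsc.rep_pos, window)
    if matcher is not None:
        return bool(matcher(seq))
    return TATA_CONSENSUS.search(seq) is not None


def annotate_cpg(tscs: list[Cluster], cpg_islands) -> dict[str, bool]:
    """Flag TSCs whose bin overlaps a CpG island (BED intervals) by >= 1 bp."""
    by_chrom: dict[str, list] = {}
    for rec in cpg_islands:
        by_chrom.setdefault(rec[0], []).append((rec[1], rec[2]))
    idx = {chrom: _MergedIntervals(iv) for chrom, iv in by_chrom.items()}
    out = {}
    for c in tscs:
        mi = idx.get(c.chrom)
        if mi is None:
            out[c.cluster_id] = False
        else:
            out[c.cluster_id] = bool(
                mi.overlaps(np.array([c.start]), np.array([c.end]))[0]
            )
    return out


def compare_cluster_sets(set_a: list[Cluster], set_b: list[Cluster],
                         slop: int = 0) -> tuple[float, float]:
    """Mutual coverage of two cluster sets.

    Returns (fraction of A with an overlapping B cluster within ``slop`` bp,
    fraction of B covered by A).  Comparison is within (chrom, strand).
    """
    if not set_a or not set_b:
        raise ValueError("cluster sets must be non-empty")

    def covered(queries, refs):
        by_loc: dict[tuple[str, str], list] = {}
        for c in refs:
            by_loc.setdefault((c.chrom, c.strand), []).append((c.start, c.end))
        idx = {k: _MergedIntervals(v) for k, v in by_loc.items()}
        n_cov = 0
        for c in queries:
            mi = idx.get((c.chrom, c.strand))
            if mi is not None and bool(
                mi.overlaps(np.array([c.start - slop]), np.array([c.end + slop]))[0]
            ):
                n_cov += 1
        return n_cov / len(queries)

    return covered(set_a, set_b), covered(set_b, set_a)


def first_base_composition(genome, tags) -> dict[str, float]:
    """Base composition at TSS tag positions on the sense strand."""
    counts = {b: 0 for b in "ACGT"}
    n = 0
    for t in tags:
        base, _, _ = _fetch(genome, t.chrom, t.pos, t.pos + 1)
        if t.strand == "-":
            base = revcomp(base)
        if base in counts:
            counts[base] += 1
            n += 1
    return {b: (c / n if n else 0.0) for b, c in counts.items()}


def build_cis_report(genome, cluster: Cluster, cpg_islands=None, **kw) -> CisFeatureReport:
    """Assemble the per-cluster cis-feature flags (total once genome given)."""
    rep = CisFeatureReport(cluster_id=cluster.cluster_id)
    if cluster.kind == "TSC":
        rep.tata = scan_tata(genome, cluster, **kw.get("tata", {}))
        if cpg_islands is not None:
            rep.cpg = annotate_cpg([cluster], cpg_islands)[cluster.cluster_id]
    else:
        present, _ = scan_polya_signal(genome, cluster, **kw.get("signal", {}))
        rep.polya_signal = present
        rep.polya_stretch = scan_polya_stretch(genome, cluster, **kw.get("stretch", {}))
    return rep
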