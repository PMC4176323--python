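"""TSC-PAC pairing statistics within and between genes.

For each gene a TSC x PAC contingency matrix of mate-pair tag counts is
built (pooled over libraries; per-library counts are retained for ppm and
tissue Z-scores).  Deviation of a cell from independent start/end selection
is scored with the Poisson upper tail at the contingency expectation
e_ij = T_i * P_j / N.  "Preferred" pairs additionally require a pooled
expression above 5 ppm with more than 10 supporting tags, mutual strict
row/column maximality, and a majority share of the tags of the TSC or the
PAC.  The same tag-pair counts, crossed between distinct genes, yield
"connected" transcript units (adjacent genes bridged by one transcript);
pairs spanning >3 Mb or different chromosomes are deferred to
fusion_detection.

Tissue specificity is summarised as z = (x - mu) / sigma with x = log2(ppm +
pseudocount) across libraries (population moments, so mean(z) = 0 and
sd(z) = 1 exactly whenever sigma > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .end_clustering import Cluster
from .gene_annotation import ClusterGeneLink
from .io_models import GeneModel, LibraryStats

__all__ = [
    "PairMatrix",
    "PairLink",
    "TissueZScore",
    "ConnectedUnit",
    "EnrichmentResult",
    "assign_pairs_to_clusters",
    "build_pair_matrix",
    "build_pair_matrices",
    "pair_independence_pvalue",
    "select_preferred",
    "unit_overlap_fraction",
    "tissue_zscores",
    "detect_switching_pairs",
    "find_connected_units",
    "geneset_enrichment",
]


@dataclass
class PairMatrix:
    """Observed TSC x PAC mate-pair counts of one gene."""

    gene_id: str
    tsc_ids: list[str]
    pac_ids: list[str]
    o: np.ndarray  # (R, C) pooled counts
    o_by_lib: np.ndarray | None = None  # (R, C, L)
    lib_ids: list[str] | None = None

    @property
    def T(self) -> np.ndarray:  # row totals
        return self.o.sum(axis=1)

    @property
    def P(self) -> np.ndarray:  # column totals
        return self.o.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.o.sum())


@dataclass
class PairLink:
    tsc_id: str
    pac_id: str
    o: int
    e: float
    p_value: float
    ppm: dict = field(default_factory=dict)  # library_id -> ppm
    pooled_ppm: float = 0.0
    preferred: bool = False
    gene_id: str = ""
    span: tuple[int, int] | None = None  # genomic [min_rep, max_rep+1)


@dataclass
class TissueZScore:
    unit_id: str
    lib_ids: list[str]
    x: np.ndarray
    mu: float
    sigma: float
    z: np.ndarray

    def __getitem__(self, lib: str) -> float:
        return float(self.z[self.lib_ids.index(lib)])


@dataclass
class ConnectedUnit:
    tsc_id: str
    pac_id: str
    gene5: str
    gene3: str
    chrom: str
    strand: str
    gap: int
    count: int
    ppm: float
    same_strand: bool = True


@dataclass
class EnrichmentResult:
    term_id: str
    k: int
    K: int
    n: int
    N_bg: int
    p: float
    fdr: float | None = None


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------


def assign_pairs_to_clusters(pairs: pd.DataFrame, tscs: list[Cluster],
                             pacs: list[Cluster]) -> pd.DataFrame:
    """Annotate an ENDPAIR frame with tsc_id/pac_id columns via grid lookup.

    Ends falling outside every (filtered) cluster get an empty id.  All
    clusters of one kind must share the same bin width.
    """
    out = pairs.copy()
    for kind, clusters, chrom_c, pos_c, strand_c, col in (
        ("TSC", tscs, "chrom5", "pos5", "strand5", "tsc_id"),
        ("PAC", pacs, "chrom3", "pos3", "strand3", "pac_id"),
    ):
        if clusters:
            widths = {c.width for c in clusters}
            if len(widths) != 1:
                raise ValueError(f"mixed bin widths among {kind}s")
            w = widths.pop()
            lut = {(c.chrom, c.strand, c.start // c.width): c.cluster_id for c in clusters}
            keys = zip(out[chrom_c], out[strand_c], out[pos_c] // w)
            out[col] = [lut.get(k, "") for k in keys]
        else:
            out[col] = ""
    return out


def build_pair_matrix(assigned: pd.DataFrame, tsc_ids: list[str],
                      pac_ids: list[str], gene_id: str) -> PairMatrix:
    """Cross-tabulate assigned pairs over the given gene's cluster ids."""
    R, C = len(tsc_ids), len(pac_ids)
    sub = assigned[assigned["tsc_id"].isin(tsc_ids) & assigned["pac_id"].isin(pac_ids)]
    lib_ids = sorted(assigned["library_id"].unique())
    o = np.zeros((R, C), dtype=np.int64)
    o_by_lib = np.zeros((R, C, len(lib_ids)), dtype=np.int64)
    ri = {t: i for i, t in enumerate(tsc_ids)}
    ci = {p: j for j, p in enumerate(pac_ids)}
    li = {l: k for k, l in enumerate(lib_ids)}
    grp = sub.groupby(["tsc_id", "pac_id", "library_id"], sort=True).size()
    for (t, p, l), n in grp.items():
        o[ri[t], ci[p]] += n
        o_by_lib[ri[t], ci[p], li[l]] = n
    return PairMatrix(gene_id=gene_id, tsc_ids=list(tsc_ids), pac_ids=list(pac_ids),
                      o=o, o_by_lib=o_by_lib, lib_ids=lib_ids)


def build_pair_matrices(assigned: pd.DataFrame,
                        tsc_links: list[ClusterGeneLink],
                        pac_links: list[ClusterGeneLink]) -> dict[str, PairMatrix]:
    """One PairMatrix per gene with >= 1 linked (non-excluded) TSC and PAC."""
    tsc_by_gene: dict[str, list[str]] = {}
    for lk in tsc_links:
        if not lk.excluded:
            tsc_by_gene.setdefault(lk.gene_id, []).append(lk.cluster_id)
    pac_by_gene: dict[str, list[str]] = {}
    for lk in pac_links:
        if not lk.excluded:
            pac_by_gene.setdefault(lk.gene_id, []).append(lk.cluster_id)
    out = {}
    for gene_id in sorted(set(tsc_by_gene) & set(pac_by_gene)):
        out[gene_id] = build_pair_matrix(
            assigned, sorted(set(tsc_by_gene[gene_id])),
            sorted(set(pac_by_gene[gene_id])), gene_id
        )
    return out


# ---------------------------------------------------------------------------
# independence statistics and preferred-pair selection
# ---------------------------------------------------------------------------


def pair_independence_pvalue(m: PairMatrix, i: int, j: int) -> PairLink:
    """Poisson upper-tail deviation of cell (i, j) from independent selection.

    e_ij = T_i * P_j / N; p = P(X >= o_ij | Poisson(e_ij)).  A 1x1 matrix has
    no alternative pairing, so p = 1 by convention.
    """
    N = m.N
    if N == 0:
        raise ValueError(f"{m.gene_id}: empty pair matrix")
    o = int(m.o[i, j])
    e = float(m.T[i] * m.P[j] / N)
    if m.o.shape == (1, 1) or o == 0:
        p = 1.0
    else:
        p = float(sps.poisson.sf(o - 1, e))
    return PairLink(tsc_id=m.tsc_ids[i], pac_id=m.pac_ids[j], o=o, e=e,
                    p_value=p, gene_id=m.gene_id)


def select_preferred(m: PairMatrix, lib_totals: dict[str, int] | dict[str, LibraryStats],
                     min_ppm: float = 5.0, min_tags: int = 10,
                     alpha: float = 0.05, min_share: float = 0.5) -> list[PairLink]:
    """Score every cell of a gene's matrix and flag the preferred pairs.

    A cell is preferred iff (a) pooled ppm > min_ppm and o > min_tags (both
    strict), (b) the independence p-value is < alpha, (c) it is the strict
    maximum of its row and of its column (ties disqualify), and (d) it holds
    more than ``min_share`` of the tags of its TSC or of its PAC.
    """
    totals = {
        k: (v.total_pairs if isinstance(v, LibraryStats) else int(v))
        for k, v in lib_totals.items()
    }
    pooled_total = sum(totals.values())
    links = []
    T, P = m.T, m.P
    for i in range(len(m.tsc_ids)):
        for j in range(len(m.pac_ids)):
            link = pair_independence_pvalue(m, i, j)
            link.pooled_ppm = link.o * 1e6 / pooled_total if pooled_total else 0.0
            if m.o_by_lib is not None and m.lib_ids is not None:
                link.ppm = {
                    lib: int(m.o_by_lib[i, j, k]) * 1e6 / totals[lib]
                    for k, lib in enumerate(m.lib_ids)
                    if lib in totals
                }
            o = link.o
            row_max = (m.o[i, :] < o).sum() == m.o.shape[1] - 1 and o == m.o[i, :].max()
            col_max = (m.o[:, j] < o).sum() == m.o.shape[0] - 1 and o == m.o[:, j].max()
            share_ok = (T[i] > 0 and o / T[i] > min_share) or (
                P[j] > 0 and o / P[j] > min_share
            )
            link.preferred = bool(
                link.pooled_ppm > min_ppm
                and o > min_tags
                and link.p_value < alpha
                and row_max
                and col_max
                and share_ok
            )
            links.append(link)
    return links


def unit_overlap_fraction(unit_a, unit_b, method: str = "jaccard") -> float:
    """Overlap between two transcript-unit spans.

    Units are (start, end) genomic spans or PairLinks carrying ``span``.
    ``jaccard`` (default) is |a & b| / |a | b|; ``shorter`` divides the
    overlap by the shorter span.
    """
    span_a = unit_a.span if hasattr(unit_a, "span") else tuple(unit_a)
    span_b = unit_b.span if hasattr(unit_b, "span") else tuple(unit_b)
    la = span_a[1] - span_a[0]
    lb = span_b[1] - span_b[0]
    if la <= 0 or lb <= 0:
        raise ValueError("degenerate zero-length unit span")
    inter = max(0, min(span_a[1], span_b[1]) - max(span_a[0], span_b[0]))
    if method == "jaccard":
        union = la + lb - inter
        return inter / union
    if method == "shorter":
        return inter / min(la, lb)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# tissue specificity
# ---------------------------------------------------------------------------


def tissue_zscores(ppm, pseudocount: float = 1.0, unit_id: str = "") -> TissueZScore:
    """Standardised log2 expression across libraries.

    ``ppm`` is a mapping library_id -> ppm (or a sequence; ids then become
    indices).  Uses population moments; sigma = 0 yields z = 0 everywhere.
    """
    if hasattr(ppm, "items"):
        lib_ids = list(ppm.keys())
        vals = np.array([ppm[k] for k in lib_ids], dtype=float)
    else:
        vals = np.asarray(ppm, dtype=float)
        lib_ids = [str(i) for i in range(len(vals))]
    if len(vals) < 2:
        raise ValueError("tissue Z-scores need >= 2 libraries")
    x = np.log2(vals + pseudocount)
    mu = float(x.mean())
    sigma = float(x.std())  # population sd
    if sigma <= 1e-12 * max(1.0, abs(mu)):  # constant unit up to rounding
        sigma = 0.0
    z = np.zeros_like(x) if sigma == 0 else (x - mu) / sigma
    return TissueZScore(unit_id=unit_id, lib_ids=lib_ids, x=x, mu=mu, sigma=sigma, z=z)


def detect_switching_pairs(zA: TissueZScore, zB: TissueZScore,
                           z_cut: float = 2.0) -> list[tuple[str, str]]:
    """Tissue pairs where unit A peaks in one tissue and unit B in another."""
    if zA.lib_ids != zB.lib_ids:
        raise ValueError("units must share the same library set")
    hits_a = [t for t, z in zip(zA.lib_ids, zA.z) if z > z_cut]
    hits_b = [t for t, z in zip(zB.lib_ids, zB.z) if z > z_cut]
    return [(ta, tb) for ta in hits_a for tb in hits_b if ta != tb]


# ---------------------------------------------------------------------------
# connected units (read-through over adjacent genes)
# ---------------------------------------------------------------------------


def find_connected_units(assigned: pd.DataFrame, genes: list[GeneModel],
                         tsc_links: list[ClusterGeneLink],
                         pac_links: list[ClusterGeneLink],
                         lib_totals: dict, min_ppm: float = 5.0,
                         max_gap: int = 3_000_000) -> list[ConnectedUnit]:
    """TSC-PAC pairs bridging two adjacent same-strand genes.

    The TSC must associate with gene A and the PAC with a distinct gene B on
    the same chromosome and strand, with B's 5' end at most ``max_gap``
    downstream of A's 3' end (in transcription orientation) and a pooled
    expression > ``min_ppm``.  Larger separations and opposite-strand or
    inter-chromosomal configurations are the business of fusion_detection.
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

    counts = (
        assigned[(assigned["tsc_id"] != "") & (assigned["pac_id"] != "")]
        .groupby(["tsc_id", "pac_id"], sort=True)
        .size()
    )
    out = []
    for (tsc_id, pac_id), n in counts.items():
        ppm = n * 1e6 / pooled_total if pooled_total else 0.0
        if ppm <= min_ppm:
            continue
        for ga_id in sorted(tsc_genes.get(tsc_id, ())):
            for gb_id in sorted(pac_genes.get(pac_id, ())):
                if ga_id == gb_id:
                    continue
                ga, gb = gene_by_id[ga_id], gene_by_id[gb_id]
                if ga.chrom != gb.chrom or ga.strand != gb.strand:
                    continue
                if ga.strand == "+":
                    gap = gb.tx_start - ga.tx_end
                else:
                    gap = ga.tx_start - gb.tx_end
                if not 0 <= gap < max_gap:
                    continue
                out.append(
                    ConnectedUnit(
                        tsc_id=tsc_id, pac_id=pac_id, gene5=ga_id, gene3=gb_id,
                        chrom=ga.chrom, strand=ga.strand, gap=int(gap),
                        count=int(n), ppm=float(ppm),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------


def geneset_enrichment(foreground, background, term_map: dict,
                       size_min: int = 100, size_max: int = 500,
                       compute_fdr: bool = True) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of term gene sets in a foreground.

    Terms with fewer than ``size_min`` or more than ``size_max`` background
    genes are skipped (too tight / too loose).  p = P(X >= k) for X
    hypergeometric with population N_bg, K term genes and n draws.  An
    optional Benjamini-Hochberg column is attached over the tested terms.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    n, N_bg = len(fg), len(bg)
    results = []
    for term_id in sorted(term_map):
        term_genes = set(term_map[term_id]) & bg
        K = len(term_genes)
        if not size_min <= K <= size_max:
            continue
        k = len(term_genes & fg)
        p = float(sps.hypergeom.sf(k - 1, N_bg, K, n)) if k > 0 else 1.0
        results.append(EnrichmentResult(term_id=term_id, k=k, K=K, n=n, N_bg=N_bg, p=p))
    if compute_fdr and results:
        from statsmodels.stats.multitest import multipletests

        _, fdr, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    return results
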