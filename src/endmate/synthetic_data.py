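"""Synthetic mate-pair tag libraries with known truth.

The generator emulates the structure the analysis assumes: a small
two-chromosome assembly; non-overlapping multi-exon genes, a subset with
alternative start (TSC) and poly(A) (PAC) positions; 18 independently
normalised libraries (14 tissues + 4 cell lines) with log-normal expression
and tissue biases; optional start-end coupling with a configurable share;
and the three experimental noise sources the protocol is known for —
5'-truncated cDNAs from failed cap replacement, oligo-dT internal priming at
genomic A-stretches, and chimeric ligation joining ends of unrelated
molecules.  Fusion transcripts between distant gene pairs can be planted at
a chosen ppm.  TSS/Random ("dR") libraries place the 3' tag at a
size-fraction-dependent insert distance from the TSS in mRNA coordinates,
with split blocks across introns.

Internal-priming events are only emitted at positions where the synthetic
genome actually carries an A-run, so the sequence-level QC scans can detect
them.  Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_models import ENDPAIR_COLUMNS, EndTag, GeneModel, revcomp

__all__ = [
    "SimConfig",
    "TruthSet",
    "DEFAULT_LIBRARIES",
    "simulate_annotation",
    "simulate_genome",
    "simulate_tags",
    "simulate_random_tags",
    "exhaustive_random_tags",
]

DEFAULT_LIBRARIES = (
    "brain", "heart", "liver", "kidney", "lung", "spleen", "testis", "ovary",
    "thymus", "colon", "stomach", "muscle", "placenta", "pancreas",
    "HeLa", "MCF7", "DLD1", "LC2AD",
)

_MAX_UNITS = 3
_MAX_ARUNS = 2


@dataclass(frozen=True)
class SimConfig:
    """The stated world of the simulator (all rates and sizes in one place)."""

    seed: int = 0
    n_genes: int = 200
    n_libraries: int = 18
    n_chroms: int = 2
    exons_per_gene: tuple[int, int] = (1, 8)
    mrna_len_range: tuple[int, int] = (500, 5000)
    intron_len_range: tuple[int, int] = (200, 2000)
    intergenic_gap_range: tuple[int, int] = (60_000, 100_000)
    alt_tsc_prob: float = 0.25
    alt_pac_prob: float = 0.20
    preferred_frac: float = 0.5  # of genes with both alt TSCs and alt PACs
    coupling_share: float = 0.9
    gene_log2_sd: float = 1.5
    tissue_log2_sd: float = 0.5
    specific_frac: float = 0.10  # genes with one boosted tissue
    specific_boost: float = 3.0  # log2
    switch_frac: float = 0.3  # of coupled genes: opposite units boosted in two tissues
    depth: int = 100_000  # pairs per library
    truncation_rate: float = 0.05
    internal_priming_rate: float = 0.05
    chimera_rate: float = 0.01
    fusions: tuple[tuple[int, int, float], ...] = ()  # (gene5 idx, gene3 idx, ppm)
    fusion_mapq: int = 60
    mapq: int = 60
    polya_signal_frac: float = 0.72
    tata_frac: float = 0.15
    dr_depth: int = 20_000
    dr_fractions: tuple[tuple[str, int, int], ...] = (
        ("dR0.5", 500, 1000),
        ("dR1.0", 1000, 2000),
        ("dR2.0", 2000, 5000),
    )
    tag_len: int = 100

    def __post_init__(self):
        for p in (self.alt_tsc_prob, self.alt_pac_prob, self.preferred_frac,
                  self.truncation_rate, self.internal_priming_rate,
                  self.chimera_rate, self.specific_frac, self.switch_frac):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.5 <= self.coupling_share <= 1.0:
            raise ValueError("coupling share must lie in [0.5, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")

    def library_ids(self) -> list[str]:
        base = list(DEFAULT_LIBRARIES)
        if self.n_libraries <= len(base):
            return base[: self.n_libraries]
        return base + [f"lib{i:02d}" for i in range(len(base), self.n_libraries)]


@dataclass
class TruthSet:
    """Planted ground truth: positions, weights, couplings, noise classes."""

    cfg: SimConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    lib_ids: list[str]
    # padded per-gene unit arrays (-1 = absent)
    k5: np.ndarray
    k3: np.ndarray
    tss_pos: np.ndarray  # (G, 3)
    pas_pos: np.ndarray  # (G, 3)
    w5: np.ndarray  # (G, 3) base sampling weights
    w3: np.ndarray
    coupled: np.ndarray  # (G,) bool: diagonal unit coupling planted
    expr_log2: np.ndarray  # (G, L) per-library log2 relative expression
    tssmod_log2: np.ndarray  # (G, L, 3) per-library TSS-weight modulation
    arun_pos: np.ndarray  # (G, 2) genomic anchors of planted A-runs
    n_arun: np.ndarray
    polya_signal: np.ndarray  # (G, 3) bool, planted AATAAA per PAS
    tata: np.ndarray  # (G,) bool
    switch_info: list = field(default_factory=list)  # (gene, libA, libB)
    tag_truth: pd.DataFrame | None = None

    # -- derived quantities -------------------------------------------------
    def gene_probs(self, lib_index: int) -> np.ndarray:
        w = np.exp2(self.expr_log2[:, lib_index])
        return w / w.sum()

    def tss_probs(self, lib_index: int) -> np.ndarray:
        w = self.w5 * np.exp2(self.tssmod_log2[:, lib_index, :])
        return w / w.sum(axis=1, keepdims=True)

    def expected_gene_ppm(self, lib_index: int) -> np.ndarray:
        return self.gene_probs(lib_index) * 1e6

    def preferred_units(self) -> list[tuple[int, int, int]]:
        """Planted couplings as (gene index, tss index, pac index)."""
        out = []
        for g in np.flatnonzero(self.coupled):
            for i in range(min(self.k5[g], self.k3[g])):
                out.append((int(g), i, i))
        return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(cfg: SimConfig) -> TruthSet:
    """Place non-overlapping genes on a synthetic assembly and plant units."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    G, L = cfg.n_genes, cfg.n_libraries
    lib_ids = cfg.library_ids()

    cursors = {f"chr{i + 1}": 60_000 for i in range(cfg.n_chroms)}
    genes: list[GeneModel] = []
    k5 = np.ones(G, dtype=np.int64)
    k3 = np.ones(G, dtype=np.int64)
    tss_pos = np.full((G, _MAX_UNITS), -1, dtype=np.int64)
    pas_pos = np.full((G, _MAX_UNITS), -1, dtype=np.int64)
    arun_pos = np.full((G, _MAX_ARUNS), -1, dtype=np.int64)
    n_arun = np.ones(G, dtype=np.int64)

    for g in range(G):
        chrom = f"chr{g % cfg.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        mrna_len = int(rng.integers(cfg.mrna_len_range[0], cfg.mrna_len_range[1] + 1))
        min_ex = 50
        if mrna_len < min_ex * n_ex:
            n_ex = max(1, mrna_len // min_ex)
        extra = rng.multinomial(mrna_len - min_ex * n_ex, [1.0 / n_ex] * n_ex)
        ex_lens = min_ex + extra
        intron_lens = rng.integers(
            cfg.intron_len_range[0], cfg.intron_len_range[1] + 1, size=max(0, n_ex - 1)
        )
        start = cursors[chrom]
        exons = []
        pos = start
        for i, el in enumerate(ex_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        end = pos
        gap = int(rng.integers(*cfg.intergenic_gap_range))
        cursors[chrom] = end + gap
        model = GeneModel(
            gene_id=f"G{g:04d}", chrom=chrom, strand=strand,
            tx_start=start, tx_end=end, exons=tuple(exons),
            coding_class="NM" if rng.random() < 0.9 else "NR",
        )
        genes.append(model)

        # alternative units: primary at the annotated terminus, alternatives
        # 0.6-5 kb into the flanking region, always > 500 bp apart so they
        # fall in distinct grid bins
        tss_pos[g, 0] = model.five_prime_pos
        if rng.random() < cfg.alt_tsc_prob:
            k5[g] = 3 if rng.random() < 0.3 else 2
            offs = [int(rng.integers(600, 2500)), int(rng.integers(3100, 5000))]
            for a in range(1, k5[g]):
                off = offs[a - 1]
                if strand == "+":
                    tss_pos[g, a] = start - off
                else:
                    tss_pos[g, a] = end - 1 + off
        pas_pos[g, 0] = model.three_prime_pos
        if rng.random() < cfg.alt_pac_prob:
            k3[g] = 3 if rng.random() < 0.3 else 2
            offs = [int(rng.integers(600, 2500)), int(rng.integers(3100, 5000))]
            for a in range(1, k3[g]):
                off = offs[a - 1]
                if strand == "+":
                    pas_pos[g, a] = end - 1 + off
                else:
                    pas_pos[g, a] = start - off
        # A-run anchors for internal priming, mid-transcript and exonic
        n_arun[g] = int(rng.integers(1, _MAX_ARUNS + 1))
        for a in range(n_arun[g]):
            m = int(rng.integers(mrna_len // 4, 3 * mrna_len // 4))
            arun_pos[g, a] = model.mrna_to_genome(m)

    chrom_sizes = {c: cur + 60_000 for c, cur in cursors.items()}

    # base unit usage weights (primary dominant, deterministic shape)
    shapes = {1: [1.0], 2: [0.65, 0.35], 3: [0.6, 0.25, 0.15]}
    w5 = np.zeros((G, _MAX_UNITS))
    w3 = np.zeros((G, _MAX_UNITS))
    for g in range(G):
        w5[g, : k5[g]] = shapes[int(k5[g])]
        w3[g, : k3[g]] = shapes[int(k3[g])]

    multi = (k5 >= 2) & (k3 >= 2)
    coupled = multi & (rng.random(G) < cfg.preferred_frac)

    # expression: gene-level log-normal plus per-library tissue dispersion,
    # a subset of genes strongly biased toward one tissue
    mu = rng.normal(0.0, cfg.gene_log2_sd, size=G)
    expr = mu[:, None] + rng.normal(0.0, cfg.tissue_log2_sd, size=(G, L))
    specific = rng.random(G) < cfg.specific_frac
    for g in np.flatnonzero(specific):
        expr[g, rng.integers(0, L)] += cfg.specific_boost

    # tissue-switching unit pairs among coupled genes: the gene is active in
    # two tissues, and the two coupled units swap their usage shares between
    # them (a share boost alone cannot move the dominant unit's log2 ppm far
    # enough to reach z > 2, since its baseline share is already near 1)
    tssmod = np.zeros((G, L, _MAX_UNITS))
    switch_info = []
    b = cfg.specific_boost
    for g in np.flatnonzero(coupled):
        if rng.random() >= cfg.switch_frac or L < 2:
            continue
        la, lb = rng.choice(L, size=2, replace=False)
        expr[g, la] += b
        expr[g, lb] += b
        tssmod[g, la, 0] += b
        tssmod[g, la, 1] -= b
        tssmod[g, lb, 0] -= b
        tssmod[g, lb, 1] += b
        switch_info.append((int(g), int(la), int(lb)))

    polya_signal = (rng.random((G, _MAX_UNITS)) < cfg.polya_signal_frac) & (pas_pos >= 0)
    tata = rng.random(G) < cfg.tata_frac

    return TruthSet(
        cfg=cfg, genes=genes, chrom_sizes=chrom_sizes, lib_ids=lib_ids,
        k5=k5, k3=k3, tss_pos=tss_pos, pas_pos=pas_pos, w5=w5, w3=w3,
        coupled=coupled, expr_log2=expr, tssmod_log2=tssmod,
        arun_pos=arun_pos, n_arun=n_arun, polya_signal=polya_signal,
        tata=tata, switch_info=switch_info,
    )


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------


def _plant(seq: np.ndarray, strand: str, anchor: int, rel0: int, motif: str) -> None:
    """Write ``motif`` on the sense strand at transcript offsets rel0.. from anchor."""
    if strand == "+":
        g0 = anchor + rel0
        written = motif
    else:
        g0 = anchor - rel0 - len(motif) + 1
        written = revcomp(motif)
    if 0 <= g0 and g0 + len(written) <= len(seq):
        seq[g0 : g0 + len(written)] = np.frombuffer(written.encode(), dtype="S1")


def simulate_genome(truth: TruthSet) -> dict[str, str]:
    """Random assembly sequence with the truth's cis-features planted.

    AATAAA hexamers end 16 bp upstream of signal-positive PASs, 8-base
    A-runs sit immediately downstream of internal-priming anchors, and a
    TATA box is written 29 bp upstream of the primary TSS of TATA genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.cfg.seed, 2]))
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        chrom: bases[rng.integers(0, 4, size=size)].copy()
        for chrom, size in truth.chrom_sizes.items()
    }
    for g, model in enumerate(truth.genes):
        arr = seqs[model.chrom]
        for a in range(truth.k3[g]):
            if truth.polya_signal[g, a]:
                _plant(arr, model.strand, int(truth.pas_pos[g, a]), -21, "AATAAA")
        for a in range(truth.n_arun[g]):
            _plant(arr, model.strand, int(truth.arun_pos[g, a]), 1, "A" * 8)
        if truth.tata[g]:
            _plant(arr, model.strand, int(truth.tss_pos[g, 0]), -29, "TATAAAAG")
    return {chrom: arr.tobytes().decode() for chrom, arr in seqs.items()}


# ---------------------------------------------------------------------------
# tag simulation
# ---------------------------------------------------------------------------


def _pad_exon_maps(truth: TruthSet):
    """Padded per-gene exon arrays in transcript order for mRNA->genome maps."""
    G = len(truth.genes)
    E = max(len(g.exons) for g in truth.genes)
    ex_start = np.zeros((G, E), dtype=np.int64)
    ex_end = np.zeros((G, E), dtype=np.int64)
    cum = np.zeros((G, E + 1), dtype=np.int64)
    L = np.zeros(G, dtype=np.int64)
    plus = np.zeros(G, dtype=bool)
    for g, model in enumerate(truth.genes):
        ex = list(model.exons)
        if model.strand == "-":
            ex = ex[::-1]
        lens = [e - s for s, e in ex]
        L[g] = sum(lens)
        plus[g] = model.strand == "+"
        c = np.concatenate([[0], np.cumsum(lens)])
        cum[g, : len(c)] = c
        cum[g, len(c):] = c[-1]
        for i, (s, e) in enumerate(ex):
            ex_start[g, i] = s
            ex_end[g, i] = e
        ex_start[g, len(ex):] = ex[-1][0]
        ex_end[g, len(ex):] = ex[-1][1]
    return ex_start, ex_end, cum, L, plus


def _mrna_to_genome_vec(m, gene_idx, maps):
    ex_start, ex_end, cum, L, plus = maps
    e = (m[:, None] >= cum[gene_idx][:, 1:]).sum(axis=1)
    within = m - cum[gene_idx, e]
    gpos = np.where(
        plus[gene_idx],
        ex_start[gene_idx, e] + within,
        ex_end[gene_idx, e] - 1 - within,
    )
    return gpos


def simulate_tags(cfg: SimConfig, truth: TruthSet) -> tuple[pd.DataFrame, TruthSet]:
    """Draw the TSS/PAS (dT) libraries and record per-tag truth.

    For each library ``cfg.depth`` pairs are drawn: the gene by expression,
    the TSS by unit weights, the PAS by the coupling rule (share ``s`` to
    the partner unit of coupled genes, marginal otherwise), then noise in
    the order truncation -> internal priming -> chimera, then planted
    fusions (Poisson-distributed support at the configured ppm).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    maps = _pad_exon_maps(truth)
    G = len(truth.genes)
    chroms = np.array([g.chrom for g in truth.genes])
    strands = np.array([g.strand for g in truth.genes])
    kmin = np.minimum(truth.k5, truth.k3)
    cum3 = np.cumsum(truth.w3, axis=1)

    frames = []
    truth_frames = []
    for l, lib in enumerate(truth.lib_ids):
        n = cfg.depth
        p_gene = truth.gene_probs(l)
        gene = rng.choice(G, size=n, p=p_gene)
        cum5 = np.cumsum(truth.tss_probs(l), axis=1)
        i5 = (rng.random(n)[:, None] > cum5[gene]).sum(axis=1)
        j3 = (rng.random(n)[:, None] > cum3[gene]).sum(axis=1)
        use_couple = (
            truth.coupled[gene]
            & (i5 < kmin[gene])
            & (rng.random(n) < cfg.coupling_share)
        )
        j3 = np.where(use_couple, i5, j3)
        pos5 = truth.tss_pos[gene, i5]
        pos3 = truth.pas_pos[gene, j3]
        noise = np.full(n, "none", dtype=object)

        # 5' truncation: cap replaced at a random internal mRNA position
        t_mask = rng.random(n) < cfg.truncation_rate
        if t_mask.any():
            gi = gene[t_mask]
            m = (rng.random(t_mask.sum()) * maps[3][gi]).astype(np.int64)
            pos5[t_mask] = _mrna_to_genome_vec(m, gi, maps)
            noise[t_mask] = "truncation"

        # internal priming at a planted genomic A-run
        p_mask = rng.random(n) < cfg.internal_priming_rate
        if p_mask.any():
            gi = gene[p_mask]
            pick = rng.integers(0, truth.n_arun[gi])
            pos3[p_mask] = truth.arun_pos[gi, pick]
            noise[p_mask] = np.where(
                noise[p_mask] == "none", "internal_priming", noise[p_mask]
            )

        # chimeric ligation: the 3' end comes from a random other molecule
        gene3 = gene.copy()
        c_mask = rng.random(n) < cfg.chimera_rate
        if c_mask.any():
            donor = rng.integers(0, n, size=c_mask.sum())
            pos3[c_mask] = pos3[donor]
            gene3[c_mask] = gene3[donor]
            noise[c_mask] = "chimera"

        lib_df = pd.DataFrame(
            {
                "library_id": lib,
                "chrom5": chroms[gene],
                "pos5": pos5,
                "strand5": strands[gene],
                "mapq5": cfg.mapq,
                "chrom3": chroms[gene3],
                "pos3": pos3,
                "strand3": strands[gene3],
                "mapq3": cfg.mapq,
                "end3_kind": "PAS",
                "blocks3_sizes": "",
                "blocks3_starts": "",
            }
        )
        tru = pd.DataFrame(
            {
                "library_id": lib,
                "gene": gene,
                "tss_idx": i5,
                "pac_idx": j3,
                "gene3": gene3,
                "noise": noise,
            }
        )

        for g5, g3, ppm in cfg.fusions:
            nf = int(rng.poisson(cfg.depth * ppm / 1e6))
            if nf == 0:
                continue
            fus = pd.DataFrame(
                {
                    "library_id": lib,
                    "chrom5": chroms[g5],
                    "pos5": truth.tss_pos[g5, 0],
                    "strand5": strands[g5],
                    "mapq5": cfg.fusion_mapq,
                    "chrom3": chroms[g3],
                    "pos3": truth.pas_pos[g3, 0],
                    "strand3": strands[g3],
                    "mapq3": cfg.fusion_mapq,
                    "end3_kind": "PAS",
                    "blocks3_sizes": "",
                    "blocks3_starts": "",
                    "_n": range(nf),
                }
            ).drop(columns="_n")
            lib_df = pd.concat([lib_df, fus], ignore_index=True)
            tru = pd.concat(
                [
                    tru,
                    pd.DataFrame(
                        {
                            "library_id": lib,
                            "gene": g5,
                            "tss_idx": 0,
                            "pac_idx": 0,
                            "gene3": g3,
                            "noise": "fusion",
                            "_n": range(nf),
                        }
                    ).drop(columns="_n"),
                ],
                ignore_index=True,
            )
        frames.append(lib_df)
        truth_frames.append(tru)

    tags = pd.concat(frames, ignore_index=True)[ENDPAIR_COLUMNS]
    truth.tag_truth = pd.concat(truth_frames, ignore_index=True)
    return tags, truth


def simulate_random_tags(cfg: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Draw the size-fractionated TSS/Random (dR) libraries.

    Only transcripts at least as long as a fraction's lower bound can enter
    that fraction (size selection); the 3' tag ends ``insert`` nt from the
    TSS in mRNA coordinates and carries split blocks across any intervening
    introns.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    maps = _pad_exon_maps(truth)
    L = maps[3]
    G = len(truth.genes)
    pooled = np.exp2(truth.expr_log2).mean(axis=1)
    rows = []
    for label, lo, hi in cfg.dr_fractions:
        lib = f"pooled.{label}"
        eligible = np.flatnonzero(L >= lo)
        if len(eligible) == 0:
            continue
        w = pooled[eligible] / pooled[eligible].sum()
        picks = rng.choice(len(eligible), size=cfg.dr_depth, p=w)
        genes_drawn = eligible[picks]
        u = rng.random(cfg.dr_depth)
        for g, uu in zip(genes_drawn, u):
            model = truth.genes[g]
            top = min(hi, int(L[g]))
            insert = lo + int(uu * (top - lo + 1))
            insert = min(insert, int(L[g]))
            m0 = max(0, insert - cfg.tag_len)
            blocks = model.mrna_interval_blocks(m0, insert)
            pos3 = model.mrna_to_genome(insert - 1)
            origin = blocks[0][0]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - origin) for s, e in blocks)
            rows.append(
                (
                    lib, model.chrom, int(truth.tss_pos[g, 0]), model.strand,
                    cfg.mapq, model.chrom, pos3, model.strand, cfg.mapq,
                    "RANDOM", sizes, starts,
                )
            )
    return pd.DataFrame(rows, columns=ENDPAIR_COLUMNS)


def exhaustive_random_tags(model: GeneModel, step: int = 50,
                           tag_len: int = 100, library_id: str = "exhaustive") -> list[EndTag]:
    """Deterministic tags tiling a transcript end to end.

    Tags of ``tag_len`` nt start every ``step`` nt of mRNA, so every exonic
    base is covered and every intron is spanned by at least one split tag
    (provided step <= tag_len).  Useful as the noiseless exhaustive-coverage
    limit for assembly tests.
    """
    L = model.mrna_length
    tags = []
    ends = list(range(min(tag_len, L), L + 1, step))
    if ends[-1] != L:
        ends.append(L)
    for m_end in ends:
        m0 = max(0, m_end - tag_len)
        blocks = model.mrna_interval_blocks(m0, m_end)
        pos = model.mrna_to_genome(m_end - 1)
        tags.append(
            EndTag(
                chrom=model.chrom, pos=int(pos), strand=model.strand,
                end_kind="RANDOM", mapq=60, library_id=library_id,
                blocks=blocks,
            )
        )
    return tags
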