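"""Domain types, coordinate conventions and file I/O.

All coordinates are 0-based, half-open internally.  Gene models are read from
refFlat (11 columns) or BED12; aligned mate-pair tags are exchanged through the
``ENDPAIR v1`` TSV dialect (see :data:`ENDPAIR_COLUMNS`).  The strand of a PAS
tag is the transcript strand: its ``pos`` is the last transcribed base.

Raw-read handling is deliberately limited to
:func:`detect_junction_signature`; alignment is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "EndTag",
    "MatePairTag",
    "LibraryStats",
    "ENDPAIR_COLUMNS",
    "read_gene_models",
    "write_gene_models",
    "read_tag_pair_table",
    "read_tag_pairs",
    "write_tag_pair_table",
    "pairs_to_frame",
    "frame_to_pairs",
    "detect_junction_signature",
    "read_bed",
    "read_fasta",
    "write_fasta",
]

TSS_SIGNATURE = "CTGCTGCC"
RANDOM3P_SIGNATURE = "CTGCTGGG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with exon structure.

    ``coding_class`` is ``"NM"`` for protein-coding and ``"NR"`` for putative
    non-coding models (RefSeq accession-prefix convention).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    coding_class: str = "NM"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start >= tx_end")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if self.coding_class not in ("NM", "NR"):
            raise ValueError(f"{self.gene_id}: coding_class must be NM or NR")

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def five_prime_pos(self) -> int:
        """Genomic base of the annotated TSS."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def three_prime_pos(self) -> int:
        """Genomic base of the annotated poly(A) site."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    # -- mRNA <-> genome coordinate maps ----------------------------------
    def _exon_cums(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exon starts/ends in transcript order plus cumulative mRNA offsets."""
        ex = np.asarray(self.exons, dtype=np.int64)
        if self.strand == "-":
            ex = ex[::-1]
        lens = ex[:, 1] - ex[:, 0]
        cum = np.concatenate([[0], np.cumsum(lens)])
        return ex[:, 0], ex[:, 1], cum

    def genome_to_mrna(self, pos: int) -> int | None:
        """mRNA offset (0 = TSS) of an exonic genomic base, else None."""
        starts, ends, cum = self._exon_cums()
        for i in range(len(starts)):
            if starts[i] <= pos < ends[i]:
                if self.strand == "+":
                    return int(cum[i] + (pos - starts[i]))
                return int(cum[i] + (ends[i] - 1 - pos))
        return None

    def mrna_to_genome(self, offset: int) -> int:
        """Genomic base of an mRNA offset (0 = TSS)."""
        if not 0 <= offset < self.mrna_length:
            raise ValueError(f"mRNA offset {offset} outside [0,{self.mrna_length})")
        starts, ends, cum = self._exon_cums()
        i = int(np.searchsorted(cum, offset, side="right")) - 1
        within = offset - cum[i]
        if self.strand == "+":
            return int(starts[i] + within)
        return int(ends[i] - 1 - within)

    def mrna_interval_blocks(self, m_start: int, m_end: int) -> tuple[tuple[int, int], ...]:
        """Genomic [start,end) blocks covered by mRNA interval [m_start,m_end)."""
        if not 0 <= m_start < m_end <= self.mrna_length:
            raise ValueError("mRNA interval outside transcript")
        starts, ends, cum = self._exon_cums()
        blocks = []
        for i in range(len(starts)):
            lo = max(m_start, cum[i])
            hi = min(m_end, cum[i + 1])
            if lo >= hi:
                continue
            if self.strand == "+":
                g0 = starts[i] + (lo - cum[i])
                blocks.append((int(g0), int(g0 + (hi - lo))))
            else:
                g1 = ends[i] - (lo - cum[i])
                blocks.append((int(g1 - (hi - lo)), int(g1)))
        return tuple(sorted(blocks))


@dataclass(frozen=True)
class EndTag:
    """One aligned tag end (the single base representing a transcript end)."""

    chrom: str
    pos: int
    strand: str
    end_kind: str  # TSS | PAS | RANDOM
    mapq: int = 60
    library_id: str = ""
    blocks: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.end_kind not in ("TSS", "PAS", "RANDOM"):
            raise ValueError(f"bad end_kind {self.end_kind!r}")
        if self.pos < 0 or self.mapq < 0:
            raise ValueError("negative position or mapq")


@dataclass(frozen=True)
class MatePairTag:
    """A linked 5'/3' end pair from a single cDNA molecule.

    Non-chimeric same-chromosome pairs should satisfy end5.pos <= end3.pos on
    '+' (converse on '-'); violations are retained and exposed via
    :attr:`discordant`.
    """

    end5: EndTag
    end3: EndTag
    library_id: str

    def __post_init__(self):
        if self.end5.end_kind != "TSS":
            raise ValueError("end5 must be a TSS tag")
        if self.end3.end_kind not in ("PAS", "RANDOM"):
            raise ValueError("end3 must be PAS or RANDOM")

    @property
    def discordant(self) -> bool:
        if self.end5.chrom != self.end3.chrom or self.end5.strand != self.end3.strand:
            return True
        if self.end5.strand == "+":
            return self.end5.pos > self.end3.pos
        return self.end5.pos < self.end3.pos


@dataclass
class LibraryStats:
    """Per-library mapped-pair totals used for ppm normalisation."""

    library_id: str
    total_pairs: int
    fraction_label: str = "dT"  # dT | dR0.5 | dR1.0 | dR2.0

    def __post_init__(self):
        if self.total_pairs <= 0:
            raise ValueError(f"{self.library_id}: total_pairs must be > 0")


# ---------------------------------------------------------------------------
# gene model I/O
# ---------------------------------------------------------------------------


def _parse_int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x != ""]


def _coding_class(name: str, explicit: str | None = None) -> str:
    if explicit in ("NM", "NR"):
        return explicit
    return "NR" if name.startswith("NR_") else "NM"


def read_gene_models(path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from a refFlat (11 col) or BED12 file.

    The format is sniffed from the column count unless ``fmt`` is given
    ("refflat" or "bed12").  Malformed lines raise :class:`FormatError`
    naming the line number.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            this_fmt = fmt or ("refflat" if len(f) == 11 else "bed12" if len(f) == 12 else None)
            if this_fmt is None:
                raise FormatError(f"{path}:{lineno}: expected 11 or 12 columns, got {len(f)}")
            try:
                if this_fmt == "refflat":
                    gene_name, name, chrom, strand = f[0], f[1], f[2], f[3]
                    tx_start, tx_end = int(f[4]), int(f[5])
                    exon_count = int(f[8])
                    starts = _parse_int_list(f[9])
                    ends = _parse_int_list(f[10])
                    if len(starts) != exon_count or len(ends) != exon_count:
                        raise FormatError(
                            f"{path}:{lineno}: exon count mismatch for {name}"
                        )
                    exons = tuple(zip(starts, ends))
                    gene_id = name or gene_name
                else:
                    chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                    strand = f[5]
                    n_blocks = int(f[9])
                    sizes = _parse_int_list(f[10])
                    bstarts = _parse_int_list(f[11])
                    if len(sizes) != n_blocks or len(bstarts) != n_blocks:
                        raise FormatError(
                            f"{path}:{lineno}: blockCount mismatch for {name}"
                        )
                    exons = tuple((start + s, start + s + sz) for s, sz in zip(bstarts, sizes))
                    tx_start, tx_end, gene_id = start, end, name
                models.append(
                    GeneModel(
                        gene_id=gene_id,
                        chrom=chrom,
                        strand=strand,
                        tx_start=tx_start,
                        tx_end=tx_end,
                        exons=exons,
                        coding_class=_coding_class(gene_id),
                    )
                )
            except FormatError:
                raise
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return models


def write_gene_models(models, path, fmt: str = "bed12") -> None:
    """Write gene models as BED12 (default) or refFlat."""
    with open(path, "w") as fh:
        for m in models:
            if fmt == "bed12":
                sizes = ",".join(str(e - s) for s, e in m.exons)
                starts = ",".join(str(s - m.tx_start) for s, e in m.exons)
                fh.write(
                    "\t".join(
                        [
                            m.chrom,
                            str(m.tx_start),
                            str(m.tx_end),
                            m.gene_id,
                            "0",
                            m.strand,
                            str(m.tx_start),
                            str(m.tx_end),
                            "0",
                            str(len(m.exons)),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )
            elif fmt == "refflat":
                fh.write(
                    "\t".join(
                        [
                            m.gene_id,
                            m.gene_id,
                            m.chrom,
                            m.strand,
                            str(m.tx_start),
                            str(m.tx_end),
                            str(m.tx_start),
                            str(m.tx_end),
                            str(len(m.exons)),
                            ",".join(str(s) for s, e in m.exons) + ",",
                            ",".join(str(e) for s, e in m.exons) + ",",
                        ]
                    )
                    + "\n"
                )
            else:
                raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# ENDPAIR v1 tag-pair tables
# ---------------------------------------------------------------------------

ENDPAIR_COLUMNS = [
    "library_id",
    "chrom5",
    "pos5",
    "strand5",
    "mapq5",
    "chrom3",
    "pos3",
    "strand3",
    "mapq3",
    "end3_kind",
    "blocks3_sizes",
    "blocks3_starts",
]

_ENDPAIR_DTYPES = {
    "library_id": str,
    "chrom5": str,
    "pos5": np.int64,
    "strand5": str,
    "mapq5": np.int64,
    "chrom3": str,
    "pos3": np.int64,
    "strand3": str,
    "mapq3": np.int64,
    "end3_kind": str,
    "blocks3_sizes": str,
    "blocks3_starts": str,
}


def read_tag_pair_table(path, min_mapq: int = 10) -> tuple[pd.DataFrame, dict[str, LibraryStats]]:
    """Read an ENDPAIR v1 table into a DataFrame plus per-library stats.

    Rows with mapq < ``min_mapq`` on either end are dropped at load (the
    stricter mapq>37 rule for fusion calling is applied in fusion_detection).
    The fraction label of a library is taken from a trailing ``.dR0.5`` /
    ``.dR1.0`` / ``.dR2.0`` suffix on its id; anything else is ``dT``.
    """
    df = pd.read_csv(path, sep="\t", dtype=_ENDPAIR_DTYPES, keep_default_na=False)
    missing = [c for c in ENDPAIR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing ENDPAIR columns {missing}")
    bad_kind = ~df["end3_kind"].isin(["PAS", "RANDOM"])
    if bad_kind.any():
        raise FormatError(
            f"{path}: unknown end3_kind {df.loc[bad_kind, 'end3_kind'].iloc[0]!r}"
        )
    if (df["pos5"] < 0).any() or (df["pos3"] < 0).any():
        raise FormatError(f"{path}: negative coordinates")
    df = df[(df["mapq5"] >= min_mapq) & (df["mapq3"] >= min_mapq)].reset_index(drop=True)
    stats = library_stats_from_frame(df)
    return df, stats


def library_stats_from_frame(df: pd.DataFrame) -> dict[str, LibraryStats]:
    stats = {}
    for lib, n in df["library_id"].value_counts().items():
        frac = "dT"
        for label in ("dR0.5", "dR1.0", "dR2.0"):
            if lib.endswith("." + label):
                frac = label
        stats[lib] = LibraryStats(library_id=lib, total_pairs=int(n), fraction_label=frac)
    return stats


def write_tag_pair_table(df: pd.DataFrame, path) -> None:
    """Write an ENDPAIR v1 DataFrame as TSV (canonical column order)."""
    df.to_csv(path, sep="\t", index=False, columns=ENDPAIR_COLUMNS)


def _blocks_to_cols(blocks, pos3) -> tuple[str, str]:
    if not blocks:
        return "", ""
    origin = min(s for s, e in blocks)
    sizes = ",".join(str(e - s) for s, e in blocks)
    starts = ",".join(str(s - origin) for s, e in blocks)
    return sizes, starts


def _cols_to_blocks(sizes: str, starts: str, pos3: int, strand3: str):
    """Reconstruct absolute blocks from relative sizes/starts.

    ``pos3`` is the base representing the tag's transcript 3' end, i.e. the
    rightmost aligned base on '+' and the leftmost on '-'.
    """
    if not sizes:
        return None
    szs = _parse_int_list(sizes)
    sts = _parse_int_list(starts)
    if len(szs) != len(sts):
        raise FormatError("blocks3_sizes/blocks3_starts length mismatch")
    rel = [(st, st + sz) for st, sz in zip(sts, szs)]
    span = rel[-1][1]
    origin = pos3 + 1 - span if strand3 == "+" else pos3
    return tuple((origin + s, origin + e) for s, e in rel)


def pairs_to_frame(pairs) -> pd.DataFrame:
    """Convert MatePairTag objects to the ENDPAIR v1 DataFrame layout."""
    rows = []
    for p in pairs:
        sizes, starts = _blocks_to_cols(p.end3.blocks, p.end3.pos)
        rows.append(
            (
                p.library_id,
                p.end5.chrom,
                p.end5.pos,
                p.end5.strand,
                p.end5.mapq,
                p.end3.chrom,
                p.end3.pos,
                p.end3.strand,
                p.end3.mapq,
                p.end3.end_kind,
                sizes,
                starts,
            )
        )
    return pd.DataFrame(rows, columns=ENDPAIR_COLUMNS).astype(_ENDPAIR_DTYPES)


def frame_to_pairs(df: pd.DataFrame) -> list[MatePairTag]:
    """Materialise ENDPAIR v1 rows as MatePairTag objects."""
    pairs = []
    for row in df.itertuples(index=False):
        blocks = _cols_to_blocks(
            row.blocks3_sizes, row.blocks3_starts, int(row.pos3), row.strand3
        )
        end5 = EndTag(
            chrom=row.chrom5,
            pos=int(row.pos5),
            strand=row.strand5,
            end_kind="TSS",
            mapq=int(row.mapq5),
            library_id=row.library_id,
        )
        end3 = EndTag(
            chrom=row.chrom3,
            pos=int(row.pos3),
            strand=row.strand3,
            end_kind=row.end3_kind,
            mapq=int(row.mapq3),
            library_id=row.library_id,
            blocks=blocks,
        )
        pairs.append(MatePairTag(end5=end5, end3=end3, library_id=row.library_id))
    return pairs


def read_tag_pairs(path, min_mapq: int = 10) -> tuple[list[MatePairTag], dict[str, LibraryStats]]:
    """Object-level ENDPAIR v1 reader (see :func:`read_tag_pair_table`)."""
    df, stats = read_tag_pair_table(path, min_mapq=min_mapq)
    return frame_to_pairs(df), stats


# ---------------------------------------------------------------------------
# junction signature classification
# ---------------------------------------------------------------------------


def detect_junction_signature(
    read_seq: str,
    polya_min_run: int = 10,
    max_start: int = 2,
) -> tuple[str, int | None]:
    """Classify a raw read by its adaptor-junction signature.

    CTGCTGCC at the junction marks an oligo-capped 5' end (TSS); CTGCTGGG
    marks the adaptor that follows the internal 3' end of a random-primed
    cDNA (RANDOM3P).  A leading poly(T) (reverse read of the tail) or
    poly(A) run of >= ``polya_min_run`` marks a PAS read.  Signatures must
    start within ``max_start`` bases of the read start (adaptor slippage
    allowance).  Returns (kind, offset of first cDNA base) or ("none", None).
    """
    seq = read_seq.upper()
    best = None
    for kind, sig in (("TSS", TSS_SIGNATURE), ("RANDOM3P", RANDOM3P_SIGNATURE)):
        idx = seq.find(sig)
        if 0 <= idx <= max_start and (best is None or idx < best[1]):
            best = (kind, idx)
    if best is not None:
        return best[0], best[1] + 8
    for base in ("T", "A"):
        run = 0
        while run < len(seq) and seq[run] == base:
            run += 1
        if run >= polya_min_run:
            return "PAS", run
    return "none", None


# ---------------------------------------------------------------------------
# small generic readers
# ---------------------------------------------------------------------------


def read_bed(path) -> list[tuple]:
    """Read BED3+ intervals as (chrom, start, end[, name, score, strand])."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                rec = (f[0], int(f[1]), int(f[2]), *f[3:6])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(rec)
    return out


def read_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA file fully into memory as {name: sequence}."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
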