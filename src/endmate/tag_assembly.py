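"""Genome-guided assembly of TSS/Random tags between a TSC and a PAC.

Each genomic coordinate of the region between the representative TSC and PAC
positions is labeled ``transcript`` when covered by at least one aligned tag
block, ``intron`` when spanned by the gap of at least one split tag, and
``unknown`` otherwise.  Direct coverage outranks a splice gap when both
apply.  The integrity of a model is the fraction of coordinates labeled
transcript or intron; the assembled length is the transcript-labeled total.
Assembling per TSC-PAC pair keeps alternative-promoter products separate by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_models import EndTag, GeneModel

__all__ = [
    "AssemblyModel",
    "assemble_region",
    "assembly_report",
    "size_fraction_distance_check",
    "models_to_bed12",
]

UNKNOWN, INTRON, TRANSCRIPT = 0, 1, 2


@dataclass
class AssemblyModel:
    tsc_id: str
    pac_id: str
    chrom: str
    strand: str
    region: tuple[int, int]  # genomic [start, end)
    labels: np.ndarray  # uint8 per coordinate: 0 unknown, 1 intron, 2 transcript
    exons: tuple[tuple[int, int], ...]
    integrity: float
    assembled_length: int


def _rep(x) -> int:
    return x.rep_pos if hasattr(x, "rep_pos") else int(x)


def assemble_region(tags: list[EndTag], tsc, pac, chrom: str | None = None,
                    strand: str | None = None,
                    region: tuple[int, int] | None = None) -> AssemblyModel:
    """Label the region between a TSC and a PAC from tag block evidence.

    ``tsc``/``pac`` are Clusters or bare representative positions; the region
    is the genomically oriented closed span between them (or an explicit
    half-open ``region`` override, which must be non-empty).  Tags without
    blocks contribute a single covered base at their position.
    """
    p5, p3 = _rep(tsc), _rep(pac)
    if region is not None:
        lo, hi = region
    else:
        lo, hi = (p5, p3 + 1) if p5 <= p3 else (p3, p5 + 1)
    if hi - lo <= 0:
        raise ValueError("empty assembly region")
    if chrom is None:
        chrom = tsc.chrom if hasattr(tsc, "chrom") else tags[0].chrom
    if strand is None:
        strand = tsc.strand if hasattr(tsc, "strand") else tags[0].strand

    n = hi - lo
    covered = np.zeros(n, dtype=bool)
    gapped = np.zeros(n, dtype=bool)
    for t in tags:
        if t.chrom != chrom or t.strand != strand:
            raise ValueError("tag off the assembly region's chromosome/strand")
        blocks = t.blocks if t.blocks else ((t.pos, t.pos + 1),)
        for s, e in blocks:
            s0, e0 = max(s, lo) - lo, min(e, hi) - lo
            if s0 < e0:
                covered[s0:e0] = True
        for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
            g0, g1 = max(e0, lo) - lo, min(s1, hi) - lo
            if g0 < g1:
                gapped[g0:g1] = True

    labels = np.zeros(n, dtype=np.uint8)
    labels[gapped] = INTRON
    labels[covered] = TRANSCRIPT  # direct coverage wins over a splice gap

    exons = _runs(labels == TRANSCRIPT, lo)
    integrity = float((labels != UNKNOWN).mean())
    return AssemblyModel(
        tsc_id=getattr(tsc, "cluster_id", str(p5)),
        pac_id=getattr(pac, "cluster_id", str(p3)),
        chrom=chrom, strand=strand, region=(lo, hi), labels=labels,
        exons=exons, integrity=integrity,
        assembled_length=int((labels == TRANSCRIPT).sum()),
    )


def _runs(mask: np.ndarray, offset: int) -> tuple[tuple[int, int], ...]:
    """Maximal True runs of a boolean mask as genomic intervals."""
    if not mask.any():
        return ()
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return tuple((int(s + offset), int(e + offset)) for s, e in zip(starts, ends))


def assembly_report(models: list[AssemblyModel], coverage_cut: float = 0.95) -> dict:
    """Summary of an assembly batch: success count (integrity strictly above
    the cut) and assembled-length distribution."""
    lengths = np.array([m.assembled_length for m in models], dtype=np.int64)
    n_ok = int(sum(1 for m in models if m.integrity > coverage_cut))
    return {
        "n_models": len(models),
        "n_assembled": n_ok,
        "coverage_cut": coverage_cut,
        "lengths": lengths,
        "mean_length": float(lengths.mean()) if len(lengths) else 0.0,
    }


def size_fraction_distance_check(pairs, genes: list[GeneModel], stats: dict):
    """mRNA-coordinate distances between TSS and 3' random tags, per fraction.

    ``pairs`` is an ENDPAIR frame (or MatePairTag list); only rows from dR
    libraries (per ``stats`` fraction labels) with both ends exonic in one
    gene model are measured; others are skipped and counted.  Distances are
    measured along the mature mRNA, i.e. with introns excised.
    """
    if hasattr(pairs, "columns"):
        it = pairs.itertuples(index=False)
        rows = [
            (r.library_id, r.chrom5, int(r.pos5), r.strand5, int(r.pos3))
            for r in it
        ]
    else:
        rows = [
            (p.library_id, p.end5.chrom, p.end5.pos, p.end5.strand, p.end3.pos)
            for p in pairs
        ]
    by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_loc.setdefault((g.chrom, g.strand), []).append(g)
    dists: dict[str, list[int]] = {}
    skipped = 0
    for lib, chrom, pos5, strand, pos3 in rows:
        st = stats.get(lib)
        if st is None or not st.fraction_label.startswith("dR"):
            continue
        found = None
        for g in by_loc.get((chrom, strand), []):
            if not (g.tx_start <= pos5 < g.tx_end and g.tx_start <= pos3 < g.tx_end):
                continue
            m5 = g.genome_to_mrna(pos5)
            m3 = g.genome_to_mrna(pos3)
            if m5 is not None and m3 is not None:
                found = abs(m3 - m5)
                break
        if found is None:
            skipped += 1
        else:
            dists.setdefault(st.fraction_label, []).append(found)
    return {k: np.array(v, dtype=np.int64) for k, v in dists.items()}, skipped


def models_to_bed12(models: list[AssemblyModel], path) -> None:
    """Write assembly models as BED12 (blocks = transcript-labeled exons)."""
    with open(path, "w") as fh:
        for m in models:
            lo, hi = m.region
            exons = m.exons or ((lo, lo + 1),)
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - lo) for s, e in exons)
            name = f"{m.tsc_id}|{m.pac_id}"
            fh.write(
                "\t".join(
                    [m.chrom, str(lo), str(hi), name, str(int(1000 * m.integrity)),
                     m.strand, str(lo), str(hi), "0", str(len(exons)), sizes, starts]
                )
                + "\n"
            )
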