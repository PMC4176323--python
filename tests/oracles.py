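"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the library's code paths: probabilities are
computed by direct term-wise summation, interval work by all-pairs loops,
and grouping by plain dictionaries.
"""

from __future__ import annotations

import math
import re
from fractions import Fraction


def poisson_sf_oracle(k: int, lam: float) -> float:
    """P(X >= k | Poisson(lam)) by direct upper-tail summation.

    Terms are accumulated with fsum from the k-th term upward until they
    fall below 1e-18 of the running sum, giving ~1e-12 relative accuracy
    without subtractive cancellation.
    """
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    # first term: lam^k e^-lam / k! in log space to avoid overflow
    log_t = k * math.log(lam) - lam - math.lgamma(k + 1)
    t = math.exp(log_t)
    terms = []
    i = k
    while True:
        terms.append(t)
        i += 1
        t *= lam / i
        if t < 1e-18 * (sum(terms[-3:]) + t) and i > lam + k:
            terms.append(t)
            break
        if i > k + 10_000:
            break
    return min(1.0, math.fsum(terms))


def hypergeom_sf_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric(N, K, n), exact rational arithmetic."""
    if k <= 0:
        return 1.0
    denom = math.comb(N, n)
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)


def group_cluster_oracle(tags, w):
    """Dictionary grouping of (chrom, strand, pos//w) -> per-lib counts, rep pos."""
    groups = {}
    for chrom, pos, strand, lib in tags:
        key = (chrom, strand, pos // w)
        g = groups.setdefault(key, {"counts": {}, "positions": {}})
        g["counts"][lib] = g["counts"].get(lib, 0) + 1
        g["positions"][pos] = g["positions"].get(pos, 0) + 1
    out = {}
    for key, g in groups.items():
        best = min(g["positions"].items(), key=lambda kv: (-kv[1], kv[0]))[0]
        out[key] = (g["counts"], best)
    return out


def classify_oracle(chrom, pos, strand, genes, max_dist=50_000):
    """Per-tag positional category by looping over every gene."""
    order = ["first_exon", "last_exon", "internal_exon", "intron",
             "upstream_50kb", "downstream_50kb"]
    found = set()
    for g in genes:
        if g.chrom != chrom or g.strand != strand:
            continue
        plus = g.strand == "+"
        exons = list(g.exons)
        first = exons[0] if plus else exons[-1]
        last = exons[-1] if plus else exons[0]
        if first[0] <= pos < first[1]:
            found.add("first_exon")
        elif last[0] <= pos < last[1]:
            found.add("last_exon")
        elif any(s <= pos < e for s, e in exons if (s, e) not in (first, last)):
            found.add("internal_exon")
        elif any(e0 <= pos < s1 for (s0, e0), (s1, e1) in zip(exons, exons[1:])):
            found.add("intron")
        if plus:
            if g.tx_start - max_dist <= pos < g.tx_start:
                found.add("upstream_50kb")
            if g.tx_end <= pos < g.tx_end + max_dist:
                found.add("downstream_50kb")
        else:
            if g.tx_end <= pos < g.tx_end + max_dist:
                found.add("upstream_50kb")
            if g.tx_start - max_dist <= pos < g.tx_start:
                found.add("downstream_50kb")
    for cat in order:
        if cat in found:
            return cat
    return "intergenic"


_RC = str.maketrans("ACGT", "TGCA")


def sense_window_oracle(seq: str, strand: str, rep_pos: int, rel0: int, rel1: int) -> str:
    """Transcript-strand window sequence by explicit slicing + revcomp."""
    if strand == "+":
        lo, hi = rep_pos + rel0, rep_pos + rel1
        lo, hi = max(0, lo), min(len(seq), hi)
        return seq[lo:hi]
    lo, hi = rep_pos - rel1 + 1, rep_pos - rel0 + 1
    lo, hi = max(0, lo), min(len(seq), hi)
    return seq[lo:hi].translate(_RC)[::-1]


def motif_present_oracle(window_seq: str, pattern: str) -> bool:
    return re.search(pattern, window_seq) is not None


def coverage_fraction_oracle(set_a, set_b, slop=0):
    """Fraction of A clusters overlapped by any B cluster (all-pairs loop)."""
    n = 0
    for a in set_a:
        hit = any(
            a.chrom == b.chrom
            and a.strand == b.strand
            and a.start - slop < b.end
            and b.start < a.end + slop
            for b in set_b
        )
        n += hit
    return n / len(set_a)


def jaccard_oracle(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union


def crosstab_oracle(rows, tsc_ids, pac_ids):
    """Brute-force cross-tabulation of (tsc_id, pac_id) observations."""
    o = {(t, p): 0 for t in tsc_ids for p in pac_ids}
    for t, p in rows:
        if (t, p) in o:
            o[(t, p)] += 1
    return o


def integrity_oracle(blocks_per_tag, region):
    """Per-coordinate labeling by explicit loops over every coordinate."""
    lo, hi = region
    labels = {}
    for blocks in blocks_per_tag:
        for s, e in blocks:
            for x in range(max(s, lo), min(e, hi)):
                labels[x] = "transcript"
        for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
            for x in range(max(e0, lo), min(s1, hi)):
                if labels.get(x) != "transcript":
                    labels[x] = "intron"
    n = hi - lo
    n_labeled = sum(1 for x in range(lo, hi) if x in labels)
    n_tx = sum(1 for x in range(lo, hi) if labels.get(x) == "transcript")
    return n_labeled / n, n_tx
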