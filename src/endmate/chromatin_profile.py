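"""ChIP fold-density tracks, metagene profiles and peak frequencies.

The IP and input coverages (bedGraph) are binned, normalised to their totals
and combined as fold = (ip_norm + eps) / (input_norm + eps).  Metaprofiles
either rescale each TSC-PAC region onto a fixed number of bins ("scaled") or
center a fixed bp flank on given positions ("centered"); minus-strand
regions are mirrored so profiles read 5'->3'.  Peak calling itself is out of
scope: peaks arrive as BED intervals from an upstream caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FoldDensityTrack",
    "MetaProfile",
    "read_bedgraph",
    "fold_density",
    "center_on_max",
    "metaprofile",
    "peak_frequency_between_units",
]

DEFAULT_BIN = 50
DEFAULT_EPS = 1e-9


@dataclass
class FoldDensityTrack:
    bin_size: int
    values: dict  # chrom -> np.ndarray of per-bin fold

    def region_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Fold values of the bins overlapping [start, end)."""
        v = self.values.get(chrom)
        if v is None:
            return np.array([])
        b0 = max(0, start // self.bin_size)
        b1 = min(len(v), -(-end // self.bin_size))
        return v[b0:b1]


@dataclass
class MetaProfile:
    mode: str  # centered | scaled
    n_regions: int
    bins: np.ndarray  # bin centers: relative bp (centered) or [0,1) fractions
    mean: np.ndarray


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="t", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return df


def _binned_mass(cov: pd.DataFrame, bin_size: int, sizes: dict[str, int]) -> dict:
    """Per-bin signal mass (value x overlap bp) for each chromosome."""
    out = {
        chrom: np.zeros(-(-length // bin_size)) for chrom, length in sizes.items()
    }
    for row in cov.itertuples(index=False):
        arr = out[row.chrom]
        b0 = row.start // bin_size
        b1 = -(-row.end // bin_size)
        for b in range(b0, b1):
            lo = max(row.start, b * bin_size)
            hi = min(row.end, (b + 1) * bin_size)
            arr[b] += row.value * (hi - lo)
    return out


def fold_density(ip_cov, input_cov, bin_size: int = DEFAULT_BIN,
                 pseudocount: float = DEFAULT_EPS,
                 chrom_sizes: dict[str, int] | None = None) -> FoldDensityTrack:
    """Normalised IP / input fold per genomic bin.

    Both coverages are bedGraph frames (or paths).  Each bin's mass is
    divided by the track total; fold = (ip + eps) / (input + eps), so bins
    with empty input stay finite.  Scaling all IP values by a constant
    leaves the folds unchanged.
    """
    if not hasattr(ip_cov, "columns"):
        ip_cov = read_bedgraph(ip_cov)
    if not hasattr(input_cov, "columns"):
        input_cov = read_bedgraph(input_cov)
    if chrom_sizes is None:
        chrom_sizes = {}
        for df in (ip_cov, input_cov):
            for chrom, end in df.groupby("chrom")["end"].max().items():
                chrom_sizes[chrom] = max(chrom_sizes.get(chrom, 0), int(end))
    ip = _binned_mass(ip_cov, bin_size, chrom_sizes)
    inp = _binned_mass(input_cov, bin_size, chrom_sizes)
    ip_total = sum(a.sum() for a in ip.values())
    in_total = sum(a.sum() for a in inp.values())
    if ip_total <= 0 or in_total <= 0:
        raise ValueError("zero total coverage in IP or input")
    values = {
        chrom: (ip[chrom] / ip_total + pseudocount)
        / (inp[chrom] / in_total + pseudocount)
        for chrom in chrom_sizes
    }
    return FoldDensityTrack(bin_size=bin_size, values=values)


def center_on_max(track: FoldDensityTrack, region: tuple[str, int, int]) -> int:
    """Genomic coordinate (bin start) of the largest fold density in a region;
    ties break toward the smallest coordinate."""
    chrom, start, end = region
    v = track.values.get(chrom)
    if v is None:
        raise ValueError(f"no track bins on {chrom}")
    b0 = max(0, start // track.bin_size)
    b1 = min(len(v), -(-end // track.bin_size))
    if b1 <= b0:
        raise ValueError("no defined bins in region")
    sub = v[b0:b1]
    return int((b0 + int(np.argmax(sub))) * track.bin_size)


def _scaled_profile(track: FoldDensityTrack, chrom: str, start: int, end: int,
                    n_bins: int) -> np.ndarray | None:
    v = track.values.get(chrom)
    length = end - start
    if v is None or length < n_bins:
        return None
    w = track.bin_size
    edges = start + np.arange(n_bins + 1) * (length / n_bins)
    out = np.empty(n_bins)
    for i in range(n_bins):
        a, b = edges[i], edges[i + 1]
        b0, b1 = int(a // w), int(np.ceil(b / w))
        acc = 0.0
        for bb in range(b0, b1):
            lo, hi = max(a, bb * w), min(b, (bb + 1) * w)
            if hi > lo:
                val = v[bb] if 0 <= bb < len(v) else 0.0
                acc += val * (hi - lo)
        out[i] = acc / (b - a)
    return out


def metaprofile(track: FoldDensityTrack, regions, mode: str = "scaled",
                n_bins: int = 100, flank_bp: int = 5000) -> MetaProfile:
    """Average fold profile over regions.

    scaled mode: ``regions`` are (chrom, start, end, strand); each is
    resampled onto ``n_bins`` equal sub-intervals by length-weighted
    averaging of overlapping track bins.  centered mode: ``regions`` are
    (chrom, pos, strand) anchor points profiled over +/- ``flank_bp``.
    Minus-strand regions are flipped; regions shorter than one profile bin
    (or anchors without track) are skipped and not counted.
    """
    if not regions:
        raise ValueError("need at least one region")
    profiles = []
    if mode == "scaled":
        for chrom, start, end, strand in regions:
            prof = _scaled_profile(track, chrom, start, end, n_bins)
            if prof is None:
                continue
            profiles.append(prof[::-1] if strand == "-" else prof)
        bins = (np.arange(n_bins) + 0.5) / n_bins
    elif mode == "centered":
        w = track.bin_size
        k = flank_bp // w
        offsets = np.arange(-k, k + 1)
        for chrom, pos, strand in regions:
            v = track.values.get(chrom)
            if v is None:
                continue
            center_bin = pos // w
            idx = center_bin + offsets
            ok = (idx >= 0) & (idx < len(v))
            prof = np.zeros(len(offsets))
            prof[ok] = v[idx[ok]]
            profiles.append(prof[::-1] if strand == "-" else prof)
        bins = offsets * w
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not profiles:
        raise ValueError("no usable regions")
    return MetaProfile(
        mode=mode, n_regions=len(profiles), bins=bins,
        mean=np.mean(np.vstack(profiles), axis=0),
    )


def peak_frequency_between_units(peaks, separating_regions,
                                 control_regions=None) -> dict:
    """Fraction of regions containing >= 1 peak, plus per-region densities.

    ``peaks`` are BED records (chrom, start, end, ...); regions are (chrom,
    start, end).  Density is peaks per kb of the region.  The same summary
    is computed for an optional control region set (e.g. other introns of
    the same genes) for downstream comparison.
    """
    by_chrom: dict[str, list] = {}
    for rec in peaks:
        by_chrom.setdefault(rec[0], []).append((rec[1], rec[2]))

    def summarise(regions):
        if not regions:
            raise ValueError("regions must be non-empty")
        hits = 0
        dens = []
        for chrom, start, end in regions:
            n = sum(
                1 for s, e in by_chrom.get(chrom, ()) if s < end and start < e
            )
            hits += n > 0
            dens.append(n / ((end - start) / 1000.0))
        return {
            "frequency": hits / len(regions),
            "densities": np.array(dens),
        }

    out = {"separating": summarise(separating_regions)}
    if control_regions is not None:
        out["control"] = summarise(control_regions)
    return out
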