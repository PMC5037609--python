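"""Fragment coverage, input-normalized enrichment, and metapeak profiles.

Reads are extended to fragments directionally, piled into per-chromosome
depth arrays, and compared IP-vs-input after normalizing each track by its
read count and fragment size. Enrichment values are unitless fold changes;
a track compared against itself is identically 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval, ValidationError


@dataclass
class CoverageTrack:
    """Per-chromosome fragment-overlap depth for one sample."""

    depth: Dict[str, np.ndarray]
    total_fragments: int
    fragment_length: int
    chrom_sizes: Dict[str, int] = field(default_factory=dict)

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def normalized(self, chrom: str) -> np.ndarray:
        """Depth scaled to mean 1 over the genome: d * G / (N * L).

        Dividing two normalized tracks yields the read-count- and
        fragment-size-normalized fold change.
        """
        scale = self.genome_length / (self.total_fragments * self.fragment_length)
        return self.depth[chrom] * scale

    def rpm(self, chrom: str) -> np.ndarray:
        """Depth in reads (fragments) per million."""
        return self.depth[chrom] * (1e6 / self.total_fragments)


def extend_reads(
    reads: pd.DataFrame, fragment_length: int, chrom_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Extend aligned reads to ``fragment_length`` in the 3' direction.

    ``+`` strand read [s, e) becomes [s, s+L); ``-`` strand read becomes
    [e-L, e); fragments are clipped to chromosome bounds.
    """
    if fragment_length <= 0:
        raise ValueError(f"fragment_length must be positive, got {fragment_length}")
    plus = reads["strand"].to_numpy() == "+"
    start = reads["start"].to_numpy(dtype=np.int64)
    end = reads["end"].to_numpy(dtype=np.int64)
    fs = np.where(plus, start, end - fragment_length)
    fe = np.where(plus, start + fragment_length, end)
    sizes = reads["chrom"].map(dict(chrom_sizes)).to_numpy()
    if np.any(pd.isna(sizes)):
        missing = sorted(set(reads["chrom"][pd.isna(sizes)]))
        raise ValidationError(f"reads on unknown chromosomes: {missing}")
    fs = np.maximum(fs, 0)
    fe = np.minimum(fe, sizes.astype(np.int64))
    return pd.DataFrame(
        {"chrom": reads["chrom"].to_numpy(), "start": fs, "end": fe}
    )


def coverage_from_fragments(
    fragments: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    fragment_length: int,
) -> CoverageTrack:
    """Pile fragments into per-base overlap depth."""
    depth: Dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        diff = np.zeros(size + 1, dtype=np.int64)
        sub = fragments[fragments["chrom"] == chrom]
        if len(sub):
            np.add.at(diff, sub["start"].to_numpy(), 1)
            np.add.at(diff, sub["end"].to_numpy(), -1)
        depth[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(
        depth=depth,
        total_fragments=len(fragments),
        fragment_length=fragment_length,
        chrom_sizes=dict(chrom_sizes),
    )


def coverage_from_reads(
    reads: pd.DataFrame, fragment_length: int, chrom_sizes: Mapping[str, int]
) -> CoverageTrack:
    return coverage_from_fragments(
        extend_reads(reads, fragment_length, chrom_sizes), chrom_sizes, fragment_length
    )


def estimate_fragment_length(
    reads: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    min_shift: int = 50,
    max_shift: int = 500,
) -> int:
    """Estimate the sequenced fragment size by strand cross-correlation.

    Returns the shift in [min_shift, max_shift] maximizing the correlation
    between + strand 5' read-start counts and - strand 5' read-end counts.
    Requires >= 1000 reads on each strand; supply the fragment length
    explicitly for sparse samples.
    """
    plus = reads[reads["strand"] == "+"]
    minus = reads[reads["strand"] == "-"]
    if len(plus) < 1000 or len(minus) < 1000:
        raise ValidationError(
            "too few reads per strand for cross-correlation "
            f"({len(plus)} +, {len(minus)} -); pass fragment_length explicitly"
        )
    shifts = np.arange(min_shift, max_shift + 1)
    cc = np.zeros(len(shifts))
    for chrom, size in chrom_sizes.items():
        p = plus[plus["chrom"] == chrom]["start"].to_numpy()
        m = minus[minus["chrom"] == chrom]["end"].to_numpy() - 1
        if len(p) == 0 or len(m) == 0:
            continue
        pc = np.bincount(p, minlength=size).astype(np.float64)
        mc = np.bincount(m, minlength=size).astype(np.float64)
        for i, d in enumerate(shifts):
            cc[i] += pc[: size - d] @ mc[d:]
    return int(shifts[int(np.argmax(cc))])


class EnrichmentTrack:
    """Lazy IP-over-input fold-change values.

    Both tracks are scaled to genome-mean 1 (depth * G / (N * L)) so the
    ratio is the read-count and fragment-size normalized fold change. The
    pseudocount ``eps`` (same normalized scale) keeps zero-input bases
    finite; with ``eps=0`` such bases are NaN, never infinity. The default
    is a quarter-fragment depth floor: 0.25 * G / (N_in * L_in).
    """

    def __init__(
        self,
        ip: CoverageTrack,
        input_track: CoverageTrack,
        pseudocount: Optional[float] = None,
    ):
        if set(ip.chrom_sizes) != set(input_track.chrom_sizes) or any(
            ip.chrom_sizes[c] != input_track.chrom_sizes[c] for c in ip.chrom_sizes
        ):
            raise ValidationError("IP and input tracks cover different chromosomes")
        self.ip = ip
        self.input = input_track
        if pseudocount is None:
            pseudocount = (
                0.25
                * input_track.genome_length
                / (input_track.total_fragments * input_track.fragment_length)
            )
        self.eps = float(pseudocount)

    def values(self, chrom: str, start: int = 0, end: Optional[int] = None) -> np.ndarray:
        """Per-base enrichment over [start, end) of ``chrom``."""
        if end is None:
            end = self.ip.chrom_sizes[chrom]
        ip_scale = self.ip.genome_length / (
            self.ip.total_fragments * self.ip.fragment_length
        )
        in_scale = self.input.genome_length / (
            self.input.total_fragments * self.input.fragment_length
        )
        num = self.ip.depth[chrom][start:end] * ip_scale + self.eps
        den = self.input.depth[chrom][start:end] * in_scale + self.eps
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        out[den == 0] = np.nan  # eps=0 and zero input: undefined, not inf
        return out

    def write_bedgraph(self, path, chroms: Optional[Sequence[str]] = None) -> None:
        """Export per-base enrichment as bedGraph (run-length encoded)."""
        with open(str(path), "w") as fh:
            for chrom in chroms or sorted(self.ip.chrom_sizes):
                vals = self.values(chrom)
                change = np.flatnonzero(np.diff(vals) != 0) + 1
                starts = np.r_[0, change]
                ends = np.r_[change, len(vals)]
                for s, e in zip(starts, ends):
                    v = vals[s]
                    if np.isfinite(v):
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")

    def window_fold(self, interval: GenomicInterval) -> float:
        """Normalized IP over normalized input summed across a window."""
        chrom, s, e = interval.chrom, interval.start, interval.end
        ip_scale = self.ip.genome_length / (
            self.ip.total_fragments * self.ip.fragment_length
        )
        in_scale = self.input.genome_length / (
            self.input.total_fragments * self.input.fragment_length
        )
        num = float(self.ip.depth[chrom][s:e].sum()) * ip_scale + self.eps * (e - s)
        den = float(self.input.depth[chrom][s:e].sum()) * in_scale + self.eps * (e - s)
        if den == 0:
            return float("nan")
        return num / den


def enrichment_over_input(
    ip: CoverageTrack, input_track: CoverageTrack, pseudocount: Optional[float] = None
) -> EnrichmentTrack:
    return EnrichmentTrack(ip, input_track, pseudocount)


@dataclass
class MetapeakProfile:
    """Average signal around summits: offsets -flank..flank."""

    offsets: np.ndarray
    values: np.ndarray
    smooth_bp: int
    n_summits: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.values})


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available span."""
    half = width // 2
    csum = np.cumsum(np.r_[0.0, x])
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def metapeak(
    source,
    summits: Sequence,
    flank: int,
    smooth_bp: int = 31,
    mode: str = "enrichment",
) -> MetapeakProfile:
    """Average per-base signal at each offset relative to a set of summits.

    ``source`` is an :class:`EnrichmentTrack` (mode="enrichment") or a
    :class:`CoverageTrack` (mode="rpm", unsmoothed per convention).
    ``summits`` is a sequence of (chrom, position) pairs; summits closer
    than ``flank`` to a chromosome edge are excluded.
    """
    if not len(summits):
        raise ValidationError("metapeak requires at least one summit")
    if mode not in ("enrichment", "rpm"):
        raise ValueError(f"unknown metapeak mode {mode!r}")
    if mode == "enrichment" and flank < smooth_bp:
        raise ValueError("flank must be >= smooth_bp")
    sizes = source.ip.chrom_sizes if mode == "enrichment" else source.chrom_sizes
    acc = np.zeros(2 * flank + 1)
    n_used = 0
    cache: Dict[str, np.ndarray] = {}
    for chrom, pos in summits:
        if pos - flank < 0 or pos + flank + 1 > sizes[chrom]:
            continue
        if chrom not in cache:
            if mode == "enrichment":
                cache[chrom] = source.values(chrom)
            else:
                cache[chrom] = source.rpm(chrom)
        acc += cache[chrom][pos - flank : pos + flank + 1]
        n_used += 1
    if n_used == 0:
        raise ValidationError("all summits were too close to chromosome edges")
    mean = acc / n_used
    if mode == "enrichment" and smooth_bp > 1:
        mean = _moving_average(mean, smooth_bp)
    return MetapeakProfile(
        offsets=np.arange(-flank, flank + 1),
        values=mean,
        smooth_bp=smooth_bp if mode == "enrichment" else 0,
        n_summits=n_used,
    )
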