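"""Standardize candidate peaks into fixed cores and counting windows.

Candidate enhancer positions come from co-factor (CBP) or accessibility
(ATAC) peak calls. Each retained peak is reduced to its summit, around
which a 201-bp core (the putative enhancer) and a 1-kb counting window
(for differential histone-acetylation testing) are placed. Candidates are
classified by gene context: TSS-proximal, intragenic, or intergenic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .core import GeneModel, GenomicInterval, PeakRecord, ValidationError

LOCATION_CLASSES = ("TSS", "intragenic", "intergenic")


@dataclass(frozen=True)
class CandidateRegion:
    """A summit-centered candidate enhancer.

    core
        201-bp putative enhancer interval, summit +/- 100.
    window
        1-kb counting window [summit-500, summit+500).
    """

    id: str
    chrom: str
    summit: int
    core: GenomicInterval
    window: GenomicInterval
    source_enrichment: float
    location_class: Optional[str] = None


def standardize_peaks(
    peaks: Sequence[PeakRecord],
    chrom_sizes: Mapping[str, int],
    min_fold: float = 2.0,
    core_width: int = 201,
    window_width: int = 1000,
    summit_fallback_midpoint: bool = False,
) -> List[CandidateRegion]:
    """Resize peaks to summit-centered cores, dropping weak peaks.

    Peaks with enrichment below ``min_fold`` (default twofold over input)
    are excluded. Cores extend summit-floor((w-1)/2) .. summit+ceil((w-1)/2),
    so an odd ``core_width`` is exactly summit-centered; the even-width tie
    breaks toward the left. Candidates whose window would run off a
    chromosome edge are dropped with a warning. IDs are assigned
    deterministically from the sorted (chrom, summit) order.
    """
    half_lo = (core_width - 1) // 2
    half_hi = core_width - 1 - half_lo
    w_lo = window_width // 2
    w_hi = window_width - w_lo
    seen = set()
    kept = []
    n_clipped = 0
    for peak in peaks:
        if peak.summit is None:
            if summit_fallback_midpoint:
                summit = peak.interval.midpoint()
            else:
                raise ValidationError(
                    f"peak {peak.name} has no summit; pass "
                    "summit_fallback_midpoint=True to use the midpoint"
                )
        else:
            summit = peak.summit
        enr = peak.enrichment if peak.enrichment is not None else peak.score
        if enr is None or enr < min_fold:
            continue
        chrom = peak.interval.chrom
        if (chrom, summit) in seen:
            continue
        size = chrom_sizes[chrom]
        if summit - w_lo < 0 or summit + w_hi > size:
            n_clipped += 1
            continue
        seen.add((chrom, summit))
        kept.append((chrom, summit, float(enr)))
    if n_clipped:
        warnings.warn(
            f"dropped {n_clipped} candidate(s) whose window crossed a "
            "chromosome edge"
        )
    kept.sort(key=lambda t: (t[0], t[1]))
    out = []
    for i, (chrom, summit, enr) in enumerate(kept, start=1):
        out.append(
            CandidateRegion(
                id=f"cand_{i:05d}",
                chrom=chrom,
                summit=summit,
                core=GenomicInterval(chrom, summit - half_lo, summit + half_hi + 1),
                window=GenomicInterval(chrom, summit - w_lo, summit + w_hi),
                source_enrichment=enr,
            )
        )
    return out


def _tss_by_chrom(genes: Sequence[GeneModel]) -> Dict[str, np.ndarray]:
    out: Dict[str, List[int]] = {}
    for g in genes:
        out.setdefault(g.span.chrom, []).append(g.tss)
    return {c: np.sort(np.asarray(v)) for c, v in out.items()}


def min_tss_distance(chrom: str, pos: int, tss_index: Mapping[str, np.ndarray]) -> float:
    """Distance from ``pos`` to the nearest TSS on ``chrom`` (inf if none)."""
    tss = tss_index.get(chrom)
    if tss is None or len(tss) == 0:
        return float("inf")
    i = np.searchsorted(tss, pos)
    best = float("inf")
    if i < len(tss):
        best = min(best, abs(int(tss[i]) - pos))
    if i > 0:
        best = min(best, abs(int(tss[i - 1]) - pos))
    return best


def classify_location(
    region: CandidateRegion,
    genes: Sequence[GeneModel],
    tss_distance: int = 1000,
    _tss_index: Optional[Mapping[str, np.ndarray]] = None,
) -> str:
    """Classify a candidate by its summit's gene context.

    TSS if the summit is < ``tss_distance`` bp from any annotated TSS;
    else intragenic if the summit lies inside any gene span; else
    intergenic.
    """
    tss_index = _tss_index if _tss_index is not None else _tss_by_chrom(genes)
    if min_tss_distance(region.chrom, region.summit, tss_index) < tss_distance:
        return "TSS"
    for g in genes:
        if (
            g.span.chrom == region.chrom
            and g.span.start <= region.summit < g.span.end
        ):
            return "intragenic"
    return "intergenic"


def classify_all(
    regions: Sequence[CandidateRegion],
    genes: Sequence[GeneModel],
    tss_distance: int = 1000,
) -> List[CandidateRegion]:
    """Classify every candidate; returns new records with location_class set."""
    if not genes:
        warnings.warn("no gene models supplied; all candidates are intergenic")
    tss_index = _tss_by_chrom(genes)
    # gene spans per chromosome as sorted arrays for the intragenic test
    spans: Dict[str, List] = {}
    for g in genes:
        spans.setdefault(g.span.chrom, []).append((g.span.start, g.span.end))
    span_arr = {
        c: (np.array([s for s, _ in sorted(v)]), np.array([e for _, e in sorted(v)]))
        for c, v in spans.items()
    }
    out = []
    for r in regions:
        if min_tss_distance(r.chrom, r.summit, tss_index) < tss_distance:
            cls = "TSS"
        else:
            cls = "intergenic"
            if r.chrom in span_arr:
                starts, ends = span_arr[r.chrom]
                inside = (starts <= r.summit) & (r.summit < ends)
                if inside.any():
                    cls = "intragenic"
        out.append(
            CandidateRegion(
                id=r.id,
                chrom=r.chrom,
                summit=r.summit,
                core=r.core,
                window=r.window,
                source_enrichment=r.source_enrichment,
                location_class=cls,
            )
        )
    return out


def sample_random_non_tss(
    chrom_sizes: Mapping[str, int],
    genes: Sequence[GeneModel],
    n: int = 5000,
    width: int = 201,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    tss_distance: int = 1000,
) -> List[GenomicInterval]:
    """Sample ``n`` uniform random regions of ``width`` bp whose midpoints
    are at least ``tss_distance`` bp from every annotated TSS.

    The null set for conservation comparisons. Reproducible under a fixed
    seed; errors out if the annotation is so dense that >99% of draws are
    rejected.
    """
    for chrom, size in chrom_sizes.items():
        if width >= size:
            raise ValidationError(
                f"width {width} >= chromosome {chrom} length {size}"
            )
    if rng is None:
        rng = np.random.default_rng(seed)
    tss_index = _tss_by_chrom(genes)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] - width for c in chroms], dtype=float)
    weights /= weights.sum()
    out: List[GenomicInterval] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n and len(out) < attempts / 100:
            raise ValidationError(
                "rejection rate above 99%: TSS annotation too dense for "
                f"non-TSS sampling at width {width}"
            )
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(0, chrom_sizes[chrom] - width))
        mid = start + width // 2
        if min_tss_distance(chrom, mid, tss_index) < tss_distance:
            continue
        out.append(GenomicInterval(chrom, start, start + width))
    return out
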