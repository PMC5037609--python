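"""Evolutionary conservation of enhancers and their motif instances.

Per-base conservation probabilities (phastCons-style, in [0, 1]) are
averaged over intervals; motif instances inside each enhancer are
compared against the surrounding 201-bp core with a paired Wilcoxon
signed-rank test, and enhancer cores are compared against random non-TSS
regions with an unpaired rank-sum test. Both tests are one-sided in the
"more conserved" direction, which is the claim under test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import GenomicInterval, ValidationError
from .motifs import MotifHit

EXACT_N_MAX = 25  # exact Wilcoxon null up to here (no ties), normal beyond


@dataclass
class ConservationComparison:
    group_labels: Tuple[str, str]
    values_a: np.ndarray
    values_b: np.ndarray
    test_type: str  # "paired_signed_rank" | "unpaired_rank_sum"
    p: float
    n_pairs: Optional[int] = None

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.values_a)) if len(self.values_a) else float("nan")

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.values_b)) if len(self.values_b) else float("nan")


def mean_score(
    track: Mapping[str, np.ndarray], interval: GenomicInterval
) -> Tuple[float, float]:
    """Mean conservation over an interval, excluding undefined (NaN) bases.

    Returns (mean, defined_fraction); mean is NaN when no base is defined.
    """
    arr = track.get(interval.chrom)
    if arr is None:
        return float("nan"), 0.0
    sl = arr[interval.start : min(interval.end, len(arr))]
    pad = interval.width - len(sl)
    defined = np.isfinite(sl)
    n_def = int(defined.sum())
    coverage = n_def / interval.width if interval.width else 0.0
    if n_def == 0:
        return float("nan"), 0.0
    return float(sl[defined].mean()), coverage


def _mean_over_bases(track, chrom: str, base_intervals: List[Tuple[int, int]]) -> float:
    """Pooled mean over the union-multiset of bases of several intervals
    (multiple motif instances in one enhancer are pooled before
    averaging)."""
    vals = []
    arr = track.get(chrom)
    if arr is None:
        return float("nan")
    for s, e in base_intervals:
        sl = arr[s : min(e, len(arr))]
        vals.append(sl[np.isfinite(sl)])
    if not vals:
        return float("nan")
    pooled = np.concatenate(vals)
    return float(pooled.mean()) if len(pooled) else float("nan")


def signed_rank_greater(diffs: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank p (median difference > 0).

    Zero differences are dropped (Wilcoxon convention); exact null for
    n <= EXACT_N_MAX without ties, normal approximation with tie and
    continuity correction otherwise. NaN for n = 0.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan")
    method = "exact" if (n <= EXACT_N_MAX and len(np.unique(np.abs(d))) == n) else "approx"
    res = stats.wilcoxon(d, alternative="greater", method=method)
    return float(res.pvalue)


def rank_sum_greater(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided rank-sum p that values in ``a`` exceed those in ``b``.

    Exact for small groups without ties, normal with tie/midrank
    correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("empty group in rank-sum test")
    combined = np.concatenate([a, b])
    if len(np.unique(combined)) == 1:
        return 0.5  # all values identical: no evidence either way
    # exact null when the groups share no values (cross-group ties would
    # invalidate the tie-free rank distribution); normal approximation
    # with midrank tie correction otherwise
    no_cross_ties = np.intersect1d(a, b).size == 0
    if no_cross_ties and len(a) <= EXACT_N_MAX and len(b) <= EXACT_N_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.pvalue)


def motif_vs_enhancer_conservation(
    enhancers: Sequence,  # CandidateRegion-like with .id, .chrom, .core
    hits: Sequence[MotifHit],
    motif_length: int,
    track: Mapping[str, np.ndarray],
    min_pairs: int = 5,
) -> ConservationComparison:
    """Paired comparison: per enhancer, the pooled mean conservation of its
    motif instances vs the mean over its whole core.

    One-sided signed-rank (motifs more conserved). Enhancers without a
    hit are excluded; fewer than ``min_pairs`` informative pairs yields a
    NaN p, flagged via n_pairs.
    """
    hits_by_region: Dict[str, List[MotifHit]] = {}
    for h in hits:
        hits_by_region.setdefault(h.region_id, []).append(h)
    motif_means, core_means = [], []
    for enh in enhancers:
        rhits = hits_by_region.get(enh.id)
        if not rhits:
            continue
        intervals = [
            (enh.core.start + h.offset, enh.core.start + h.offset + motif_length)
            for h in rhits
        ]
        m = _mean_over_bases(track, enh.chrom, intervals)
        c, _ = mean_score(track, enh.core)
        if np.isfinite(m) and np.isfinite(c):
            motif_means.append(m)
            core_means.append(c)
    motif_means = np.asarray(motif_means)
    core_means = np.asarray(core_means)
    diffs = motif_means - core_means
    informative = int((diffs != 0).sum())
    p = signed_rank_greater(diffs) if informative >= min_pairs else float("nan")
    return ConservationComparison(
        group_labels=("motif_instances", "enhancer_cores"),
        values_a=motif_means,
        values_b=core_means,
        test_type="paired_signed_rank",
        p=p,
        n_pairs=informative,
    )


def enhancers_vs_random_conservation(
    enhancer_cores: Sequence[GenomicInterval],
    random_regions: Sequence[GenomicInterval],
    track: Mapping[str, np.ndarray],
) -> ConservationComparison:
    """Unpaired comparison of mean conservation: enhancer cores vs random
    non-TSS regions of equal width (one-sided, enhancers higher)."""
    if not enhancer_cores or not random_regions:
        raise ValidationError("empty group in conservation comparison")
    a = np.array([mean_score(track, iv)[0] for iv in enhancer_cores])
    b = np.array([mean_score(track, iv)[0] for iv in random_regions])
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    p = rank_sum_greater(a, b)
    return ConservationComparison(
        group_labels=("enhancers", "random_non_tss"),
        values_a=a,
        values_b=b,
        test_type="unpaired_rank_sum",
        p=p,
    )
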