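"""TF-occupancy scoring, reporter-tile overlap tests, and the
high-confidence enhancer grouping.

Enhancers are scored for transcription-factor ChIP occupancy (fold over
input in a 201-bp window around the local summit), filtered against known
enhancers and expression criteria, and assigned to confidence groups by a
threshold cascade: mesoderm enhancers by Dl (>= 3-fold) then Twi
(>= 5-fold with Dl < 3), dorsal-ectoderm enhancers by Mad (>= 3-fold)
then Zen (>= 3-fold with Mad < 3). Heatmap display values are normalized
per factor between 0 (no enrichment over input) and 1 (98th percentile).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .candidates import CandidateRegion
from .core import ExpressionRecord, GenomicInterval, PeakRecord, ValidationError
from .coverage import EnrichmentTrack
from .differential import CALL_DEE, CALL_ME


@dataclass(frozen=True)
class TFEnrichmentRecord:
    enhancer_id: str
    tf_name: str
    summit: int  # local TF summit within the enhancer core
    enrichment: float  # fold over input in the 201-bp window at the summit


@dataclass(frozen=True)
class ConfidenceGroup:
    enhancer_id: str
    group: str  # Dl_binding | Twi | Mad_binding | Zen_binding | unassigned
    exclusion_reason: Optional[str] = None


def tf_enrichment_at(
    enhancers: Sequence[CandidateRegion],
    track: EnrichmentTrack,
    tf_name: str,
    window_width: int = 201,
) -> List[TFEnrichmentRecord]:
    """Per-enhancer TF occupancy: locate the IP-coverage summit within the
    201-bp core (ties: leftmost) and compute normalized IP over input in a
    201-bp window centered there."""
    half_lo = (window_width - 1) // 2
    out: List[TFEnrichmentRecord] = []
    for enh in enhancers:
        core = enh.core
        ip_depth = track.ip.depth[core.chrom][core.start : core.end]
        summit = core.start + int(np.argmax(ip_depth))
        size = track.ip.chrom_sizes[core.chrom]
        ws = max(summit - half_lo, 0)
        we = min(ws + window_width, size)
        fold = track.window_fold(GenomicInterval(core.chrom, ws, we))
        out.append(
            TFEnrichmentRecord(
                enhancer_id=enh.id, tf_name=tf_name, summit=summit, enrichment=fold
            )
        )
    return out


def select_top_peaks(
    peak_replicates: Sequence[Sequence[PeakRecord]],
    location_class: Mapping[Tuple[str, int], str],
    n: int = 400,
    exclude_tss: bool = True,
) -> List[PeakRecord]:
    """Top-n TF peaks by score from the replicate with the most peaks.

    TSS-class peaks (looked up by (chrom, summit)) are dropped first; ties
    at the score boundary break by genomic position (leftmost kept).
    """
    if not peak_replicates:
        raise ValidationError("no peak replicates supplied")
    best = max(peak_replicates, key=len)
    peaks = list(best)
    if exclude_tss:
        peaks = [
            p
            for p in peaks
            if location_class.get((p.interval.chrom, p.summit)) != "TSS"
        ]
    peaks.sort(key=lambda p: (-p.score, p.interval.chrom, p.interval.start))
    if len(peaks) < n:
        warnings.warn(f"only {len(peaks)} non-TSS peaks available (requested {n})")
    return peaks[:n]


def fisher_one_sided_greater(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided Fisher's exact p that group 1's proportion exceeds
    group 2's (hypergeometric upper tail)."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def annotation_overlap_test(
    group_regions: Sequence[GenomicInterval],
    control_regions: Sequence[GenomicInterval],
    tiles: Sequence[Tuple[GenomicInterval, bool]],
    method: str = "fisher",
) -> Tuple[float, float, float]:
    """Reporter-tile overlap test.

    ``tiles`` pairs each tile interval with whether it satisfies the
    annotation predicate (already evaluated, e.g. "any term contains
    'mesoderm'" or "expressed in stages 4-10"). For each region set, the
    tiles it overlaps (>= 1 bp) are collected and the fraction of
    predicate-positive tiles compared one-sided (group > control), by
    Fisher's exact test (default) or a pooled proportion z test.
    Returns (frac_group, frac_control, p); NaN fractions when a set
    overlaps no tile.
    """

    def overlapped(regions):
        hit = []
        for i, (tile, positive) in enumerate(tiles):
            for r in regions:
                if tile.overlaps(r):
                    hit.append(positive)
                    break
        return hit

    g = overlapped(group_regions)
    c = overlapped(control_regions)
    if not g or not c:
        warnings.warn("a region set overlaps no annotated tile")
        return float("nan"), float("nan"), float("nan")
    k1, n1 = sum(g), len(g)
    k2, n2 = sum(c), len(c)
    if method == "fisher":
        p = fisher_one_sided_greater(k1, n1, k2, n2)
    elif method == "proportion":
        from .motifs import one_sided_proportion_p

        p = one_sided_proportion_p(k1, n1, k2, n2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return k1 / n1, k2 / n2, p


def assign_confidence_groups(
    enhancers: Sequence[CandidateRegion],
    calls: Mapping[str, str],
    tf_enrichments: Mapping[str, Mapping[str, float]],  # tf -> enhancer id -> fold
    assigned_gene: Mapping[str, str],  # enhancer id -> gene id
    expression: Sequence[ExpressionRecord],
    pair: Tuple[str, str],
    known_enhancers: Sequence[GenomicInterval] = (),
    third_condition: Optional[str] = None,
    dl_min: float = 3.0,
    twi_min: float = 5.0,
    mad_min: float = 3.0,
    zen_min: float = 3.0,
) -> List[ConfidenceGroup]:
    """Sequential filters then the TF threshold cascade.

    Filters (each records an exclusion reason): (1) overlap with a known
    enhancer; (2) assigned gene's FPKM strictly highest in the third
    (neurectoderm-proxy) condition; (3) acetylation tissue disagrees with
    the gene's differential-expression tissue. Survivors are grouped:
    MEs with Dl >= dl_min -> Dl_binding, else Twi >= twi_min (and Dl <
    dl_min) -> Twi; DEEs with Mad >= mad_min -> Mad_binding, else Zen >=
    zen_min (and Mad < mad_min) -> Zen_binding; everything else
    unassigned. Thresholds are inclusive ("at least"), the secondary
    rule's upper bound strict ("less than").
    """
    expr = {r.gene_id: r for r in expression}
    out: List[ConfidenceGroup] = []
    for enh in enhancers:
        call = calls.get(enh.id)
        if call not in (CALL_ME, CALL_DEE):
            continue
        if any(k.overlaps(enh.core) for k in known_enhancers):
            out.append(ConfidenceGroup(enh.id, "unassigned", "overlaps_known_enhancer"))
            continue
        gene = assigned_gene.get(enh.id)
        rec = expr.get(gene) if gene else None
        if rec is None:
            out.append(ConfidenceGroup(enh.id, "unassigned", "no_assigned_gene"))
            continue
        if third_condition is not None:
            f3 = rec.fpkm_by_condition.get(third_condition, 0.0)
            fa = rec.fpkm_by_condition.get(pair[0], 0.0)
            fb = rec.fpkm_by_condition.get(pair[1], 0.0)
            if f3 > fa and f3 > fb:
                out.append(
                    ConfidenceGroup(enh.id, "unassigned", "highest_in_third_condition")
                )
                continue
        dcall = rec.diff_call_by_pair.get(pair) or rec.diff_call_by_pair.get(
            (pair[1], pair[0])
        )
        expected = f"up_in_{pair[0]}" if call == CALL_ME else f"up_in_{pair[1]}"
        if dcall != expected:
            out.append(
                ConfidenceGroup(enh.id, "unassigned", "expression_tissue_mismatch")
            )
            continue

        def fold(tf: str) -> Optional[float]:
            return tf_enrichments.get(tf, {}).get(enh.id)

        if call == CALL_ME:
            dl, twi = fold("Dl"), fold("Twi")
            if dl is None or twi is None:
                out.append(ConfidenceGroup(enh.id, "unassigned", "missing_tf_record"))
            elif dl >= dl_min:
                out.append(ConfidenceGroup(enh.id, "Dl_binding"))
            elif twi >= twi_min:
                out.append(ConfidenceGroup(enh.id, "Twi"))
            else:
                out.append(ConfidenceGroup(enh.id, "unassigned", "below_tf_thresholds"))
        else:
            mad, zen = fold("Mad"), fold("Zen")
            if mad is None or zen is None:
                out.append(ConfidenceGroup(enh.id, "unassigned", "missing_tf_record"))
            elif mad >= mad_min:
                out.append(ConfidenceGroup(enh.id, "Mad_binding"))
            elif zen >= zen_min:
                out.append(ConfidenceGroup(enh.id, "Zen_binding"))
            else:
                out.append(ConfidenceGroup(enh.id, "unassigned", "below_tf_thresholds"))
    return out


def normalize_for_heatmap(values: Sequence[float]) -> np.ndarray:
    """Map one factor's enrichment values to [0, 1] for display.

    0 is "no enrichment over input or less" (fold <= 1), 1 is the 98th
    percentile or higher; linear interpolation between order statistics
    defines the percentile.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot normalize an empty vector")
    p98 = float(np.percentile(v[np.isfinite(v)], 98))
    if p98 <= 1:
        warnings.warn("98th percentile <= 1: all values map to 0")
        return np.zeros_like(v)
    return np.clip((v - 1.0) / (p98 - 1.0), 0.0, 1.0)
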