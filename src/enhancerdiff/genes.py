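"""Nearest-gene assignment, enhancer naming, and expression concordance.

Each called enhancer is linked to nearby *active* genes (FPKM >= 5 in at
least one of the two tissues). A region overlapping an active gene is
assigned to it; otherwise the active gene with the closest TSS wins, with
further ranks by increasing TSS distance. Names follow the
``<gene>-<ME|DEE>[-TSS]<k>`` convention with ordinals along the
chromosome. Validation asks whether assigned genes are differentially
expressed in the tissue the enhancer call predicts, compared with the
non-differential control group (one-sided chi-squared on the 2x2 table).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .candidates import CandidateRegion
from .core import ExpressionRecord, GeneModel, ValidationError
from .differential import CALL_DEE, CALL_ME


@dataclass(frozen=True)
class GeneAssignment:
    region_id: str
    rank: int  # 1 = closest
    gene_id: str
    assignment_mode: str  # "overlap" or "nearest_tss"
    distance: int  # bp, 0 for overlap


@dataclass(frozen=True)
class NamedEnhancer:
    name: str
    region_id: str
    gene_id: str
    enhancer_type: str  # ME / DEE / ME-TSS / DEE-TSS
    ordinal: int


def active_genes(
    expression: Sequence[ExpressionRecord],
    conditions: Sequence[str],
    min_fpkm: float = 5.0,
) -> set:
    """Genes with FPKM >= min_fpkm in at least one condition (inclusive
    boundary)."""
    return {
        r.gene_id for r in expression if r.max_fpkm(conditions) >= min_fpkm
    }


def assign_nearest(
    regions: Sequence[CandidateRegion],
    gene_models: Sequence[GeneModel],
    active: set,
    k: int = 3,
) -> Dict[str, List[GeneAssignment]]:
    """Assign ranks 1..k active genes to each region.

    Rank 1 is an overlapping active gene when one exists (ties by TSS
    distance from the summit); otherwise the nearest-TSS active gene.
    Higher ranks follow by increasing TSS distance, excluding genes
    already ranked.
    """
    models = [g for g in gene_models if g.gene_id in active]
    if not models:
        raise ValidationError("no active genes available for assignment")
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.span.chrom, []).append(g)

    out: Dict[str, List[GeneAssignment]] = {}
    for r in regions:
        cands = by_chrom.get(r.chrom, [])
        if not cands:
            out[r.id] = []
            continue
        dists = np.array([abs(g.tss - r.summit) for g in cands])
        overlap = np.array(
            [g.span.start < r.core.end and r.core.start < g.span.end for g in cands]
        )
        order = np.lexsort((dists,))
        assignments: List[GeneAssignment] = []
        # rank 1: overlapping gene if any, ties by TSS distance
        if overlap.any():
            ov_idx = np.flatnonzero(overlap)
            first = ov_idx[np.argmin(dists[ov_idx])]
            assignments.append(
                GeneAssignment(r.id, 1, cands[first].gene_id, "overlap", 0)
            )
            used = {first}
        else:
            first = order[0]
            assignments.append(
                GeneAssignment(
                    r.id, 1, cands[first].gene_id, "nearest_tss", int(dists[first])
                )
            )
            used = {first}
        for idx in order:
            if len(assignments) >= k:
                break
            if idx in used:
                continue
            used.add(idx)
            assignments.append(
                GeneAssignment(
                    r.id,
                    len(assignments) + 1,
                    cands[idx].gene_id,
                    "nearest_tss",
                    int(dists[idx]),
                )
            )
        out[r.id] = assignments
    return out


def name_enhancers(
    regions: Sequence[CandidateRegion],
    calls: Mapping[str, str],
    assignments: Mapping[str, List[GeneAssignment]],
) -> List[NamedEnhancer]:
    """Name every ME/DEE region "<gene>-<type>[-TSS]<k>".

    Ordinals run 1..n per (gene, type) in ascending genomic position, so
    naming is deterministic and independent of input order.
    """
    called = [
        r
        for r in regions
        if calls.get(r.id) in (CALL_ME, CALL_DEE) and assignments.get(r.id)
    ]
    called.sort(key=lambda r: (r.chrom, r.summit))
    counters: Dict[Tuple[str, str], int] = {}
    out: List[NamedEnhancer] = []
    for r in called:
        gene = assignments[r.id][0].gene_id
        etype = calls[r.id]
        if r.location_class == "TSS":
            etype = f"{etype}-TSS"
        key = (gene, etype)
        counters[key] = counters.get(key, 0) + 1
        out.append(
            NamedEnhancer(
                name=f"{gene}-{etype}{counters[key]}",
                region_id=r.id,
                gene_id=gene,
                enhancer_type=etype,
                ordinal=counters[key],
            )
        )
    return out


def _concordant(
    region_id: str,
    call: str,
    rank: int,
    assignments: Mapping[str, List[GeneAssignment]],
    expression_by_gene: Mapping[str, ExpressionRecord],
    pair: Tuple[str, str],
) -> Optional[bool]:
    """Is the rank-th assigned gene differentially up in the tissue the
    call predicts (ME -> condition A, DEE -> condition B)? None if the
    region lacks that rank."""
    ranked = assignments.get(region_id, [])
    match = [a for a in ranked if a.rank == rank]
    if not match:
        return None
    rec = expression_by_gene.get(match[0].gene_id)
    if rec is None:
        return False
    dcall = rec.diff_call_by_pair.get(pair)
    if dcall is None:
        dcall = rec.diff_call_by_pair.get((pair[1], pair[0]))
    if dcall is None:
        return False
    expected = f"up_in_{pair[0]}" if call == CALL_ME else f"up_in_{pair[1]}"
    return dcall == expected


def one_sided_chi2_proportions(
    k1: int, n1: int, k2: int, n2: int
) -> Tuple[float, float]:
    """One-sided chi-squared test that proportion 1 exceeds proportion 2.

    Realized as the signed z on the pooled two-proportion difference
    (z^2 equals the 2x2 chi-squared without continuity correction); the
    one-sided p is the upper normal tail of the signed z, i.e. half the
    two-sided chi-squared p when the effect is in the tested direction.
    Returns (chi2, p).
    """
    if n1 == 0 or n2 == 0:
        raise ValidationError("zero-size group in proportion test")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    denom = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if denom == 0:
        return 0.0, 0.5
    z = (p1 - p2) / np.sqrt(denom)
    return float(z * z), float(stats.norm.sf(z))


def concordance_test(
    test_regions: Sequence[CandidateRegion],
    control_regions: Sequence[CandidateRegion],
    calls: Mapping[str, str],
    assignments: Mapping[str, List[GeneAssignment]],
    expression: Sequence[ExpressionRecord],
    pair: Tuple[str, str],
    rank: int = 1,
) -> Tuple[float, float, float]:
    """Fraction of regions whose rank-th gene is up in the predicted
    tissue, test vs control, with a one-sided chi-squared p.

    Control regions are scored against both directions (a control region
    counts as concordant if its gene is up in either tissue), mirroring
    the use of non-differential regions as a neutral baseline.
    """
    expr = {r.gene_id: r for r in expression}

    def frac(regions, as_control: bool):
        k = n = 0
        for r in regions:
            if as_control:
                # count either-direction differential expression
                a = _concordant(r.id, CALL_ME, rank, assignments, expr, pair)
                b = _concordant(r.id, CALL_DEE, rank, assignments, expr, pair)
                if a is None and b is None:
                    continue
                n += 1
                k += int(bool(a) or bool(b))
            else:
                c = _concordant(r.id, calls[r.id], rank, assignments, expr, pair)
                if c is None:
                    continue
                n += 1
                k += int(c)
        return k, n

    k1, n1 = frac(test_regions, as_control=False)
    k2, n2 = frac(control_regions, as_control=True)
    if n1 == 0 or n2 == 0:
        raise ValidationError("zero-size group in concordance test")
    _, p = one_sided_chi2_proportions(k1, n1, k2, n2)
    return k1 / n1, k2 / n2, p


def correlate_enrichment_expression(x, y) -> float:
    """Squared Pearson correlation between paired (already log-scaled)
    enrichment and expression values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
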