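"""PWM motif scanning and enrichment testing.

Motifs (position weight matrices in MEME minimal format) are scanned
against region sequences as log2-likelihood ratios over a Markov
background model. Hit p-values — the probability a background window
scores at least as high — come from exhaustive dynamic programming over
the discretized score distribution (bin width 1e-3 bits). Motif presence
in test vs control region groups is compared with one-sided two-proportion
tests (both directions, BH-corrected per direction), and redundant motifs
are collapsed by occurrence overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .differential import adjust_bh

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G
SCORE_BIN_BITS = 1e-3
PWM_FLOOR = 1e-4  # probability floor applied in log-odds to avoid -inf


@dataclass
class PositionWeightMatrix:
    motif_id: str
    matrix: np.ndarray  # L x 4 probabilities
    tf_name: str = ""
    tf_gene_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError(f"{self.motif_id}: matrix must be L x 4")
        if self.matrix.shape[0] < 4:
            raise ValidationError(f"{self.motif_id}: motif length must be >= 4")
        if np.any(self.matrix < 0):
            raise ValidationError(f"{self.motif_id}: negative probabilities")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-6):
            raise ValidationError(f"{self.motif_id}: rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, COMPLEMENT_IDX],
            tf_name=self.tf_name,
            tf_gene_id=self.tf_gene_id,
        )


@dataclass
class BackgroundModel:
    """Markov background of given order; ``probs`` maps a context string
    ("" for order 0) to a length-4 probability vector."""

    order: int
    probs: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for ctx, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if abs(p.sum() - 1) > 1e-6:
                raise ValidationError(f"background probs for {ctx!r} must sum to 1")
            self.probs[ctx] = p

    def base_probs(self) -> np.ndarray:
        """Stationary single-base probabilities (exact for order 0; the
        average over contexts otherwise)."""
        return np.mean([p for p in self.probs.values()], axis=0)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    region_id: str
    offset: int  # window start within the region sequence (forward coords)
    strand: str
    score: float  # log2 likelihood ratio, bits
    p: float


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    direction: str  # "enriched" (test > control) or "depleted"
    test_with: int
    test_total: int
    control_with: int
    control_total: int
    p: float
    q: float = np.nan


def uniform_background() -> BackgroundModel:
    return BackgroundModel(order=0, probs={"": np.full(4, 0.25)})


def build_background(sequences: Iterable[str], order: int = 0) -> BackgroundModel:
    """Estimate a Markov background from sequences.

    Frequencies get add-one smoothing and are reverse-complement
    symmetrized by counting each sequence together with its reverse
    complement, so both strands share one model (A/T and C/G balance at
    order 0).
    """
    seqs = [s.upper() for s in sequences]
    total = sum(len(s) for s in seqs)
    if total < 1000 * 4**order:
        raise ValidationError(
            f"need >= {1000 * 4 ** order} bases to fit an order-{order} background"
        )
    offenders = sorted(
        {ch for s in seqs for ch in s if ch not in "ACGTN"}
    )
    if offenders:
        raise ValidationError(f"non-ACGTN characters in input: {offenders}")

    def revcomp(s: str) -> str:
        return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]

    contexts = ["".join(c) for c in _product_bases(order)]
    counts = {ctx: np.ones(4) for ctx in contexts}  # add-one smoothing
    for s in seqs:
        for strand_seq in (s, revcomp(s)):
            if order == 0:
                arr = encode_sequence(strand_seq)
                valid = arr >= 0
                counts[""] += np.bincount(arr[valid], minlength=4)
            else:
                for i in range(order, len(strand_seq)):
                    ctx = strand_seq[i - order : i]
                    b = strand_seq[i]
                    if b not in BASE_INDEX or ("N" in ctx):
                        continue
                    counts[ctx][BASE_INDEX[b]] += 1
    probs: Dict[str, np.ndarray] = {
        ctx: counts[ctx] / counts[ctx].sum() for ctx in contexts
    }
    return BackgroundModel(order=order, probs=probs)


def _product_bases(order: int) -> List[Tuple[str, ...]]:
    if order == 0:
        return [()]
    out = [()]
    for _ in range(order):
        out = [c + (b,) for c in out for b in BASES]
    return out


# ---------------------------------------------------------------------------
# Scoring and DP p-values
# ---------------------------------------------------------------------------

def log_odds_matrix(pwm: PositionWeightMatrix, background: BackgroundModel) -> np.ndarray:
    """L x 4 matrix of log2(pwm / background) scores in bits, with the PWM
    probabilities floored at PWM_FLOOR."""
    bg = background.base_probs()
    p = np.maximum(pwm.matrix, PWM_FLOOR)
    return np.log2(p / bg)


def _binned(matrix_bits: np.ndarray) -> np.ndarray:
    return np.rint(matrix_bits / SCORE_BIN_BITS).astype(np.int64)


def score_distribution(
    pwm: PositionWeightMatrix, background: BackgroundModel
) -> Tuple[np.ndarray, int]:
    """Exact null pmf of the binned score under the background.

    Returns (pmf, offset): pmf[k] = Pr(binned score = k + offset), where
    scores accumulate per-position integers rounded to 1e-3-bit bins.
    Position independence at the background's marginal base frequencies is
    assumed (contexts beyond order 0 use the averaged base probabilities).
    """
    S = _binned(log_odds_matrix(pwm, background))
    bg = background.base_probs()
    lo = int(S.min(axis=1).sum())
    hi = int(S.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # position 0
    pos_lo = int(S[0].min())
    cur = np.zeros(int(S[0].max()) - pos_lo + 1)
    for b in range(4):
        cur[S[0, b] - pos_lo] += bg[b]
    cur_lo = pos_lo
    for i in range(1, len(pwm)):
        p_lo = int(S[i].min())
        p_hi = int(S[i].max())
        new = np.zeros(len(cur) + (p_hi - p_lo))
        for b in range(4):
            shift = S[i, b] - p_lo
            new[shift : shift + len(cur)] += cur * bg[b]
        cur = new
        cur_lo += p_lo
    pmf[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    return pmf, lo


def score_pvalues(pmf: np.ndarray, offset: int) -> np.ndarray:
    """Survival function over binned scores: sf[k] = Pr(score >= k+offset)."""
    return np.cumsum(pmf[::-1])[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence to base indices; non-ACGT characters become -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class CompiledPWM:
    """A PWM with its log-odds matrices and DP null precomputed for a
    background, so many sequences can be scanned cheaply."""

    def __init__(self, pwm: PositionWeightMatrix, background: BackgroundModel):
        self.pwm = pwm
        self.length = len(pwm)
        self.strand_data = []
        for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
            bits = log_odds_matrix(mat, background)
            self.strand_data.append((strand, bits, _binned(bits)))
        pmf, offset = score_distribution(pwm, background)
        self.sf = score_pvalues(pmf, offset)
        self.offset = offset

    def pvalue(self, total_int: np.ndarray) -> np.ndarray:
        k = np.clip(total_int - self.offset, 0, len(self.sf) - 1)
        p = self.sf[k]
        p = np.where(total_int - self.offset >= len(self.sf), 0.0, p)
        return np.where(total_int - self.offset < 0, 1.0, p)

    def scan_encoded(
        self, idx: np.ndarray, p_threshold: float, region_id: str
    ) -> List[MotifHit]:
        L = self.length
        if L > len(idx):
            return []
        win = np.lib.stride_tricks.sliding_window_view(idx, L)
        valid = (win >= 0).all(axis=1)
        safe = np.where(win >= 0, win, 0)
        pos_idx = np.arange(L)
        hits: List[MotifHit] = []
        for strand, bits, ints in self.strand_data:
            total_int = ints[pos_idx, safe].sum(axis=1)
            pvals = self.pvalue(total_int)
            keep = np.flatnonzero(valid & (pvals <= p_threshold))
            if len(keep):
                total_bits = bits[pos_idx, safe[keep]].sum(axis=1)
                for o, s, p in zip(keep, total_bits, pvals[keep]):
                    hits.append(
                        MotifHit(
                            motif_id=self.pwm.motif_id,
                            region_id=region_id,
                            offset=int(o),
                            strand=strand,
                            score=float(s),
                            p=float(p),
                        )
                    )
        hits.sort(key=lambda h: (h.offset, h.strand))
        return hits


def scan_pwm(
    pwm: PositionWeightMatrix,
    sequence: str,
    background: BackgroundModel,
    p_threshold: float = 1e-4,
    region_id: str = "",
) -> List[MotifHit]:
    """Scan both strands of ``sequence`` for PWM hits with p <= threshold.

    Scores are exact log2 likelihood ratios; hit p-values use the binned
    DP null. Windows containing non-ACGT characters are skipped. The
    reverse strand scores the reverse complement; its offset is still the
    window start in forward coordinates.
    """
    return CompiledPWM(pwm, background).scan_encoded(
        encode_sequence(sequence), p_threshold, region_id
    )


def scan_regions(
    pwms: Sequence[PositionWeightMatrix],
    sequences: Mapping[str, str],
    background: BackgroundModel,
    p_threshold: float = 1e-4,
) -> Dict[str, List[MotifHit]]:
    """Scan many PWMs against many region sequences.

    Returns motif_id -> list of hits across all regions. The DP null is
    compiled once per PWM and shared across regions.
    """
    encoded = {rid: encode_sequence(s) for rid, s in sequences.items()}
    out: Dict[str, List[MotifHit]] = {}
    for pwm in pwms:
        compiled = CompiledPWM(pwm, background)
        hits: List[MotifHit] = []
        for region_id, idx in encoded.items():
            hits.extend(compiled.scan_encoded(idx, p_threshold, region_id))
        out[pwm.motif_id] = hits
    return out


# ---------------------------------------------------------------------------
# Expression filtering
# ---------------------------------------------------------------------------

def filter_motifs_by_expression(
    pwms: Sequence[PositionWeightMatrix],
    expression_by_gene: Mapping[str, float],
    min_fpkm: float = 3.0,
    exclusions: Optional[set] = None,
    keep_unmapped: bool = True,
) -> List[PositionWeightMatrix]:
    """Keep motifs whose TF gene is expressed (max FPKM strictly > min_fpkm
    in at least one condition) and not on the exclusion list (e.g. known
    heterodimer-derived motifs)."""
    exclusions = exclusions or set()
    out = []
    for pwm in pwms:
        if pwm.motif_id in exclusions:
            continue
        if not pwm.tf_gene_id:
            if keep_unmapped:
                out.append(pwm)
            continue
        fpkm = expression_by_gene.get(pwm.tf_gene_id)
        if fpkm is not None and fpkm > min_fpkm:
            out.append(pwm)
    return out


# ---------------------------------------------------------------------------
# Enrichment testing and motif collapsing
# ---------------------------------------------------------------------------

def presence_matrix(
    hits_by_motif: Mapping[str, Sequence[MotifHit]], region_ids: Sequence[str]
) -> pd.DataFrame:
    """Boolean regions x motifs matrix: >= 1 hit in the region."""
    mat = pd.DataFrame(False, index=list(region_ids), columns=list(hits_by_motif))
    for motif_id, hits in hits_by_motif.items():
        present = {h.region_id for h in hits}
        mat.loc[[r for r in region_ids if r in present], motif_id] = True
    return mat


def one_sided_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Upper-tail p that proportion 1 exceeds proportion 2 (pooled z,
    no continuity correction). NaN when the pooled variance is zero."""
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    denom = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if denom == 0:
        return float("nan")
    z = (p1 - p2) / np.sqrt(denom)
    return float(stats.norm.sf(z))


def enrichment_test(
    test_presence: pd.DataFrame,
    control_presence: pd.DataFrame,
) -> List[MotifEnrichmentResult]:
    """Per-motif one-sided proportion tests, both directions, BH within
    each direction. Motifs absent from both groups are skipped."""
    if len(test_presence) == 0 or len(control_presence) == 0:
        raise ValidationError("empty region group in motif enrichment test")
    results: List[MotifEnrichmentResult] = []
    for direction in ("enriched", "depleted"):
        dir_results = []
        for motif_id in test_presence.columns:
            k1 = int(test_presence[motif_id].sum())
            n1 = len(test_presence)
            k2 = int(control_presence[motif_id].sum())
            n2 = len(control_presence)
            if direction == "enriched":
                p = one_sided_proportion_p(k1, n1, k2, n2)
            else:
                p = one_sided_proportion_p(k2, n2, k1, n1)
            if np.isnan(p):
                continue
            dir_results.append(
                MotifEnrichmentResult(
                    motif_id=motif_id,
                    direction=direction,
                    test_with=k1,
                    test_total=n1,
                    control_with=k2,
                    control_total=n2,
                    p=p,
                )
            )
        qs = adjust_bh(np.array([r.p for r in dir_results]))
        for r, q in zip(dir_results, qs):
            r.q = float(q)
        results.extend(dir_results)
    return results


def _occurrence_overlap_count(
    hits_a: Sequence[MotifHit],
    hits_b: Sequence[MotifHit],
    len_a: int,
    len_b: int,
    same_strand: bool = False,
) -> int:
    """Number of A hits overlapping >= 1 bp with some B hit in the same
    region."""
    b_by_region: Dict[str, List[MotifHit]] = {}
    for h in hits_b:
        b_by_region.setdefault(h.region_id, []).append(h)
    count = 0
    for h in hits_a:
        for hb in b_by_region.get(h.region_id, []):
            if same_strand and hb.strand != h.strand:
                continue
            if h.offset < hb.offset + len_b and hb.offset < h.offset + len_a:
                count += 1
                break
    return count


def collapse_motifs(
    significant: Sequence[MotifEnrichmentResult],
    hits_by_motif: Mapping[str, Sequence[MotifHit]],
    motif_lengths: Mapping[str, int],
    overlap_frac: float = 0.10,
    same_strand: bool = False,
) -> List[Dict]:
    """Group significant motifs whose occurrences overlap in more than
    ``overlap_frac`` of instances (denominator: the rarer motif's hit
    count); each connected component is one group represented by its
    lowest-p member.
    """
    best_p: Dict[str, float] = {}
    for r in significant:
        if r.motif_id not in best_p or r.p < best_p[r.motif_id]:
            best_p[r.motif_id] = r.p
    ids = sorted(best_p)
    parent = {m: m for m in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ha, hb = hits_by_motif.get(a, []), hits_by_motif.get(b, [])
            if not ha or not hb:
                continue
            n = _occurrence_overlap_count(
                ha, hb, motif_lengths[a], motif_lengths[b], same_strand
            )
            frac = n / min(len(ha), len(hb))
            if frac > overlap_frac:  # strictly more than the threshold
                parent[find(a)] = find(b)

    groups: Dict[str, List[str]] = {}
    for m in ids:
        groups.setdefault(find(m), []).append(m)
    out = []
    for members in groups.values():
        rep = min(members, key=lambda m: (best_p[m], m))
        out.append(
            {"representative": rep, "members": sorted(members), "p": best_p[rep]}
        )
    out.sort(key=lambda g: g["p"])
    return out


def tf_binding_at_motif_test(
    enhancer_ids: Sequence[str],
    hits: Sequence[MotifHit],
    tf_enrichment: Mapping[str, float],
) -> Tuple[float, float, float]:
    """Compare a TF's ChIP enrichment at enhancers containing vs lacking a
    motif (two-sided Wilcoxon rank-sum).

    Returns (median_with, median_without, p); p is NaN when either group
    has fewer than 3 members.
    """
    with_motif = {h.region_id for h in hits}
    vals_with = [tf_enrichment[e] for e in enhancer_ids if e in with_motif and e in tf_enrichment]
    vals_without = [tf_enrichment[e] for e in enhancer_ids if e not in with_motif and e in tf_enrichment]
    med_w = float(np.median(vals_with)) if vals_with else float("nan")
    med_wo = float(np.median(vals_without)) if vals_without else float("nan")
    if len(vals_with) < 3 or len(vals_without) < 3:
        return med_w, med_wo, float("nan")
    stat = stats.mannwhitneyu(vals_with, vals_without, alternative="two-sided")
    return med_w, med_wo, float(stat.pvalue)


# ---------------------------------------------------------------------------
# MEME minimal format I/O
# ---------------------------------------------------------------------------

def read_meme(path) -> List[PositionWeightMatrix]:
    """Read PWMs from MEME minimal format. The optional alternate name on
    the MOTIF line is taken as the TF name (and gene id for expression
    filtering)."""
    pwms: List[PositionWeightMatrix] = []
    with open(str(path)) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            tf = parts[2] if len(parts) > 2 else ""
            # find letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                j += 1
            if j >= len(lines):
                raise ValidationError(f"{path}: motif {motif_id} lacks a matrix")
            rows = []
            j += 1
            while j < len(lines):
                vals = lines[j].split()
                if len(vals) != 4:
                    break
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    break
                j += 1
            pwms.append(
                PositionWeightMatrix(
                    motif_id=motif_id,
                    matrix=np.array(rows),
                    tf_name=tf,
                    tf_gene_id=tf,
                )
            )
            i = j
        else:
            i += 1
    return pwms


def write_meme(pwms: Sequence[PositionWeightMatrix], path) -> None:
    with open(str(path), "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for pwm in pwms:
            name = f" {pwm.tf_name}" if pwm.tf_name else ""
            fh.write(f"MOTIF {pwm.motif_id}{name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(format(v, ".6f") for v in row) + "\n")
            fh.write("\n")


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": h.motif_id,
                "region_id": h.region_id,
                "offset": h.offset,
                "strand": h.strand,
                "score": h.score,
                "p": h.p,
            }
            for h in hits
        ]
    )
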