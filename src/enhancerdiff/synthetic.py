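"""Self-contained two-tissue synthetic datasets with known ground truth.

The generator emulates the data geometry the pipeline is designed for:
candidate enhancer cores (CBP-like summits) whose flanking H3K27ac signal
is bimodal (fragments centered ~330 bp on either side of the
nucleosome-depleted core), with a tissue-differential amplitude for
planted mesoderm (ME) and dorsal-ectoderm (DEE) enhancers; unimodal
CBP/TF signal at the core; uniform input background; gamma-mixed Poisson
(i.e. negative binomial) replicate noise; expression of adjacent genes
coupled to enhancer activity; motifs planted in cores with class-specific
probabilities; and conservation elevated at planted motif bases.

Layout is deterministic given the config: differential enhancers sit in
gene blocks (each with an adjacent gene whose expression follows the
enhancer's tissue), non-differential candidates tile a separate section,
and a few non-differential candidates are placed near/inside genes to
exercise the TSS/intragenic location classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ExpressionRecord, GeneModel, GenomicInterval, PeakRecord, ValidationError
from .motifs import BASES, PositionWeightMatrix

COND_A = "mesoderm"  # ventralized tissue: MEs have higher H3K27ac here
COND_B = "dorsal_ectoderm"  # dorsalized tissue: DEEs higher here
COND_THIRD = "neurectoderm"  # exclusion-filter proxy condition

ASSAY_CODES = {"H3K27ac": 1, "CBP": 2, "input": 3, "Dl": 4, "Twi": 5, "Mad": 6, "Zen": 7}
COND_CODES = {COND_A: 1, COND_B: 2, "": 0}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a 5-Mb genome with 200 ME + 200 DEE + 2600
    non-differential candidates, a 3-fold flank-acetylation differential,
    NB dispersion 0.05, and 3 (tissue A) vs 2 (tissue B) replicates.
    """

    genome_size: int = 5_000_000
    chrom_name: str = "chrS"
    n_me: int = 200
    n_dee: int = 200
    n_nondiff: int = 2600
    n_tss_class: int = 50  # nondiff candidates placed < 1 kb from a TSS
    n_intragenic_class: int = 50  # nondiff candidates inside a gene body
    effect_fold: float = 3.0  # flank acetylation fold, active vs other tissue
    flank_offset: int = 330
    flank_jitter_sd: float = 60.0
    signal_per_enhancer: float = 150.0  # expected H3K27ac fragments per flank pair
    cbp_signal: float = 60.0
    tf_signal: float = 25.0  # fragments at a TF-bound core
    background_per_bp: float = 0.02  # background fragment starts per bp
    input_per_bp: float = 0.03
    dispersion: float = 0.05  # NB alpha for replicate noise
    fragment_length: int = 180
    read_length: int = 36
    replicates: Dict[str, int] = field(
        default_factory=lambda: {COND_A: 3, COND_B: 2}
    )
    # expression coupling
    expression_fold: float = 4.0
    baseline_fpkm: float = 20.0
    expression_noise_sd: float = 0.2  # lognormal sd on log-FPKM
    n_background_genes: int = 18
    silent_fraction: float = 0.3  # of background genes
    # motifs
    motif_length: int = 8
    plant_prob_matched: float = 0.6  # class motif in its own class
    plant_prob_background: float = 0.1  # class motif elsewhere
    n_decoy_motifs: int = 20
    # TF occupancy truth probabilities
    tf_bound_prob: Dict[str, float] = field(
        default_factory=lambda: {"Dl": 0.6, "Twi": 0.5, "Mad": 0.6, "Zen": 0.5}
    )
    # conservation
    conservation_beta: Tuple[float, float] = (2.0, 8.0)
    motif_conservation_bonus: float = 0.3
    core_conservation_bonus: float = 0.15
    base_probs: Tuple[float, float, float, float] = (0.29, 0.21, 0.21, 0.29)
    seed: int = 0


def small_test_config(seed: int = 0) -> SyntheticConfig:
    """A scaled-down dataset (400 kb, 40 differential enhancers) with the
    same geometry and noise model; for quick runs and tests."""
    return SyntheticConfig(
        genome_size=400_000,
        n_me=20,
        n_dee=20,
        n_nondiff=160,
        n_tss_class=5,
        n_intragenic_class=5,
        n_background_genes=4,
        n_decoy_motifs=5,
        seed=seed,
    )


def _sharp_pwm(consensus: str, motif_id: str, tf_name: str = "", sharpness: float = 0.85) -> PositionWeightMatrix:
    off = (1 - sharpness) / 3
    mat = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        mat[i, BASES.index(b)] = sharpness
    return PositionWeightMatrix(motif_id=motif_id, matrix=mat, tf_name=tf_name, tf_gene_id=tf_name)


def planted_motifs(config: SyntheticConfig) -> Tuple[PositionWeightMatrix, PositionWeightMatrix]:
    """The two planted motifs: an E-box-like ME motif and a GC-rich DEE
    motif (lengths follow config.motif_length, padded with the consensus)."""
    me = "CACATGTG"[: config.motif_length].ljust(config.motif_length, "T")
    dee = "GGCGCCAG"[: config.motif_length].ljust(config.motif_length, "C")
    return (
        _sharp_pwm(me, "ME_motif", tf_name="twi_like"),
        _sharp_pwm(dee, "DEE_motif", tf_name="mad_like"),
    )


def make_decoy_pwms(
    n: int, length: int, rng: np.random.Generator
) -> List[PositionWeightMatrix]:
    """Random sharp-consensus PWMs that are never planted."""
    out = []
    for i in range(n):
        consensus = "".join(BASES[j] for j in rng.integers(0, 4, size=length))
        out.append(_sharp_pwm(consensus, f"decoy_{i + 1:02d}"))
    return out


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: Dict[str, str]
    chrom_sizes: Dict[str, int]
    genes: List[GeneModel]
    truth: pd.DataFrame  # one row per candidate: summit, class, gene, motifs, TF truth
    candidate_peaks: List[PeakRecord]
    expression: List[ExpressionRecord]
    motifs: List[PositionWeightMatrix]  # planted first, then decoys
    conservation: Dict[str, np.ndarray] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def _sample_rng(self, assay: str, condition: str, replicate: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.config.seed, ASSAY_CODES[assay], COND_CODES.get(condition, 0), replicate]
        )

    def _fragments_to_reads(self, starts: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
        """Fragment start positions -> single-end reads sampled from a
        random fragment end, per the sequencing convention the fragment
        estimator assumes."""
        cfg = self.config
        L, R = cfg.fragment_length, cfg.read_length
        size = self.chrom_sizes[cfg.chrom_name]
        starts = np.clip(starts, 0, size - L)
        ends = starts + L
        plus = rng.random(len(starts)) < 0.5
        rs = np.where(plus, starts, ends - R)
        re_ = rs + R
        order = np.argsort(rs, kind="mergesort")
        return pd.DataFrame(
            {
                "chrom": cfg.chrom_name,
                "start": rs[order],
                "end": re_[order],
                "strand": np.where(plus, "+", "-")[order],
            }
        )

    def _background_starts(self, rate: float, rng: np.random.Generator) -> np.ndarray:
        size = self.chrom_sizes[self.config.chrom_name]
        n = rng.poisson(rate * size)
        return rng.integers(0, size, size=n)

    def simulate_chip_sample(
        self, assay: str, condition: str = "", replicate: int = 1
    ) -> pd.DataFrame:
        """Simulate one sample's aligned reads (tagAlign-style frame).

        assay is H3K27ac (requires condition), CBP, input, or one of the
        TFs Dl/Twi/Mad/Zen. Deterministic per (seed, assay, condition,
        replicate).
        """
        cfg = self.config
        if assay not in ASSAY_CODES:
            raise ValidationError(f"unknown assay {assay!r}")
        if assay == "H3K27ac" and condition not in (COND_A, COND_B):
            raise ValidationError("H3K27ac samples need a tissue condition")
        rng = self._sample_rng(assay, condition, replicate)
        summits = self.truth["summit"].to_numpy()
        frag_starts = [self._background_starts(cfg.background_per_bp, rng)]

        if assay == "H3K27ac":
            active = np.ones(len(summits))
            if condition == COND_A:
                active[self.truth["class"].to_numpy() == "ME"] = cfg.effect_fold
            else:
                active[self.truth["class"].to_numpy() == "DEE"] = cfg.effect_fold
            lam = cfg.signal_per_enhancer * active
            shape = 1.0 / cfg.dispersion
            gam = rng.gamma(shape, scale=1.0 / shape, size=len(lam))
            counts = rng.poisson(lam * gam)
            centers_summit = np.repeat(summits, counts).astype(float)
            side = np.where(rng.random(len(centers_summit)) < 0.5, 1.0, -1.0)
            centers = (
                centers_summit
                + side * cfg.flank_offset
                + rng.normal(0, cfg.flank_jitter_sd, size=len(centers_summit))
            )
            frag_starts.append(np.round(centers - cfg.fragment_length / 2).astype(np.int64))
        elif assay == "CBP":
            counts = rng.poisson(cfg.cbp_signal, size=len(summits))
            centers = np.repeat(summits, counts) + rng.normal(
                0, 40, size=int(counts.sum())
            )
            frag_starts.append(np.round(centers - cfg.fragment_length / 2).astype(np.int64))
        elif assay in ("Dl", "Twi", "Mad", "Zen"):
            bound = self.truth[f"{assay}_bound"].to_numpy()
            lam = np.where(bound, cfg.tf_signal, 0.0)
            counts = rng.poisson(lam)
            centers = np.repeat(summits, counts) + rng.normal(
                0, 40, size=int(counts.sum())
            )
            frag_starts.append(np.round(centers - cfg.fragment_length / 2).astype(np.int64))
        elif assay == "input":
            frag_starts = [self._background_starts(cfg.input_per_bp, rng)]

        starts = np.concatenate(frag_starts)
        if len(starts) == 0:
            raise ValidationError("simulated sample has zero fragments")
        return self._fragments_to_reads(starts, rng)

    def h3k27ac_samples(self) -> Dict[str, Tuple[str, pd.DataFrame]]:
        """All H3K27ac replicates: sample id -> (condition, reads)."""
        out = {}
        for cond, n in self.config.replicates.items():
            for r in range(1, n + 1):
                out[f"H3K27ac_{cond}_rep{r}"] = (
                    cond,
                    self.simulate_chip_sample("H3K27ac", cond, r),
                )
        return out

    def tf_peak_replicates(self, tf: str, n_replicates: int = 2) -> List[List[PeakRecord]]:
        """Truth-derived TF peak calls, one list per replicate; the first
        replicate detects more peaks (exercises replicate selection)."""
        cfg = self.config
        bound = self.truth[self.truth[f"{tf}_bound"]]
        reps = []
        for r in range(n_replicates):
            rng = np.random.default_rng([cfg.seed, ASSAY_CODES[tf], 90 + r])
            detect = rng.random(len(bound)) < (0.95 if r == 0 else 0.8)
            peaks = []
            for (_, row), keep in zip(bound.iterrows(), detect):
                if not keep:
                    continue
                s = int(row["summit"])
                peaks.append(
                    PeakRecord(
                        interval=GenomicInterval(cfg.chrom_name, s - 100, s + 101),
                        name=f"{tf}_{s}",
                        score=float(cfg.tf_signal * (1 + 0.2 * rng.standard_normal())),
                        summit=s,
                        enrichment=float(cfg.tf_signal / 5.0),
                    )
                )
            reps.append(peaks)
        return reps


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _layout(config: SyntheticConfig):
    """Deterministic genomic layout. Returns (blocks, nd_summits, extra)."""
    margin = 2000
    n_diff = config.n_me + config.n_dee
    n_special = config.n_tss_class + config.n_intragenic_class
    if n_special > config.n_nondiff:
        raise ValidationError("TSS/intragenic class counts exceed n_nondiff")
    if n_special > n_diff:
        raise ValidationError("need at least one gene block per special candidate")
    n_nd_slots = config.n_nondiff - n_special
    nd_width = 1000
    gene_tail = config.n_background_genes * 5000
    avail = config.genome_size - 2 * margin - n_nd_slots * nd_width - gene_tail
    b_diff = avail // n_diff if n_diff else 0
    if n_diff and b_diff < 5500:
        need = 2 * margin + n_nd_slots * nd_width + gene_tail + n_diff * 5500
        raise ValidationError(
            f"genome too small for requested elements; need >= {need} bp"
        )
    return margin, n_diff, n_nd_slots, nd_width, int(b_diff), gene_tail


def generate(config: Optional[SyntheticConfig] = None) -> SyntheticDataset:
    """Build the full synthetic dataset for a config (byte-reproducible
    under a fixed seed)."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng([cfg.seed, 7])
    margin, n_diff, n_nd_slots, nd_width, b_diff, gene_tail = _layout(cfg)
    chrom = cfg.chrom_name
    size = cfg.genome_size

    # --- background sequence
    seq_idx = rng.choice(4, size=size, p=list(cfg.base_probs)).astype(np.uint8)

    # --- differential blocks: alternating ME/DEE, each with an adjacent gene
    classes: List[str] = []
    summits: List[int] = []
    genes: List[GeneModel] = []
    gene_of: List[Optional[str]] = []
    for i in range(n_diff):
        cls = "ME" if i % 2 == 0 else "DEE"
        start = margin + i * b_diff
        s = start + 1200
        classes.append(cls)
        summits.append(s)
        gid = f"g_{cls}_{i + 1:03d}"
        genes.append(
            GeneModel(gene_id=gid, span=GenomicInterval(chrom, s + 2500, s + 4000, "+"))
        )
        gene_of.append(gid)

    # --- special nondiff candidates near/inside the first gene blocks
    for j in range(cfg.n_tss_class):
        tss = margin + j * b_diff + 1200 + 2500
        classes.append("nondiff")
        summits.append(tss + 400)  # < 1 kb from the TSS
        gene_of.append(None)
    for j in range(cfg.n_intragenic_class):
        tss = margin + (cfg.n_tss_class + j) * b_diff + 1200 + 2500
        classes.append("nondiff")
        summits.append(tss + 1200)  # inside the gene span, >= 1 kb from TSS
        gene_of.append(None)

    # --- distal nondiff slots
    nd_start = margin + n_diff * b_diff
    for j in range(n_nd_slots):
        classes.append("nondiff")
        summits.append(nd_start + j * nd_width + nd_width // 2)
        gene_of.append(None)

    # --- background genes in the tail (some silent)
    tail_start = nd_start + n_nd_slots * nd_width
    silent: Dict[str, bool] = {}
    for j in range(cfg.n_background_genes):
        gid = f"g_bg_{j + 1:03d}"
        s = tail_start + j * 5000 + 1000
        strand = "+" if j % 2 == 0 else "-"
        genes.append(GeneModel(gene_id=gid, span=GenomicInterval(chrom, s, s + 1500, strand)))
        silent[gid] = j < int(cfg.silent_fraction * cfg.n_background_genes)

    order = np.argsort(summits, kind="mergesort")
    classes = [classes[i] for i in order]
    summits = [summits[i] for i in order]
    gene_of = [gene_of[i] for i in order]

    # --- plant motifs in cores and record their positions
    me_pwm, dee_pwm = planted_motifs(cfg)
    decoys = make_decoy_pwms(cfg.n_decoy_motifs, cfg.motif_length, rng)
    motif_cols: Dict[str, List] = {
        "ME_motif_pos": [],
        "DEE_motif_pos": [],
    }
    mlen = cfg.motif_length
    for cls, s in zip(classes, summits):
        for pwm, col, matched_cls, half in (
            (me_pwm, "ME_motif_pos", "ME", 0),
            (dee_pwm, "DEE_motif_pos", "DEE", 1),
        ):
            prob = (
                cfg.plant_prob_matched if cls == matched_cls else cfg.plant_prob_background
            )
            if rng.random() < prob:
                # plant in the left or right half of the core so the two
                # motifs never overwrite each other
                lo = s - 100 + half * 100
                off = int(rng.integers(lo, lo + 100 - mlen))
                inst = [
                    int(rng.choice(4, p=pwm.matrix[k])) for k in range(mlen)
                ]
                seq_idx[off : off + mlen] = inst
                motif_cols[col].append(off)
            else:
                motif_cols[col].append(-1)

    # --- TF occupancy truth
    tf_truth: Dict[str, np.ndarray] = {}
    for tf, owner in (("Dl", "ME"), ("Twi", "ME"), ("Mad", "DEE"), ("Zen", "DEE")):
        p = cfg.tf_bound_prob[tf]
        tf_truth[f"{tf}_bound"] = np.array(
            [cls == owner and rng.random() < p for cls in classes]
        )

    truth = pd.DataFrame(
        {
            "summit": summits,
            "class": classes,
            "gene_id": [g if g else "" for g in gene_of],
            "true_fold": [cfg.effect_fold if c != "nondiff" else 1.0 for c in classes],
            "ME_motif_pos": motif_cols["ME_motif_pos"],
            "DEE_motif_pos": motif_cols["DEE_motif_pos"],
            **tf_truth,
        }
    )
    truth.index = [f"truth_{i + 1:05d}" for i in range(len(truth))]

    # --- candidate peaks (CBP-like, summit-annotated, enrichment >= 2)
    peaks = []
    for i, s in enumerate(summits):
        enr = float(2.5 + 5.5 * rng.random())
        peaks.append(
            PeakRecord(
                interval=GenomicInterval(chrom, s - 250, s + 251),
                name=f"peak_{i + 1:05d}",
                score=enr,
                summit=s,
                enrichment=enr,
            )
        )
    # a few sub-threshold peaks that standardization must drop
    for j in range(20):
        s = nd_start + j * nd_width  # slot boundaries, away from real summits
        peaks.append(
            PeakRecord(
                interval=GenomicInterval(chrom, s - 250, s + 251),
                name=f"weak_{j:02d}",
                score=1.5,
                summit=s,
                enrichment=1.5,
            )
        )

    # --- expression table
    expression = []
    pair = (COND_A, COND_B)
    for g in genes:
        base = cfg.baseline_fpkm * np.exp(
            rng.normal(0, cfg.expression_noise_sd)
        )
        if silent.get(g.gene_id, False):
            base = 1.0 * np.exp(rng.normal(0, cfg.expression_noise_sd))
        fold_a = fold_b = 1.0
        if g.gene_id.startswith("g_ME"):
            fold_a = cfg.expression_fold
        elif g.gene_id.startswith("g_DEE"):
            fold_b = cfg.expression_fold
        noise = np.exp(rng.normal(0, cfg.expression_noise_sd, size=3))
        fa, fb, fn = base * fold_a * noise[0], base * fold_b * noise[1], base * noise[2]
        true_l2 = np.log2(fold_a / fold_b)
        if true_l2 >= 1:
            call = f"up_in_{COND_A}"
        elif true_l2 <= -1:
            call = f"up_in_{COND_B}"
        else:
            call = "ns"
        expression.append(
            ExpressionRecord(
                gene_id=g.gene_id,
                fpkm_by_condition={COND_A: fa, COND_B: fb, COND_THIRD: fn},
                diff_call_by_pair={pair: call},
            )
        )
    # the planted motifs' TFs are expressed (so the FPKM>3 filter keeps them)
    for tf_gene in ("twi_like", "mad_like"):
        expression.append(
            ExpressionRecord(
                gene_id=tf_gene,
                fpkm_by_condition={COND_A: 12.0, COND_B: 12.0, COND_THIRD: 12.0},
                diff_call_by_pair={pair: "ns"},
            )
        )

    genome = {chrom: "".join(BASES[b] for b in seq_idx)}
    ds = SyntheticDataset(
        config=cfg,
        genome=genome,
        chrom_sizes={chrom: size},
        genes=genes,
        truth=truth,
        candidate_peaks=peaks,
        expression=expression,
        motifs=[me_pwm, dee_pwm] + decoys,
    )
    ds.conservation = simulate_conservation(ds, rng)
    return ds


def simulate_conservation(
    ds: SyntheticDataset, rng: Optional[np.random.Generator] = None
) -> Dict[str, np.ndarray]:
    """Per-base conservation: Beta baseline, + half bonus across 201-bp
    cores, + full bonus at planted motif bases (clamped to 1)."""
    cfg = ds.config
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 11])
    a, b = cfg.conservation_beta
    out = {}
    for chrom, size in ds.chrom_sizes.items():
        arr = rng.beta(a, b, size=size)
        for s in ds.truth["summit"]:
            arr[s - 100 : s + 101] += cfg.core_conservation_bonus
        for col in ("ME_motif_pos", "DEE_motif_pos"):
            for off in ds.truth[col]:
                if off >= 0:
                    arr[off : off + cfg.motif_length] += cfg.motif_conservation_bonus
        out[chrom] = np.clip(arr, 0.0, 1.0)
    return out


def core_sequences(ds: SyntheticDataset, summits: Sequence[int], width: int = 201) -> List[str]:
    chrom = ds.config.chrom_name
    seq = ds.genome[chrom]
    half = (width - 1) // 2
    return [seq[s - half : s - half + width] for s in summits]
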