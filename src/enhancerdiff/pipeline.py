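"""Pipeline orchestration: candidates -> counts -> differential ->
assignment -> motifs -> conservation -> validation.

Each stage is a pure function of its inputs, the parameter block, and the
seed; stage tables are written as TSVs into the output directory and the
log records parameters and per-stage region counts, so a rerun with an
identical configuration reproduces every output byte for byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import candidates as cand_mod
from . import confidence as conf_mod
from . import conservation as cons_mod
from . import coverage as cov_mod
from . import differential as diff_mod
from . import genes as genes_mod
from . import motifs as motif_mod
from .core import ExpressionRecord, GeneModel, GenomicInterval, PeakRecord, ValidationError
from .synthetic import COND_A, COND_B, COND_THIRD, SyntheticConfig, SyntheticDataset, core_sequences, generate

logger = logging.getLogger("enhancerdiff")

STAGES = (
    "candidates",
    "counts",
    "differential",
    "assignment",
    "motifs",
    "conservation",
    "validation",
)


@dataclass
class Parameters:
    """Numeric constants of the method, with their standard defaults."""

    window_width: int = 1000
    core_width: int = 201
    min_peak_fold: float = 2.0
    q_cutoff: float = 0.01
    min_fpkm_active: float = 5.0  # gene assignment (inclusive)
    min_fpkm_tf: float = 3.0  # motif TF expression filter (strict)
    motif_p_threshold: float = 1e-4
    motif_overlap_frac: float = 0.10
    n_random_regions: int = 5000
    top_n_tf_peaks: int = 400
    metapeak_smooth_bp: int = 31
    metapeak_flank: int = 1000
    tss_distance: int = 1000
    dl_min_fold: float = 3.0
    twi_min_fold: float = 5.0
    mad_min_fold: float = 3.0
    zen_min_fold: float = 3.0


@dataclass
class PipelineInputs:
    """Everything the stages consume, already in memory."""

    chrom_sizes: Dict[str, int]
    peaks: List[PeakRecord]
    reads_by_sample: Dict[str, pd.DataFrame]  # H3K27ac replicates
    conditions: Dict[str, str]  # sample id -> condition
    fragment_length: int
    genes: List[GeneModel]
    expression: List[ExpressionRecord]
    condition_pair: Tuple[str, str]
    genome: Optional[Dict[str, str]] = None
    motif_pwms: List = field(default_factory=list)
    conservation: Optional[Dict[str, np.ndarray]] = None
    tf_tracks: Dict[str, cov_mod.EnrichmentTrack] = field(default_factory=dict)
    known_enhancers: List[GenomicInterval] = field(default_factory=list)
    third_condition: Optional[str] = None


class Pipeline:
    """Runs the stages in order, caching results and writing stage TSVs."""

    def __init__(
        self,
        inputs: PipelineInputs,
        params: Optional[Parameters] = None,
        outdir: Optional[Path] = None,
        seed: int = 0,
    ):
        self.inputs = inputs
        self.params = params or Parameters()
        self.outdir = Path(outdir) if outdir else None
        self.seed = seed
        self.results: Dict[str, object] = {}
        self.stage_counts: Dict[str, int] = {}
        if self.outdir:
            self.outdir.mkdir(parents=True, exist_ok=True)

    # -- helpers ---------------------------------------------------------
    def _write(self, name: str, df: pd.DataFrame) -> None:
        if self.outdir:
            df.to_csv(self.outdir / f"{name}.tsv", sep="\t", index=True)

    # -- stages ----------------------------------------------------------
    def stage_candidates(self) -> List[cand_mod.CandidateRegion]:
        p = self.params
        regions = cand_mod.standardize_peaks(
            self.inputs.peaks,
            self.inputs.chrom_sizes,
            min_fold=p.min_peak_fold,
            core_width=p.core_width,
            window_width=p.window_width,
        )
        regions = cand_mod.classify_all(
            regions, self.inputs.genes, tss_distance=p.tss_distance
        )
        self.results["candidates"] = regions
        self.stage_counts["candidates"] = len(regions)
        self._write(
            "candidates",
            pd.DataFrame(
                {
                    "id": [r.id for r in regions],
                    "chrom": [r.chrom for r in regions],
                    "summit": [r.summit for r in regions],
                    "core_start": [r.core.start for r in regions],
                    "core_end": [r.core.end for r in regions],
                    "window_start": [r.window.start for r in regions],
                    "window_end": [r.window.end for r in regions],
                    "enrichment": [r.source_enrichment for r in regions],
                    "location_class": [r.location_class for r in regions],
                }
            ).set_index("id"),
        )
        return regions

    def stage_counts_matrix(self) -> diff_mod.CountMatrix:
        regions = self.results["candidates"]
        fragments = {
            s: cov_mod.extend_reads(df, self.inputs.fragment_length, self.inputs.chrom_sizes)
            for s, df in self.inputs.reads_by_sample.items()
        }
        cm = diff_mod.count_in_windows(fragments, regions, self.inputs.conditions)
        self.results["counts"] = cm
        self.stage_counts["counts"] = int(cm.counts.to_numpy().sum())
        self._write("counts", cm.counts)
        return cm

    def stage_differential(self) -> pd.DataFrame:
        cm = self.results["counts"]
        a, b = self.inputs.condition_pair
        res = diff_mod.differential_analysis(cm, a, b, alpha=self.params.q_cutoff)
        self.results["differential"] = res
        self.stage_counts["ME"] = int((res["call"] == diff_mod.CALL_ME).sum())
        self.stage_counts["DEE"] = int((res["call"] == diff_mod.CALL_DEE).sum())
        self._write("differential", res)
        return res

    def stage_assignment(self) -> pd.DataFrame:
        regions = self.results["candidates"]
        res = self.results["differential"]
        active = genes_mod.active_genes(
            self.inputs.expression,
            self.inputs.condition_pair,
            min_fpkm=self.params.min_fpkm_active,
        )
        if not active:
            logger.warning("no active genes; skipping assignment")
            self.results["assignment"] = ({}, [])
            return pd.DataFrame()
        assignments = genes_mod.assign_nearest(regions, self.inputs.genes, active)
        calls = res["call"].to_dict()
        named = genes_mod.name_enhancers(regions, calls, assignments)
        self.results["assignment"] = (assignments, named)
        self.stage_counts["named_enhancers"] = len(named)
        region_by_id = {r.id: r for r in regions}
        master = pd.DataFrame(
            {
                "name": [n.name for n in named],
                "region_id": [n.region_id for n in named],
                "gene": [n.gene_id for n in named],
                "type": [n.enhancer_type for n in named],
                "chrom": [region_by_id[n.region_id].chrom for n in named],
                "core_start": [region_by_id[n.region_id].core.start for n in named],
                "core_end": [region_by_id[n.region_id].core.end for n in named],
                "log2fc": [res.loc[n.region_id, "log2fc"] for n in named],
                "q": [res.loc[n.region_id, "q"] for n in named],
            }
        ).set_index("name")
        self._write("enhancers", master)
        self.results["master"] = master
        return master

    def stage_motifs(self):
        if self.inputs.genome is None or not self.inputs.motif_pwms:
            logger.warning("no genome/motifs supplied; skipping motif stage")
            return None
        p = self.params
        regions = self.results["candidates"]
        res = self.results["differential"]
        calls = res["call"]
        fpkm = {
            r.gene_id: r.max_fpkm(self.inputs.condition_pair)
            for r in self.inputs.expression
        }
        pwms = motif_mod.filter_motifs_by_expression(
            self.inputs.motif_pwms, fpkm, min_fpkm=p.min_fpkm_tf
        )
        chrom_seqs = self.inputs.genome
        seqs = {
            r.id: chrom_seqs[r.chrom][r.core.start : r.core.end] for r in regions
        }
        background = motif_mod.build_background(list(chrom_seqs.values()), order=0)
        hits = motif_mod.scan_regions(pwms, seqs, background, p.motif_p_threshold)
        test_ids = [r.id for r in regions if calls[r.id] != diff_mod.CALL_NONDIFF]
        ctrl_ids = [r.id for r in regions if calls[r.id] == diff_mod.CALL_NONDIFF]
        pres = motif_mod.presence_matrix(hits, [r.id for r in regions])
        enr = motif_mod.enrichment_test(pres.loc[test_ids], pres.loc[ctrl_ids])
        sig = [r for r in enr if np.isfinite(r.q) and r.q < p.q_cutoff]
        groups = motif_mod.collapse_motifs(
            sig, hits, {m.motif_id: len(m) for m in pwms}, p.motif_overlap_frac
        )
        self.results["motifs"] = {
            "hits": hits,
            "enrichment": enr,
            "groups": groups,
            "background": background,
            "pwms": pwms,
        }
        self.stage_counts["significant_motifs"] = len(sig)
        self._write(
            "motif_enrichment",
            pd.DataFrame(
                [
                    {
                        "motif_id": r.motif_id,
                        "direction": r.direction,
                        "test_with": r.test_with,
                        "test_total": r.test_total,
                        "control_with": r.control_with,
                        "control_total": r.control_total,
                        "p": r.p,
                        "q": r.q,
                    }
                    for r in enr
                ]
            ).set_index("motif_id"),
        )
        return self.results["motifs"]

    def stage_conservation(self):
        if self.inputs.conservation is None:
            logger.warning("no conservation track; skipping stage")
            return None
        p = self.params
        regions = self.results["candidates"]
        calls = self.results["differential"]["call"]
        enh = [r for r in regions if calls[r.id] != diff_mod.CALL_NONDIFF]
        rng = np.random.default_rng([self.seed, 23])
        random_regions = cand_mod.sample_random_non_tss(
            self.inputs.chrom_sizes,
            self.inputs.genes,
            n=p.n_random_regions,
            width=p.core_width,
            rng=rng,
            tss_distance=p.tss_distance,
        )
        comp = cons_mod.enhancers_vs_random_conservation(
            [r.core for r in enh], random_regions, self.inputs.conservation
        )
        rows = [
            {
                "comparison": "enhancers_vs_random",
                "motif_id": "",
                "mean_a": comp.mean_a,
                "mean_b": comp.mean_b,
                "p": comp.p,
            }
        ]
        motif_comps = {}
        motifs = self.results.get("motifs")
        if motifs:
            for motif_id, hits in motifs["hits"].items():
                length = next(
                    (len(m) for m in motifs["pwms"] if m.motif_id == motif_id), None
                )
                if length is None:
                    continue
                mc = cons_mod.motif_vs_enhancer_conservation(
                    enh, hits, length, self.inputs.conservation
                )
                motif_comps[motif_id] = mc
                rows.append(
                    {
                        "comparison": "motif_vs_enhancer",
                        "motif_id": motif_id,
                        "mean_a": mc.mean_a,
                        "mean_b": mc.mean_b,
                        "p": mc.p,
                    }
                )
        self.results["conservation"] = {
            "enhancers_vs_random": comp,
            "per_motif": motif_comps,
        }
        self._write("conservation", pd.DataFrame(rows).set_index("comparison"))
        return self.results["conservation"]

    def stage_validation(self):
        p = self.params
        regions = self.results["candidates"]
        res = self.results["differential"]
        calls = res["call"].to_dict()
        assignments, _named = self.results.get("assignment", ({}, []))
        out: Dict[str, object] = {}
        test = [r for r in regions if calls[r.id] != diff_mod.CALL_NONDIFF]
        ctrl = [r for r in regions if calls[r.id] == diff_mod.CALL_NONDIFF]
        if assignments and test and ctrl:
            frac_t, frac_c, pval = genes_mod.concordance_test(
                test,
                ctrl,
                calls,
                assignments,
                self.inputs.expression,
                self.inputs.condition_pair,
                rank=1,
            )
            out["concordance"] = {
                "frac_test": frac_t,
                "frac_control": frac_c,
                "p": pval,
            }
        if self.inputs.tf_tracks:
            tf_enr: Dict[str, Dict[str, float]] = {}
            for tf, track in self.inputs.tf_tracks.items():
                recs = conf_mod.tf_enrichment_at(test, track, tf, p.core_width)
                tf_enr[tf] = {r.enhancer_id: r.enrichment for r in recs}
            assigned_gene = {
                rid: alist[0].gene_id for rid, alist in assignments.items() if alist
            }
            groups = conf_mod.assign_confidence_groups(
                test,
                calls,
                tf_enr,
                assigned_gene,
                self.inputs.expression,
                self.inputs.condition_pair,
                known_enhancers=self.inputs.known_enhancers,
                third_condition=self.inputs.third_condition,
                dl_min=p.dl_min_fold,
                twi_min=p.twi_min_fold,
                mad_min=p.mad_min_fold,
                zen_min=p.zen_min_fold,
            )
            out["tf_enrichment"] = tf_enr
            out["confidence_groups"] = groups
            self._write(
                "confidence",
                pd.DataFrame(
                    [
                        {
                            "enhancer_id": g.enhancer_id,
                            "group": g.group,
                            "exclusion_reason": g.exclusion_reason or "",
                            **{
                                tf: tf_enr[tf].get(g.enhancer_id, np.nan)
                                for tf in tf_enr
                            },
                        }
                        for g in groups
                    ]
                ).set_index("enhancer_id"),
            )
            self.stage_counts["confidence_grouped"] = sum(
                1 for g in groups if g.group != "unassigned"
            )
        self.results["validation"] = out
        return out

    # -- driver ----------------------------------------------------------
    def run(self, stages: Optional[Sequence[str]] = None) -> Dict[str, object]:
        stages = list(stages) if stages else list(STAGES)
        if stages != list(STAGES[: len(stages)]):
            raise ValidationError(
                f"stages must be a prefix of {STAGES}, got {stages}"
            )
        dispatch = {
            "candidates": self.stage_candidates,
            "counts": self.stage_counts_matrix,
            "differential": self.stage_differential,
            "assignment": self.stage_assignment,
            "motifs": self.stage_motifs,
            "conservation": self.stage_conservation,
            "validation": self.stage_validation,
        }
        for s in stages:
            logger.info("stage %s", s)
            dispatch[s]()
        if self.outdir:
            with open(self.outdir / "pipeline_log.json", "w") as fh:
                json.dump(
                    {
                        "parameters": asdict(self.params),
                        "seed": self.seed,
                        "stage_counts": self.stage_counts,
                    },
                    fh,
                    indent=2,
                )
        return self.results


# ---------------------------------------------------------------------------
# File-based inputs
# ---------------------------------------------------------------------------

def inputs_from_manifest(path) -> PipelineInputs:
    """Build pipeline inputs from a YAML manifest of on-disk files.

    Expected keys: ``chrom_sizes`` (name -> bp), ``fragment_length``,
    ``condition_pair`` ([A, B]), ``peaks`` (narrowPeak path), ``gtf``,
    ``expression`` (TSV), ``samples`` (list of {path, condition,
    replicate} tagAlign H3K27ac entries) and optionally ``genome``
    (FASTA), ``motifs`` (MEME), ``conservation`` (WIG/bedGraph),
    ``known_enhancers`` (BED6), ``third_condition``, ``aliases``.
    """
    import yaml

    from . import io as io_mod
    from .motifs import read_meme

    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    required = ["chrom_sizes", "fragment_length", "condition_pair", "peaks", "gtf", "expression", "samples"]
    missing = [k for k in required if k not in spec]
    if missing:
        raise ValidationError(f"manifest missing keys: {missing}")
    pair = tuple(spec["condition_pair"])
    if len(pair) != 2:
        raise ValidationError("condition_pair must name exactly two conditions")
    aliases = spec.get("aliases")
    conditions = {}
    reads = {}
    for s in spec["samples"]:
        sid = f"H3K27ac_{s['condition']}_rep{s['replicate']}"
        reads[sid] = io_mod.read_reads_frame(resolve(s["path"]), aliases)
        conditions[sid] = s["condition"]
    if set(conditions.values()) != set(pair):
        raise ValidationError(
            f"samples cover conditions {sorted(set(conditions.values()))}, "
            f"manifest pair is {sorted(pair)}"
        )
    exp_conditions = list(pair) + (
        [spec["third_condition"]] if spec.get("third_condition") else []
    )
    chrom_sizes = dict(spec["chrom_sizes"])
    return PipelineInputs(
        chrom_sizes=chrom_sizes,
        peaks=io_mod.read_intervals(resolve(spec["peaks"]), "narrowPeak", aliases),
        reads_by_sample=reads,
        conditions=conditions,
        fragment_length=int(spec["fragment_length"]),
        genes=io_mod.read_gene_models(resolve(spec["gtf"]), aliases),
        expression=io_mod.read_expression_table(resolve(spec["expression"]), exp_conditions),
        condition_pair=pair,
        genome=io_mod.read_fasta(resolve(spec["genome"])) if spec.get("genome") else None,
        motif_pwms=read_meme(resolve(spec["motifs"])) if spec.get("motifs") else [],
        conservation=(
            io_mod.read_wig_scores(resolve(spec["conservation"]), chrom_sizes, aliases)
            if spec.get("conservation")
            else None
        ),
        known_enhancers=(
            [p.interval for p in io_mod.read_intervals(resolve(spec["known_enhancers"]), "bed6", aliases)]
            if spec.get("known_enhancers")
            else []
        ),
        third_condition=spec.get("third_condition"),
    )


# ---------------------------------------------------------------------------
# Synthetic end-to-end
# ---------------------------------------------------------------------------

def inputs_from_synthetic(ds: SyntheticDataset, with_tf_tracks: bool = True) -> PipelineInputs:
    """Wire a generated dataset into pipeline inputs."""
    samples = ds.h3k27ac_samples()
    reads = {sid: df for sid, (cond, df) in samples.items()}
    conditions = {sid: cond for sid, (cond, df) in samples.items()}
    tf_tracks = {}
    if with_tf_tracks:
        input_reads = ds.simulate_chip_sample("input")
        input_cov = cov_mod.coverage_from_reads(
            input_reads, ds.config.fragment_length, ds.chrom_sizes
        )
        for tf in ("Dl", "Twi", "Mad", "Zen"):
            ip = cov_mod.coverage_from_reads(
                ds.simulate_chip_sample(tf),
                ds.config.fragment_length,
                ds.chrom_sizes,
            )
            tf_tracks[tf] = cov_mod.EnrichmentTrack(ip, input_cov)
    return PipelineInputs(
        chrom_sizes=ds.chrom_sizes,
        peaks=ds.candidate_peaks,
        reads_by_sample=reads,
        conditions=conditions,
        fragment_length=ds.config.fragment_length,
        genes=ds.genes,
        expression=ds.expression,
        condition_pair=(COND_A, COND_B),
        genome=ds.genome,
        motif_pwms=ds.motifs,
        conservation=ds.conservation,
        tf_tracks=tf_tracks,
        third_condition=COND_THIRD,
    )


def recovery_metrics(
    ds: SyntheticDataset,
    regions: Sequence[cand_mod.CandidateRegion],
    results: pd.DataFrame,
) -> Dict[str, float]:
    """Sensitivity and empirical FDR of ME/DEE calls against the planted
    truth (matched by summit position)."""
    truth_by_summit = dict(zip(ds.truth["summit"], ds.truth["class"]))
    tp = fp = fn = 0
    n_true = int((ds.truth["class"] != "nondiff").sum())
    for r in regions:
        true_cls = truth_by_summit.get(r.summit, "nondiff")
        call = results.loc[r.id, "call"]
        if call in (diff_mod.CALL_ME, diff_mod.CALL_DEE):
            if call == true_cls:
                tp += 1
            else:
                fp += 1
    fn = n_true - tp
    n_called = tp + fp
    return {
        "sensitivity": tp / n_true if n_true else float("nan"),
        "fdr": fp / n_called if n_called else 0.0,
        "n_called": float(n_called),
        "n_true": float(n_true),
    }


def run_synthetic(
    config: Optional[SyntheticConfig] = None,
    params: Optional[Parameters] = None,
    outdir: Optional[Path] = None,
    stages: Optional[Sequence[str]] = None,
    with_tf_tracks: bool = True,
) -> Tuple[SyntheticDataset, Pipeline, Dict[str, float]]:
    """Generate a dataset, run the pipeline, and score recovery vs truth."""
    cfg = config or SyntheticConfig()
    ds = generate(cfg)
    pipe = Pipeline(
        inputs_from_synthetic(ds, with_tf_tracks=with_tf_tracks),
        params=params,
        outdir=outdir,
        seed=cfg.seed,
    )
    pipe.run(stages)
    if "differential" not in pipe.results:
        return ds, pipe, {}
    metrics = recovery_metrics(ds, pipe.results["candidates"], pipe.results["differential"])
    if outdir:
        with open(Path(outdir) / "recovery.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
    return ds, pipe, metrics
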