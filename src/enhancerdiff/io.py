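"""Readers and writers for the external formats the pipeline touches.

BED-family formats are native 0-based half-open; GTF (1-based inclusive)
and WIG (1-based) are converted here and only here. Chromosome name
matching is exact string match, optionally routed through an alias table
(e.g. ``{"chr2L": "2L"}``) to absorb dialect drift.
"""
from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionRecord,
    GeneModel,
    GenomicInterval,
    ParseError,
    PeakRecord,
    ReadRecord,
    ValidationError,
)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLUMNS = BED6_COLUMNS + ["signalValue", "pValue", "qValue", "peak"]


def apply_aliases(chrom: str, aliases: Optional[Mapping[str, str]]) -> str:
    if aliases:
        return aliases.get(chrom, chrom)
    return chrom


# ---------------------------------------------------------------------------
# BED-family interval records
# ---------------------------------------------------------------------------

def _split_line(line: str, n_min: int, lineno: int, path: str) -> List[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < n_min:
        raise ParseError(
            f"{path}:{lineno}: expected >= {n_min} tab-separated fields, "
            f"got {len(fields)}"
        )
    return fields


def read_intervals(path, format: str, aliases: Optional[Mapping[str, str]] = None):
    """Read interval records from a BED-family file.

    ``format`` is one of ``bed6``, ``narrowPeak``, ``tagAlign``. narrowPeak
    summit offsets are converted to absolute positions. Input order is
    preserved. Malformed lines raise :class:`ParseError` naming the line.
    """
    path = str(path)
    if format not in ("bed6", "narrowPeak", "tagAlign"):
        raise ValueError(f"unknown interval format {format!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            try:
                if format == "narrowPeak":
                    f = _split_line(line, 10, lineno, path)
                    start, end = int(f[1]), int(f[2])
                    iv = GenomicInterval(apply_aliases(f[0], aliases), start, end, f[5])
                    offset = int(f[9])
                    summit = None
                    if offset >= 0:
                        if offset >= end - start:
                            raise ValidationError(
                                f"summit offset {offset} >= width {end - start}"
                            )
                        summit = start + offset
                    records.append(
                        PeakRecord(
                            interval=iv,
                            name=f[3],
                            score=float(f[4]),
                            summit=summit,
                            enrichment=float(f[6]),
                            pvalue=float(f[7]),
                            qvalue=float(f[8]),
                        )
                    )
                elif format == "bed6":
                    f = _split_line(line, 6, lineno, path)
                    iv = GenomicInterval(
                        apply_aliases(f[0], aliases), int(f[1]), int(f[2]), f[5]
                    )
                    records.append(PeakRecord(interval=iv, name=f[3], score=float(f[4])))
                else:  # tagAlign: bed6 with sequence/quality in cols 4-5
                    f = _split_line(line, 6, lineno, path)
                    iv = GenomicInterval(
                        apply_aliases(f[0], aliases), int(f[1]), int(f[2]), f[5]
                    )
                    records.append(ReadRecord(interval=iv))
            except (ValueError, ValidationError) as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_intervals(records, path, format: str) -> None:
    """Write records back out; inverse of :func:`read_intervals`."""
    path = str(path)
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            if format == "narrowPeak":
                offset = -1 if rec.summit is None else rec.summit - iv.start
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            str(iv.start),
                            str(iv.end),
                            rec.name,
                            _fmt_score(rec.score),
                            iv.strand,
                            _fmt_float(rec.enrichment),
                            _fmt_float(rec.pvalue),
                            _fmt_float(rec.qvalue),
                            str(offset),
                        ]
                    )
                    + "\n"
                )
            elif format == "bed6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t"
                    f"{_fmt_score(rec.score)}\t{iv.strand}\n"
                )
            elif format == "tagAlign":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tN\t1000\t{iv.strand}\n")
            else:
                raise ValueError(f"unknown interval format {format!r}")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _fmt_float(x: Optional[float]) -> str:
    if x is None:
        return "-1"
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# Bulk read tables (fast path for millions of aligned reads)
# ---------------------------------------------------------------------------

def read_reads_frame(path, aliases: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Read a tagAlign/BED6 file of aligned reads into a DataFrame with
    columns chrom/start/end/strand. Vectorized; use for full samples."""
    df = pd.read_csv(
        str(path),
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        comment="#",
    )
    if aliases:
        df["chrom"] = df["chrom"].map(lambda c: aliases.get(c, c))
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        raise ValidationError(
            f"{path}: {int(bad.sum())} reads with invalid coordinates "
            f"(first at data row {int(np.flatnonzero(bad)[0]) + 1})"
        )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"{path}: reads must have +/- strand")
    return df


def write_reads_frame(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["name"] = "N"
    out["score"] = 1000
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        str(path), sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str, lineno: int, path: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) == 2:
            out[parts[0]] = parts[1].strip().strip('"')
    return out


def read_gene_models(gtf_path, aliases: Optional[Mapping[str, str]] = None) -> List[GeneModel]:
    """Read gene models from a GTF file.

    Produces one :class:`GeneModel` per ``gene_id``: the span is the union
    over all its features, converted from GTF's 1-based inclusive
    coordinates to the internal 0-based half-open convention, and the TSS
    follows the strand rule (span start on +, span end - 1 on -).
    """
    gtf_path = str(gtf_path)
    spans: Dict[str, List] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{gtf_path}:{lineno}: expected 9 GTF fields")
            attrs = _parse_gtf_attributes(f[8], lineno, gtf_path)
            if "gene_id" not in attrs:
                raise ParseError(f"{gtf_path}:{lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            chrom = apply_aliases(f[0], aliases)
            start = int(f[3]) - 1  # GTF 1-based inclusive -> 0-based half-open
            end = int(f[4])
            strand = f[6]
            if gid not in spans:
                spans[gid] = [chrom, start, end, strand]
            else:
                rec = spans[gid]
                if rec[0] != chrom or rec[3] != strand:
                    raise ParseError(
                        f"{gtf_path}:{lineno}: gene {gid} features on multiple "
                        "chromosomes/strands"
                    )
                rec[1] = min(rec[1], start)
                rec[2] = max(rec[2], end)
    return [
        GeneModel(gene_id=gid, span=GenomicInterval(c, s, e, strand))
        for gid, (c, s, e, strand) in spans.items()
    ]


def write_gene_models_gtf(genes: Sequence[GeneModel], path, source: str = "enhancerdiff") -> None:
    """Write gene models as single-feature GTF lines (inverse of the reader
    for union spans)."""
    with open(str(path), "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.span.chrom,
                        source,
                        "gene",
                        str(g.span.start + 1),
                        str(g.span.end),
                        ".",
                        g.span.strand,
                        ".",
                        f'gene_id "{g.gene_id}";',
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(tsv_path, conditions: Sequence[str]) -> List[ExpressionRecord]:
    """Read a per-gene expression table.

    Expected header: ``gene_id``, one ``fpkm_<condition>`` column per
    condition, and optionally ``diff_<A>_vs_<B>`` columns holding
    ``up_in_<A>`` / ``up_in_<B>`` / ``ns`` calls (differential expression is
    consumed, never recomputed).
    """
    df = pd.read_csv(str(tsv_path), sep="\t", dtype=str)
    required = ["gene_id"] + [f"fpkm_{c}" for c in conditions]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{tsv_path}: missing required columns {missing}")
    diff_cols = [c for c in df.columns if c.startswith("diff_")]
    records: List[ExpressionRecord] = []
    for i, row in df.iterrows():
        fpkm = {}
        for c in conditions:
            val = float(row[f"fpkm_{c}"])
            if val < 0:
                raise ValidationError(
                    f"{tsv_path}: gene {row['gene_id']}: negative FPKM {val}"
                )
            fpkm[c] = val
        calls = {}
        for col in diff_cols:
            pair = tuple(col[len("diff_"):].split("_vs_"))
            if len(pair) != 2:
                raise ValidationError(f"{tsv_path}: malformed diff column {col!r}")
            call = str(row[col])
            allowed = {f"up_in_{pair[0]}", f"up_in_{pair[1]}", "ns"}
            if call not in allowed:
                raise ValidationError(
                    f"{tsv_path}: gene {row['gene_id']}: call {call!r} not in {sorted(allowed)}"
                )
            calls[pair] = call
        records.append(
            ExpressionRecord(
                gene_id=str(row["gene_id"]),
                fpkm_by_condition=fpkm,
                diff_call_by_pair=calls,
            )
        )
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path, conditions: Sequence[str]) -> None:
    rows = []
    pairs = set()
    records = list(records)
    for r in records:
        pairs.update(r.diff_call_by_pair)
    pairs = sorted(pairs)
    for r in records:
        row = {"gene_id": r.gene_id}
        for c in conditions:
            row[f"fpkm_{c}"] = r.fpkm_by_condition.get(c, 0.0)
        for p in pairs:
            row[f"diff_{p[0]}_vs_{p[1]}"] = r.diff_call_by_pair.get(p, "ns")
        rows.append(row)
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Conservation score tracks (fixedStep WIG / bedGraph)
# ---------------------------------------------------------------------------

def read_wig_scores(
    path,
    chrom_sizes: Optional[Mapping[str, int]] = None,
    aliases: Optional[Mapping[str, str]] = None,
) -> Dict[str, np.ndarray]:
    """Read per-base scores in [0, 1] from fixedStep WIG or bedGraph.

    Returns per-chromosome float arrays with NaN at bases the file does not
    cover; downstream averaging excludes NaN bases. WIG coordinates are
    1-based and converted here.
    """
    path = str(path)
    chunks: Dict[str, List] = {}  # chrom -> list of (start0, values array)
    maxend: Dict[str, int] = {}

    def add(chrom, start0, values):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return
        if np.any((values < 0) | (values > 1)):
            bad = values[(values < 0) | (values > 1)][0]
            raise ValidationError(f"{path}: score {bad} outside [0, 1]")
        chunks.setdefault(chrom, []).append((start0, values))
        maxend[chrom] = max(maxend.get(chrom, 0), start0 + values.size)

    with open(path) as fh:
        mode = None
        chrom = None
        pos0 = step = span = None
        buf: List[float] = []
        first_data = None

        def flush_fixed():
            nonlocal buf
            if buf and chrom is not None:
                if span == 1 and step == 1:
                    add(chrom, first_data, buf)
                else:
                    for i, v in enumerate(buf):
                        add(chrom, first_data + i * step, [v] * span)
            buf = []

        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                flush_fixed()
                mode = "fixed"
                params = dict(kv.split("=") for kv in line.split()[1:])
                chrom = apply_aliases(params["chrom"], aliases)
                pos0 = int(params["start"]) - 1  # WIG is 1-based
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                if span > step:
                    raise ValidationError(
                        f"{path}:{lineno}: span {span} > step {step}"
                    )
                first_data = pos0
                continue
            if line.startswith("variableStep"):
                raise ValidationError(f"{path}:{lineno}: variableStep unsupported")
            f = line.split("\t") if "\t" in line else line.split()
            if mode == "fixed" and len(f) == 1:
                buf.append(float(f[0]))
            elif len(f) == 4:  # bedGraph
                flush_fixed()
                mode = "bedgraph"
                c = apply_aliases(f[0], aliases)
                s, e = int(f[1]), int(f[2])
                if s >= e:
                    raise ParseError(f"{path}:{lineno}: empty bedGraph interval")
                add(c, s, [float(f[3])] * (e - s))
            else:
                raise ParseError(f"{path}:{lineno}: unrecognized line {line!r}")
        flush_fixed()

    out: Dict[str, np.ndarray] = {}
    for c, parts in chunks.items():
        size = maxend[c]
        if chrom_sizes and c in chrom_sizes:
            size = max(size, chrom_sizes[c])
        arr = np.full(size, np.nan)
        seen = np.zeros(size, dtype=bool)
        for start0, values in parts:
            sl = slice(start0, start0 + values.size)
            if np.any(seen[sl]):
                raise ValidationError(f"{path}: overlapping intervals on {c}")
            arr[sl] = values
            seen[sl] = True
        out[c] = arr
    return out


def write_wig_fixedstep(scores: Mapping[str, np.ndarray], path) -> None:
    """Write dense per-base scores as fixedStep WIG (NaN runs are omitted)."""
    with open(str(path), "w") as fh:
        for chrom in scores:
            arr = np.asarray(scores[chrom], dtype=float)
            defined = ~np.isnan(arr)
            if not defined.any():
                continue
            # contiguous defined runs, vectorized
            d = defined.astype(np.int8)
            starts = np.flatnonzero(np.diff(np.r_[0, d]) == 1)
            ends = np.flatnonzero(np.diff(np.r_[d, 0]) == -1) + 1
            for s, e in zip(starts, ends):
                fh.write(f"fixedStep chrom={chrom} start={s + 1} step=1\n")
                fh.write("\n".join(format(v, ".4g") for v in arr[s:e]) + "\n")


# ---------------------------------------------------------------------------
# FASTA (synthetic genomes are small; kept fully in memory)
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    seqs: Dict[str, List[str]] = {}
    name = None
    with open(str(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(str(path), "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
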