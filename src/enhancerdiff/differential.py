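"""Negative-binomial differential testing of H3K27ac counts in candidate
windows.

Fragments from each replicate of two tissues are counted in the 1-kb
window around every candidate summit. Counts are modelled as negative
binomial with per-sample size factors (median-of-ratios), per-region
dispersions (method-of-moments, shrunk toward a mean-dispersion trend),
and a Wald test on the log2 fold change between tissues. Regions passing
the Benjamini-Hochberg threshold (default q < 0.01) are called enhancers
of the tissue with higher acetylation: ME (mesoderm-like, condition A up)
or DEE (dorsal-ectoderm-like, condition B up).

This is a deliberately transparent, documented pipeline: the scientific
contribution it supports is the windowed differential design, so the
statistics favour auditability (closed-form moments, explicit shrinkage)
over the full machinery of general-purpose count-model packages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .candidates import CandidateRegion
from .core import ValidationError

LN2 = np.log(2.0)

CALL_ME = "ME"
CALL_DEE = "DEE"
CALL_NONDIFF = "non_differential"


@dataclass
class CountMatrix:
    """Integer fragment counts, regions x samples, with sample metadata."""

    counts: pd.DataFrame  # index: region ids, columns: sample ids
    conditions: pd.Series  # sample id -> condition label

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValidationError("region ids must be unique")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.issubdtype(vals.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")
        conds = self.conditions.loc[self.counts.columns]
        if conds.nunique() < 2:
            raise ValidationError("need samples from two conditions")
        if (conds.value_counts() < 1).any():
            raise ValidationError("each condition needs >= 1 replicate")

    def condition_columns(self, condition: str) -> List[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


def count_in_windows(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    windows: Sequence[CandidateRegion],
    conditions: Mapping[str, str],
) -> CountMatrix:
    """Count fragments overlapping each candidate window (>= 1 bp,
    half-open intervals; a fragment spanning two windows counts in both).
    """
    region_ids = [w.id for w in windows]
    data = {}
    for sample, frags in fragments_by_sample.items():
        if len(frags) == 0:
            raise ValidationError(f"sample {sample} has zero fragments")
        col = np.zeros(len(windows), dtype=np.int64)
        for chrom, sub in frags.groupby("chrom", sort=False):
            starts = np.sort(sub["start"].to_numpy())
            ends = np.sort(sub["end"].to_numpy())
            idx = [i for i, w in enumerate(windows) if w.chrom == chrom]
            if not idx:
                continue
            ws = np.array([windows[i].window.start for i in idx])
            we = np.array([windows[i].window.end for i in idx])
            # overlap iff fragment start < window end and fragment end > window start
            n_start_before_end = np.searchsorted(starts, we, side="left")
            n_end_before_start = np.searchsorted(ends, ws, side="right")
            col[idx] = n_start_before_end - n_end_before_start
        data[sample] = col
    counts = pd.DataFrame(data, index=region_ids)
    return CountMatrix(counts=counts, conditions=pd.Series(dict(conditions)))


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each region present in all samples (no zero count), compute the
    ratio of each sample's count to the region's geometric mean; the
    factor is the per-sample median of those ratios. Falls back to
    total-count ratios (normalized to geometric mean 1) when no region is
    all-nonzero.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        warnings.warn(
            "no region with nonzero counts in every sample; falling back "
            "to total-count size factors"
        )
        totals = mat.sum(axis=0)
        if np.any(totals == 0):
            raise ValidationError("sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns)
    sub = mat[all_nonzero]
    log_gm = np.mean(np.log(sub), axis=1)
    log_ratios = np.log(sub) - log_gm[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns)


def _normalized(counts: pd.DataFrame, size_factors: pd.Series) -> np.ndarray:
    return counts.to_numpy(dtype=float) / size_factors.loc[counts.columns].to_numpy()


def _fit_trend(mu: np.ndarray, alpha: np.ndarray) -> Tuple[float, float]:
    X = np.column_stack([1.0 / mu, np.ones_like(mu)])
    coef, *_ = np.linalg.lstsq(X, alpha, rcond=None)
    return max(float(coef[0]), 0.0), max(float(coef[1]), 1e-8)


def estimate_dispersions(
    cm: CountMatrix,
    size_factors: pd.Series,
    d0: float = 2.0,
) -> pd.Series:
    """Per-region NB dispersion alpha, trend-shrunk.

    Raw method-of-moments estimate on normalized counts, within condition:
    for each condition c, alpha_c = (s_c^2 - mu_c)/mu_c^2, combined across
    conditions with df weights, clipped at 0. A mean-dispersion trend
    alpha_tr(mu) = a0/mu + a1 is fitted across regions (least squares with
    one outlier-trimming pass), and each region's estimate is shrunk
    toward the trend on the log scale with weight w = d/(d + d0), d =
    residual degrees of freedom. With the few replicates typical of ChIP
    designs, downward deviations of alpha_hat from the trend are sampling
    noise, so the shrunk estimate is floored at the trend value; only
    excess dispersion above the trend is retained (partially). All-zero
    regions get NaN (untestable).
    """
    counts = cm.counts
    norm = _normalized(counts, size_factors)
    conds = cm.conditions.loc[counts.columns].to_numpy()
    uniq = pd.unique(conds)
    n_samples = norm.shape[1]
    d = n_samples - len(uniq)  # residual df
    if d < 0 or n_samples < 2:
        raise ValidationError("need >= 2 samples to estimate dispersion")

    grand_mean = norm.mean(axis=1)
    alpha_num = np.zeros(norm.shape[0])
    for c in uniq:
        cols = conds == c
        n_c = int(cols.sum())
        if n_c < 2:
            continue
        sub = norm[:, cols]
        mu_c = sub.mean(axis=1)
        s2_c = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_c = np.where(mu_c > 0, (s2_c - mu_c) / mu_c**2, 0.0)
        alpha_num += (n_c - 1) * a_c
    with np.errstate(invalid="ignore"):
        alpha_hat = alpha_num / d if d > 0 else np.full(norm.shape[0], np.nan)
    alpha_hat = np.where(grand_mean > 0, np.maximum(alpha_hat, 0.0), np.nan)

    ok = np.isfinite(alpha_hat) & (grand_mean > 0)
    mu_ok = grand_mean[ok]
    a_ok = alpha_hat[ok]
    # least-squares fit of alpha ~ a0/mu + a1, with one trimming pass to
    # guard the fit against the heavy right tail of the MoM estimates
    if ok.sum() >= 10 and d > 0:
        a0, a1 = _fit_trend(mu_ok, a_ok)
        trend0 = a0 / mu_ok + a1
        keep = a_ok <= 4.0 * trend0
        if keep.sum() >= 10:
            a0, a1 = _fit_trend(mu_ok[keep], a_ok[keep])
    else:  # too few regions for a trend: use the global mean dispersion
        a0 = 0.0
        a1 = max(float(np.nanmean(a_ok)) if len(a_ok) else 1e-8, 1e-8)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_tr = np.where(grand_mean > 0, a0 / grand_mean + a1, np.nan)
    w = d / (d + d0) if d > 0 else 0.0
    alpha_plus = np.maximum(alpha_hat, 1e-8)
    with np.errstate(invalid="ignore"):
        final = np.exp(w * np.log(alpha_plus) + (1 - w) * np.log(alpha_tr))
        final = np.maximum(final, alpha_tr)  # downward deviations are noise
    final = np.where(grand_mean > 0, final, np.nan)
    return pd.Series(final, index=counts.index)


def wald_test(
    cm: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    condition_a: str,
    condition_b: str,
) -> pd.DataFrame:
    """Wald test of log2(mu_A / mu_B) under the NB model.

    Condition means are means of normalized counts; a +0.5 pseudocount is
    applied (to both means) only when one condition mean is zero. The
    standard error comes from the delta method on log2 of an NB mean:
    se^2 = (1/ln2)^2 * [1/(n_A mu_A) + alpha/n_A + 1/(n_B mu_B) + alpha/n_B].
    Untestable regions (all-zero, NaN dispersion) get NaN p-values.
    """
    counts = cm.counts
    norm = _normalized(counts, size_factors)
    conds = cm.conditions.loc[counts.columns].to_numpy()
    in_a = conds == condition_a
    in_b = conds == condition_b
    if not in_a.any() or not in_b.any():
        raise ValidationError(
            f"conditions {condition_a!r}/{condition_b!r} not both present"
        )
    n_a, n_b = int(in_a.sum()), int(in_b.sum())
    mu_a = norm[:, in_a].mean(axis=1)
    mu_b = norm[:, in_b].mean(axis=1)
    base_mean = norm.mean(axis=1)
    alpha = dispersions.loc[counts.index].to_numpy()

    zero_mean = (mu_a == 0) | (mu_b == 0)
    mu_a_eff = np.where(zero_mean, mu_a + 0.5, mu_a)
    mu_b_eff = np.where(zero_mean, mu_b + 0.5, mu_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mu_a_eff / mu_b_eff)
        se2 = (1 / LN2) ** 2 * (
            1 / (n_a * mu_a_eff)
            + alpha / n_a
            + 1 / (n_b * mu_b_eff)
            + alpha / n_b
        )
        se = np.sqrt(se2)
        z = log2fc / se
        p = 2 * stats.norm.sf(np.abs(z))
    untestable = ~np.isfinite(alpha) | (base_mean == 0)
    p = np.where(untestable, np.nan, p)
    log2fc = np.where(base_mean == 0, np.nan, log2fc)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
        },
        index=counts.index,
    )


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; NaN entries are
    preserved and excluded from m.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


def call_enhancers(results: pd.DataFrame, alpha: float = 0.01) -> pd.Series:
    """Call ME (A-up), DEE (B-up), or non_differential at q < alpha.

    Non-differential regions are retained downstream as the control group.
    """
    q = results["q"].to_numpy()
    lfc = results["log2fc"].to_numpy()
    call = np.full(len(results), CALL_NONDIFF, dtype=object)
    with np.errstate(invalid="ignore"):
        call[(q < alpha) & (lfc > 0)] = CALL_ME
        call[(q < alpha) & (lfc < 0)] = CALL_DEE
    return pd.Series(call, index=results.index, name="call")


def differential_analysis(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.01,
    min_base_mean: float = 0.0,
) -> pd.DataFrame:
    """Full pipeline: size factors, dispersions, Wald test, BH, calls.

    ``min_base_mean`` > 0 enables independent filtering: regions below the
    threshold are excluded from multiple testing (q = NaN). Off by default.
    """
    sf = estimate_size_factors(cm.counts)
    disp = estimate_dispersions(cm, sf)
    res = wald_test(cm, sf, disp, condition_a, condition_b)
    p_for_bh = res["p"].to_numpy().copy()
    if min_base_mean > 0:
        p_for_bh[res["baseMean"].to_numpy() < min_base_mean] = np.nan
    res["q"] = adjust_bh(p_for_bh)
    res["call"] = call_enhancers(res, alpha=alpha)
    res.attrs["size_factors"] = sf
    res.attrs["dispersions"] = disp
    return res
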