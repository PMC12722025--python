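"""Region-gene transcriptional-coordination screen and set enrichment.

For every pair of a transcribed intergenic region and its transcribed
nearest gene, abundance across samples is compared by Spearman rank
correlation (plus a least-squares slope on log2-normalized values).
P-values are Benjamini-Hochberg adjusted over the whole screen and pairs
are classified positive / negative / ns at an FDR threshold.  A preranked,
permutation-based set-enrichment statistic (weighted Kolmogorov-Smirnov
running sum) is provided for downstream gene lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def spearman_pair(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (Pearson of midranks) and two-sided t-approximation p.

    Returns (NaN, 1.0) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4 or len(x) != len(y):
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, 1.0
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_pairs(
    gene_norm: pd.DataFrame,
    region_norm: pd.DataFrame,
    links: pd.DataFrame,
    gene_transcribed: pd.Series | None = None,
    region_transcribed: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Coordination screen over all transcribed region-gene linked pairs.

    ``gene_norm`` and ``region_norm`` are size-factor-normalized abundance
    matrices (features x samples) over an identical, identically ordered
    sample set.  Correlations use log2(normalized + 1).  The result has one
    row per pair with rho, slope, p, BH-adjusted p and a sign call
    (positive / negative / ns) at ``padj < alpha``.
    """
    if list(gene_norm.columns) != list(region_norm.columns):
        raise ValueError("gene and region matrices must share the same ordered samples")

    glog = np.log2(gene_norm + 1.0)
    rlog = np.log2(region_norm + 1.0)
    rows = []
    for row in links.itertuples(index=False):
        rid, gid = row.region_id, row.gene_id
        if rid not in rlog.index or gid not in glog.index:
            continue
        if region_transcribed is not None and not bool(region_transcribed.get(rid, False)):
            continue
        if gene_transcribed is not None and not bool(gene_transcribed.get(gid, False)):
            continue
        x = rlog.loc[rid].to_numpy()
        y = glog.loc[gid].to_numpy()
        rho, p = spearman_pair(x, y)
        slope = float(np.polyfit(x, y, 1)[0]) if np.ptp(x) > 0 else math.nan
        rows.append((rid, gid, rho, slope, p))
    res = pd.DataFrame(rows, columns=["region_id", "gene_id", "rho", "slope", "p"])
    if res.empty:
        res["padj"] = []
        res["sign"] = []
        return res
    res["padj"] = bh_adjust(res["p"].to_numpy())
    sign = np.where(
        (res["padj"] < alpha) & (res["rho"] > 0),
        "positive",
        np.where((res["padj"] < alpha) & (res["rho"] < 0), "negative", "ns"),
    )
    res["sign"] = sign
    return res


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    fdr: float
    n_perm: int


def _running_sum_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed extreme of the weighted KS running sum over a ranked list."""
    n = len(in_set)
    k = int(in_set.sum())
    if k == 0 or k == n:
        return 0.0
    w = weights * in_set
    w_sum = w.sum()
    hit_step = w / w_sum if w_sum > 0 else in_set / k
    miss_step = (~in_set.astype(bool)).astype(float) / (n - k)
    running = np.cumsum(hit_step - miss_step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_set_enrichment(
    scores: pd.Series,
    gene_set: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Preranked set enrichment by weighted KS running sum with label permutations.

    ``scores`` maps each gene in the universe to a ranking score (sorted
    internally, descending).  Hits advance the running sum by
    |score|^weight_exponent (normalized over the set); misses retreat it
    uniformly.  ES is the signed extreme of the running sum.  The null is
    built from ``n_perm`` permutations of set membership over the ranked
    labels; NES divides ES by the mean |ES| of same-sign permutation
    values, and FDR is the fraction of same-sign permutation NES at least
    as extreme.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    missing = gene_set - set(scores.index)
    if missing:
        raise ValueError(f"{len(missing)} set members absent from the ranked universe")
    rng = np.random.default_rng(seed)
    ranked = scores.sort_values(ascending=False, kind="stable")
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    in_set = np.array([g in gene_set for g in ranked.index], dtype=float)
    es = _running_sum_es(in_set, weights)

    k = int(in_set.sum())
    n = len(in_set)
    perm_es = np.empty(n_perm)
    base = np.zeros(n)
    base[:k] = 1.0
    for i in range(n_perm):
        perm = rng.permutation(base)
        perm_es[i] = _running_sum_es(perm, weights)

    same_sign = perm_es[perm_es * es > 0] if es != 0 else perm_es
    denom = float(np.mean(np.abs(same_sign))) if len(same_sign) else float(np.mean(np.abs(perm_es)) or 1.0)
    nes = es / denom if denom > 0 else 0.0
    if es == 0:
        fdr = 1.0
    else:
        perm_nes = same_sign / denom if denom > 0 else same_sign
        fdr = float(np.mean(np.abs(perm_nes) >= abs(nes))) if len(same_sign) else 1.0
    return EnrichmentResult(
        set_name=",".join(sorted(gene_set)) if len(gene_set) <= 3 else f"set(n={len(gene_set)})",
        es=es,
        nes=float(nes),
        fdr=min(1.0, fdr),
        n_perm=n_perm,
    )
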