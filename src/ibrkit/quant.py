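"""Count-matrix handling: QC filters, normalization, selection, rank tests.

Implements the quantification conventions used throughout the pipeline:
samples with <50% mapped reads are dropped, outlier samples are flagged
once by low mean inter-sample correlation, features count as transcribed
with >=1 read in >=3 samples, per-sample size factors follow the
median-of-ratios rule (rescaled to geometric mean 1), and two-group
comparisons use the Wilcoxon rank-sum test with a rank-biserial effect
size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with lazy size factors."""

    counts: pd.DataFrame  # features x samples, integer >= 0
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(np.int64))

    def write_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("feature_id").to_csv(path, sep="\t")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def normalized(self) -> pd.DataFrame:
        """Counts divided by per-sample size factors (computed on demand)."""
        if self.size_factors is None:
            self.size_factors = size_factors_median_of_ratios(self)
        return self.counts / self.size_factors

    def subset(self, features=None, samples=None) -> "CountMatrix":
        df = self.counts
        if features is not None:
            df = df.loc[features]
        if samples is not None:
            df = df[samples]
        return CountMatrix(df)


def filter_low_mapped(
    counts: CountMatrix | pd.DataFrame,
    mapped_fraction: pd.Series,
    threshold: float = 0.5,
) -> CountMatrix:
    """Drop samples whose mapped-read fraction is below ``threshold``."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    keep = [s for s in df.columns if mapped_fraction[s] >= threshold]
    if not keep:
        raise ValueError("all samples fall below the mapped-fraction threshold")
    dropped = set(df.columns) - set(keep)
    if dropped:
        logger.info("dropped %d low-mapped samples: %s", len(dropped), sorted(dropped))
    return CountMatrix(df[keep])


def detect_outlier_samples(m: CountMatrix, k: float = 2.0) -> pd.DataFrame:
    """Flag outlier samples by weak mean inter-sample correlation.

    Pearson correlation is computed between samples on log2(count+1); a
    sample is an outlier iff its mean off-diagonal correlation falls more
    than ``k`` standard deviations below the mean of those means.  Applied
    once, without iteration.  Returns a QC frame with columns
    ``mean_corr`` and ``outlier`` indexed by sample.
    """
    if m.counts.shape[1] < 4:
        raise ValueError("outlier detection needs at least 4 samples")
    log = np.log2(m.counts.to_numpy(dtype=float) + 1.0)
    corr = np.corrcoef(log.T)
    corr = np.nan_to_num(corr, nan=0.0)  # constant samples correlate with nothing
    n = corr.shape[0]
    mean_corr = (corr.sum(axis=1) - np.diag(corr)) / (n - 1)
    mu, sd = mean_corr.mean(), mean_corr.std(ddof=1)
    outlier = mean_corr < mu - k * sd if sd > 0 else np.zeros(n, dtype=bool)
    return pd.DataFrame(
        {"mean_corr": mean_corr, "outlier": outlier}, index=m.counts.columns
    )


def filter_expressed(
    m: CountMatrix, min_reads: int = 1, min_samples: int = 3
) -> tuple[CountMatrix, pd.Series]:
    """Transcribed-feature filter: >= ``min_reads`` in >= ``min_samples`` samples.

    Returns the retained matrix and the per-feature boolean ``transcribed``
    flag over all input features.
    """
    flags = (m.counts >= min_reads).sum(axis=1) >= min_samples
    return CountMatrix(m.counts[flags]), flags


def size_factors_median_of_ratios(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each feature with nonzero counts in every sample, the ratio of the
    sample's count to the feature's geometric mean is formed; the
    per-sample factor is the median of those ratios.  Falls back to
    upper-quartile factors (with a warning) when no feature is nonzero in
    all samples.
    """
    x = m.counts.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if all_nonzero.any():
        rows = x[all_nonzero]
        geomean = np.exp(np.log(rows).mean(axis=1))
        factors = np.median(rows / geomean[:, None], axis=0)
    else:
        logger.warning(
            "no feature with nonzero counts in all samples; "
            "falling back to upper-quartile size factors"
        )
        uq = np.array([np.percentile(col[col > 0], 75) if (col > 0).any() else 1.0 for col in x.T])
        factors = uq
    # rescale to geometric mean 1 so normalized values share a common scale
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def mean_normalized_abundance(m: CountMatrix) -> pd.Series:
    """Per-feature mean of size-factor-normalized counts across samples."""
    return m.normalized().mean(axis=1).rename("mean_abundance")


def select_highly_variable(m: CountMatrix, n: int = 500) -> list[str]:
    """Top-``n`` features by variance of log2(normalized + 1).

    Constant features (zero variance) are excluded before ranking; ties
    break by feature_id so selection is deterministic.
    """
    if n > m.counts.shape[0]:
        raise ValueError("n exceeds feature count")
    log = np.log2(m.normalized() + 1.0)
    var = log.var(axis=1, ddof=1)
    var = var[var > 0]
    order = sorted(var.index, key=lambda f: (-var[f], f))
    return order[:n]


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumeration of group labels.

    Enumerates all C(n+m, n) assignments of the pooled values to group x,
    so ties are handled exactly.  Intended for n+m <= 16.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    obs = ranks[:n].sum()
    mean_w = ranks.sum() * n / len(pooled)
    obs_dev = abs(obs - mean_w)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean_w) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p and rank-biserial effect size.

    The p-value is exact (full enumeration, tie-safe) when n+m <= 16 and a
    normal approximation with tie and continuity corrections otherwise.
    The effect size is ``1 - 2U/(n*m)`` where U counts (x > y) pairs with
    half-weight ties: +1 when every x lies below every y, -1 for the
    reverse, 0 for identical distributions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    # U for x: number of (x_i > y_j) pairs, ties counted 1/2
    u_stat = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[0])
    es = 1.0 - 2.0 * u_stat / (n * m)
    if n + m <= 16:
        p = _rank_sum_exact_p(x, y)
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            )[1]
        )
    return p, float(es)
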