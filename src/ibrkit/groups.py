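"""Six-group transcription/linkage classification and abundance strata.

Every gene receives a 3-bit code: first digit gene transcription status,
second digit whether any linked intergenic RNAPII-bound region is
transcribed, third digit whether the gene is linked to such a region at
all.  A transcribed linked region implies linkage, so only six of the
eight codes can occur (000, 001, 011, 100, 101, 111).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CODES = ("000", "001", "011", "100", "101", "111")
STRATA = ("low", "below-average", "average", "above-average", "high")


def classify_gene_groups(
    gene_ids: Sequence[str],
    links: pd.DataFrame,
    gene_transcribed: Mapping[str, bool],
    region_transcribed: Mapping[str, bool],
    nearest_only: bool = False,
) -> pd.Series:
    """Assign each gene its 3-bit transcription/linkage group code.

    Parameters
    ----------
    gene_ids
        All genes to classify.
    links
        Link table with ``region_id, gene_id`` (and ``signed_distance``
        when ``nearest_only`` is used).
    gene_transcribed, region_transcribed
        Boolean transcription flags by id.  Flags for region ids absent
        from the link table are ignored with a warning.
    nearest_only
        When True the second digit reflects only the linked region closest
        to the TSS, instead of any linked region.

    Returns
    -------
    Series of codes (one of :data:`VALID_CODES`), indexed by gene_id.
    """
    if "region_id" not in links.columns:
        links = pd.DataFrame(columns=["region_id", "gene_id", "signed_distance"])
    linked_ids = set(links["region_id"])
    stray = set(region_transcribed) - linked_ids
    if stray:
        logger.warning(
            "%d region transcription flags refer to unlinked region ids; ignored",
            len(stray),
        )

    if nearest_only:
        lk = links.copy()
        lk["absdist"] = lk["signed_distance"].abs()
        lk = lk.sort_values(["absdist", "region_id"]).drop_duplicates("gene_id")
    else:
        lk = links
    any_t = (
        lk.assign(rt=lk["region_id"].map(lambda r: bool(region_transcribed.get(r, False))))
        .groupby("gene_id")["rt"]
        .any()
    )
    linked_genes = set(links["gene_id"])

    codes = []
    for gid in gene_ids:
        d1 = int(bool(gene_transcribed.get(gid, False)))
        d3 = int(gid in linked_genes)
        d2 = int(bool(any_t.get(gid, False))) if d3 else 0
        codes.append(f"{d1}{d2}{d3}")
    out = pd.Series(codes, index=list(gene_ids), name="group_code")
    bad = set(out.unique()) - set(VALID_CODES)
    assert not bad, f"invalid group codes produced: {bad}"
    return out


def group_summary(codes: pd.Series) -> pd.DataFrame:
    """Group sizes and percentages over all six codes (zeros included)."""
    n = len(codes)
    rows = []
    for code in VALID_CODES:
        k = int((codes == code).sum())
        rows.append({"code": code, "n": k, "pct": 100.0 * k / n if n else 0.0})
    return pd.DataFrame(rows).set_index("code")


def quantile_stratify(scores: pd.Series, k: int = 5) -> pd.Series:
    """Rank-based quantile strata of a per-feature abundance score.

    Features are ordered by score with stable tie-breaking in input
    (feature_id) order, then split into ``k`` near-equal bins at the
    empirical quantiles.  With k=5 the strata are labelled low,
    below-average, average, above-average, high.  Bin sizes differ by at
    most one even when many values tie (e.g. zeros).
    """
    n = len(scores)
    if n < k:
        raise ValueError(f"need at least {k} values to form {k} strata")
    order = np.argsort(scores.to_numpy(), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    bins = (ranks * k) // n
    labels = STRATA if k == 5 else tuple(f"q{i + 1}" for i in range(k))
    return pd.Series(
        pd.Categorical.from_codes(bins, categories=list(labels), ordered=True),
        index=scores.index,
        name="stratum",
    )
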