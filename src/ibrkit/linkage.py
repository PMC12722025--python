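"""Region-to-gene linkage and catalog-overlap enrichment.

Each intergenic RNAPII-bound region is assigned to the gene whose TSS is
closest to the region's center on the same chromosome; the signed distance
is negative upstream of the gene (strand-aware).  Overlap of the region set
with external cis-regulatory-element catalogs is scored by coverage,
Fisher's exact test against a placement-matched shuffled control, and a
permutation z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneRecord, merge_intervals

logger = logging.getLogger(__name__)

QWINDOW_HALF = 500  # the 1-kb quantification window spans center +/- 500


@dataclass
class RegionRecord:
    """One intergenic RNAPII-bound region (0-based half-open coordinates)."""

    region_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.region_id}: start must be < end")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def qwindow(self) -> tuple[int, int]:
        """1-kb quantification window centered on the region center."""
        return (self.center - QWINDOW_HALF, self.center + QWINDOW_HALF)


@dataclass
class OverlapResult:
    """Overlap of a region set with one catalog of intervals."""

    catalog: str
    n_catalog: int
    n_catalog_hit: int
    n_regions: int
    n_regions_hit: int
    coverage_pct: float
    fisher_p: float
    perm_z: float


def read_bed(path: str | Path, prefix: str = "region") -> list[RegionRecord]:
    """Read BED3+ intervals (0-based half-open) into RegionRecords.

    The 4th column is used as the region id when present, else ids are
    generated as ``{prefix}_{i}``.
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: BED line {i + 1} has fewer than 3 columns")
            rid = parts[3] if len(parts) > 3 and parts[3] != "." else f"{prefix}_{i}"
            out.append(RegionRecord(rid, parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(regions: Sequence[RegionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def assign_nearest_gene(
    regions: Sequence[RegionRecord], genes: Sequence[GeneRecord]
) -> pd.DataFrame:
    """Link every region to the gene with the nearest TSS on its chromosome.

    Nearness is ``|center - tss|``.  Ties are broken by smaller gene start,
    then lexicographic gene_id, so assignment is deterministic.  The signed
    distance follows gene orientation: ``center - tss`` for + strand genes
    and ``tss - center`` for - strand genes, so negative values always mean
    upstream of the gene.  Regions on chromosomes without genes are dropped
    with a warning.

    Returns
    -------
    DataFrame with columns ``region_id, gene_id, signed_distance`` (the link
    table), one row per assignable region.
    """
    if not genes:
        raise ValueError("empty gene set")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    # sort genes by (tss, start, gene_id) so searchsorted neighbours respect tie-breaks
    chrom_arrays = {}
    for chrom, gs in by_chrom.items():
        gs_sorted = sorted(gs, key=lambda g: (g.tss, g.start, g.gene_id))
        chrom_arrays[chrom] = (np.array([g.tss for g in gs_sorted]), gs_sorted)

    rows = []
    for r in regions:
        if r.chrom not in chrom_arrays:
            logger.warning("region %s: no genes on chromosome %s; dropped", r.region_id, r.chrom)
            continue
        tss_arr, gs_sorted = chrom_arrays[r.chrom]
        i = int(np.searchsorted(tss_arr, r.center))
        # nearest |center - tss| is attained at one of the two flanking TSSs
        cand = [j for j in (i - 1, i) if 0 <= j < len(gs_sorted)]
        dmin = min(abs(r.center - tss_arr[j]) for j in cand)
        # collect every gene at exactly dmin so ties break deterministically
        left = int(np.searchsorted(tss_arr, r.center - dmin, side="left"))
        right = int(np.searchsorted(tss_arr, r.center + dmin, side="right"))
        best = None
        best_key = None
        for j in range(left, right):
            g = gs_sorted[j]
            d = abs(r.center - g.tss)
            key = (d, g.start, g.gene_id)
            if best is None or key < best_key:
                best, best_key = g, key
        signed = r.center - best.tss if best.strand == "+" else best.tss - r.center
        rows.append((r.region_id, best.gene_id, int(signed)))
    return pd.DataFrame(rows, columns=["region_id", "gene_id", "signed_distance"])


def link_summary(links: pd.DataFrame, genes: Sequence[GeneRecord]) -> dict:
    """Per-gene linked-region counts and the linked/unlinked partition.

    Returns a dict with ``counts`` (Series indexed by gene_id, 0 for
    unlinked genes), ``linked`` (boolean Series), and the mean/SD of region
    counts over linked genes.
    """
    tally = links.groupby("gene_id").size()
    gene_ids = [g.gene_id for g in genes]
    counts = pd.Series([int(tally.get(gid, 0)) for gid in gene_ids], index=gene_ids)
    linked = counts > 0
    linked_counts = counts[linked]
    return {
        "counts": counts,
        "linked": linked,
        "n_linked": int(linked.sum()),
        "mean_regions_per_linked_gene": float(linked_counts.mean()) if linked.any() else 0.0,
        "sd_regions_per_linked_gene": float(linked_counts.std(ddof=1))
        if linked.sum() > 1
        else 0.0,
    }


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _interval_hits(
    intervals: np.ndarray, catalog_starts: np.ndarray, catalog_ends: np.ndarray
) -> np.ndarray:
    """Boolean: does each [s,e) interval overlap any merged catalog interval by >=1 bp?

    Catalog intervals must be disjoint and sorted.
    """
    if len(catalog_starts) == 0:
        return np.zeros(len(intervals), dtype=bool)
    s, e = intervals[:, 0], intervals[:, 1]
    # the catalog interval with the greatest start < e is the only candidate
    idx = np.searchsorted(catalog_starts, e, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(len(intervals), dtype=bool)
    hit[ok] = catalog_ends[idx[ok]] > s[ok]
    return hit


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    merged = merge_intervals(list(zip(starts.tolist(), ends.tolist())))
    if not merged:
        return np.array([], dtype=int), np.array([], dtype=int)
    arr = np.array(merged)
    return arr[:, 0], arr[:, 1]


def catalog_overlap(
    regions: Sequence[RegionRecord],
    catalog: Sequence[RegionRecord],
    chrom_sizes: Mapping[str, int],
    name: str = "catalog",
    n_shuffles: int = 100,
    seed: int = 0,
) -> OverlapResult:
    """Overlap of the region set with one catalog.

    A region *hits* iff it overlaps any catalog interval by >= 1 bp (the
    catalog is merged first so nested entries are not double-counted).
    ``fisher_p`` comes from the 2x2 table of hit/no-hit counts in the real
    regions versus one length- and chromosome-matched shuffle; ``perm_z``
    standardises the real hit count against ``n_shuffles`` such shuffles.
    """
    rng = np.random.default_rng(seed)
    by_chrom_cat: dict[str, list[tuple[int, int]]] = {}
    for c in catalog:
        by_chrom_cat.setdefault(c.chrom, []).append((c.start, c.end))
    merged_cat = {}
    for chrom, ivs in by_chrom_cat.items():
        arr = np.array(merge_intervals(ivs))
        merged_cat[chrom] = (arr[:, 0], arr[:, 1])

    def hits_of(region_arrs: Mapping[str, np.ndarray]) -> int:
        n = 0
        for chrom, arr in region_arrs.items():
            if chrom not in merged_cat or len(arr) == 0:
                continue
            cs, ce = merged_cat[chrom]
            n += int(_interval_hits(arr, cs, ce).sum())
        return n

    real_arrs: dict[str, list[list[int]]] = {}
    for r in regions:
        real_arrs.setdefault(r.chrom, []).append([r.start, r.end])
    real_np = {c: np.array(v) for c, v in real_arrs.items()}

    n_regions = len(regions)
    n_hit = hits_of(real_np)

    def shuffle_once() -> dict[str, np.ndarray]:
        out = {}
        for chrom, arr in real_np.items():
            lens = arr[:, 1] - arr[:, 0]
            size = chrom_sizes[chrom]
            starts = rng.integers(0, np.maximum(1, size - lens))
            out[chrom] = np.column_stack([starts, starts + lens])
        return out

    shuffle_hits = np.array([hits_of(shuffle_once()) for _ in range(n_shuffles)])
    ctrl_hit = int(shuffle_hits[0]) if n_shuffles else 0
    fisher_p = fisher_exact_2x2(n_hit, n_regions - n_hit, ctrl_hit, n_regions - ctrl_hit)
    sd = float(shuffle_hits.std(ddof=1)) if n_shuffles > 1 else 0.0
    perm_z = (n_hit - float(shuffle_hits.mean())) / sd if sd > 0 else _degenerate_z(n_hit, shuffle_hits)

    # catalog entries hit by >=1 region (merged regions for the scan)
    n_cat_hit = 0
    merged_regions = {c: _merge_arrays(v[:, 0], v[:, 1]) for c, v in real_np.items()}
    for c in catalog:
        if c.chrom in merged_regions:
            rs, re = merged_regions[c.chrom]
            if len(rs) and _interval_hits(np.array([[c.start, c.end]]), rs, re)[0]:
                n_cat_hit += 1

    return OverlapResult(
        catalog=name,
        n_catalog=len(catalog),
        n_catalog_hit=n_cat_hit,
        n_regions=n_regions,
        n_regions_hit=n_hit,
        coverage_pct=100.0 * n_hit / n_regions if n_regions else 0.0,
        fisher_p=fisher_p,
        perm_z=float(perm_z),
    )


def _degenerate_z(n_hit: int, shuffle_hits: np.ndarray) -> float:
    """z fallback when shuffled hit counts have zero spread."""
    diff = n_hit - float(shuffle_hits.mean()) if len(shuffle_hits) else 0.0
    if diff == 0:
        return 0.0
    return float(np.inf) if diff > 0 else float(-np.inf)


def overlap_report(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """Catalog-overlap table (one row per catalog)."""
    return pd.DataFrame(
        [
            {
                "dataset": r.catalog,
                "n_catalog": r.n_catalog,
                "catalog_hits": r.n_catalog_hit,
                "region_hits": r.n_regions_hit,
                "coverage_pct": r.coverage_pct,
                "fisher_p": r.fisher_p,
                "perm_z": r.perm_z,
            }
            for r in results
        ]
    )
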