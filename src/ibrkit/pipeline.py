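"""End-to-end pipeline: annotation -> linkage -> quantification -> groups ->
TSS-relative profile -> coordination screen, with optional catalog-overlap
and motif stages, and a summary report of headline counts and percentages.

Every percentage in the report is 100 * numerator / denominator of counts
that are themselves present in the report, rounded half-up to two decimals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotation, coordination, groups, linkage, profile, quant

logger = logging.getLogger(__name__)


def pct(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to 2 decimals (0.0 for an empty denominator)."""
    if denominator == 0:
        return 0.0
    val = Decimal(100 * numerator) / Decimal(denominator)
    return float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    gtf: str | Path = ""
    regions_bed: str | Path = ""
    gene_counts: str | Path = ""
    region_counts: str | Path = ""
    fasta: str | Path | None = None
    regulator_table: str | Path | None = None
    catalogs: dict[str, str] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    out_dir: str | Path | None = None
    seed: int = 0
    # stage parameters (module defaults)
    min_reads: int = 1
    min_samples: int = 3
    outlier_sd: float = 2.0
    hvf_n: int = 500
    window: int = profile.DEFAULT_WINDOW
    n_bins: int = profile.DEFAULT_N_BINS
    alpha: float = 0.05
    nearest_only: bool = False


@dataclass
class PipelineResult:
    genes: list
    regions: list
    links: pd.DataFrame
    gene_matrix: quant.CountMatrix
    region_matrix: quant.CountMatrix
    gene_transcribed: pd.Series
    region_transcribed: pd.Series
    codes: pd.Series
    spatial: profile.SpatialProfile
    peaks: list
    pairs: pd.DataFrame
    overlaps: pd.DataFrame | None
    report: dict


def _summary_report(res: "PipelineResult", seed: int) -> dict:
    n_genes = len(res.genes)
    n_regions = len(res.regions)
    linked = res.links.groupby("gene_id").size()
    n_linked = int((linked > 0).sum())
    n_gene_tr = int(res.gene_transcribed.sum())
    n_region_tr = int(res.region_transcribed.sum())

    # genes linked to >=1 transcribed region, split by own transcription
    tr_regions = set(res.region_transcribed.index[res.region_transcribed])
    genes_with_tr_region = set(
        res.links.loc[res.links["region_id"].isin(tr_regions), "gene_id"]
    )
    cotr = sum(1 for g in genes_with_tr_region if res.gene_transcribed.get(g, False))
    n_assoc = len(genes_with_tr_region)

    sig = res.pairs[res.pairs["sign"] != "ns"] if len(res.pairs) else res.pairs
    group_sizes = groups.group_summary(res.codes)

    report = {
        "seed": seed,
        "n_genes": n_genes,
        "n_regions": n_regions,
        "n_linked_genes": n_linked,
        "linked_gene_pct": pct(n_linked, n_genes),
        "unlinked_gene_pct": pct(n_genes - n_linked, n_genes),
        "n_transcribed_genes": n_gene_tr,
        "transcribed_gene_pct": pct(n_gene_tr, n_genes),
        "n_transcribed_regions": n_region_tr,
        "transcribed_region_pct": pct(n_region_tr, n_regions),
        "n_genes_with_transcribed_region": n_assoc,
        "n_cotranscribed_genes": int(cotr),
        "cotranscribed_gene_pct": pct(cotr, n_assoc),
        "not_cotranscribed_gene_pct": pct(n_assoc - cotr, n_assoc),
        "group_sizes": {
            code: {"n": int(row["n"]), "pct": pct(row["n"], n_genes)}
            for code, row in group_sizes.iterrows()
        },
        "peaks": profile.peaks_table(res.peaks).to_dict(orient="records"),
        "n_pairs_screened": int(len(res.pairs)),
        "n_pairs_significant": int(len(sig)),
        "significant_pair_pct": pct(len(sig), len(res.pairs)) if len(res.pairs) else 0.0,
        "n_pairs_positive": int((res.pairs["sign"] == "positive").sum()) if len(res.pairs) else 0,
        "n_pairs_negative": int((res.pairs["sign"] == "negative").sum()) if len(res.pairs) else 0,
    }
    if res.overlaps is not None:
        report["catalog_overlap"] = res.overlaps.to_dict(orient="records")
    return report


def run_pipeline(
    cfg: PipelineConfig,
    mapped_fraction: pd.Series | None = None,
) -> PipelineResult:
    """Execute every stage on the configured inputs and build the report."""
    logger.info("stage annotation: %s", cfg.gtf)
    genes = annotation.parse_gene_annotation(cfg.gtf)
    logger.info("stage linkage: %s", cfg.regions_bed)
    regions = linkage.read_bed(cfg.regions_bed)
    links = linkage.assign_nearest_gene(regions, genes)

    logger.info("stage quant")
    gm = quant.CountMatrix.read_tsv(cfg.gene_counts)
    rm = quant.CountMatrix.read_tsv(cfg.region_counts)
    if mapped_fraction is not None:
        gm = quant.filter_low_mapped(gm, mapped_fraction)
        rm = quant.filter_low_mapped(rm, mapped_fraction)
    qc = quant.detect_outlier_samples(gm, k=cfg.outlier_sd)
    keep = list(qc.index[~qc["outlier"]])
    gm, rm = gm.subset(samples=keep), rm.subset(samples=keep)

    gm_f, gene_tr = quant.filter_expressed(gm, cfg.min_reads, cfg.min_samples)
    rm_f, region_tr = quant.filter_expressed(rm, cfg.min_reads, cfg.min_samples)

    logger.info("stage groups")
    codes = groups.classify_gene_groups(
        [g.gene_id for g in genes],
        links,
        gene_tr.to_dict(),
        region_tr.to_dict(),
        nearest_only=cfg.nearest_only,
    )

    logger.info("stage profile")
    region_scores = quant.mean_normalized_abundance(rm_f)
    spatial = profile.build_spatial_profile(
        links,
        regions,
        genes,
        region_scores.to_dict(),
        window=cfg.window,
        n_bins=cfg.n_bins,
    )
    peaks = profile.call_profile_peaks(spatial)
    peaks = profile.assign_members(spatial, peaks, links)

    logger.info("stage coordination")
    pairs = coordination.screen_pairs(
        gm_f.normalized(),
        rm_f.normalized(),
        links,
        gene_transcribed=gene_tr,
        region_transcribed=region_tr,
        alpha=cfg.alpha,
    )

    overlaps = None
    if cfg.catalogs:
        logger.info("stage overlap: %d catalogs", len(cfg.catalogs))
        results = []
        for name, path in cfg.catalogs.items():
            cat = linkage.read_bed(path, prefix=name)
            results.append(
                linkage.catalog_overlap(
                    regions, cat, cfg.chrom_sizes, name=name, seed=cfg.seed
                )
            )
        overlaps = linkage.overlap_report(results)

    res = PipelineResult(
        genes=genes,
        regions=regions,
        links=links,
        gene_matrix=gm_f,
        region_matrix=rm_f,
        gene_transcribed=gene_tr,
        region_transcribed=region_tr,
        codes=codes,
        spatial=spatial,
        peaks=peaks,
        pairs=pairs,
        overlaps=overlaps,
        report={},
    )
    res.report = _summary_report(res, cfg.seed)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        links.to_csv(out / "links.tsv", sep="\t", index=False)
        codes.rename_axis("gene_id").to_frame().to_csv(out / "groups.tsv", sep="\t")
        if len(region_scores) >= 5:
            groups.quantile_stratify(region_scores).rename_axis("feature_id").to_frame().to_csv(
                out / "region_strata.tsv", sep="\t"
            )
        spatial.to_frame().to_csv(out / "profile.tsv", sep="\t", index=False)
        profile.peaks_table(peaks).to_csv(out / "peaks.tsv", sep="\t", index=False)
        pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
        if overlaps is not None:
            overlaps.to_csv(out / "overlap_report.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(res.report, fh, indent=2)
    return res
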