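"""Synthetic genome / annotation / region / count-matrix generator.

Emulates the statistical structure the pipeline assumes so every stage can
be exercised at desk scale with known ground truth:

* two gene classes — a "linked" class of long, intron-rich, sparsely placed
  genes with low-CpG promoters, and an "unlinked" class of short, exon-dense,
  clustered genes with high-CpG promoters;
* intergenic regions planted in clusters at fixed upstream TSS offsets
  (defaults -1.5, -3.5, -6.5, -9 kb) with abundance decreasing with
  distance, plus uniformly placed distal decoys;
* negative-binomial count matrices for genes and regions over two sample
  cohorts, with positive/negative region-gene couplings planted through
  per-gene latent factors and a differential subset between cohorts;
* truth tables (gene class and group code, region cluster and intended
  gene, pair signs, differential features) consistent with the emitted
  GTF/BED/TSV files.

Everything is drawn from a single seeded generator, so an identical
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneRecord, write_gene_annotation
from .linkage import RegionRecord, assign_nearest_gene, write_bed
from .quant import CountMatrix

DECOY_MIN_TSS_DIST = 12_000  # decoys stay distal so planted peaks dominate near-TSS bins
INTERGENIC_MARGIN = 1_000  # regions keep >= 1 kb from gene bodies


@dataclass
class SimConfig:
    """All knobs of the generator; defaults size a <2 min desk-scale run."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 5_000_000
    n_genes: int = 400
    frac_linked: float = 0.5
    gc: float = 0.41
    # gene architecture per class (log-normal lengths, nt)
    linked_len_median: float = 15_000.0
    linked_len_sdlog: float = 0.5
    unlinked_len_median: float = 2_000.0
    unlinked_len_sdlog: float = 0.4
    # planted promoter CpG dinucleotide rates per class
    cpg_rate_linked: float = 0.01
    cpg_rate_unlinked: float = 0.12
    # region placement
    n_regions: int = 1200
    frac_decoy: float = 0.15
    cluster_offsets: tuple[float, ...] = (-1_500.0, -3_500.0, -6_500.0, -9_000.0)
    cluster_abundance: tuple[float, ...] = (50.0, 30.0, 15.0, 8.0)
    cluster_weights: tuple[float, ...] = (0.3, 0.3, 0.25, 0.15)
    cluster_jitter_sd: float = 120.0
    region_len_range: tuple[int, int] = (300, 2_000)
    decoy_abundance: float = 3.0
    # counts
    n_samples: int = 60
    cohort_sizes: tuple[int, int] = (30, 30)
    nb_dispersion: float = 10.0
    gene_mu_median: float = 200.0
    gene_mu_sdlog: float = 1.0
    library_sdlog: float = 0.15
    frac_silent_genes: float = 0.3
    frac_silent_regions: float = 0.3
    # region silencing clusters by locus: some genes have (nearly) all their
    # regions silent, which populates the 001/101 group codes
    frac_region_silenced_genes: float = 0.2
    region_silent_rate_in_silenced: float = 0.9
    # planted couplings and cohort contrast
    n_pos_pairs: int = 40
    n_neg_pairs: int = 20
    gamma: float = 0.8
    gene_latent_beta: float = 1.0
    n_de_genes: int = 20
    n_de_regions: int = 20
    de_lfc: float = 1.0

    def validate(self) -> None:
        if not 0 <= self.frac_linked <= 1 or not 0 <= self.frac_decoy <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if len(self.cluster_offsets) != len(self.cluster_abundance):
            raise ValueError("cluster offsets and abundances must align")
        if any(abs(o) > 20_000 for o in self.cluster_offsets):
            raise ValueError("planted cluster offsets must lie within +/-20 kb")
        if sum(self.cohort_sizes) != self.n_samples:
            raise ValueError("cohort sizes must sum to n_samples")


@dataclass
class TruthTables:
    genes: pd.DataFrame  # gene_id, gene_class, transcribed, group_code, ...
    regions: pd.DataFrame  # region_id, cluster, gene_id, offset, transcribed, ...
    pairs: pd.DataFrame  # region_id, gene_id, sign
    samples: pd.DataFrame  # sample_id, cohort, library_factor
    de_genes: list[str] = field(default_factory=list)
    de_regions: list[str] = field(default_factory=list)




@dataclass
class SimData:
    config: SimConfig
    genes: list[GeneRecord]
    genome: dict[str, str]
    regions: list[RegionRecord]
    gene_counts: CountMatrix
    region_counts: CountMatrix
    truth: TruthTables

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        write_gene_annotation(self.genes, out / "genes.gtf")
        write_bed(self.regions, out / "regions.bed")
        self.gene_counts.write_tsv(out / "gene_counts.tsv")
        self.region_counts.write_tsv(out / "region_counts.tsv")
        self.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.truth.regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
        self.truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
        self.truth.samples.to_csv(out / "truth_samples.tsv", sep="\t", index=False)
        with open(out / "sim_config.json", "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2, default=list)


def _gene_structures(cfg: SimConfig, rng: np.random.Generator):
    """Place both gene classes on every chromosome.

    Each chromosome holds a sparse zone of linked-class genes (gaps 20-30 kb
    leave room for upstream region clusters) followed by a dense zone of
    unlinked-class genes (gaps 0.2-2 kb).
    """
    per_chrom = cfg.n_genes // cfg.n_chroms
    n_linked = round(per_chrom * cfg.frac_linked)
    genes: list[GeneRecord] = []
    classes: dict[str, str] = {}
    gid_counter = 0

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = 60_000
        for k in range(per_chrom):
            linked = k < n_linked
            if linked:
                L = int(
                    np.clip(
                        rng.lognormal(math.log(cfg.linked_len_median), cfg.linked_len_sdlog),
                        4_000,
                        60_000,
                    )
                )
                gap = int(rng.integers(20_000, 30_000))
                n_ex = int(rng.integers(3, 7))
                exon_span = int(rng.integers(100, 300))
            else:
                if k == n_linked:
                    cursor += 30_000  # buffer between zones
                L = int(
                    np.clip(
                        rng.lognormal(math.log(cfg.unlinked_len_median), cfg.unlinked_len_sdlog),
                        600,
                        6_000,
                    )
                )
                gap = int(rng.integers(200, 2_000))
                n_ex = int(rng.integers(2, 5))
                exon_span = None  # exon-dense: exons fill segments minus a small intron
            if cursor + L + 20_000 > cfg.chrom_len:
                raise RuntimeError(
                    "gene placement exhausted the chromosome; "
                    "increase chrom_len or reduce n_genes"
                )
            start, end = cursor, cursor + L
            seg = L // n_ex
            exons = []
            for e in range(n_ex):
                seg_lo = start + e * seg
                if exon_span is not None:  # linked class: short exons, long introns
                    elen = min(exon_span, seg - 1)
                    off = int(rng.integers(0, max(1, seg - elen)))
                    exons.append((seg_lo + off, seg_lo + off + elen))
                else:  # unlinked class: exon fills the segment minus a short intron
                    intron = int(rng.integers(50, min(150, max(51, seg // 2))))
                    exons.append((seg_lo, seg_lo + max(50, seg - intron)))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"G{gid_counter:05d}"
            gid_counter += 1
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype="protein_coding" if rng.random() < 0.6 else "lncRNA",
                    exons=exons,
                )
            )
            classes[gid] = "linked" if linked else "unlinked"
            cursor = end + gap
    return genes, classes


def generate_annotation(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Two-class gene annotation plus the per-gene class truth."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    genes, classes = _gene_structures(cfg, rng)
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_class": [classes[g.gene_id] for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    )
    return genes, truth


def _plant_cpg(rng: np.random.Generator, width: int, rate: float, gc: float) -> str:
    """Random sequence of ``width`` nt with CG dinucleotides planted at ~``rate``."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(list("ACGT"), size=width, p=p)
    i = 0
    while i < width - 1:
        if rng.random() < rate:
            bases[i], bases[i + 1] = "C", "G"
            i += 2
        else:
            i += 1
    return "".join(bases)


def generate_genome(
    cfg: SimConfig,
    genes: list[GeneRecord],
    gene_truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """I.i.d. base sequence per chromosome with class-specific promoter CpG.

    The 1-kb promoter of every gene (forward-strand footprint; CG counts
    are strand-symmetric) is rewritten with a low planted CpG rate for the
    linked class and a high rate for the unlinked class.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    p = [(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2]
    genome = {}
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        genome[chrom] = rng.choice(list("ACGT"), size=cfg.chrom_len, p=p)
    cls = dict(zip(gene_truth["gene_id"], gene_truth["gene_class"]))
    for g in genes:
        rate = cfg.cpg_rate_linked if cls[g.gene_id] == "linked" else cfg.cpg_rate_unlinked
        if g.strand == "+":
            lo, hi = max(0, g.tss - 1_000), g.tss
        else:
            lo, hi = g.tss + 1, min(cfg.chrom_len, g.tss + 1_001)
        promo = _plant_cpg(rng, hi - lo, rate, cfg.gc)
        genome[g.chrom][lo:hi] = list(promo)
    return {c: "".join(arr) for c, arr in genome.items()}


def generate_regions(
    cfg: SimConfig,
    genes: list[GeneRecord],
    gene_truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """Planted upstream region clusters plus distal decoys, with truth.

    Every planted region's nearest gene under the linkage rule is verified
    to be its intended gene; violating placements are re-drawn.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    cls = dict(zip(gene_truth["gene_id"], gene_truth["gene_class"]))
    linked_genes = [g for g in genes if cls[g.gene_id] == "linked"]
    if not linked_genes:
        raise ValueError("no linked-class genes to anchor regions")
    n_planted = round(cfg.n_regions * (1 - cfg.frac_decoy))
    weights = np.asarray(cfg.cluster_weights, dtype=float)
    weights = weights / weights.sum()

    gene_bodies: dict[str, list[tuple[int, int]]] = {}
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        gene_bodies.setdefault(g.chrom, []).append((g.start, g.end))
    for chrom in gene_bodies:
        gene_bodies[chrom].sort()
        tss_by_chrom[chrom] = np.sort(
            np.array([g.tss for g in genes if g.chrom == chrom])
        )

    def min_tss_dist(chrom: str, pos: int) -> int:
        arr = tss_by_chrom[chrom]
        i = int(np.searchsorted(arr, pos))
        cands = [abs(pos - arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)]
        return min(cands)

    def intergenic(chrom: str, s: int, e: int) -> bool:
        for gs, ge in gene_bodies[chrom]:
            if s < ge + INTERGENIC_MARGIN and e > gs - INTERGENIC_MARGIN:
                return False
        return True

    regions: list[RegionRecord] = []
    rows = []
    rid_counter = 0
    lo_len, hi_len = cfg.region_len_range

    for _ in range(n_planted):
        gi = int(rng.integers(len(linked_genes)))
        c = int(rng.choice(len(weights), p=weights))
        for _attempt in range(50):
            g = linked_genes[gi]
            offset = cfg.cluster_offsets[c] + rng.normal(0, cfg.cluster_jitter_sd)
            # cap length so the region stays > 1 kb clear of the TSS
            max_len = int(min(hi_len, 2 * (abs(offset) - INTERGENIC_MARGIN) - 10))
            if max_len < lo_len:
                continue
            length = int(rng.integers(lo_len, max_len + 1))
            center = int(g.tss + offset) if g.strand == "+" else int(g.tss - offset)
            start, end = center - length // 2, center - length // 2 + length
            if start < 0 or end > cfg.chrom_len:
                continue
            if not intergenic(g.chrom, start, end):
                continue
            # nearest-gene self-check: intended gene must win the linkage rule
            rr = RegionRecord(f"R{rid_counter:05d}", g.chrom, start, end)
            link = assign_nearest_gene([rr], genes)
            if len(link) and link.iloc[0]["gene_id"] == g.gene_id:
                regions.append(rr)
                rows.append(
                    {
                        "region_id": rr.region_id,
                        "chrom": rr.chrom,
                        "start": start,
                        "end": end,
                        "center": rr.center,
                        "gene_id": g.gene_id,
                        "cluster": f"e{c + 1}",
                        "offset": float(offset),
                        "abundance_mean": float(
                            cfg.cluster_abundance[c] * rng.lognormal(0, 0.3)
                        ),
                    }
                )
                rid_counter += 1
                break
        else:
            raise RuntimeError(
                "could not place a planted region after 50 redraws; "
                "widen gene spacing or shrink cluster offsets"
            )

    n_decoys = cfg.n_regions - n_planted
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    placed = 0
    attempts = 0
    while placed < n_decoys:
        attempts += 1
        if attempts > 200 * max(1, n_decoys):
            raise RuntimeError("could not place distal decoy regions")
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(0, cfg.chrom_len - length))
        end = start + length
        center = (start + end) // 2
        if min_tss_dist(chrom, center) < DECOY_MIN_TSS_DIST:
            continue
        if not intergenic(chrom, start, end):
            continue
        rr = RegionRecord(f"R{rid_counter:05d}", chrom, start, end)
        rid_counter += 1
        regions.append(rr)
        rows.append(
            {
                "region_id": rr.region_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "center": center,
                "gene_id": "",
                "cluster": "decoy",
                "offset": math.nan,
                "abundance_mean": float(cfg.decoy_abundance * rng.lognormal(0, 0.3)),
            }
        )
        placed += 1

    truth = pd.DataFrame(rows)
    # actual nearest gene for every region (decoys included); for planted
    # regions this was verified to equal the intended anchor above
    full_links = assign_nearest_gene(regions, genes)
    truth = truth.merge(
        full_links.rename(columns={"gene_id": "nearest_gene_id"})[
            ["region_id", "nearest_gene_id"]
        ],
        on="region_id",
        how="left",
    )
    planted_mask = truth["cluster"] != "decoy"
    if not (truth.loc[planted_mask, "nearest_gene_id"] == truth.loc[planted_mask, "gene_id"]).all():
        raise AssertionError("planted region linkage self-check failed")
    return regions, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draw parameterised by mean and size (dispersion)."""
    mean = np.maximum(mean, 1e-8)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate_counts(
    cfg: SimConfig,
    gene_truth: pd.DataFrame,
    region_truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """NB count matrices with planted couplings, cohorts and silent features.

    Returns (gene CountMatrix, region CountMatrix, updated gene truth,
    updated region truth, pair truth, sample truth).
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    cohort = np.array([0] * cfg.cohort_sizes[0] + [1] * cfg.cohort_sizes[1])
    lib = rng.lognormal(0, cfg.library_sdlog, size=n)

    gene_ids = list(gene_truth["gene_id"])
    region_ids = list(region_truth["region_id"])

    gene_silent = rng.random(len(gene_ids)) < cfg.frac_silent_genes
    # per-gene region-silencing state; the base rate is adjusted so the
    # marginal silent fraction stays at frac_silent_regions
    anchor_genes = sorted(set(region_truth["gene_id"]) - {""})
    silenced_locus = {
        g: rng.random() < cfg.frac_region_silenced_genes for g in anchor_genes
    }
    hi_rate = cfg.region_silent_rate_in_silenced
    base_rate = (
        cfg.frac_silent_regions - cfg.frac_region_silenced_genes * hi_rate
    ) / max(1e-12, 1 - cfg.frac_region_silenced_genes)
    base_rate = float(np.clip(base_rate, 0.0, 1.0))
    region_silent = np.empty(len(region_ids), dtype=bool)
    for i, row in enumerate(region_truth.itertuples(index=False)):
        if row.gene_id and silenced_locus.get(row.gene_id, False):
            region_silent[i] = rng.random() < hi_rate
        elif row.gene_id:
            region_silent[i] = rng.random() < base_rate
        else:
            region_silent[i] = rng.random() < cfg.frac_silent_regions

    # eligible coupled pairs: transcribed planted region with transcribed intended gene
    silent_gene_set = {g for g, s in zip(gene_ids, gene_silent) if s}
    eligible = [
        i
        for i, row in enumerate(region_truth.itertuples(index=False))
        if row.cluster != "decoy"
        and not region_silent[i]
        and row.gene_id not in silent_gene_set
    ]
    n_coupled = cfg.n_pos_pairs + cfg.n_neg_pairs
    if len(eligible) < n_coupled:
        raise ValueError(
            f"only {len(eligible)} eligible region-gene pairs for {n_coupled} "
            "planted couplings; increase n_regions or lower the silent fractions"
        )
    picked = rng.choice(eligible, size=n_coupled, replace=False)
    pair_sign = {}
    for j, i in enumerate(picked):
        rid = region_ids[i]
        pair_sign[rid] = +1 if j < cfg.n_pos_pairs else -1

    # per-gene latent factors drive planted couplings
    coupled_genes = sorted(
        {region_truth.iloc[i]["gene_id"] for i in picked}
    )
    latent = {g: rng.standard_normal(n) for g in coupled_genes}

    # cohort-differential subsets among transcribed features
    tr_gene_idx = [i for i, s in enumerate(gene_silent) if not s]
    tr_region_idx = [i for i, s in enumerate(region_silent) if not s]
    de_genes = [
        gene_ids[i]
        for i in rng.choice(tr_gene_idx, size=min(cfg.n_de_genes, len(tr_gene_idx)), replace=False)
    ]
    de_regions = [
        region_ids[i]
        for i in rng.choice(
            tr_region_idx, size=min(cfg.n_de_regions, len(tr_region_idx)), replace=False
        )
    ]
    de_gene_set, de_region_set = set(de_genes), set(de_regions)

    def silent_row() -> np.ndarray:
        """All-zero except sub-threshold noise (a read in at most 2 samples)."""
        row = np.zeros(n, dtype=np.int64)
        k = int(rng.integers(0, 3))
        if k:
            idx = rng.choice(n, size=k, replace=False)
            row[idx] = 1
        return row

    def ensure_transcribed(row: np.ndarray) -> np.ndarray:
        # guarantee the expressed filter passes even after a few samples
        # are removed downstream as correlation outliers
        if (row >= 1).sum() < 8:
            row = row.copy()
            row[:8] = np.maximum(row[:8], 1)
        return row

    gene_mat = np.zeros((len(gene_ids), n), dtype=np.int64)
    gene_mu = rng.lognormal(math.log(cfg.gene_mu_median), cfg.gene_mu_sdlog, size=len(gene_ids))
    for i, gid in enumerate(gene_ids):
        if gene_silent[i]:
            gene_mat[i] = silent_row()
            continue
        log2fc = np.zeros(n)
        if gid in latent:
            log2fc += cfg.gene_latent_beta * latent[gid]
        if gid in de_gene_set:
            log2fc += cfg.de_lfc * cohort
        mean = gene_mu[i] * np.exp2(log2fc) * lib
        gene_mat[i] = ensure_transcribed(_nb_draw(rng, mean, cfg.nb_dispersion))

    region_mat = np.zeros((len(region_ids), n), dtype=np.int64)
    for i, row in enumerate(region_truth.itertuples(index=False)):
        rid = region_ids[i]
        if region_silent[i]:
            region_mat[i] = silent_row()
            continue
        log2fc = np.zeros(n)
        if rid in pair_sign:
            log2fc += pair_sign[rid] * cfg.gamma * latent[row.gene_id]
        if rid in de_region_set:
            log2fc += cfg.de_lfc * cohort
        mean = row.abundance_mean * np.exp2(log2fc) * lib
        region_mat[i] = ensure_transcribed(_nb_draw(rng, mean, cfg.nb_dispersion))

    gene_truth = gene_truth.copy()
    gene_truth["transcribed"] = ~gene_silent
    gene_truth["de"] = gene_truth["gene_id"].isin(de_gene_set)
    region_truth = region_truth.copy()
    region_truth["transcribed"] = ~region_silent
    region_truth["de"] = region_truth["region_id"].isin(de_region_set)
    region_truth["pair_sign"] = [
        pair_sign.get(rid, 0) for rid in region_ids
    ]

    # planted 3-bit group code from the emitted linkage (actual nearest gene,
    # decoys included) and the transcription truth
    any_tr = region_truth.groupby("nearest_gene_id")["transcribed"].any()
    linked_set = set(any_tr.index)
    codes = []
    for gid, silent in zip(gene_ids, gene_silent):
        d1 = int(not silent)
        d3 = int(gid in linked_set)
        d2 = int(bool(any_tr.get(gid, False))) if d3 else 0
        codes.append(f"{d1}{d2}{d3}")
    gene_truth["group_code"] = codes

    pairs = pd.DataFrame(
        {
            "region_id": [region_ids[i] for i in picked],
            "gene_id": [region_truth.iloc[i]["gene_id"] for i in picked],
            "sign": [pair_sign[region_ids[i]] for i in picked],
        }
    )
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "cohort": cohort, "library_factor": lib}
    )
    gcm = CountMatrix(pd.DataFrame(gene_mat, index=gene_ids, columns=sample_ids))
    rcm = CountMatrix(pd.DataFrame(region_mat, index=region_ids, columns=sample_ids))
    return gcm, rcm, gene_truth, region_truth, pairs, samples


def simulate(cfg: SimConfig | None = None, out_dir: str | Path | None = None) -> SimData:
    """Run the full generator; optionally write all artefacts to ``out_dir``."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, gene_truth = generate_annotation(cfg, rng)
    genome = generate_genome(cfg, genes, gene_truth, rng)
    regions, region_truth = generate_regions(cfg, genes, gene_truth, rng)
    gcm, rcm, gene_truth, region_truth, pairs, samples = generate_counts(
        cfg, gene_truth, region_truth, rng
    )
    truth = TruthTables(
        genes=gene_truth,
        regions=region_truth,
        pairs=pairs,
        samples=samples,
        de_genes=list(gene_truth.loc[gene_truth["de"], "gene_id"]),
        de_regions=list(region_truth.loc[region_truth["de"], "region_id"]),
    )
    data = SimData(
        config=cfg,
        genes=genes,
        genome=genome,
        regions=regions,
        gene_counts=gcm,
        region_counts=rcm,
        truth=truth,
    )
    if out_dir is not None:
        data.write(out_dir)
    return data
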