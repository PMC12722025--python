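"""Gene annotation ingestion and per-gene architecture features.

Parses a GRCh38-style GTF into :class:`GeneRecord` objects (internal
coordinates are 0-based half-open; the GTF border stays 1-based closed) and
computes the gene-architecture features used to contrast genes with and
without linked intergenic RNAPII-bound regions: gene length, exon-to-intron
ratio, CpG dinucleotide frequency of the gene body and of the 1-kb promoter,
local gene density in a +/-100 kb flank, and the number of distinct
transcription factors regulating each gene.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: window (nt) on each side of a gene used for local gene density
DENSITY_FLANK = 100_000
#: promoter width (nt) upstream of the TSS
PROMOTER_WIDTH = 1_000


@dataclass
class GeneRecord:
    """One annotated gene with merged exons.

    Coordinates are 0-based half-open.  ``tss`` is the 5' end of the gene
    record: ``start`` on the + strand, ``end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneFeatures:
    """Architecture features of one gene; NaN marks undefined values."""

    gene_id: str
    length: int
    exon_len: int
    intron_len: int
    ei_ratio: float  # NaN for intronless genes
    cpg_body: float = math.nan
    cpg_promoter: float = math.nan
    density: float = math.nan
    n_regulators: int = 0


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended half-open intervals into a disjoint sorted list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _validate_gtf_lines(path: str | Path) -> None:
    """Cheap structural check so a malformed line is reported with its number."""
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            n_fields = line.rstrip("\n").count("\t") + 1
            if n_fields < 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, found {n_fields}"
                )


def parse_gene_annotation(
    gtf_path: str | Path,
    chromosomes: Sequence[str] | None = None,
) -> list[GeneRecord]:
    """Parse ``gene`` and ``exon`` features of a GTF into :class:`GeneRecord` objects.

    GTF 1-based closed coordinates are converted to 0-based half-open;
    exons are merged per gene.  Exon lines whose ``gene_id`` has no gene
    line are skipped with a warning.

    Parameters
    ----------
    gtf_path
        Path to a GTF file, optionally gzip-compressed.
    chromosomes
        Restrict output to these chromosome names (None keeps all).
    """
    _validate_gtf_lines(gtf_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    keep = set(chromosomes) if chromosomes is not None else None

    genes: dict[str, GeneRecord] = {}
    for feat in db.features_of_type("gene"):
        if keep is not None and feat.seqid not in keep:
            continue
        gid = feat.attributes["gene_id"][0]
        biotype = (
            feat.attributes.get("gene_biotype", feat.attributes.get("gene_type", ["unknown"]))
        )[0]
        genes[gid] = GeneRecord(
            gene_id=gid,
            chrom=feat.seqid,
            start=feat.start - 1,  # 1-based closed -> 0-based half-open
            end=feat.end,
            strand=feat.strand,
            biotype=biotype,
        )

    exons: dict[str, list[tuple[int, int]]] = {gid: [] for gid in genes}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes["gene_id"][0]
        if gid not in genes:
            if keep is None or feat.seqid in keep:
                logger.warning("exon with no parent gene %s skipped", gid)
            continue
        exons[gid].append((feat.start - 1, feat.end))

    out = []
    for gid, g in genes.items():
        g.exons = merge_intervals(exons[gid])
        out.append(g)
    return out


def write_gene_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene and exon lines as GTF (1-based closed), the inverse of parsing."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tibrkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tibrkit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def exon_intron_ratio(g: GeneRecord) -> GeneFeatures:
    """Gene length, summed exon/intron lengths and the exon-to-intron ratio.

    The ratio is NaN (undefined) for intronless genes; such genes are
    excluded from group comparisons rather than assigned an infinity.
    """
    exon_len = sum(e - s for s, e in g.exons)
    intron_len = g.length - exon_len
    if intron_len < 0:
        raise ValueError(f"{g.gene_id}: exon length exceeds gene length")
    ratio = exon_len / intron_len if intron_len > 0 else math.nan
    return GeneFeatures(
        gene_id=g.gene_id,
        length=g.length,
        exon_len=exon_len,
        intron_len=intron_len,
        ei_ratio=ratio,
    )


def cpg_frequency(seq: str) -> float:
    """CG dinucleotide frequency of ``seq`` (forward strand, case-insensitive).

    The denominator is the number of dinucleotide positions (len - 1);
    positions where either base is N are excluded from both numerator and
    denominator.  Returns NaN for sequences shorter than 2 nt or with no
    N-free dinucleotide position.
    """
    s = seq.upper()
    if len(s) < 2:
        return math.nan
    n_cg = 0
    n_valid = 0
    for i in range(len(s) - 1):
        a, b = s[i], s[i + 1]
        if a == "N" or b == "N":
            continue
        n_valid += 1
        if a == "C" and b == "G":
            n_cg += 1
    return n_cg / n_valid if n_valid else math.nan


def promoter_sequence(g: GeneRecord, genome, width: int = PROMOTER_WIDTH) -> str:
    """The ``width`` nt immediately upstream of the TSS, strand-aware.

    For a + strand gene this is ``[tss - width, tss)`` on the forward strand;
    for a - strand gene, the reverse complement of ``(tss, tss + width]``.
    The window is clipped at chromosome bounds and may be shorter than
    ``width``.  ``genome`` is a :class:`pyfaidx.Fasta` (or mapping of
    chromosome name to sequence string).
    """
    if g.chrom not in genome:
        raise KeyError(f"chromosome {g.chrom!r} absent from genome FASTA")
    chrom_seq = genome[g.chrom]
    chrom_len = len(chrom_seq)
    if g.strand == "+":
        lo = max(0, g.tss - width)
        sub = chrom_seq[lo : g.tss]
        return str(sub if isinstance(sub, str) else sub.seq)
    lo = g.tss + 1
    hi = min(chrom_len, g.tss + 1 + width)
    sub = chrom_seq[lo:hi]
    fwd = str(sub if isinstance(sub, str) else sub.seq)
    return str(Seq(fwd).reverse_complement())


def gene_density(g: GeneRecord, all_genes: Sequence[GeneRecord]) -> float:
    """Local gene density: neighbours per nt within a +/-100 kb flank.

    Counts other genes whose body overlaps ``[start - 100kb, end + 100kb)``
    on the same chromosome (the focal gene itself excluded) and divides by
    200,000 nt.
    """
    lo = g.start - DENSITY_FLANK
    hi = g.end + DENSITY_FLANK
    n = sum(
        1
        for other in all_genes
        if other.chrom == g.chrom
        and other.gene_id != g.gene_id
        and other.start < hi
        and other.end > lo
    )
    return n / (2 * DENSITY_FLANK)


def gene_densities(genes: Sequence[GeneRecord]) -> pd.Series:
    """Vectorised :func:`gene_density` for a whole annotation set."""
    out = pd.Series(0.0, index=[g.gene_id for g in genes])
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        starts = np.array([g.start for g in chrom_genes])
        ends = np.array([g.end for g in chrom_genes])
        order_s = np.sort(starts)
        order_e = np.sort(ends)
        # neighbours overlapping the flank window: start < hi and end > lo
        n_start_lt_hi = np.searchsorted(order_s, ends + DENSITY_FLANK, side="left")
        n_end_le_lo = np.searchsorted(order_e, starts - DENSITY_FLANK, side="right")
        counts = n_start_lt_hi - n_end_le_lo - 1  # focal gene always qualifies
        for g, c in zip(chrom_genes, counts):
            out[g.gene_id] = c / (2 * DENSITY_FLANK)
    return out


def count_regulators(
    gene_ids: Sequence[str], regulator_table: pd.DataFrame
) -> pd.Series:
    """Distinct transcription-factor count per target gene.

    ``regulator_table`` needs ``tf`` and ``target`` columns; genes absent
    from the table get 0.
    """
    if not {"tf", "target"}.issubset(regulator_table.columns):
        raise ValueError("regulator table must have 'tf' and 'target' columns")
    counts = regulator_table.groupby("target")["tf"].nunique()
    return pd.Series(
        [int(counts.get(gid, 0)) for gid in gene_ids], index=list(gene_ids), dtype=int
    )


def gene_features_table(
    genes: Sequence[GeneRecord],
    genome=None,
    regulator_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-gene feature table (one row per gene, indexed by gene_id).

    Sequence-derived columns (CpG frequencies) are NaN when ``genome`` is
    not supplied; regulator counts are 0 without a ``regulator_table``.
    """
    rows = []
    densities = gene_densities(genes)
    n_reg = (
        count_regulators([g.gene_id for g in genes], regulator_table)
        if regulator_table is not None
        else None
    )
    for g in genes:
        f = exon_intron_ratio(g)
        f.density = float(densities[g.gene_id])
        if genome is not None:
            body = genome[g.chrom][g.start : g.end]
            body = str(body if isinstance(body, str) else body.seq)
            if g.strand == "-":
                body = str(Seq(body).reverse_complement())
            f.cpg_body = cpg_frequency(body)
            f.cpg_promoter = cpg_frequency(promoter_sequence(g, genome))
        if n_reg is not None:
            f.n_regulators = int(n_reg[g.gene_id])
        rows.append(f)
    df = pd.DataFrame([vars(f) for f in rows]).set_index("gene_id")
    return df
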