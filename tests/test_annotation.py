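import math

import numpy as np
import pandas as pd
import pytest

from ibrkit.annotation import (
    GeneRecord,
    count_regulators,
    cpg_frequency,
    exon_intron_ratio,
    gene_densities,
    gene_density,
    merge_intervals,
    parse_gene_annotation,
    promoter_sequence,
    write_gene_annotation,
)

GTF_SMALL = """\
chr1\tsrc\tgene\t100\t200\t.\t+\t.\tgene_id "G1"; gene_biotype "protein_coding";
chr1\tsrc\texon\t100\t140\t.\t+\t.\tgene_id "G1";
chr1\tsrc\texon\t161\t200\t.\t+\t.\tgene_id "G1";
"""


def _random_genes(rng, n=40, chrom_len=500_000, n_chroms=2):
    genes = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_len - 10_000))
        length = int(rng.integers(500, 10_000))
        n_ex = int(rng.integers(1, 5))
        bounds = np.sort(rng.choice(np.arange(1, length), size=2 * n_ex, replace=False))
        exons = [
            (start + int(bounds[2 * j]), start + int(bounds[2 * j + 1]))
            for j in range(n_ex)
        ]
        genes.append(
            GeneRecord(
                gene_id=f"G{i:03d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
            )
        )
    return genes


class TestParseGtf:
    def test_coordinate_conversion_and_exon_merge(self, tmp_path):
        """1-based closed GTF becomes 0-based half-open with merged exons."""
        p = tmp_path / "g.gtf"
        p.write_text(GTF_SMALL)
        (g,) = parse_gene_annotation(p)
        assert (g.start, g.end, g.tss) == (99, 200, 99)
        assert g.exons == [(99, 140), (160, 200)]

    def test_overlapping_exons_merged(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "G";\n'
            'chr1\ts\texon\t10\t50\t.\t+\t.\tgene_id "G";\n'
            'chr1\ts\texon\t40\t80\t.\t+\t.\tgene_id "G";\n'
        )
        (g,) = parse_gene_annotation(p)
        assert g.exons == [(9, 80)]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "G";\nnot-a-gtf-line\n')
        with pytest.raises(ValueError, match="line 2"):
            parse_gene_annotation(p)

    def test_orphan_exon_skipped(self, tmp_path, caplog):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "G";\n'
            'chr1\ts\texon\t10\t50\t.\t+\t.\tgene_id "ORPHAN";\n'
        )
        (g,) = parse_gene_annotation(p)
        assert g.gene_id == "G" and g.exons == []

    def test_chromosome_filter(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "A";\n'
            'chr2\ts\tgene\t1\t100\t.\t+\t.\tgene_id "B";\n'
        )
        assert [g.gene_id for g in parse_gene_annotation(p, chromosomes=["chr2"])] == ["B"]

    def test_round_trip_identity(self, tmp_path, rng):
        """Writing GeneRecords to GTF and re-parsing preserves coordinates."""
        genes = _random_genes(rng)
        p = tmp_path / "rt.gtf"
        write_gene_annotation(genes, p)
        back = {g.gene_id: g for g in parse_gene_annotation(p)}
        for g in genes:
            h = back[g.gene_id]
            assert (g.chrom, g.start, g.end, g.strand) == (h.chrom, h.start, h.end, h.strand)
            assert merge_intervals(g.exons) == h.exons


class TestExonIntronRatio:
    def test_basic_and_degenerate(self):
        g = GeneRecord("G", "chr1", 0, 1000, "+", exons=[(0, 400)])
        f = exon_intron_ratio(g)
        assert (f.length, f.exon_len, f.intron_len) == (1000, 400, 600)
        assert f.ei_ratio == pytest.approx(0.6667, abs=1e-4)
        single = GeneRecord("S", "chr1", 0, 500, "+", exons=[(0, 500)])
        assert math.isnan(exon_intron_ratio(single).ei_ratio)

    def test_matches_brute_force_on_random_structures(self, rng):
        for g in _random_genes(rng, n=30):
            f = exon_intron_ratio(g)
            exon_len = sum(e - s for s, e in merge_intervals(g.exons))
            assert f.exon_len == exon_len
            assert f.intron_len == (g.end - g.start) - exon_len
            if f.intron_len:
                assert f.ei_ratio == pytest.approx(exon_len / f.intron_len)


class TestCpgFrequency:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGT", 1 / 3),
            ("CGCGCG", 0.6),
            ("acgt", 1 / 3),  # case-insensitive
            ("AAAA", 0.0),
        ],
    )
    def test_examples(self, seq, expected):
        assert cpg_frequency(seq) == pytest.approx(expected)

    def test_short_and_all_n_are_undefined(self):
        assert math.isnan(cpg_frequency("A"))
        assert math.isnan(cpg_frequency("NNNN"))

    def test_n_positions_excluded_both_sides(self):
        # dinucleotide windows touching N drop out of numerator and denominator
        assert cpg_frequency("CGNNA") == pytest.approx(1 / 1)

    def test_matches_sliding_recount_and_revcomp_invariance(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 60))))
            naive = sum(seq[i : i + 2] == "CG" for i in range(len(seq) - 1)) / (len(seq) - 1)
            assert cpg_frequency(seq) == pytest.approx(naive)
            rc = seq.translate(comp)[::-1]
            assert cpg_frequency(rc) == pytest.approx(cpg_frequency(seq))


class TestPromoterSequence:
    genome = {"chr1": "".join(np.random.default_rng(5).choice(list("ACGT"), size=10_000))}

    def test_plus_strand_window(self):
        g = GeneRecord("G", "chr1", 5000, 6000, "+")
        assert promoter_sequence(g, self.genome) == self.genome["chr1"][4000:5000]

    def test_minus_strand_is_revcomp_downstream(self):
        g = GeneRecord("G", "chr1", 4000, 5000, "-")
        comp = str.maketrans("ACGT", "TGCA")
        fwd = self.genome["chr1"][5000:6000]
        assert promoter_sequence(g, self.genome) == fwd.translate(comp)[::-1]

    def test_clipped_at_chromosome_start(self):
        g = GeneRecord("G", "chr1", 300, 1300, "+")
        assert promoter_sequence(g, self.genome) == self.genome["chr1"][0:300]

    def test_missing_chromosome_named_in_error(self):
        g = GeneRecord("G", "chrX", 5000, 6000, "+")
        with pytest.raises(KeyError, match="chrX"):
            promoter_sequence(g, self.genome)


class TestGeneDensity:
    def test_isolated_gene_is_zero(self):
        g = GeneRecord("G", "chr1", 500_000, 501_000, "+")
        assert gene_density(g, [g]) == 0.0

    def test_four_neighbors(self):
        focal = GeneRecord("F", "chr1", 500_000, 501_000, "+")
        neighbors = [
            GeneRecord(f"N{i}", "chr1", 500_000 + i * 100, 500_500 + i * 100, "+")
            for i in range(1, 5)
        ]
        assert gene_density(focal, [focal] + neighbors) == pytest.approx(4 / 200_000)

    def test_vectorised_matches_brute_force_and_order_invariant(self, rng):
        genes = _random_genes(rng, n=120, chrom_len=600_000)
        fast = gene_densities(genes)
        for g in genes:
            assert fast[g.gene_id] == pytest.approx(gene_density(g, genes))
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert gene_densities(shuffled).sort_index().equals(fast.sort_index())


class TestCountRegulators:
    def test_dedup_and_absent(self):
        table = pd.DataFrame({"tf": ["A", "B", "A"], "target": ["G1", "G1", "G1"]})
        counts = count_regulators(["G1", "G2"], table)
        assert counts["G1"] == 2 and counts["G2"] == 0

    def test_matches_naive_tally(self, rng):
        tfs = [f"T{i}" for i in range(20)]
        targets = [f"G{i}" for i in range(30)]
        table = pd.DataFrame(
            {
                "tf": rng.choice(tfs, size=300),
                "target": rng.choice(targets, size=300),
            }
        )
        counts = count_regulators(targets, table)
        for g in targets:
            naive = len({t for t, tg in zip(table["tf"], table["target"]) if tg == g})
            assert counts[g] == naive
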