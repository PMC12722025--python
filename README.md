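# ibrkit

Analysis toolkit for **intergenic RNA-polymerase-II-bound regions
(iRNAPII-BRs)** — candidate enhancer-like elements where RNAPII binds and
often transcribes outside annotated gene bodies — and their relationship to
nearby genes in bulk RNA-seq data.

Given a gene annotation (GTF), a region atlas (BED) and feature × sample
count matrices for genes and for 1-kb region windows, the pipeline:

1. **annotation** — per-gene architecture features: length, exon-to-intron
   ratio, body/promoter CpG dinucleotide frequency, local gene density in a
   ±100 kb flank, distinct-regulator counts;
2. **linkage** — assigns every region to the gene with the nearest TSS on
   the same chromosome (signed distance, negative upstream) and scores
   overlap with external cis-regulatory-element catalogs (coverage,
   Fisher's exact test against a placement-matched shuffle, permutation z);
3. **quant** — sample QC (mapped-read fraction ≥ 50 %, one-shot
   correlation-outlier removal at 2 SD), the transcribed-feature rule
   (≥ 1 read in ≥ 3 samples), median-of-ratios size factors, variable-feature
   selection, and Wilcoxon rank-sum comparisons with rank-biserial effect
   sizes;
4. **groups** — classifies each gene by a 3-bit code
   (gene transcribed / any linked region transcribed / linked), yielding the
   six valid configurations 000, 001, 011, 100, 101, 111; quantile strata of
   abundance;
5. **profile** — aggregates transcribed-region abundance into 147 bins of a
   strand-corrected ±20 kb window around linked TSSs and calls upstream
   peaks e1…eK;
6. **coordination** — Spearman + linear-fit screen of transcribed
   region–gene pairs with Benjamini–Hochberg FDR and sign calls, plus a
   preranked permutation set-enrichment statistic;
7. **motifs** — PWM mean-affinity enrichment of region and promoter
   sequences against length-matched genomic background draws;
8. **simulate** — a fully seeded synthetic generator (genome, two-class
   annotation, planted region clusters, negative-binomial counts with
   latent-factor couplings and two cohorts) with truth tables for every
   recovery test.

Key statistics, in the field's usual notation: the nearest-gene rule
minimises |center − TSS|; the group code digits are (g, r, l) with
r = 1 ⇒ l = 1; size factors are s_j = median_i (c_ij / (∏_j c_ij)^(1/n));
pair screening uses Spearman's ρ on log2(normalized + 1) with BH-adjusted
two-sided p; motif affinity is the mean over positions and strands of
∏_k p_k(b)/q(b).

## Worked example

Generate a default synthetic dataset (400 genes, 1200 regions, 60 samples
on 2 × 5 Mb chromosomes) and run the whole pipeline:

```bash
ibr simulate --seed 17 --out demo/sim
ibr run-all --gtf demo/sim/genes.gtf --regions demo/sim/regions.bed \
    --gene-counts demo/sim/gene_counts.tsv \
    --region-counts demo/sim/region_counts.tsv \
    --seed 17 --out demo/out
```

The summary (`demo/out/summary.json`) printed for this seed includes:

```json
{
  "n_genes": 400,
  "n_linked_genes": 203,
  "linked_gene_pct": 50.75,
  "n_transcribed_genes": 280,
  "transcribed_gene_pct": 70.0,
  "n_transcribed_regions": 849,
  "transcribed_region_pct": 70.75,
  "n_cotranscribed_genes": 138,
  "cotranscribed_gene_pct": 73.02,
  "n_pairs_screened": 625,
  "n_pairs_positive": 42,
  "n_pairs_negative": 23
}
```

with group sizes `000: 65, 001: 4, 011: 51, 100: 132, 101: 10, 111: 138`
and the called profile peaks:

| label | apex offset (nt) | regions | genes |
|-------|------------------|---------|-------|
| e1    | −1633            | 222     | 127   |
| e2    | −3537            | 214     | 122   |
| e3    | −6803            | 177     | 111   |
| e4    | −8980            | 99      | 81    |

Reading the output: half the genes are linked to at least one region
(`linked_gene_pct`), the generator's planted upstream clusters at −1.5,
−3.5, −6.5 and −9 kb are recovered as peaks e1–e4 with apex intensity
decreasing away from the TSS, and the coordination screen calls 42 positive
and 23 negative region–gene couplings at FDR < 0.05 (the generator planted
40 positive and 20 negative, plus a few borderline nulls). Every percentage
in the report equals 100 · numerator/denominator of counts in the same
report, rounded half-up to 2 decimals.

All stages are also available individually (`ibr annotate`, `ibr link`,
`ibr quant`, `ibr classify`, `ibr profile`, `ibr coordinate`, `ibr motifs`,
`ibr overlap`) or as library functions under `ibrkit.*`.

## Layout

```
src/ibrkit/        annotation, linkage, quant, groups, profile,
                   coordination, motifs, simulate, pipeline, cli
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    models, parameters, design choices, limitations
```
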