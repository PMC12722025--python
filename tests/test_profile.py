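import numpy as np
import pandas as pd
import pytest

from ibrkit.annotation import GeneRecord
from ibrkit.linkage import QWINDOW_HALF, RegionRecord, assign_nearest_gene
from ibrkit.profile import (
    SpatialProfile,
    assign_members,
    build_spatial_profile,
    call_profile_peaks,
)


def brute_force_profile(links, regions, genes, scores, window, n_bins):
    """O(regions x bins) direct overlap-sum oracle."""
    tss = {g.gene_id: (g.tss, g.strand) for g in genes}
    rmap = {r.region_id: r for r in regions}
    bw = 2.0 * window / n_bins
    out = np.zeros(n_bins)
    for row in links.itertuples(index=False):
        if row.region_id not in scores:
            continue
        t, strand = tss[row.gene_id]
        c = rmap[row.region_id].center
        off = c - t if strand == "+" else t - c
        lo, hi = off - QWINDOW_HALF, off + QWINDOW_HALF
        if hi <= -window or lo >= window:
            continue
        for b in range(n_bins):
            blo, bhi = -window + b * bw, -window + (b + 1) * bw
            if min(hi, bhi) - max(lo, blo) > 0:
                out[b] += scores[row.region_id]
    return out


def _instance(rng, n_genes=12, n_regions=60, chrom_len=400_000):
    genes, regions = [], []
    for i in range(n_genes):
        start = 30_000 + i * 30_000
        genes.append(
            GeneRecord(f"G{i}", "chr1", start, start + 5_000, "+" if rng.random() < 0.5 else "-")
        )
    for i in range(n_regions):
        s = int(rng.integers(0, chrom_len - 1_000))
        regions.append(RegionRecord(f"R{i}", "chr1", s, s + int(rng.integers(200, 900))))
    links = assign_nearest_gene(regions, genes)
    scores = {r.region_id: float(rng.uniform(0.5, 5)) for r in regions}
    return genes, regions, links, scores


class TestBuildProfile:
    def test_single_region_at_tss_covers_qwindow_bins(self):
        g = GeneRecord("G", "chr1", 50_000, 60_000, "+")
        r = RegionRecord("R", "chr1", 49_900, 50_100)  # center at TSS
        links = pd.DataFrame({"region_id": ["R"], "gene_id": ["G"], "signed_distance": [0]})
        p = build_spatial_profile(links, [r], [g], {"R": 1.0})
        covered = int((p.bin_scores > 0).sum())
        assert covered in (4, 5)  # 1-kb window over ~272-nt bins
        assert p.bin_scores.max() == 1.0

    def test_empty_region_set_all_zero(self):
        g = GeneRecord("G", "chr1", 0, 100, "+")
        p = build_spatial_profile(
            pd.DataFrame(columns=["region_id", "gene_id", "signed_distance"]), [], [g], {}
        )
        assert not p.bin_scores.any()

    def test_invalid_parameters_error(self):
        g = GeneRecord("G", "chr1", 0, 100, "+")
        empty = pd.DataFrame(columns=["region_id", "gene_id", "signed_distance"])
        with pytest.raises(ValueError):
            build_spatial_profile(empty, [], [g], {}, n_bins=0)
        with pytest.raises(ValueError):
            build_spatial_profile(empty, [], [g], {}, window=-5)

    def test_matches_brute_force_bin_sums(self, rng):
        genes, regions, links, scores = _instance(rng)
        p = build_spatial_profile(links, regions, genes, scores)
        expect = brute_force_profile(links, regions, genes, scores, p.window, p.n_bins)
        assert np.allclose(p.bin_scores, expect, atol=1e-9)

    def test_mass_conservation(self, rng):
        """Total profile mass equals sum of score x overlapped-bin count."""
        genes, regions, links, scores = _instance(rng)
        p = build_spatial_profile(links, regions, genes, scores)
        bw = p.bin_width
        total = 0.0
        rmap = {r.region_id: r for r in regions}
        for rid, off in p.region_offsets.items():
            lo, hi = off - QWINDOW_HALF, off + QWINDOW_HALF
            nb = sum(
                1
                for b in range(p.n_bins)
                if min(hi, -p.window + (b + 1) * bw) - max(lo, -p.window + b * bw) > 0
            )
            total += scores[rid] * nb
        assert p.bin_scores.sum() == pytest.approx(total, abs=1e-9)

    def test_strand_mirror_symmetry(self, rng):
        """Mirroring all coordinates and strands leaves the profile identical."""
        genes, regions, links, scores = _instance(rng)
        L = 400_000
        flip = {"+": "-", "-": "+"}
        mgenes = [
            GeneRecord(g.gene_id, g.chrom, L - g.end, L - g.start, flip[g.strand])
            for g in genes
        ]
        mregions = [
            RegionRecord(r.region_id, r.chrom, L - r.end, L - r.start) for r in regions
        ]
        mlinks = assign_nearest_gene(mregions, mgenes)
        p1 = build_spatial_profile(links, regions, genes, scores)
        p2 = build_spatial_profile(mlinks, mregions, mgenes, scores)
        assert np.allclose(p1.bin_scores, p2.bin_scores)

    def test_length_weighted_conserves_score_mass(self, rng):
        genes, regions, links, scores = _instance(rng)
        p = build_spatial_profile(links, regions, genes, scores, length_weighted=True)
        interior = {
            rid: s
            for rid, s in scores.items()
            if rid in p.region_offsets
            and abs(p.region_offsets[rid]) < p.window - QWINDOW_HALF
        }
        # pro-rated contributions of fully-inside windows sum to their scores
        p_in = build_spatial_profile(
            links, regions, genes, interior, length_weighted=True
        )
        assert p_in.bin_scores.sum() == pytest.approx(sum(interior.values()), rel=1e-9)


class TestPeaks:
    def _profile(self, scores):
        return SpatialProfile(
            window=20_000,
            n_bins=len(scores),
            bin_scores=np.asarray(scores, dtype=float),
            region_offsets=pd.Series(dtype=float),
        )

    def test_single_gaussian_bump(self):
        x = np.arange(101)
        p = self._profile(10 * np.exp(-0.5 * ((x - 30) / 3) ** 2))
        peaks = call_profile_peaks(p)
        assert len(peaks) == 1 and peaks[0].apex_bin == 30

    def test_two_separated_bumps_labelled_by_tss_distance(self):
        x = np.arange(147)
        prof = 5 * np.exp(-0.5 * ((x - 40) / 2.5) ** 2) + 9 * np.exp(
            -0.5 * ((x - 100) / 2.5) ** 2
        )
        peaks = call_profile_peaks(self._profile(prof))
        assert [p.apex_bin for p in peaks[:2]] in ([40, 100], [100, 40])
        # e1 is the apex closest to the TSS (bin 73.5 is offset 0)
        by_label = {p.label: p for p in peaks}
        assert abs(by_label["e1"].apex_offset) <= abs(by_label["e2"].apex_offset)

    def test_all_zero_profile_empty(self):
        assert call_profile_peaks(self._profile(np.zeros(50))) == []

    def test_monotone_profile_single_edge_peak(self):
        peaks = call_profile_peaks(self._profile(np.linspace(0, 10, 60)))
        assert len(peaks) == 1 and peaks[0].apex_bin == 59

    def test_member_assignment_matches_containment(self, rng):
        genes, regions, links, scores = _instance(rng)
        p = build_spatial_profile(links, regions, genes, scores)
        peaks = assign_members(p, call_profile_peaks(p), links)
        bw = p.bin_width
        for pk in peaks:
            for rid in pk.region_ids:
                b = int(np.floor((p.region_offsets[rid] + p.window) / bw))
                assert pk.extent[0] <= b <= pk.extent[1]
        assigned = {rid for pk in peaks for rid in pk.region_ids}
        for rid, off in p.region_offsets.items():
            b = int(np.floor((off + p.window) / bw))
            in_any = any(pk.extent[0] <= b <= pk.extent[1] for pk in peaks)
            # a region is assigned iff some extent contains it (first match wins)
            assert (rid in assigned) == in_any

    def test_planted_cluster_recovery(self, sim, pipeline_result):
        """Planted upstream clusters are recovered within one bin, in order."""
        res = pipeline_result
        offsets = sim.config.cluster_offsets
        p = res.spatial
        bw = p.bin_width
        called = {pk.label: pk for pk in res.peaks}
        for i, off in enumerate(offsets):
            pk = called[f"e{i + 1}"]
            planted_bin = int(np.floor((off + p.window) / bw))
            assert abs(pk.apex_bin - planted_bin) <= 1
        apex_scores = [called[f"e{i + 1}"].apex_score for i in range(len(offsets))]
        assert apex_scores == sorted(apex_scores, reverse=True)
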