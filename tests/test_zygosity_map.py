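import numpy as np
import pytest

from homeoscan.allele_pairing import PairAlignment
from homeoscan.zygosity_map import (
    HEMIZYGOUS,
    HETEROZYGOUS,
    HOMOZYGOUS,
    ZygositySegment,
    estimate_generations,
    junction_report,
    loh_density,
    order_loh_events,
    segment_zygosity,
    window_divergence,
)


def _alignment(length, mismatch_positions=(), unaligned=()):  # helper
    aligned = np.ones(length, dtype=bool)
    mism = np.zeros(length, dtype=bool)
    for s, e in unaligned:
        aligned[s:e] = False
    for p in mismatch_positions:
        mism[p] = True
    mism &= aligned
    return PairAlignment(
        pair_id="pX",
        chrom1_id="c1",
        chrom2_id="c2",
        aligned=aligned,
        mismatch=mism,
        c2pos=np.where(aligned, np.arange(length), -1),
        len2=length,
    )


def _mosaic_alignment(length, het_until, het_rate=0.11, homo_rate=0.00005, seed=0):
    """Heterozygous left part, homozygous right part, exact change-point."""
    rng = np.random.default_rng(seed)
    mism = np.concatenate(
        [
            rng.random(het_until) < het_rate,
            rng.random(length - het_until) < homo_rate,
        ]
    )
    return _alignment(length, np.nonzero(mism)[0])


class TestWindowDivergence:
    def test_identical_windows(self):
        stats = window_divergence(_alignment(30_000))
        assert np.allclose(stats.divergence, 0.0)
        assert np.allclose(stats.aligned_fraction, 1.0)

    def test_two_mismatches_in_window(self):
        stats = window_divergence(_alignment(10_000, mismatch_positions=[100, 200]))
        assert stats.divergence[0] == pytest.approx(2e-4)

    def test_unaligned_window_undefined(self):
        stats = window_divergence(_alignment(10_000, unaligned=[(0, 10_000)]))
        assert np.isnan(stats.divergence[0])
        assert stats.aligned_fraction[0] == 0.0


class TestSegmentation:
    def test_uniformly_heterozygous_single_segment(self):
        aln = _mosaic_alignment(120_000, 120_000)
        segs = segment_zygosity(aln, window_divergence(aln))
        assert [s.label for s in segs] == [HETEROZYGOUS]
        assert (segs[0].start, segs[0].end) == (0, 120_000)

    def test_partition_covers_chromosome(self):
        aln = _mosaic_alignment(150_000, 60_000)
        segs = segment_zygosity(aln, window_divergence(aln))
        assert segs[0].start == 0 and segs[-1].end == 150_000
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start

    def test_junction_recovered_to_base_precision(self):
        """The het->homo change-point lands within ~100 bp of the planted
        boundary thanks to the Poisson refinement."""
        aln = _mosaic_alignment(200_000, 87_654, seed=3)
        segs = segment_zygosity(aln, window_divergence(aln))
        assert [s.label for s in segs] == [HETEROZYGOUS, HOMOZYGOUS]
        assert segs[0].end == pytest.approx(87_654, abs=150)

    def test_unalignable_territory_called_hemizygous(self):
        aln = _alignment(100_000, unaligned=[(40_000, 70_000)])
        segs = segment_zygosity(aln, window_divergence(aln))
        labels = [s.label for s in segs]
        assert HEMIZYGOUS in labels
        hemi = segs[labels.index(HEMIZYGOUS)]
        assert hemi.start == pytest.approx(40_000, abs=6000)
        assert hemi.end == pytest.approx(70_000, abs=6000)

    def test_short_segments_absorbed(self):
        # a 3 kb homozygous islet inside heterozygous territory disappears
        rng = np.random.default_rng(4)
        mism = rng.random(100_000) < 0.11
        mism[50_000:53_000] = False
        aln = _alignment(100_000, np.nonzero(mism)[0])
        segs = segment_zygosity(aln, window_divergence(aln), min_segment=5_000)
        assert [s.label for s in segs] == [HETEROZYGOUS]

    def test_monotonic_in_homo_threshold(self):
        """Raising homo_max can only grow homozygous territory."""
        aln = _mosaic_alignment(150_000, 70_000, homo_rate=0.002, seed=5)
        stats = window_divergence(aln)
        homo_bp = []
        for thr in (0.001, 0.005, 0.02):
            segs = segment_zygosity(aln, stats, homo_max=thr)
            homo_bp.append(sum(s.length for s in segs if s.label == HOMOZYGOUS))
        assert homo_bp == sorted(homo_bp)


class TestLohDensity:
    def test_examples(self):
        aln = _mosaic_alignment(180_000, 0, homo_rate=0.0, seed=6)
        aln.mismatch[np.linspace(100, 179_000, 10, dtype=int)] = True
        seg = ZygositySegment("p", "c", 0, 180_000, HOMOZYGOUS, 0.0, 1.0)
        assert loh_density(seg, aln) == pytest.approx(10 / 18.0, rel=1e-6)

    def test_one_snp_per_51474_bp(self):
        aln = _alignment(51_474, mismatch_positions=[25_000])
        seg = ZygositySegment("p", "c", 0, 51_474, HOMOZYGOUS, 0.0, 1.0)
        assert loh_density(seg, aln) == pytest.approx(0.194, abs=0.001)

    def test_zero_snps(self):
        aln = _alignment(20_000)
        seg = ZygositySegment("p", "c", 0, 20_000, HOMOZYGOUS, 0.0, 1.0)
        assert loh_density(seg, aln) == 0.0

    def test_heterozygous_segment_rejected(self):
        aln = _alignment(20_000)
        seg = ZygositySegment("p", "c", 0, 20_000, HETEROZYGOUS, 0.11, 1.0)
        with pytest.raises(ValueError):
            loh_density(seg, aln)


def _homo_segment(pair_id, density):
    return ZygositySegment(
        pair_id, "c", 0, 100_000, HOMOZYGOUS, density / 1e4, 1.0, snp_per_10kb=density
    )


class TestLohOrdering:
    def test_density_rank_order(self):
        """Densest block is the oldest event: the study's G/H -> K/L -> A/B
        -> C/D succession falls out of the densities alone."""
        segs = [
            _homo_segment("C/D", 0.194),
            _homo_segment("G/H", 0.556),
            _homo_segment("A/B", 0.28),
            _homo_segment("K/L", 0.40),
        ]
        events = order_loh_events(segs)
        assert [e.segment.pair_id for e in events] == ["G/H", "K/L", "A/B", "C/D"]
        assert [e.rank for e in events] == [1, 2, 3, 4]
        assert not any(e.tied for e in events)

    def test_single_segment(self):
        events = order_loh_events([_homo_segment("X", 0.3)])
        assert len(events) == 1 and events[0].rank == 1

    def test_ties_flagged(self):
        events = order_loh_events([_homo_segment("a", 0.3), _homo_segment("b", 0.3)])
        assert all(e.tied for e in events)
        assert events[0].rank == events[1].rank == 1

    def test_empty(self):
        assert order_loh_events([]) == []


class TestGenerations:
    def test_simple_arithmetic(self):
        assert estimate_generations(1e-5, 1e-10, 1) == pytest.approx(100_000)

    def test_study_scale_backcalculation(self):
        """1 SNP per 18,000 bp at the budding-yeast rate of ~3e-10 per site
        per generation gives ~185,000 generations since LOH onset."""
        d = 1 / 18_000
        assert estimate_generations(d, 3.0e-10, 1) == pytest.approx(185_185, rel=1e-3)

    def test_rate_scaling(self):
        g1 = estimate_generations(1e-5, 1e-10, 1)
        g2 = estimate_generations(1e-5, 2e-10, 1)
        assert g1 == pytest.approx(2 * g2)

    def test_zero_density_reports_upper_bound(self):
        with pytest.warns(UserWarning, match="upper bound"):
            assert estimate_generations(0.0, 1e-10, 1) == 0.0

    @pytest.mark.parametrize("mu,factor", [(0.0, 1), (1e-10, 3)])
    def test_invalid_parameters(self, mu, factor):
        with pytest.raises(ValueError):
            estimate_generations(1e-5, mu, factor)


class TestJunctionReport:
    def test_junction_inside_gene_reported(self, small_pipeline, small_sim):
        pr = small_pipeline.pairs["pC"]
        reports = junction_report(pr.segments, pr.gene_pairs, pr.alignment)
        assert len(reports) == 1
        j = reports[0]
        truth = [b for b in small_sim.truth.loh_blocks if b["pair_id"] == "pC"][0]
        assert j.position == pytest.approx(truth["start"], abs=2000)
        assert j.flank_het_identity == pytest.approx(0.89, abs=0.01)
        if j.gene_id is not None:
            gp = [p for p in pr.gene_pairs if p.gene_1.gene_id == j.gene_id][0]
            assert gp.gene_1.start <= j.position < gp.gene_1.end

    def test_intergenic_junction_has_empty_gene_field(self):
        aln = _mosaic_alignment(120_000, 60_000, seed=9)
        segs = segment_zygosity(aln, window_divergence(aln))
        reports = junction_report(segs, [], aln)
        assert len(reports) == 1
        assert reports[0].gene_id is None
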