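import numpy as np
import pytest

from homeoscan.feature_scan import (
    BIALLELIC_NUMT,
    HEMIZYGOUS_NUMT,
    NumtHit,
    classify_numt_states,
    match_centromere_pairs,
    numt_asymmetry,
    scan_centromeres,
    scan_numts,
)
from homeoscan.gc_trend import P_EPSILON, P_GAMMA
from homeoscan.genome_io import ChromosomeRecord, GeneAnnotation, Genome, reverse_complement
from homeoscan.allele_pairing import PairAlignment

from .conftest import mutate, random_dna
from .oracles import brute_numt_hits


class TestCentromereScan:
    def test_uniform_chromosome_has_no_candidates(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 60_000, gc=0.45)
        assert scan_centromeres(seq, [], "c") == []

    def test_planted_island_called_once(self):
        """Gene-free GC-poor island among densely annotated background: one
        call (the gene-free filter suppresses background GC dips)."""
        rng = np.random.default_rng(1)
        base = random_dna(rng, 80_000, gc=0.45)
        island = random_dna(rng, 2500, gc=0.45 * 0.88)
        seq = base[:40_000] + island + base[40_000:]
        genes = [
            GeneAnnotation(f"g{k}", "c", s, s + 1400, "+")
            for k, s in enumerate(range(0, len(seq) - 1500, 2000))
            if not (38_000 <= s <= 44_000)  # gene-free window hosts the island
        ]
        cands = scan_centromeres(seq, genes, "c")
        assert len(cands) == 1
        c = cands[0]
        assert c.start < 40_000 + 1250 < c.end
        assert c.unique and c.gene_free
        assert c.mean_gc < c.global_gc

    def test_island_overlapping_gene_excluded(self):
        rng = np.random.default_rng(2)
        base = random_dna(rng, 80_000, gc=0.45)
        island = random_dna(rng, 2500, gc=0.45 * 0.88)
        seq = base[:40_000] + island + base[40_000:]
        gene = GeneAnnotation("g", "c", 41_000, 41_900, "+")
        assert scan_centromeres(seq, [gene], "c") == []

    def test_simulated_islands_all_recovered(self, small_sim):
        g = small_sim.genome
        for cen in small_sim.truth.centromeres:
            chrom = cen["chromosome_id"]
            cands = scan_centromeres(
                g.chromosomes[chrom].sequence, g.genes_of(chrom), chrom
            )
            assert len(cands) == 1
            assert cands[0].start < (cen["start"] + cen["end"]) // 2 < cands[0].end


class TestCentromereMatching:
    def test_homologous_islands_matched(self, small_sim, small_pipeline):
        g = small_sim.genome
        for pair_id, c1_id, c2_id in g.pairs:
            aln = small_pipeline.pairs[pair_id].alignment
            m = match_centromere_pairs(
                small_pipeline.centromeres[c1_id],
                small_pipeline.centromeres[c2_id],
                aln,
            )
            assert len(m) == 1
            c1, c2 = m[0]
            assert c2 is not None
            assert c1.partner_start == c2.start

    def test_unmatched_island_flagged(self):
        from homeoscan.feature_scan import CentromereCandidate

        aln = PairAlignment(
            "p", "c1", "c2",
            aligned=np.ones(100_000, dtype=bool),
            mismatch=np.zeros(100_000, dtype=bool),
            c2pos=np.arange(100_000),
            len2=100_000,
        )
        lone = CentromereCandidate("c1", 50_000, 52_500, 10.0, 0.4, 0.45, True)
        m = match_centromere_pairs([lone], [], aln)
        assert m == [(lone, None)]


def _two_copy_genome(seq1, seq2):
    genome = Genome(
        chromosomes={
            "c1": ChromosomeRecord("c1", seq1, "pA", 1),
            "c2": ChromosomeRecord("c2", seq2, "pA", 2),
        },
        genes={"c1": [], "c2": []},
        pairs=[("pA", "c1", "c2")],
    )
    n = min(len(seq1), len(seq2))
    a1 = np.frombuffer(seq1[:n].encode(), dtype=np.uint8)
    a2 = np.frombuffer(seq2[:n].encode(), dtype=np.uint8)
    aligned = np.zeros(len(seq1), dtype=bool)
    aligned[:n] = True
    mism = np.zeros(len(seq1), dtype=bool)
    mism[:n] = a1 != a2
    aln = PairAlignment(
        "pA", "c1", "c2", aligned, mism,
        np.where(aligned, np.arange(len(seq1)), -1), len(seq2),
    )
    return genome, {"pA": aln}


class TestNumtScan:
    def test_no_shared_kmers_no_hits(self):
        rng = np.random.default_rng(3)
        genome, _ = _two_copy_genome("AT" * 2000, "AT" * 2000)
        assert scan_numts(genome, "GC" * 1000) == []

    def test_planted_fragment_found_and_hemizygous(self):
        rng = np.random.default_rng(4)
        mito = random_dna(rng, 5000)
        nuc1 = random_dna(rng, 8000)
        nuc2 = random_dna(rng, 8000)
        frag = mutate(rng, mito[1000:1300], 0.05)
        seq1 = nuc1[:4000] + frag + nuc1[4000:]
        genome, alns = _two_copy_genome(seq1, nuc2 + random_dna(rng, 300))
        hits = scan_numts(genome, mito)
        hits = [h for h in hits if h.length_bp >= 100]
        assert len(hits) == 1
        h = hits[0]
        assert h.chromosome_id == "c1"
        assert h.start == pytest.approx(4000, abs=30)
        assert h.identity >= 0.9
        assert 900 <= h.mito_start <= 1100
        classify_numt_states(hits, genome, alns)
        assert h.state == HEMIZYGOUS_NUMT

    def test_fragment_on_both_copies_biallelic(self):
        rng = np.random.default_rng(5)
        mito = random_dna(rng, 5000)
        nuc = random_dna(rng, 8000)
        frag = mutate(rng, mito[2000:2400], 0.03)
        seq = nuc[:3000] + frag + nuc[3000:]
        genome, alns = _two_copy_genome(seq, seq)
        hits = [h for h in scan_numts(genome, mito) if h.length_bp >= 100]
        assert len(hits) == 2
        classify_numt_states(hits, genome, alns)
        assert {h.state for h in hits} == {BIALLELIC_NUMT}

    def test_reverse_strand_fragment_found(self):
        rng = np.random.default_rng(6)
        mito = random_dna(rng, 5000)
        nuc = random_dna(rng, 6000)
        frag = reverse_complement(mito[800:1100])
        seq = nuc[:2500] + frag + nuc[2500:]
        genome, _ = _two_copy_genome(seq, random_dna(rng, 6300))
        hits = [h for h in scan_numts(genome, mito) if h.length_bp >= 100]
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert 700 <= hits[0].mito_start <= 900

    def test_strand_symmetry(self):
        """Scanning against the reverse-complemented mitochondrial genome
        yields the same nuclear hit intervals."""
        rng = np.random.default_rng(7)
        mito = random_dna(rng, 4000)
        nuc = random_dna(rng, 5000)
        seq = (
            nuc[:1000]
            + mutate(rng, mito[100:400], 0.04)
            + nuc[1000:3000]
            + reverse_complement(mutate(rng, mito[2000:2500], 0.04))
            + nuc[3000:]
        )
        genome, _ = _two_copy_genome(seq, random_dna(rng, len(seq)))
        fwd = {(h.chromosome_id, h.start, h.end) for h in scan_numts(genome, mito)}
        rev = {
            (h.chromosome_id, h.start, h.end)
            for h in scan_numts(genome, reverse_complement(mito))
        }
        assert fwd == rev

    @pytest.mark.parametrize("case", range(4))
    def test_matches_exhaustive_oracle_on_toys(self, case):
        rng = np.random.default_rng(40 + case)
        mito = random_dna(rng, 1500)
        nuc = random_dna(rng, 3000)
        inserts = []
        for _ in range(2):
            s = int(rng.integers(0, 1200))
            ln = int(rng.integers(80, 300))
            frag = mutate(rng, mito[s : s + ln], float(rng.uniform(0.0, 0.1)))
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            pos = int(rng.integers(200, 2800))
            nuc = nuc[:pos] + frag + nuc[pos:]
            inserts.append(pos)
        genome, _ = _two_copy_genome(nuc, random_dna(rng, len(nuc)))
        got = sorted(
            (h.start, h.end) for h in scan_numts(genome, mito) if h.chromosome_id == "c1"
        )
        expected = brute_numt_hits(nuc, mito)
        assert got == expected


class TestAsymmetry:
    def _origin(self, label):
        return lambda chrom, pos: label

    def test_zero_hits_empty_summary(self, small_sim, small_pipeline):
        summ = numt_asymmetry(
            [], small_sim.genome, {p: r.alignment for p, r in small_pipeline.pairs.items()},
            self._origin(P_GAMMA),
        )
        assert summ.n_loci == 0 and summ.ratio is None and not summ.infinite

    def test_single_subgenome_flagged_infinite(self, small_sim, small_pipeline):
        hits = [
            NumtHit("chrA_1", 100, 400, 0, 300, "+", 0.95, state=HEMIZYGOUS_NUMT)
        ]
        summ = numt_asymmetry(
            hits, small_sim.genome,
            {p: r.alignment for p, r in small_pipeline.pairs.items()},
            self._origin(P_EPSILON),
        )
        assert summ.ratio is None and summ.infinite

    def test_counts_by_subgenome(self, small_sim, small_pipeline):
        """Locus counting (biallelic twins merged) with ground-truth origins
        reproduces the planted per-subgenome counts exactly."""
        truth = small_sim.truth
        expected = {P_GAMMA: 0, P_EPSILON: 0}
        for n in truth.numts:
            expected[n["parent"]] += 1
        summ = numt_asymmetry(
            small_pipeline.numt_hits,
            small_sim.genome,
            {p: r.alignment for p, r in small_pipeline.pairs.items()},
            truth.origin_at,
        )
        assert summ.counts[P_GAMMA] == expected[P_GAMMA]
        assert summ.counts[P_EPSILON] == expected[P_EPSILON]
        assert summ.n_loci == len(truth.numts)
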