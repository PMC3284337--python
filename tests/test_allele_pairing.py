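import numpy as np
import pytest
from hypothesis import given, strategies as st

from homeoscan.allele_pairing import (
    align_alleles,
    align_chromosome_pair,
    hamming_identity,
    pair_genes,
    select_dgc_genes,
)
from homeoscan.genome_io import ChromosomeRecord, GeneAnnotation, Genome

from .oracles import brute_collinear_matching, nw_affine_oracle
from .conftest import mutate, random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestAlignAlleles:
    def test_identical_sequences(self):
        a = align_alleles("ACGT", "ACGT")
        assert a.identity == 1.0
        assert a.gap_columns == 0

    def test_single_mismatch(self):
        a = align_alleles("ACGTACGT", "ACGAACGT")
        assert a.identity == pytest.approx(7 / 8)

    @given(dna)
    def test_self_identity_is_one(self, s):
        assert align_alleles(s, s).identity == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_alleles("", "ACGT")

    @pytest.mark.parametrize("case", range(12))
    def test_matches_reference_dp_oracle(self, case):
        """Score and identity equal an independent Gotoh implementation on
        diverged allele pairs with substitutions and indels."""
        rng = np.random.default_rng(900 + case)
        n = int(rng.integers(40, 120))
        s1 = random_dna(rng, n)
        s2 = mutate(rng, s1, rate=float(rng.uniform(0.02, 0.3)))
        # introduce up to two indels
        for _ in range(int(rng.integers(0, 3))):
            pos = int(rng.integers(0, len(s2)))
            if rng.random() < 0.5:
                s2 = s2[:pos] + random_dna(rng, int(rng.integers(1, 5))) + s2[pos:]
            else:
                s2 = s2[:pos] + s2[pos + int(rng.integers(1, 5)) :]
        if not s2:
            s2 = "A"
        score, identity, ops = nw_affine_oracle(s1, s2)
        a = align_alleles(s1, s2)
        assert a.score == pytest.approx(score)
        assert a.identity == pytest.approx(identity)
        assert a.ops == ops


def _toy_genome(cds1, cds2):
    """Two single-pair chromosomes whose genes are laid out back to back."""

    def build(cds_list, chrom_id, copy):
        seq = ""
        genes = []
        for k, c in enumerate(cds_list):
            genes.append(
                GeneAnnotation(
                    gene_id=f"{chrom_id}g{k}",
                    chromosome_id=chrom_id,
                    start=len(seq),
                    end=len(seq) + len(c),
                    strand="+",
                )
            )
            seq += c
        seq += "ACGT"  # tail so sequences are non-empty even with no genes
        return ChromosomeRecord(chrom_id, seq, "pA", copy), genes

    c1, g1 = build(cds1, "c1", 1)
    c2, g2 = build(cds2, "c2", 2)
    genome = Genome(
        chromosomes={"c1": c1, "c2": c2},
        genes={"c1": g1, "c2": g2},
        pairs=[("pA", "c1", "c2")],
    )
    return genome, g1, g2


class TestPairGenes:
    def test_identical_gene_lists_fully_paired(self):
        rng = np.random.default_rng(0)
        cds = [random_dna(rng, 60) for _ in range(5)]
        genome, g1, g2 = _toy_genome(cds, cds)
        pairs, s1, s2 = pair_genes(g1, g2, genome)
        assert len(pairs) == 5 and not s1 and not s2
        assert all(p.nucleotide_identity == 1.0 for p in pairs)

    def test_inserted_gene_reported_single_allele(self):
        """Copy 2 carries one extra gene; the optimal collinear matching
        (checked against exhaustive enumeration) leaves exactly it unpaired."""
        rng = np.random.default_rng(1)
        cds = [random_dna(rng, 66) for _ in range(6)]
        extra = random_dna(rng, 66)
        cds2 = cds[:3] + [extra] + cds[3:]
        genome, g1, g2 = _toy_genome(cds, cds2)
        pairs, s1, s2 = pair_genes(g1, g2, genome)
        assert len(pairs) == 6 and not s1
        assert [g.gene_id for g in s2] == ["c2g3"]
        # cross-check the matching weight against brute force
        weights = {}
        for i in range(6):
            for j in range(7):
                ident = hamming_identity(cds[i], cds2[j]) if len(cds[i]) == len(cds2[j]) else 0.0
                if ident >= 0.5:
                    weights[(i, j)] = ident
        best_w, best_pairs = brute_collinear_matching(weights, max_rank_offset=3)
        got = [(g1.index(p.gene_1), g2.index(p.gene_2)) for p in pairs]
        assert got == best_pairs

    def test_divergent_alleles_identity(self):
        """300-nt alleles differing at 30 positions pair at identity 0.90."""
        rng = np.random.default_rng(2)
        a = random_dna(rng, 300)
        pos = rng.choice(300, size=30, replace=False)
        b = list(a)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        genome, g1, g2 = _toy_genome([a], ["".join(b)])
        pairs, _, _ = pair_genes(g1, g2, genome)
        assert pairs[0].nucleotide_identity == pytest.approx(0.90)

    def test_empty_side_yields_single_alleles(self):
        rng = np.random.default_rng(3)
        cds = [random_dna(rng, 60) for _ in range(3)]
        genome, g1, _ = _toy_genome(cds, [])
        pairs, s1, s2 = pair_genes(g1, [], genome)
        assert not pairs and len(s1) == 3 and not s2

    def test_matching_is_symmetric(self):
        """Swapping the copy-1/copy-2 inputs returns the same pair set."""
        rng = np.random.default_rng(4)
        cds1 = [random_dna(rng, 60) for _ in range(8)]
        cds2 = [mutate(rng, c, 0.1) for c in cds1]
        del cds2[4]
        genome, g1, g2 = _toy_genome(cds1, cds2)
        fwd, f1, f2 = pair_genes(g1, g2, genome)
        rev, r2, r1 = pair_genes(g2, g1, genome)
        fwd_ids = {(p.gene_1.gene_id, p.gene_2.gene_id) for p in fwd}
        rev_ids = {(p.gene_2.gene_id, p.gene_1.gene_id) for p in rev}
        assert fwd_ids == rev_ids
        assert {g.gene_id for g in f1} == {g.gene_id for g in r1}


class TestSelectDgcGenes:
    def test_identical_length_filter(self):
        rng = np.random.default_rng(5)
        lens = [(300, 300), (300, 303), (150, 150)]
        cds1 = [random_dna(rng, a) for a, _ in lens]
        cds2 = [mutate(rng, c, 0.05)[: b] .ljust(b, "A") for c, (_, b) in zip(cds1, lens)]
        genome, g1, g2 = _toy_genome(cds1, cds2)
        pairs, _, _ = pair_genes(g1, g2, genome)
        subset = select_dgc_genes(pairs)
        assert [p.cds_length_1 for p in subset] == [300, 150]

    def test_all_unequal_warns_and_returns_empty(self):
        rng = np.random.default_rng(6)
        genome, g1, g2 = _toy_genome([random_dna(rng, 300)], [random_dna(rng, 303)])
        pairs, _, _ = pair_genes(g1, g2, genome, min_identity=0.0)
        with pytest.warns(UserWarning, match="identical-length"):
            assert select_dgc_genes(pairs) == []

    def test_indel_free_simulation_keeps_all_pairs(self, tiny_sim):
        g = tiny_sim.genome
        pairs, s1, s2 = pair_genes(
            g.genes_of("chrA_1"), g.genes_of("chrA_2"), g, pair_id="pA"
        )
        assert not s1 and not s2
        assert len(select_dgc_genes(pairs)) == len(pairs)


class TestChromosomePairAlignment:
    def test_divergence_matches_planted_rate(self, tiny_sim):
        g = tiny_sim.genome
        pairs, _, _ = pair_genes(
            g.genes_of("chrA_1"), g.genes_of("chrA_2"), g, pair_id="pA"
        )
        aln = align_chromosome_pair(g, "pA", pairs)
        # mask planted unrelated territory (centromere island, NUMTs), which
        # dominates the average on a chromosome this short
        keep = np.ones(len(aln.aligned), dtype=bool)
        for cen in tiny_sim.truth.centromeres:
            if cen["chromosome_id"] == "chrA_1":
                keep[cen["start"] - 500 : cen["end"] + 500] = False
        for numt in tiny_sim.truth.numts:
            for pl in numt["placements"]:
                if pl["chromosome_id"].startswith("chrA"):
                    keep[pl["start"] - 100 : pl["end"] + 100] = False
        div = (aln.mismatch & keep).sum() / (aln.aligned & keep).sum()
        assert div == pytest.approx(0.1084, abs=0.005)
        # projection is monotone over aligned columns
        c2 = aln.c2pos[aln.aligned]
        assert (np.diff(c2) > 0).all()

    def test_projection_roundtrip(self, tiny_sim):
        g = tiny_sim.genome
        pairs, _, _ = pair_genes(
            g.genes_of("chrB_1"), g.genes_of("chrB_2"), g, pair_id="pB"
        )
        aln = align_chromosome_pair(g, "pB", pairs)
        rev = aln.c1pos()
        idx = np.nonzero(aln.aligned)[0][::97]
        assert (rev[aln.c2pos[idx]] == idx).all()
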