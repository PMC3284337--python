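"""Seeded generator of allodiploid hybrid genomes with known ground truth.

The generative model mirrors the history the pipeline is built to read back:

1. an ancestor genome is drawn as a gene/intergenic mosaic, genes built
   codon-wise so that third-position T/C usage is controllable;
2. two parents ("gamma", the GC-richer, and "epsilon") are derived by
   substituting sites to a target divergence, with a directed third-position
   C->T excess in epsilon over the 12 two-codon tRNA families;
3. parent-specific NUMTs (copied from a generated mitochondrial genome) and
   one gene-free AT-rich centromere island per chromosome are planted;
4. the hybrid is formed (one copy per parent and pair), loss of
   heterozygosity overwrites configured blocks with one parent's sequence
   and sprinkles residual SNPs at a planted density, and one reciprocal
   exchange swaps the two copies distal to a breakpoint.

Every planted structure is reported in a SimTruth record whose coordinates
refer to the emitted FASTA/GFF, so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .genome_io import ChromosomeRecord, GeneAnnotation, Genome

GAMMA = "Pgamma"
EPSILON = "Pepsilon"

# 2-bit encoding A=0, C=1, G=2, T=3; complement is 3-x.
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_IDS = (48, 50, 56)  # TAA, TAG, TGA as 16a+4b+c


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class LohBlockSpec:
    """A planted LOH block: part of one pair resolved to one parent."""

    pair_index: int
    start_frac: float
    end_frac: float
    parent: str  # GAMMA or EPSILON
    snp_per_10kb: float


@dataclass
class SimConfig:
    seed: int
    n_pairs: int = 7
    genes_per_chromosome: int = 500
    mean_cds_codons: int = 465
    sd_cds_codons: int = 110
    min_cds_codons: int = 60
    mean_intergenic_len: int = 600
    min_intergenic_len: int = 150
    intergenic_gc: Optional[float] = None  # default: expected coding GC
    het_divergence: float = 0.1084
    third_pos_c_offset: float = 1.57
    family_codon_fraction: float = 0.55
    loh_fraction: float = 0.40
    loh_blocks: Optional[list[LohBlockSpec]] = None
    exchange_events: Optional[list[tuple[int, int]]] = None  # (pair, gene index)
    numt_hemizygous: tuple[int, int] = (1, 13)  # (gamma, epsilon)
    numt_biallelic: tuple[int, int] = (3, 7)
    numt_len_range: tuple[int, int] = (150, 800)
    numt_identity: float = 0.95
    centromere_len: int = 2500
    centromere_flank: int = 1750
    centromere_gc_deficit: float = 0.12
    centromere_gene_frac: float = 0.45
    minus_strand_fraction: float = 0.4
    indel_rate: float = 0.0
    mito_len: int = 30_000
    mito_gc: float = 0.25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for f in (self.het_divergence, self.loh_fraction, self.indel_rate):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be within [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of a simulated hybrid, on emitted-file coordinates."""

    copy1_parent: dict[str, str]  # pair_id -> parent of copy 1
    origin_intervals: dict[str, list[tuple[int, int, str]]]  # per chromosome
    loh_blocks: list[dict]
    exchanges: list[dict]
    numts: list[dict]
    centromeres: list[dict]
    n_genes: dict[str, int]  # per pair

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        d["origin_intervals"] = {
            k: [tuple(x) for x in v] for k, v in d["origin_intervals"].items()
        }
        return cls(**d)

    def origin_at(self, chromosome_id: str, pos: int) -> str:
        for s, e, p in self.origin_intervals[chromosome_id]:
            if s <= pos < e:
                return p
        raise KeyError((chromosome_id, pos))


# ---------------------------------------------------------------------------
# codon pool
# ---------------------------------------------------------------------------


def _codon_pool(family_fraction: float) -> np.ndarray:
    """Length-64 codon sampling probabilities for ancestor/gamma genes.

    The 12 two-codon NNT/NNC families carry ``family_fraction`` of all
    codons, weighted and T/C-split like the published GC-richer subgenome;
    the remaining mass is uniform over the other sense codons.
    """
    from .codon_bias import TWO_CODON_FAMILIES, load_published_counts, _codon_index

    gamma, _ = load_published_counts()
    fam_tot = gamma.n_t + gamma.n_c
    weights = fam_tot / fam_tot.sum() * family_fraction
    p = np.zeros(64)
    family_ids = set()
    for i, (_aa, ct, cc) in enumerate(TWO_CODON_FAMILIES):
        it, ic = _codon_index(ct), _codon_index(cc)
        u_t = gamma.n_t[i] / fam_tot[i]
        p[it] = weights[i] * u_t
        p[ic] = weights[i] * (1.0 - u_t)
        family_ids.update((it, ic))
    others = [i for i in range(64) if i not in family_ids and i not in _STOP_IDS]
    p[others] = (1.0 - family_fraction) / len(others)
    return p / p.sum()


def expected_coding_gc(pool: np.ndarray) -> float:
    codons = np.arange(64)
    bases = np.stack([codons // 16, (codons // 4) % 4, codons % 4])
    gc = ((bases == 1) | (bases == 2)).sum(axis=0) / 3.0
    return float((pool * gc).sum())


# ---------------------------------------------------------------------------
# internal part model
# ---------------------------------------------------------------------------


@dataclass
class _Part:
    kind: str  # 'intergenic' | 'gene' | 'centromere'
    strand: str = "+"
    gene_index: int = -1
    island: Optional[tuple[int, int]] = None  # island offsets within part
    seq: dict = field(default_factory=dict)  # parent/copy label -> 2-bit array


def _sense(arr: np.ndarray, strand: str) -> np.ndarray:
    return arr if strand == "+" else (3 - arr[::-1])


def _from_sense(arr: np.ndarray, strand: str) -> np.ndarray:
    return arr if strand == "+" else (3 - arr[::-1])


def _repair_stops(sense: np.ndarray) -> None:
    """Set the third base of internal stop codons to C (in place, sense frame)."""
    body = sense[3:-3]
    cods = body.reshape(-1, 3)
    ids = cods[:, 0] * 16 + cods[:, 1] * 4 + cods[:, 2]
    bad = np.isin(ids, _STOP_IDS)
    cods[bad, 2] = 1  # TAC / TGC, never a stop


class _PairBuild:
    """Working state for one chromosome pair during generation."""

    def __init__(self, pair_index: int, parts: list[_Part]):
        self.pair_index = pair_index
        self.parts = parts
        self.copy_parent: dict[int, str] = {}
        self.copy_parts: dict[int, list[np.ndarray]] = {}
        self.copy_origin: dict[int, list[str]] = {}
        self.loh_part_ranges: list[tuple[int, int, LohBlockSpec]] = []
        self.exchange_part: Optional[int] = None

    def part_lengths(self, parent: str) -> np.ndarray:
        return np.array([len(p.seq[parent]) for p in self.parts], dtype=np.int64)

    def copy_offsets(self, copy: int) -> np.ndarray:
        lens = [len(a) for a in self.copy_parts[copy]]
        return np.concatenate([[0], np.cumsum(lens)])


def generate(config: SimConfig):
    """Generate a hybrid genome; returns a SimResult (genome, mito, truth)."""
    rng = np.random.default_rng(config.seed)
    pool = _codon_pool(config.family_codon_fraction)
    coding_gc = expected_coding_gc(pool)
    inter_gc = config.intergenic_gc if config.intergenic_gc is not None else coding_gc

    pair_letters = [chr(ord("A") + i) for i in range(config.n_pairs)]
    builds: list[_PairBuild] = []

    def rand_seq(n: int, gc: float) -> np.ndarray:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return rng.choice(4, size=n, p=p).astype(np.uint8)

    # --- 1. ancestor/gamma structure and sequence -------------------------
    cen_gene = int(config.genes_per_chromosome * config.centromere_gene_frac)
    for pi in range(config.n_pairs):
        parts: list[_Part] = []
        for gi in range(config.genes_per_chromosome):
            ilen = max(
                config.min_intergenic_len,
                int(rng.normal(config.mean_intergenic_len, config.mean_intergenic_len / 3)),
            )
            parts.append(_Part("intergenic"))
            parts[-1].seq[GAMMA] = rand_seq(ilen, inter_gc)
            if gi == cen_gene:
                clen = config.centromere_len + 2 * config.centromere_flank
                cen = _Part(
                    "centromere",
                    island=(config.centromere_flank, config.centromere_flank + config.centromere_len),
                )
                cen.seq[GAMMA] = rand_seq(clen, inter_gc)
                parts.append(cen)
            ncod = max(
                config.min_cds_codons,
                int(rng.normal(config.mean_cds_codons, config.sd_cds_codons)),
            )
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            codons = rng.choice(64, size=ncod, p=pool)
            sense = np.empty(3 * (ncod + 2), dtype=np.uint8)
            sense[:3] = (0, 3, 2)  # ATG
            body = np.stack([codons // 16, (codons // 4) % 4, codons % 4], axis=1)
            sense[3:-3] = body.reshape(-1).astype(np.uint8)
            sense[-3:] = (3, 0, 0)  # TAA
            gene = _Part("gene", strand=strand, gene_index=gi)
            gene.seq[GAMMA] = _from_sense(sense, strand)
            parts.append(gene)
        tail = _Part("intergenic")
        tail.seq[GAMMA] = rand_seq(
            max(config.min_intergenic_len, int(rng.normal(config.mean_intergenic_len, config.mean_intergenic_len / 3))),
            inter_gc,
        )
        parts.append(tail)
        builds.append(_PairBuild(pi, parts))

    # --- 2. parents by symmetric substitution from the ancestor -----------
    # Each parent mutates independently at the same rate, so compositional
    # (mutation-pressure) drift is identical in the two parents and cancels
    # in every within-pair comparison.  Substitutions are applied in two
    # rounds: an undershooting first round, then -- after the directed
    # third-position flips and stop repairs, which add their own mismatches
    # -- a measured top-up so the realized divergence hits het_divergence.
    q = config.het_divergence

    def _per_parent_rate(target: float) -> float:
        # pairwise divergence of two independently mutated copies:
        # 1 - (1-r)^2 - r^2/3 = 2r - (4/3) r^2 = target
        if target <= 0:
            return 0.0
        return (2.0 - float(np.sqrt(4.0 - 16.0 * target / 3.0))) / (8.0 / 3.0)

    def _substitute_round(rate: float, first_round: bool) -> None:
        for b in builds:
            for part in b.parts:
                ancestor = part.seq[GAMMA] if first_round else None
                for parent in (GAMMA, EPSILON):
                    e = (ancestor if first_round else part.seq[parent]).copy()
                    mask = rng.random(len(e)) < rate
                    n = int(mask.sum())
                    if n:
                        e[mask] = (
                            e[mask] + rng.integers(1, 4, size=n).astype(np.uint8)
                        ) % 4
                    if part.kind == "gene":
                        s = _sense(e, part.strand).copy()
                        _repair_stops(s)
                        e = _from_sense(s, part.strand)
                        if (
                            first_round
                            and parent == EPSILON
                            and config.indel_rate > 0
                            and rng.random() < config.indel_rate
                        ):
                            s = _sense(e, part.strand).copy()
                            if rng.random() < 0.5 and len(s) > 3 * (
                                config.min_cds_codons + 2
                            ):
                                cut = 3 * int(rng.integers(1, len(s) // 3 - 1))
                                s = np.concatenate([s[:cut], s[cut + 3 :]])
                            else:
                                ins = rng.choice(64, p=pool)
                                cut = 3 * int(rng.integers(1, len(s) // 3 - 1))
                                tri = np.array(
                                    [ins // 16, (ins // 4) % 4, ins % 4],
                                    dtype=np.uint8,
                                )
                                s = np.concatenate([s[:cut], tri, s[cut:]])
                            _repair_stops(s)
                            e = _from_sense(s, part.strand)
                    part.seq[parent] = e

    def _measured_divergence() -> float:
        mism = total_len = 0
        for b in builds:
            for part in b.parts:
                a, e = part.seq[GAMMA], part.seq[EPSILON]
                if len(a) != len(e):
                    continue  # indel parts: skip in the calibration measure
                mism += int((a != e).sum())
                total_len += len(a)
        return mism / total_len if total_len else 0.0

    undershoot = 0.008 if q > 0.02 else 0.0
    _substitute_round(_per_parent_rate(q - undershoot), first_round=True)

    # --- 3. third-position calibration on the 12 families -----------------
    _calibrate_third_position(builds, config, rng)
    if undershoot > 0:
        topup = q - _measured_divergence()
        if topup > 0:
            _substitute_round(_per_parent_rate(topup), first_round=False)

    # --- 4. centromere islands (independent AT-rich sequence per parent) --
    island_gc = (1.0 - config.centromere_gc_deficit) * inter_gc
    for b in builds:
        for part in b.parts:
            if part.kind == "centromere":
                s, e = part.island
                for parent in (GAMMA, EPSILON):
                    part.seq[parent] = part.seq[parent].copy()
                    part.seq[parent][s:e] = rand_seq(e - s, island_gc)

    # --- 5. LOH layout and exchange selection -----------------------------
    exchanges = (
        config.exchange_events
        if config.exchange_events is not None
        else [(0, config.genes_per_chromosome // 2)]
    )
    exchange_pairs = {pi for pi, _ in exchanges}
    blocks = config.loh_blocks
    if blocks is None:
        blocks = _default_loh_layout(builds, config, exchange_pairs)
    for blk in blocks:
        if blk.pair_index in exchange_pairs:
            raise ValueError("LOH block would overlap a reciprocal exchange pair")
    for blk in blocks:
        b = builds[blk.pair_index]
        lens = b.part_lengths(GAMMA)
        offs = np.concatenate([[0], np.cumsum(lens)])
        total = offs[-1]
        p0 = int(np.searchsorted(offs, blk.start_frac * total, side="right") - 1)
        p1 = int(np.searchsorted(offs, blk.end_frac * total, side="left"))
        p0 = max(0, p0)
        p1 = min(len(b.parts), max(p1, p0 + 1))
        b.loh_part_ranges.append((p0, p1, blk))

    # --- 6. mitochondrial genome and NUMT planting ------------------------
    mito = rand_seq(config.mito_len, config.mito_gc)
    numt_records = _plant_numts(builds, config, mito, exchange_pairs, rng)

    # --- 7. hybrid assembly, LOH overwrite + sprinkle, exchange -----------
    for b in builds:
        c1_parent = GAMMA if rng.random() < 0.5 else EPSILON
        c2_parent = EPSILON if c1_parent == GAMMA else GAMMA
        b.copy_parent = {1: c1_parent, 2: c2_parent}
        for copy, parent in b.copy_parent.items():
            b.copy_parts[copy] = [p.seq[parent].copy() for p in b.parts]
            b.copy_origin[copy] = [parent] * len(b.parts)
    loh_truth: list[dict] = []
    for b in builds:
        for p0, p1, blk in b.loh_part_ranges:
            src = 1 if b.copy_parent[1] == blk.parent else 2
            dst = 3 - src
            for p in range(p0, p1):
                b.copy_parts[dst][p] = b.copy_parts[src][p].copy()
                b.copy_origin[dst][p] = blk.parent
            n_planted, block_len = _sprinkle_block(b, p0, p1, blk, rng)
            offs = b.copy_offsets(1)
            loh_truth.append(
                {
                    "pair_id": f"p{pair_letters[b.pair_index]}",
                    "start": int(offs[p0]),
                    "end": int(offs[p1]),
                    "parent": blk.parent,
                    "snp_per_10kb": blk.snp_per_10kb,
                    "achieved_snp_per_10kb": n_planted / block_len * 1e4,
                }
            )
    exchange_truth: list[dict] = []
    for pi, gene_idx in exchanges:
        b = builds[pi]
        pb = None
        for k, part in enumerate(b.parts):
            if part.kind == "gene" and part.gene_index == gene_idx:
                pb = k + 1  # boundary after this gene part
                break
        if pb is None:
            raise ValueError(f"exchange gene index {gene_idx} not found in pair {pi}")
        b.exchange_part = pb
        b.copy_parts[1][pb:], b.copy_parts[2][pb:] = (
            b.copy_parts[2][pb:],
            b.copy_parts[1][pb:],
        )
        b.copy_origin[1][pb:], b.copy_origin[2][pb:] = (
            b.copy_origin[2][pb:],
            b.copy_origin[1][pb:],
        )
        exchange_truth.append(
            {
                "pair_id": f"p{pair_letters[pi]}",
                "position": int(b.copy_offsets(1)[pb]),
            }
        )

    # --- 8. emit genome model + truth -------------------------------------
    chromosomes: dict[str, ChromosomeRecord] = {}
    genes: dict[str, list[GeneAnnotation]] = {}
    pairs: list[tuple[str, str, str]] = []
    origin_intervals: dict[str, list[tuple[int, int, str]]] = {}
    centromere_truth: list[dict] = []
    n_genes: dict[str, int] = {}
    copy1_parent: dict[str, str] = {}
    for b in builds:
        letter = pair_letters[b.pair_index]
        pair_id = f"p{letter}"
        c1_id, c2_id = f"chr{letter}_1", f"chr{letter}_2"
        pairs.append((pair_id, c1_id, c2_id))
        copy1_parent[pair_id] = b.copy_parent[1]
        n_genes[pair_id] = sum(1 for p in b.parts if p.kind == "gene")
        for copy, chrom_id in ((1, c1_id), (2, c2_id)):
            offs = b.copy_offsets(copy)
            seq = _decode(np.concatenate(b.copy_parts[copy]))
            chromosomes[chrom_id] = ChromosomeRecord(chrom_id, seq, pair_id, copy)
            glist: list[GeneAnnotation] = []
            intervals: list[tuple[int, int, str]] = []
            for k, part in enumerate(b.parts):
                s, e = int(offs[k]), int(offs[k + 1])
                org = b.copy_origin[copy][k]
                if intervals and intervals[-1][2] == org and intervals[-1][1] == s:
                    intervals[-1] = (intervals[-1][0], e, org)
                else:
                    intervals.append((s, e, org))
                if part.kind == "gene":
                    glist.append(
                        GeneAnnotation(
                            gene_id=f"{pair_id}c{copy}g{part.gene_index:04d}",
                            chromosome_id=chrom_id,
                            start=s,
                            end=e,
                            strand=part.strand,
                        )
                    )
                elif part.kind == "centromere" and copy == 1:
                    isl_s, isl_e = part.island
                    centromere_truth.append(
                        {"chromosome_id": c1_id, "start": s + isl_s, "end": s + isl_e}
                    )
                    centromere_truth.append(
                        {
                            "chromosome_id": c2_id,
                            "start": int(b.copy_offsets(2)[k]) + isl_s,
                            "end": int(b.copy_offsets(2)[k]) + isl_e,
                        }
                    )
            genes[chrom_id] = glist
            origin_intervals[chrom_id] = intervals
    numt_truth = _numt_truth(builds, numt_records, pair_letters)
    genome = Genome(chromosomes=chromosomes, genes=genes, pairs=pairs)
    truth = SimTruth(
        copy1_parent=copy1_parent,
        origin_intervals=origin_intervals,
        loh_blocks=loh_truth,
        exchanges=exchange_truth,
        numts=numt_truth,
        centromeres=centromere_truth,
        n_genes=n_genes,
    )
    return SimResult(genome=genome, mito_sequence=_decode(mito), truth=truth, config=config)


def _default_loh_layout(
    builds: list[_PairBuild], config: SimConfig, exchange_pairs: set[int]
) -> list[LohBlockSpec]:
    """LOH layout reproducing the study's mosaic at the configured fraction.

    Two pairs fully homozygous (oldest events, resolved to gamma), two pairs
    with one terminal block each (one resolved to epsilon), remaining pairs
    heterozygous; terminal-block sizes are solved so the homozygous share of
    the realized genome hits ``loh_fraction``.
    """
    n = config.n_pairs
    densities = [0.556, 0.40, 0.28, 0.194]
    lengths = np.array([b.part_lengths(GAMMA).sum() for b in builds], dtype=float)
    total = lengths.sum()
    target = config.loh_fraction * total
    candidates = [i for i in range(n) if i not in exchange_pairs]
    if not candidates:
        if config.loh_fraction == 0:
            return []
        raise ValueError("no pair available for the default LOH layout")
    blocks: list[LohBlockSpec] = []
    full: list[int] = []
    for i in reversed(candidates):
        if (
            len(full) < 2
            and target - lengths[i] > 0
            and len(candidates) - len(full) > 1
        ):
            full.append(i)
            target -= lengths[i]
    for k, i in enumerate(full):
        blocks.append(LohBlockSpec(i, 0.0, 1.0, GAMMA, densities[k]))
    partial = [i for i in candidates if i not in full][-2:]
    if target > 0 and partial:
        f_first = min(0.7, 0.55 * target / lengths[partial[0]])
        if len(partial) == 1:
            f_first = min(0.7, target / lengths[partial[0]])
        blocks.append(
            LohBlockSpec(partial[0], 1.0 - f_first, 1.0, EPSILON, densities[2])
        )
        if len(partial) == 2:
            f_second = min(
                0.7, (target - f_first * lengths[partial[0]]) / lengths[partial[1]]
            )
            if f_second > 0.02:
                blocks.append(
                    LohBlockSpec(partial[1], 1.0 - f_second, 1.0, GAMMA, densities[3])
                )
    return blocks


def _calibrate_third_position(
    builds: list[_PairBuild], config: SimConfig, rng: np.random.Generator
) -> None:
    """Flip epsilon third positions so each family's u_T exceeds gamma's by
    the configured offset (directed C->T when positive)."""
    from .codon_bias import TWO_CODON_FAMILIES, _codon_index

    t_ids = np.array([_codon_index(f[1]) for f in TWO_CODON_FAMILIES])
    c_ids = np.array([_codon_index(f[2]) for f in TWO_CODON_FAMILIES])
    fam_of = np.full(64, -1, dtype=np.int64)
    for k in range(12):
        fam_of[t_ids[k]] = k
        fam_of[c_ids[k]] = k

    def family_counts(parent: str) -> tuple[np.ndarray, np.ndarray]:
        nt = np.zeros(12, dtype=np.int64)
        nc = np.zeros(12, dtype=np.int64)
        for b in builds:
            for part in b.parts:
                if part.kind != "gene":
                    continue
                s = _sense(part.seq[parent], part.strand)
                cods = s[3:-3].reshape(-1, 3)
                ids = cods[:, 0] * 16 + cods[:, 1] * 4 + cods[:, 2]
                nt += np.bincount(
                    fam_of[ids[np.isin(ids, t_ids)]], minlength=12
                )
                nc += np.bincount(
                    fam_of[ids[np.isin(ids, c_ids)]], minlength=12
                )
        return nt, nc

    g_t, g_c = family_counts(GAMMA)
    e_t, e_c = family_counts(EPSILON)
    u_g = 100.0 * g_t / (g_t + g_c)
    u_e = 100.0 * e_t / (e_t + e_c)
    delta = (u_g + config.third_pos_c_offset) - u_e  # percentage points of u_T
    n_tot = (e_t + e_c).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_ct = np.clip(np.where(delta > 0, delta / 100.0 * n_tot / e_c, 0.0), 0, 1)
        p_tc = np.clip(np.where(delta < 0, -delta / 100.0 * n_tot / e_t, 0.0), 0, 1)
    for b in builds:
        for part in b.parts:
            if part.kind != "gene":
                continue
            s = _sense(part.seq[EPSILON], part.strand).copy()
            cods = s[3:-3].reshape(-1, 3)
            ids = cods[:, 0] * 16 + cods[:, 1] * 4 + cods[:, 2]
            fams = fam_of[ids]
            isC = np.isin(ids, c_ids)
            isT = np.isin(ids, t_ids)
            r = rng.random(len(ids))
            flip_ct = isC & (r < p_ct[np.where(fams >= 0, fams, 0)])
            flip_tc = isT & (r < p_tc[np.where(fams >= 0, fams, 0)])
            cods[flip_ct, 2] = 3  # C -> T
            cods[flip_tc, 2] = 1  # T -> C
            part.seq[EPSILON] = _from_sense(s, part.strand)


@dataclass
class _NumtRecord:
    pair_index: int
    part_index: int
    offset: int
    length: int
    parent: str
    intended_state: str
    strand: str
    mito_start: int
    mito_end: int


def _plant_numts(
    builds: list[_PairBuild],
    config: SimConfig,
    mito: np.ndarray,
    exchange_pairs: set[int],
    rng: np.random.Generator,
) -> list[_NumtRecord]:
    """Overwrite intergenic slices with mutated mitochondrial fragments.

    Hemizygous NUMTs go to heterozygous territory of one parent; biallelic
    NUMTs go inside an LOH block resolved to their parent (the LOH overwrite
    later copies them onto both chromosomes).
    """
    margin = 40
    lo, hi = config.numt_len_range

    def loh_ranges(b: _PairBuild) -> list[tuple[int, int, str]]:
        return [(p0, p1, blk.parent) for p0, p1, blk in b.loh_part_ranges]

    het_sites: list[tuple[int, int]] = []  # (pair, part)
    block_sites: dict[str, list[tuple[int, int]]] = {GAMMA: [], EPSILON: []}
    for b in builds:
        ranges = loh_ranges(b)
        for k, part in enumerate(b.parts):
            if part.kind != "intergenic" or len(part.seq[GAMMA]) < lo + 2 * margin:
                continue
            inside = None
            for p0, p1, parent in ranges:
                if p0 <= k < p1:
                    inside = parent
            if inside is None:
                if b.pair_index not in exchange_pairs:
                    het_sites.append((b.pair_index, k))
            else:
                block_sites[inside].append((b.pair_index, k))
    rng.shuffle(het_sites)
    for v in block_sites.values():
        rng.shuffle(v)
    records: list[_NumtRecord] = []

    def plant(site: tuple[int, int], parent: str, state: str) -> None:
        pi, k = site
        part = builds[pi].parts[k]
        length = min(int(rng.integers(lo, hi + 1)), len(part.seq[GAMMA]) - 2 * margin)
        room = len(part.seq[GAMMA]) - length - 2 * margin
        off = margin + int(rng.integers(0, max(1, room)))
        ms = int(rng.integers(0, config.mito_len - length))
        frag = mito[ms : ms + length].copy()
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = 3 - frag[::-1]
        mmask = rng.random(length) < (1.0 - config.numt_identity)
        nm = int(mmask.sum())
        if nm:
            frag[mmask] = (frag[mmask] + rng.integers(1, 4, size=nm).astype(np.uint8)) % 4
        part.seq[parent] = part.seq[parent].copy()
        part.seq[parent][off : off + length] = frag
        records.append(
            _NumtRecord(pi, k, off, length, parent, state, strand, ms, ms + length)
        )

    needs = [
        (GAMMA, "hemizygous", config.numt_hemizygous[0]),
        (EPSILON, "hemizygous", config.numt_hemizygous[1]),
        (GAMMA, "biallelic", config.numt_biallelic[0]),
        (EPSILON, "biallelic", config.numt_biallelic[1]),
    ]
    for parent, state, count in needs:
        pool = het_sites if state == "hemizygous" else block_sites[parent]
        if len(pool) < count:
            raise ValueError(
                f"not enough {state} planting sites for {count} {parent} NUMTs"
            )
        for _ in range(count):
            plant(pool.pop(), parent, state)
    return records


def _numt_truth(
    builds: list[_PairBuild], records: list[_NumtRecord], pair_letters: list[str]
) -> list[dict]:
    out: list[dict] = []
    for r in records:
        b = builds[r.pair_index]
        placements = []
        for copy in (1, 2):
            if b.copy_origin[copy][r.part_index] == r.parent:
                off = int(b.copy_offsets(copy)[r.part_index]) + r.offset
                chrom = f"chr{pair_letters[r.pair_index]}_{copy}"
                placements.append(
                    {"chromosome_id": chrom, "start": off, "end": off + r.length}
                )
        out.append(
            {
                "parent": r.parent,
                "state": r.intended_state,
                "strand": r.strand,
                "mito_start": r.mito_start,
                "mito_end": r.mito_end,
                "length": r.length,
                "placements": placements,
            }
        )
    return out


def _sprinkle_block(
    b: _PairBuild, p0: int, p1: int, blk: LohBlockSpec, rng: np.random.Generator
) -> tuple[int, int]:
    """Sprinkle residual SNPs over an LOH block at the planted density.

    The number of SNPs is deterministic (round(density x length / 1e4)) so
    recovered densities are limited only by boundary precision; each SNP
    lands on one randomly chosen copy, never creating an in-frame stop.
    """
    lens = np.array([len(b.copy_parts[1][p]) for p in range(p0, p1)], dtype=np.int64)
    offs = np.concatenate([[0], np.cumsum(lens)])
    total = int(offs[-1])
    n_snp = int(round(blk.snp_per_10kb * total / 1e4))
    if n_snp == 0:
        return 0, total
    positions = rng.choice(total, size=n_snp, replace=False)
    for pos in sorted(int(x) for x in positions):
        local = int(np.searchsorted(offs, pos, side="right") - 1)
        part_idx = p0 + local
        within = pos - int(offs[local])
        copy = 1 if rng.random() < 0.5 else 2
        arr = b.copy_parts[copy][part_idx]
        part = b.parts[part_idx]
        old = int(arr[within])
        deltas = rng.permutation([1, 2, 3])
        for d in deltas:
            new = (old + int(d)) % 4
            arr[within] = new
            if part.kind != "gene":
                break
            s = _sense(arr, part.strand)
            cods = s[3:-3].reshape(-1, 3)
            ids = cods[:, 0] * 16 + cods[:, 1] * 4 + cods[:, 2]
            if not np.isin(ids, _STOP_IDS).any():
                break
            arr[within] = old  # revert and try another base
        else:
            arr[within] = old
    return n_snp, total


@dataclass
class SimResult:
    genome: Genome
    mito_sequence: str
    truth: SimTruth
    config: SimConfig

    def write(self, outdir) -> dict[str, str]:
        """Write FASTA/GFF/manifest/mito FASTA/truth JSON; returns the paths."""
        import os

        from .genome_io import write_genome

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "fasta": os.path.join(outdir, "genome.fasta"),
            "gff": os.path.join(outdir, "genes.gff3"),
            "manifest": os.path.join(outdir, "pairs.tsv"),
            "mito": os.path.join(outdir, "mito.fasta"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        write_genome(self.genome, paths["fasta"], paths["gff"], paths["manifest"])
        with open(paths["mito"], "w") as fh:
            fh.write(">mito\n")
            for i in range(0, len(self.mito_sequence), 80):
                fh.write(self.mito_sequence[i : i + 80] + "\n")
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json())
        return paths


def verify_truth(result: SimResult) -> None:
    """Internal consistency checks between emitted genome and truth record.

    Raises AssertionError on any violation: LOH copies must match except for
    sprinkled SNPs, genes must be open frames, centromere islands GC-poor,
    and NUMT placements must match the mitochondrial fragment.
    """
    g = result.genome
    t = result.truth
    for blk in t.loh_blocks:
        c1, c2 = g.pair_chromosomes(blk["pair_id"])
        if len(c1.sequence) != len(c2.sequence):
            continue  # indel runs: base-level check not applicable
        a = np.frombuffer(c1.sequence.encode(), dtype=np.uint8)[blk["start"] : blk["end"]]
        b = np.frombuffer(c2.sequence.encode(), dtype=np.uint8)[blk["start"] : blk["end"]]
        mism = int((a != b).sum())
        expected = blk["snp_per_10kb"] * (blk["end"] - blk["start"]) / 1e4
        assert mism <= expected * 1.2 + 5, (mism, expected)
    stops = {"TAA", "TAG", "TGA"}
    for chrom_id in g.chromosomes:
        for gene in g.genes_of(chrom_id)[::25]:  # sampled: full check is slow
            cds = g.cds_sequence(gene)
            assert len(cds) % 3 == 0
            internal = {cds[i : i + 3] for i in range(3, len(cds) - 3, 3)}
            assert not (internal & stops), gene.gene_id
    for cen in t.centromeres:
        chrom = g.chromosomes[cen["chromosome_id"]]
        from .gc_trend import gc_fraction

        island = chrom.sequence[cen["start"] : cen["end"]]
        assert gc_fraction(island) < gc_fraction(chrom.sequence)
    for numt in t.numts:
        expected_placements = 2 if numt["state"] == "biallelic" else 1
        assert len(numt["placements"]) == expected_placements, numt
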