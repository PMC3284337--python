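"""End-to-end orchestration of the hybrid-genome resolution pipeline.

Stage order follows the logic of the analysis: allele pairing -> dGC trend
curves and exchange detection -> zygosity segmentation -> subgenome polarity
of heterozygous regions -> codon-usage centroids and LOH classification ->
feature scanning (centromeres, NUMTs).  All stages are deterministic; the
only randomness in the package lives in the simulator.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import allele_pairing as ap
from . import codon_bias as cb
from . import feature_scan as fs
from . import gc_trend as gt
from . import zygosity_map as zm
from .genome_io import BedInterval, Genome, write_segments_bed


@dataclass
class RunConfig:
    """All tunable stage parameters with their pipeline defaults."""

    # pairing
    min_identity: float = 0.5
    max_rank_offset: int = 3
    # trend curves
    trend_window: int = 11
    trend_step: int = 1
    anchor_copy: int = 1
    polarity_min_genes: int = 20
    polarity_epsilon: float = 0.001
    exchange_min_run: int = 40
    exchange_min_amplitude: float = 0.0035
    # zygosity
    window_bp: int = 10_000
    step_bp: int = 1_000
    homo_max: float = 0.005
    het_max: float = 0.25
    min_aligned: float = 0.4
    min_segment: int = 5_000
    # generations (mandatory inputs when an estimate is requested)
    mutation_rate: Optional[float] = None
    ploidy_factor: Optional[int] = None
    # codon bias
    min_margin: float = 0.05
    min_codons: int = 2000
    # centromeres
    cen_window_bp: int = 1_000
    cen_step_bp: int = 200
    cen_rel_deficit: float = 0.08
    cen_merge_gap: int = 600
    cen_min_len: int = 1_500
    cen_max_len: int = 5_000
    cen_max_offset: int = 50_000
    # NUMTs
    numt_min_len: int = 50
    numt_min_identity: float = 0.8
    numt_k: int = 12
    numt_max_gap: int = 40
    numt_slack: int = 100


@dataclass
class RegionPolarity:
    pair_id: str
    start: int
    end: int
    copy_1: str
    copy_2: str
    mean_dgc_1: float
    mean_dgc_2: float
    separation: float


@dataclass
class LohCall:
    pair_id: str
    start: int
    end: int
    label: str
    margin: float
    snp_per_10kb: float


@dataclass
class PairResult:
    pair_id: str
    gene_pairs: list[ap.GenePair]
    singles_1: list
    singles_2: list
    alignment: ap.PairAlignment
    dgc: list[gt.DgcValue]
    curve: gt.TrendCurve
    exchanges: list[gt.ExchangeBreakpoint]
    segments: list[zm.ZygositySegment]
    polarity: list[RegionPolarity]
    junctions: list[zm.JunctionAnnotation]


@dataclass
class PipelineResult:
    genome: Genome
    config: RunConfig
    pairs: dict[str, PairResult]
    loh_calls: list[LohCall]
    loh_events: list[zm.LohEvent]
    centroid_gamma: Optional[cb.CodonUsageProfile]
    centroid_epsilon: Optional[cb.CodonUsageProfile]
    centromeres: dict[str, list[fs.CentromereCandidate]]
    numt_hits: list[fs.NumtHit]
    numt_summary: Optional[fs.NumtAsymmetry]
    summary: pd.DataFrame

    def origin_of(self, chromosome_id: str, pos: int) -> str:
        """Subgenome label of a position on either copy of a pair."""
        chrom = self.genome.chromosomes[chromosome_id]
        pr = self.pairs[chrom.pair_id]
        if chrom.copy_index == 2:
            rev = pr.alignment.c1pos()
            pos1 = _nearest_defined(rev, pos)
            if pos1 is None:
                return gt.UNDETERMINED
        else:
            pos1 = pos
        for reg in pr.polarity:
            if reg.start <= pos1 < reg.end:
                return reg.copy_1 if chrom.copy_index == 1 else reg.copy_2
        for call in self.loh_calls:
            if call.pair_id == chrom.pair_id and call.start <= pos1 < call.end:
                return call.label
        return gt.UNDETERMINED


def _nearest_defined(arr: np.ndarray, pos: int, radius: int = 2000) -> Optional[int]:
    lo, hi = max(0, pos - radius), min(len(arr), pos + radius)
    window = arr[lo:hi]
    ok = np.nonzero(window >= 0)[0]
    if ok.size == 0:
        return None
    best = ok[np.argmin(np.abs(ok + lo - pos))]
    return int(window[best])


def _split_het_regions(
    segments: list[zm.ZygositySegment],
    exchanges: list[gt.ExchangeBreakpoint],
) -> list[tuple[int, int]]:
    """Heterozygous intervals, split at detected exchange breakpoints."""
    cuts = sorted((bp.start + bp.end) // 2 for bp in exchanges)
    regions: list[tuple[int, int]] = []
    for seg in segments:
        if seg.label != zm.HETEROZYGOUS:
            continue
        edges = [seg.start] + [c for c in cuts if seg.start < c < seg.end] + [seg.end]
        for a, b in zip(edges, edges[1:]):
            regions.append((a, b))
    return regions


def run_all(
    genome: Genome,
    config: Optional[RunConfig] = None,
    mito_sequence: Optional[str] = None,
) -> PipelineResult:
    """Run every stage on a phased assembly and collect the report bundle."""
    config = config if config is not None else RunConfig()
    pair_results: dict[str, PairResult] = {}
    for pair_id, c1_id, c2_id in genome.pairs:
        g1, g2 = genome.genes_of(c1_id), genome.genes_of(c2_id)
        pairs, s1, s2 = ap.pair_genes(
            g1,
            g2,
            genome,
            min_identity=config.min_identity,
            max_rank_offset=config.max_rank_offset,
            pair_id=pair_id,
        )
        aln = ap.align_chromosome_pair(genome, pair_id, pairs)
        dgc_pairs = ap.select_dgc_genes(pairs) if pairs else []
        dvals = gt.dgc_values(dgc_pairs, anchor_copy=config.anchor_copy)
        curve = gt.build_trend_curve(dvals, config.trend_window, config.trend_step)
        exchanges = (
            gt.detect_trend_exchange(
                curve, config.exchange_min_run, config.exchange_min_amplitude
            )
            if len(curve)
            else []
        )
        stats = zm.window_divergence(aln, config.window_bp, config.step_bp)
        segments = zm.segment_zygosity(
            aln,
            stats,
            pair_id=pair_id,
            chromosome_id=c1_id,
            homo_max=config.homo_max,
            het_max=config.het_max,
            min_aligned=config.min_aligned,
            min_segment=config.min_segment,
        )
        polarity: list[RegionPolarity] = []
        for start, end in _split_het_regions(segments, exchanges):
            mask = (curve.positions >= start) & (curve.positions < end) if len(curve) else np.array([])
            if len(curve) == 0 or int(mask.sum()) < config.polarity_min_genes:
                continue
            call = gt.assign_polarity(
                curve,
                (start, end),
                min_genes=config.polarity_min_genes,
                epsilon=config.polarity_epsilon,
            )
            polarity.append(
                RegionPolarity(
                    pair_id,
                    start,
                    end,
                    call.copy_1,
                    call.copy_2,
                    call.mean_dgc_1,
                    call.mean_dgc_2,
                    call.separation,
                )
            )
        junctions = zm.junction_report(segments, pairs, aln)
        pair_results[pair_id] = PairResult(
            pair_id, pairs, s1, s2, aln, dvals, curve, exchanges, segments,
            polarity, junctions,
        )

    # codon-usage centroids from polarity-assigned heterozygous regions
    cds_gamma: list[str] = []
    cds_epsilon: list[str] = []
    for pr in pair_results.values():
        for reg in pr.polarity:
            if gt.UNDETERMINED in (reg.copy_1, reg.copy_2):
                continue
            for gp in pr.gene_pairs:
                if gp.gene_2 is None:
                    continue
                if reg.start <= gp.gene_1.start < reg.end:
                    c1 = genome.cds_sequence(gp.gene_1)
                    c2 = genome.cds_sequence(gp.gene_2)
                    (cds_gamma if reg.copy_1 == gt.P_GAMMA else cds_epsilon).append(c1)
                    (cds_gamma if reg.copy_2 == gt.P_GAMMA else cds_epsilon).append(c2)
    centroid_g = centroid_e = None
    if cds_gamma and cds_epsilon:
        centroid_g = cb.CodonUsageProfile.from_cds_sequences(gt.P_GAMMA, cds_gamma)
        centroid_e = cb.CodonUsageProfile.from_cds_sequences(gt.P_EPSILON, cds_epsilon)

    loh_calls: list[LohCall] = []
    all_homo: list[zm.ZygositySegment] = []
    for pr in pair_results.values():
        for seg in pr.segments:
            if seg.label != zm.HOMOZYGOUS:
                continue
            all_homo.append(seg)
            label, margin = gt.UNDETERMINED, 0.0
            if centroid_g is not None and centroid_e is not None:
                region_cds = [
                    genome.cds_sequence(gp.gene_1)
                    for gp in pr.gene_pairs
                    if gp.gene_2 is not None and seg.start <= gp.gene_1.start < seg.end
                ]
                prof = cb.CodonUsageProfile.from_cds_sequences("region", region_cds)
                cls = cb.classify_homozygous_region(
                    prof, centroid_g, centroid_e, config.min_margin, config.min_codons
                )
                label, margin = cls.label, cls.margin
            loh_calls.append(
                LohCall(
                    pr.pair_id, seg.start, seg.end, label, margin, seg.snp_per_10kb or 0.0
                )
            )
    loh_events = zm.order_loh_events(all_homo)
    if config.mutation_rate is not None and config.ploidy_factor is not None:
        for ev in loh_events:
            ev.generations_estimate = zm.estimate_generations(
                ev.snp_per_10kb / 1e4, config.mutation_rate, config.ploidy_factor
            )

    centromeres: dict[str, list[fs.CentromereCandidate]] = {}
    for chrom_id, chrom in genome.chromosomes.items():
        centromeres[chrom_id] = fs.scan_centromeres(
            chrom.sequence,
            genome.genes_of(chrom_id),
            chromosome_id=chrom_id,
            window_bp=config.cen_window_bp,
            step_bp=config.cen_step_bp,
            rel_deficit=config.cen_rel_deficit,
            merge_gap=config.cen_merge_gap,
            min_len=config.cen_min_len,
            max_len=config.cen_max_len,
        )
    alignments = {pid: pr.alignment for pid, pr in pair_results.items()}
    for pair_id, c1_id, c2_id in genome.pairs:
        fs.match_centromere_pairs(
            centromeres[c1_id],
            centromeres[c2_id],
            alignments[pair_id],
            max_offset=config.cen_max_offset,
        )

    numt_hits: list[fs.NumtHit] = []
    numt_summary = None
    result = PipelineResult(
        genome=genome,
        config=config,
        pairs=pair_results,
        loh_calls=loh_calls,
        loh_events=loh_events,
        centroid_gamma=centroid_g,
        centroid_epsilon=centroid_e,
        centromeres=centromeres,
        numt_hits=numt_hits,
        numt_summary=None,
        summary=pd.DataFrame(),
    )
    if mito_sequence:
        numt_hits = fs.scan_numts(
            genome,
            mito_sequence,
            min_len=config.numt_min_len,
            min_identity=config.numt_min_identity,
            k=config.numt_k,
            max_gap=config.numt_max_gap,
        )
        fs.classify_numt_states(numt_hits, genome, alignments, slack=config.numt_slack)
        result.numt_hits = numt_hits
        numt_summary = fs.numt_asymmetry(
            numt_hits, genome, alignments, result.origin_of
        )
        result.numt_summary = numt_summary

    result.summary = _summarize(result)
    return result


def _summarize(result: PipelineResult) -> pd.DataFrame:
    rows = []
    numts_by_pair: dict[str, int] = {}
    for h in result.numt_hits:
        pid = result.genome.chromosomes[h.chromosome_id].pair_id
        numts_by_pair[pid] = numts_by_pair.get(pid, 0) + 1
    for pair_id, c1_id, c2_id in result.genome.pairs:
        pr = result.pairs[pair_id]
        lens = {lab: 0 for lab in (zm.HETEROZYGOUS, zm.HOMOZYGOUS, zm.HEMIZYGOUS)}
        het_div = []
        for seg in pr.segments:
            lens[seg.label] += seg.length
            if seg.label == zm.HETEROZYGOUS:
                het_div.append((seg.divergence, seg.length))
        mean_ident = (
            1.0 - sum(d * l for d, l in het_div) / sum(l for _, l in het_div)
            if het_div
            else float("nan")
        )
        pol = ";".join(
            f"[{r.start}-{r.end}):{r.copy_1}/{r.copy_2}" for r in pr.polarity
        )
        densities = ";".join(
            f"{c.snp_per_10kb:.3f}" for c in result.loh_calls if c.pair_id == pair_id
        )
        rows.append(
            {
                "pair_id": pair_id,
                "heterozygous_bp": lens[zm.HETEROZYGOUS],
                "homozygous_bp": lens[zm.HOMOZYGOUS],
                "hemizygous_bp": lens[zm.HEMIZYGOUS],
                "mean_het_identity": mean_ident,
                "polarity": pol,
                "loh_snp_per_10kb": densities,
                "n_exchange_breakpoints": len(pr.exchanges),
                "n_centromere_copy1": len(result.centromeres.get(c1_id, [])),
                "n_centromere_copy2": len(result.centromeres.get(c2_id, [])),
                "n_numt_hits": numts_by_pair.get(pair_id, 0),
            }
        )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir: str) -> None:
    """Write all per-stage tables and BED tracks plus the run summary."""
    os.makedirs(outdir, exist_ok=True)
    # segments BED (score = divergence x 1000)
    segs = [
        BedInterval(s.chromosome_id, s.start, s.end, s.label, round(s.divergence * 1000, 3))
        for pr in result.pairs.values()
        for s in pr.segments
    ]
    write_segments_bed(segs, os.path.join(outdir, "zygosity_segments.bed"))
    # per-gene dGC table
    rows = [
        {
            "pair_id": pr.pair_id,
            "gene_id": v.gene_pair_id,
            "anchor": v.anchor_position,
            "dgc_1": v.dgc_1,
            "dgc_2": v.dgc_2,
        }
        for pr in result.pairs.values()
        for v in pr.dgc
    ]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "dgc_genes.tsv"), sep="\t", index=False)
    rows = [
        {
            "pair_id": pr.pair_id,
            "position": int(p),
            "dgc_1": d1,
            "dgc_2": d2,
        }
        for pr in result.pairs.values()
        for p, d1, d2 in zip(pr.curve.positions, pr.curve.dgc_1, pr.curve.dgc_2)
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "trend_curves.tsv"), sep="\t", index=False
    )
    ex = [
        BedInterval(
            result.genome.pair_chromosomes(pr.pair_id)[0].id, bp.start, bp.end, "exchange"
        )
        for pr in result.pairs.values()
        for bp in pr.exchanges
    ]
    write_segments_bed(ex, os.path.join(outdir, "exchange_breakpoints.bed"))
    pd.DataFrame([asdict(r) for pr in result.pairs.values() for r in pr.polarity]).to_csv(
        os.path.join(outdir, "polarity.tsv"), sep="\t", index=False
    )
    pd.DataFrame([asdict(c) for c in result.loh_calls]).to_csv(
        os.path.join(outdir, "loh_classification.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "pair_id": e.segment.pair_id,
                "start": e.segment.start,
                "end": e.segment.end,
                "rank": e.rank,
                "snp_per_10kb": e.snp_per_10kb,
                "tied": e.tied,
                "generations_estimate": e.generations_estimate,
            }
            for e in result.loh_events
        ]
    ).to_csv(os.path.join(outdir, "loh_events.tsv"), sep="\t", index=False)
    cen = [
        BedInterval(c.chromosome_id, c.start, c.end, "centromere", round(c.gc_deficit, 2))
        for cands in result.centromeres.values()
        for c in cands
    ]
    write_segments_bed(cen, os.path.join(outdir, "centromere_candidates.bed"))
    numt = [
        BedInterval(h.chromosome_id, h.start, h.end, h.state or "numt", round(h.identity * 1000))
        for h in result.numt_hits
    ]
    write_segments_bed(numt, os.path.join(outdir, "numt_hits.bed"))
    if result.numt_summary is not None:
        with open(os.path.join(outdir, "numt_asymmetry.json"), "w") as fh:
            json.dump(asdict(result.numt_summary), fh, indent=1, sort_keys=True)
    junc = [
        asdict(j) for pr in result.pairs.values() for j in pr.junctions
    ]
    pd.DataFrame(junc).to_csv(os.path.join(outdir, "junctions.tsv"), sep="\t", index=False)
    result.summary.to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "run_config.json"), "w") as fh:
        json.dump(asdict(result.config), fh, indent=1, sort_keys=True)
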