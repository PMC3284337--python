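#!/usr/bin/env python
"""Segment chromosome pairs into het/homo/hemizygous states and date LOH.

Writes the zygosity segmentation, the ranked LOH event table (with a
generations-since-onset estimate at the budding-yeast mutation rate
mu = 3e-10 per site per generation, single-copy accrual), and the junction
annotations under results/.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from _common import pipeline, results_dir

from homeoscan.zygosity_map import HOMOZYGOUS


def main() -> None:
    out, truth = pipeline(with_mito=False)
    res = results_dir()
    segs = pd.DataFrame(
        [
            {
                "pair_id": s.pair_id,
                "start": s.start,
                "end": s.end,
                "label": s.label,
                "divergence": round(s.divergence, 5),
                "snp_per_10kb": None if s.snp_per_10kb is None else round(s.snp_per_10kb, 3),
            }
            for pr in out.pairs.values()
            for s in pr.segments
        ]
    )
    segs.to_csv(os.path.join(res, "zygosity_segments.tsv"), sep="\t", index=False)
    homo = segs[segs["label"] == HOMOZYGOUS]["end"].sub(
        segs[segs["label"] == HOMOZYGOUS]["start"]
    ).sum()
    total = segs["end"].sub(segs["start"]).sum()
    print(f"homozygous fraction: {100*homo/total:.1f}% (planted 40%)")
    events = pd.DataFrame(
        [
            {
                "rank": e.rank,
                "pair_id": e.segment.pair_id,
                "snp_per_10kb": round(e.snp_per_10kb, 3),
                "generations_estimate": None
                if e.generations_estimate is None
                else round(e.generations_estimate),
            }
            for e in out.loh_events
        ]
    )
    events.to_csv(os.path.join(res, "loh_events.tsv"), sep="\t", index=False)
    print("LOH events, oldest first:")
    print(events.to_string(index=False))
    junctions = pd.DataFrame(
        [
            {
                "pair_id": j.pair_id,
                "position": j.position,
                "gene_id": j.gene_id,
                "gene_identity": None if j.gene_identity is None else round(j.gene_identity, 4),
                "flank_het_identity": None
                if j.flank_het_identity is None
                else round(j.flank_het_identity, 4),
            }
            for pr in out.pairs.values()
            for j in pr.junctions
        ]
    )
    junctions.to_csv(os.path.join(res, "loh_junctions.tsv"), sep="\t", index=False)
    print(f"wrote zygosity_segments.tsv, loh_events.tsv, loh_junctions.tsv under {res}")


if __name__ == "__main__":
    main()
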