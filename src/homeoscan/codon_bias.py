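"""Two-codon tRNA codon-usage statistics and subgenome classification.

Twelve synonymous codon pairs of the form NNT/NNC are each read by a single
tRNA species; the relative usage of the T-ending versus the C-ending codon
is therefore a clean readout of third-position composition.  For a set of
CDS the usage of each family is

    u_T = 100 * n_T / (n_T + n_C),      u_C = 100 - u_T

and the per-family absolute difference |u_T(A) - u_T(B)| between two gene
sets, averaged over the 12 families, quantifies the systematic third-position
C/T offset between the two parental subgenomes.  Pooled heterozygous-region
profiles per subgenome serve as centroids for a nearest-profile assignment of
homozygous (LOH) regions to the parent that resolved them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .gc_trend import P_EPSILON, P_GAMMA, UNDETERMINED

#: The 12 two-codon tRNA families (amino acid, T-ending codon, C-ending codon).
TWO_CODON_FAMILIES: list[tuple[str, str, str]] = [
    ("Phe", "TTT", "TTC"),
    ("Val", "GTT", "GTC"),
    ("Ser", "TCT", "TCC"),
    ("Pro", "CCT", "CCC"),
    ("Thr", "ACT", "ACC"),
    ("Ala", "GCT", "GCC"),
    ("His", "CAT", "CAC"),
    ("Asn", "AAT", "AAC"),
    ("Asp", "GAT", "GAC"),
    ("Cys", "TGT", "TGC"),
    ("Ser", "AGT", "AGC"),
    ("Gly", "GGT", "GGC"),
]

_STOPS = {"TAA", "TAG", "TGA"}

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _codon_index(codon: str) -> int:
    a, b, c = (int(_BASE_CODE[ord(x)]) for x in codon)
    return 16 * a + 4 * b + c


_FAMILY_T_IDX = np.array([_codon_index(f[1]) for f in TWO_CODON_FAMILIES])
_FAMILY_C_IDX = np.array([_codon_index(f[2]) for f in TWO_CODON_FAMILIES])


def codon_counts(cds_sequences: Iterable[str]) -> np.ndarray:
    """In-frame codon counts (length-64 array) over a collection of CDS.

    CDS whose length is not a multiple of 3 are skipped with a warning; a
    terminal stop codon is excluded; codons containing N are ignored.
    """
    counts = np.zeros(64, dtype=np.int64)
    skipped = 0
    for seq in cds_sequences:
        if len(seq) % 3 != 0:
            skipped += 1
            continue
        if len(seq) >= 3 and seq[-3:] in _STOPS:
            seq = seq[:-3]
        if not seq:
            continue
        arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        cods = arr.reshape(-1, 3)
        valid = (cods >= 0).all(axis=1)
        idx = cods[valid] @ np.array([16, 4, 1])
        counts += np.bincount(idx, minlength=64)
    if skipped:
        warnings.warn(f"skipped {skipped} CDS with length not a multiple of 3")
    return counts


@dataclass
class CodonUsageProfile:
    """Per-family T/C codon counts and usage percentages for one region."""

    label: str
    n_t: np.ndarray  # counts of the T-ending codon, per family
    n_c: np.ndarray

    @classmethod
    def from_cds_sequences(cls, label: str, cds_sequences: Iterable[str]) -> "CodonUsageProfile":
        counts = codon_counts(cds_sequences)
        return cls(label, counts[_FAMILY_T_IDX].copy(), counts[_FAMILY_C_IDX].copy())

    @classmethod
    def from_counts(
        cls, label: str, counts: dict[str, tuple[int, int]]
    ) -> "CodonUsageProfile":
        """Build from explicit per-family (n_T, n_C) counts keyed by T codon."""
        n_t = np.zeros(12, dtype=np.int64)
        n_c = np.zeros(12, dtype=np.int64)
        for i, (_aa, ct, _cc) in enumerate(TWO_CODON_FAMILIES):
            n_t[i], n_c[i] = counts[ct]
        return cls(label, n_t, n_c)

    @property
    def total_counts(self) -> int:
        return int(self.n_t.sum() + self.n_c.sum())

    def usage_t(self) -> np.ndarray:
        """u_T per family in percent; NaN where the family has no counts."""
        denom = (self.n_t + self.n_c).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, 100.0 * self.n_t / denom, np.nan)

    def usage_c(self) -> np.ndarray:
        return 100.0 - self.usage_t()

    def __add__(self, other: "CodonUsageProfile") -> "CodonUsageProfile":
        return CodonUsageProfile(
            self.label, self.n_t + other.n_t, self.n_c + other.n_c
        )


def round2(x: float) -> float:
    """Round to two decimals, half up (presentation convention)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def bias_table(
    profile_a: CodonUsageProfile, profile_b: CodonUsageProfile
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-family |u_T(A) - u_T(B)| with average / median / quartile summary.

    Differences are computed from unrounded usage values; the printed table
    rounds to two decimals only for presentation.  Families undefined in
    either profile are excluded from the summary with a warning.
    """
    ua, ub = profile_a.usage_t(), profile_b.usage_t()
    diff = np.abs(ua - ub)
    rows = []
    for i, (aa, ct, cc) in enumerate(TWO_CODON_FAMILIES):
        rows.append(
            {
                "family": aa,
                "codon_t": ct,
                "codon_c": cc,
                f"n_t_{profile_a.label}": int(profile_a.n_t[i]),
                f"n_t_{profile_b.label}": int(profile_b.n_t[i]),
                f"n_c_{profile_a.label}": int(profile_a.n_c[i]),
                f"n_c_{profile_b.label}": int(profile_b.n_c[i]),
                f"usage_t_{profile_a.label}": round2(ua[i]) if np.isfinite(ua[i]) else np.nan,
                f"usage_t_{profile_b.label}": round2(ub[i]) if np.isfinite(ub[i]) else np.nan,
                "abs_diff": round2(diff[i]) if np.isfinite(diff[i]) else np.nan,
            }
        )
    valid = np.isfinite(diff)
    if not valid.all():
        warnings.warn("families with zero counts excluded from the bias summary")
    d = diff[valid]
    summary = {
        "average": float(d.mean()),
        "median": float(np.median(d)),
        "q1": float(np.percentile(d, 25)),
        "q3": float(np.percentile(d, 75)),
        "n_families": int(valid.sum()),
    }
    return pd.DataFrame(rows), summary


def gene_level_bias(
    cds_a: Sequence[str], cds_b: Sequence[str]
) -> dict[str, float]:
    """Gene-level variant: per-gene mean family u_T, summarized across genes.

    Provided for completeness; the family-level pooled statistic of
    ``bias_table`` is the validated summary.
    """

    def per_gene(seqs: Sequence[str]) -> np.ndarray:
        out = []
        for s in seqs:
            p = CodonUsageProfile.from_cds_sequences("g", [s])
            u = p.usage_t()
            if np.isfinite(u).any():
                out.append(np.nanmean(u))
        return np.array(out)

    ua, ub = per_gene(cds_a), per_gene(cds_b)
    d = abs(float(ua.mean()) - float(ub.mean()))
    return {"mean_diff": d, "n_genes_a": len(ua), "n_genes_b": len(ub)}


@dataclass
class RegionClassification:
    label: str
    margin: float
    distance_gamma: float
    distance_epsilon: float


def classify_homozygous_region(
    region_profile: CodonUsageProfile,
    centroid_gamma: CodonUsageProfile,
    centroid_epsilon: CodonUsageProfile,
    min_margin: float = 0.05,
    min_codons: int = 2000,
) -> RegionClassification:
    """Assign an LOH region to its resolving parent by nearest usage profile.

    Distances are Euclidean on the 12-dimensional u_T vector; the margin
    |d_eps - d_gamma| / (d_eps + d_gamma) must exceed ``min_margin`` and the
    region must contain at least ``min_codons`` family codons, otherwise the
    call is undetermined.
    """
    if region_profile.total_counts < min_codons:
        return RegionClassification(UNDETERMINED, 0.0, float("nan"), float("nan"))
    u = region_profile.usage_t()
    ug = centroid_gamma.usage_t()
    ue = centroid_epsilon.usage_t()
    valid = np.isfinite(u) & np.isfinite(ug) & np.isfinite(ue)
    dg = float(np.sqrt(((u - ug)[valid] ** 2).sum()))
    de = float(np.sqrt(((u - ue)[valid] ** 2).sum()))
    if dg + de == 0:
        return RegionClassification(UNDETERMINED, 0.0, dg, de)
    margin = abs(de - dg) / (de + dg)
    if margin < min_margin:
        return RegionClassification(UNDETERMINED, margin, dg, de)
    label = P_GAMMA if dg < de else P_EPSILON
    return RegionClassification(label, margin, dg, de)


def load_published_counts() -> tuple[CodonUsageProfile, CodonUsageProfile]:
    """Published two-codon counts for the two subgenomes of the hybrid yeast.

    Returns (Pgamma profile, Pepsilon profile) read from the bundled counts
    table (counts of the 24 codons as printed for the sequenced strain).
    """
    with resources.files("homeoscan.data").joinpath(
        "psorbitophila_two_codon_counts.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    cg: dict[str, tuple[int, int]] = {}
    ce: dict[str, tuple[int, int]] = {}
    for _, row in df.iterrows():
        cg[row["codon_t"]] = (int(row["n_t_pgamma"]), int(row["n_c_pgamma"]))
        ce[row["codon_t"]] = (int(row["n_t_pepsilon"]), int(row["n_c_pepsilon"]))
    return (
        CodonUsageProfile.from_counts(P_GAMMA, cg),
        CodonUsageProfile.from_counts(P_EPSILON, ce),
    )
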