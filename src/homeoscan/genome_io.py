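"""Genome data model and I/O for the hybrid-genome resolution pipeline.

The pipeline operates on a *phased* allodiploid assembly: every chromosome
copy is its own FASTA record, gene models come from a GFF3 file, and a small
TSV manifest states which two records form a homeologous (or homologous)
chromosome pair.  All internal coordinates are 0-based half-open; the GFF3
(1-based inclusive) and BED (0-based half-open) dialects are converted only
at the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset(b"ACGTN")

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


class GenomeIOError(ValueError):
    """Raised for malformed or inconsistent genome inputs."""


@dataclass
class ChromosomeRecord:
    """One chromosome copy of the phased assembly."""

    id: str
    sequence: str  # uppercase over {A,C,G,T,N}
    pair_id: str
    copy_index: int  # 1 or 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"chromosome {self.id!r}: empty sequence")
        if self.copy_index not in (1, 2):
            raise GenomeIOError(f"chromosome {self.id!r}: copy_index must be 1 or 2")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A protein-coding gene; exons sorted, non-overlapping, 0-based half-open."""

    gene_id: str
    chromosome_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise GenomeIOError(f"gene {self.gene_id!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not self.exon_intervals:
            self.exon_intervals = [(self.start, self.end)]
        prev_end = self.start - 1
        for s, e in self.exon_intervals:
            if s < self.start or e > self.end or s >= e or s <= prev_end:
                raise GenomeIOError(
                    f"gene {self.gene_id!r}: exons must be sorted, disjoint and "
                    f"contained in [{self.start},{self.end})"
                )
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exon_intervals)


@dataclass
class Genome:
    """Phased assembly: chromosome records, gene annotations and the pairing."""

    chromosomes: dict[str, ChromosomeRecord]
    genes: dict[str, list[GeneAnnotation]]  # per chromosome, sorted by start
    pairs: list[tuple[str, str, str]]  # (pair_id, chrom_id copy 1, chrom_id copy 2)

    def pair_ids(self) -> list[str]:
        return [p[0] for p in self.pairs]

    def pair_chromosomes(self, pair_id: str) -> tuple[ChromosomeRecord, ChromosomeRecord]:
        for pid, c1, c2 in self.pairs:
            if pid == pair_id:
                return self.chromosomes[c1], self.chromosomes[c2]
        raise KeyError(pair_id)

    def genes_of(self, chromosome_id: str) -> list[GeneAnnotation]:
        return self.genes.get(chromosome_id, [])

    def cds_sequence(self, gene: GeneAnnotation) -> str:
        """Spliced, strand-corrected CDS sequence of a gene."""
        chrom = self.chromosomes[gene.chromosome_id]
        parts = [chrom.sequence[s:e] for s, e in gene.exon_intervals]
        seq = "".join(parts)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def seq_array(self, chromosome_id: str) -> np.ndarray:
        """Chromosome sequence as a uint8 array of ASCII codes."""
        return np.frombuffer(
            self.chromosomes[chromosome_id].sequence.encode("ascii"), dtype=np.uint8
        )


def _validate_sequence(chrom_id: str, seq: str) -> None:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ok = np.zeros(256, dtype=bool)
    ok[list(_VALID_BASES)] = True
    bad = ~ok[arr]
    if bad.any():
        pos = int(np.argmax(bad))
        raise GenomeIOError(
            f"chromosome {chrom_id!r}: non-ACGTN character {seq[pos]!r} at position {pos}"
        )


def read_manifest(manifest_path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Read the chromosome-pairing manifest (TSV: pair_id, copy1, copy2)."""
    rows: list[tuple[str, str, str]] = []
    with open(manifest_path) as fh:
        header = fh.readline().split()
        if header[:3] != ["pair_id", "copy1", "copy2"]:
            raise GenomeIOError(
                f"manifest {manifest_path}: expected header 'pair_id copy1 copy2'"
            )
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise GenomeIOError(f"manifest row too short: {line!r}")
            rows.append((fields[0], fields[1], fields[2]))
    seen: set[str] = set()
    for pid, c1, c2 in rows:
        for cid in (c1, c2):
            if cid in seen:
                raise GenomeIOError(f"chromosome {cid!r} appears in more than one manifest row")
            seen.add(cid)
    return rows


def _genes_from_gff(gff_path: str | os.PathLike) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    for g in db.features_of_type("gene"):
        exons = []
        for c in db.children(g, featuretype=("CDS", "exon")):
            exons.append((c.featuretype, c.start - 1, c.end))
        # Prefer CDS features; fall back to exons, then to the gene body.
        cds = sorted((s, e) for t, s, e in exons if t == "CDS")
        if not cds:
            cds = sorted((s, e) for t, s, e in exons if t == "exon")
        genes.append(
            GeneAnnotation(
                gene_id=g.id,
                chromosome_id=g.seqid,
                start=g.start - 1,
                end=g.end,
                strand=g.strand if g.strand in ("+", "-") else "+",
                exon_intervals=cds or None or [],
            )
        )
    return genes


def read_genome(
    fasta_path: str | os.PathLike,
    gff_path: str | os.PathLike,
    manifest_path: str | os.PathLike,
) -> Genome:
    """Load a phased assembly (FASTA + GFF3 + pairing manifest) into the model.

    GFF coordinates are converted from 1-based inclusive to 0-based half-open.
    Referential integrity is enforced: every gene and manifest entry must name
    an existing chromosome, and sequences must be over {A,C,G,T,N}.
    """
    pairs = read_manifest(manifest_path)
    membership: dict[str, tuple[str, int]] = {}
    for pid, c1, c2 in pairs:
        membership[c1] = (pid, 1)
        membership[c2] = (pid, 2)

    chromosomes: dict[str, ChromosomeRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        _validate_sequence(rec.id, seq)
        pid, copy = membership.get(rec.id, (rec.id, 1))
        chromosomes[rec.id] = ChromosomeRecord(rec.id, seq, pid, copy)

    for pid, c1, c2 in pairs:
        for cid in (c1, c2):
            if cid not in chromosomes:
                raise GenomeIOError(
                    f"manifest pair {pid!r} references missing chromosome {cid!r}"
                )

    genes: dict[str, list[GeneAnnotation]] = {cid: [] for cid in chromosomes}
    for gene in _genes_from_gff(gff_path):
        if gene.chromosome_id not in chromosomes:
            raise GenomeIOError(
                f"gene {gene.gene_id!r} annotated on missing chromosome "
                f"{gene.chromosome_id!r}"
            )
        if gene.end > len(chromosomes[gene.chromosome_id]):
            raise GenomeIOError(
                f"gene {gene.gene_id!r} extends past the end of {gene.chromosome_id!r}"
            )
        genes[gene.chromosome_id].append(gene)
    for lst in genes.values():
        lst.sort(key=lambda g: g.start)
    return Genome(chromosomes=chromosomes, genes=genes, pairs=pairs)


def write_genome(
    genome: Genome,
    fasta_path: str | os.PathLike,
    gff_path: str | os.PathLike,
    manifest_path: str | os.PathLike,
) -> None:
    """Write the model back to FASTA + GFF3 + manifest (inverse of read_genome)."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="")
        for c in genome.chromosomes.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in genome.chromosomes:
            for g in genome.genes_of(cid):
                attrs = f"ID={g.gene_id}"
                fh.write(
                    f"{cid}\thomeoscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{cid}\thomeoscan\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(g.exon_intervals, 1):
                    fh.write(
                        f"{cid}\thomeoscan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={g.gene_id}.cds{i};Parent={g.gene_id}.t1\n"
                    )
    with open(manifest_path, "w") as fh:
        fh.write("pair_id\tcopy1\tcopy2\n")
        for pid, c1, c2 in genome.pairs:
            fh.write(f"{pid}\t{c1}\t{c2}\n")


@dataclass
class BedInterval:
    """A labeled, scored genomic interval (BED6 line)."""

    chromosome_id: str
    start: int
    end: int
    label: str
    score: float = 0.0
    strand: str = "."


def write_segments_bed(segments: Sequence[BedInterval], path: str | os.PathLike) -> None:
    """Write segments as BED6, sorted by (chromosome, start).

    Overlapping segments on one chromosome are a hard error: the pipeline's
    segmentations are partitions and overlap indicates an upstream bug.
    """
    ordered = sorted(segments, key=lambda s: (s.chromosome_id, s.start, s.end))
    prev: dict[str, int] = {}
    for seg in ordered:
        if seg.start < 0 or seg.end <= seg.start:
            raise GenomeIOError(f"bad interval [{seg.start},{seg.end}) on {seg.chromosome_id}")
        if prev.get(seg.chromosome_id, -1) > seg.start:
            raise GenomeIOError(
                f"overlapping segments on {seg.chromosome_id} at {seg.start}"
            )
        prev[seg.chromosome_id] = seg.end
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for seg in ordered:
            fh.write(
                f"{seg.chromosome_id}\t{seg.start}\t{seg.end}\t{seg.label}\t"
                f"{seg.score:g}\t{seg.strand}\n"
            )


def read_segments_bed(path: str | os.PathLike) -> list[BedInterval]:
    segments: list[BedInterval] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            segments.append(
                BedInterval(chrom, int(start), int(end), name, float(score), strand)
            )
    return segments
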