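"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

import os
import warnings

from homeoscan import RunConfig, SimConfig, generate, read_genome, run_all
from homeoscan.synthetic_hybrid import SimResult, SimTruth

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SIM_DIR = os.path.join(ROOT, "scratch", "sim")
RESULTS = os.path.join(ROOT, "results")

#: study conditions: the generator defaults at a fixed, documented seed
SIM_SEED = 42


def simulate(force: bool = False) -> SimResult:
    result = generate(SimConfig(seed=SIM_SEED))
    if force or not os.path.exists(os.path.join(SIM_DIR, "truth.json")):
        result.write(SIM_DIR)
    return result


def load_or_simulate():
    """Return (genome, mito_sequence, truth), reading the files written by
    01_simulate_hybrid.py when present (exercising the I/O path), otherwise
    regenerating them in memory."""
    truth_path = os.path.join(SIM_DIR, "truth.json")
    if os.path.exists(truth_path):
        genome = read_genome(
            os.path.join(SIM_DIR, "genome.fasta"),
            os.path.join(SIM_DIR, "genes.gff3"),
            os.path.join(SIM_DIR, "pairs.tsv"),
        )
        from Bio import SeqIO

        mito = str(next(SeqIO.parse(os.path.join(SIM_DIR, "mito.fasta"), "fasta")).seq)
        truth = SimTruth.from_json(open(truth_path).read())
        return genome, mito, truth
    res = simulate()
    return res.genome, res.mito_sequence, res.truth


def pipeline(with_mito: bool = True):
    genome, mito, truth = load_or_simulate()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = run_all(
            genome,
            RunConfig(mutation_rate=3.0e-10, ploidy_factor=1),
            mito_sequence=mito if with_mito else None,
        )
    return out, truth


def results_dir() -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return RESULTS
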