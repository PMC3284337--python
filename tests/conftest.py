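import warnings

import numpy as np
import pytest
from hypothesis import settings

from homeoscan import RunConfig, SimConfig, generate, run_all
from homeoscan.synthetic_hybrid import LohBlockSpec

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


@pytest.fixture(scope="session")
def tiny_sim():
    """2 pairs x 60 short genes; no LOH, no exchange: fast structural checks."""
    cfg = SimConfig(
        seed=5,
        n_pairs=2,
        genes_per_chromosome=60,
        mean_cds_codons=150,
        sd_cds_codons=30,
        exchange_events=[],
        loh_blocks=[],
        numt_hemizygous=(1, 2),
        numt_biallelic=(0, 0),
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """3 pairs x 150 genes with one full-LOH pair, one partial block, one
    exchange and a handful of NUMTs: the standard mid-scale fixture."""
    cfg = SimConfig(
        seed=11,
        n_pairs=3,
        genes_per_chromosome=150,
        mean_cds_codons=320,
        sd_cds_codons=60,
        exchange_events=[],
        loh_blocks=[
            LohBlockSpec(1, 0.0, 1.0, "Pgamma", 0.556),
            LohBlockSpec(2, 0.55, 1.0, "Pepsilon", 0.28),
        ],
        numt_hemizygous=(1, 3),
        numt_biallelic=(1, 2),
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(
            small_sim.genome, RunConfig(), mito_sequence=small_sim.mito_sequence
        )
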