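"""Shared fixtures: pore models, an ABCA7-like locus, reference sets."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import squiggletr as sq

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_model_k1():
    """Minimal complete k=1 model: A, C, G, T at 80..110 pA."""
    return sq.PoreModel(k=1, levels={"A": 80.0, "C": 90.0, "G": 100.0, "T": 110.0})


@pytest.fixture(scope="session")
def model6():
    """Session-wide synthetic 6-mer model (deterministic)."""
    return sq.synthetic_pore_model()


@pytest.fixture(scope="session")
def model5():
    return sq.synthetic_pore_model(k=5)


@pytest.fixture(scope="session")
def locus():
    """ABCA7-like VNTR locus: real consensus motif, synthetic 250 bp flanks."""
    rng = np.random.default_rng(1)
    flank = lambda: "".join(rng.choice(list("ACGT"), 250))
    return sq.LocusDefinition(
        name="abca7_like",
        motif=sq.ABCA7_CONSENSUS,
        flank_left=flank(),
        flank_right=flank(),
        chrom="chr19",
        start=1049436,
        end=1050028,
        ref_units=23.2,
    )


@pytest.fixture(scope="session")
def refs(locus, model6):
    return sq.build_references(locus, model6)


@pytest.fixture(scope="session")
def variant_motifs(locus):
    return sq.known_variant_motifs(locus.motif)


def simulate(locus, model, n_units, strand="+", noise=0.0, dwell_model="geometric",
             dwell_mean=10.0, seed=0, variants=None):
    """Convenience wrapper used across tests."""
    cfg = sq.SimConfig(
        locus=locus,
        unit_chain=sq.make_chain(locus.motif, n_units, variants),
        strand=strand,
        noise_sd=noise,
        dwell_model=dwell_model,
        dwell_mean=dwell_mean,
        seed=seed,
    )
    return sq.simulate_read(cfg, model, read_id=f"r{seed}_{strand}{n_units}")
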