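"""Synthetic squiggle generator with ground truth.

Emulates the generative process behind raw nanopore data at a tandem-repeat
locus: expected current per k-mer (from a pore model), a variable dwell
(several consecutive samples per k-mer), additive Gaussian measurement noise,
a per-read gain/baseline (scale/offset), and both DNA strands.  Each
simulated read carries its ground truth (strand, TR boundary samples,
per-unit boundaries, motif chain), so every pipeline stage can be tested
without sequencing data.

Not modeled: low-frequency drift, stray-current spikes, pore stalls, or
modification-induced level shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pore_model import (
    LocusDefinition,
    PoreModel,
    SequenceError,
    normalize_sequence,
    reverse_complement,
    sequence_to_squiggle,
)
from .signal_io import RawRead


@dataclass
class SimConfig:
    """Generative parameters for one read.

    ``noise_sd`` is expressed relative to the clean signal's own spread, so a
    value of 0.3 means additive noise with sd 0.3 z-units after
    normalization.  ``dwell_model`` is ``"fixed"`` (every k-mer dwells
    ``dwell_mean`` samples) or ``"geometric"`` (geometric dwell with that
    mean, floored at 1 sample).
    """

    locus: LocusDefinition
    unit_chain: list[str]
    strand: str = "+"
    dwell_mean: float = 10.0
    dwell_model: str = "geometric"
    noise_sd: float = 0.0
    scale: float = 1.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")
        if self.dwell_model not in {"fixed", "geometric"}:
            raise ValueError("dwell_model must be 'fixed' or 'geometric'")
        if not self.unit_chain:
            raise ValueError("unit_chain must be non-empty")
        self.unit_chain = [normalize_sequence(u) for u in self.unit_chain]


@dataclass
class SimulatedRead:
    """A RawRead plus its generative ground truth (in read time order)."""

    read: RawRead
    strand: str
    tr_start_sample: int
    tr_end_sample: int
    unit_boundaries: list[int]  # first sample of each unit's first k-mer, + TR end
    unit_chain: list[str]  # genomic (left-to-right) orientation
    n_units: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_units = len(self.unit_chain)


def simulate_read(config: SimConfig, model: PoreModel, read_id: str = "sim") -> SimulatedRead:
    """Simulate one read spanning the locus' TR with the given unit chain."""
    locus = config.locus
    tr_seq = "".join(config.unit_chain)
    full = locus.flank_left + tr_seq + locus.flank_right
    if config.strand == "-":
        seq = reverse_complement(full)
        # read-time unit order is the genomic order reversed
        units_in_time = [reverse_complement(u) for u in reversed(config.unit_chain)]
        lead = len(locus.flank_right)
    else:
        seq = full
        units_in_time = list(config.unit_chain)
        lead = len(locus.flank_left)
    if len(seq) < model.k:
        raise SequenceError("simulated sequence shorter than k")
    clean = sequence_to_squiggle(seq, model).values
    n_windows = clean.size

    rng = np.random.default_rng(config.seed)
    if config.dwell_model == "fixed":
        dwells = np.full(n_windows, int(round(config.dwell_mean)), dtype=np.int64)
    else:
        dwells = rng.geometric(1.0 / config.dwell_mean, size=n_windows).astype(np.int64)
        np.maximum(dwells, 1, out=dwells)
    starts = np.concatenate(([0], np.cumsum(dwells)))  # sample index of window w
    samples = np.repeat(clean, dwells)
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd * clean.std(), size=samples.size)
    samples = samples * config.scale + config.offset

    # ground-truth boundaries: first sample of the k-mer window starting at
    # the first base of each unit (read-time order), plus the TR end
    boundaries = []
    base = lead
    for unit in units_in_time:
        boundaries.append(int(starts[base]))
        base += len(unit)
    boundaries.append(int(starts[base]))
    return SimulatedRead(
        read=RawRead(read_id=read_id, samples=samples),
        strand=config.strand,
        tr_start_sample=boundaries[0],
        tr_end_sample=boundaries[-1],
        unit_boundaries=boundaries,
        unit_chain=list(config.unit_chain),
    )


def make_chain(motif: str, n_units: int, variants: dict[int, str] | None = None) -> list[str]:
    """Chain of ``n_units`` motif copies with optional variant substitutions
    at 0-based unit positions."""
    chain = [motif] * n_units
    for pos, alt in (variants or {}).items():
        if not 0 <= pos < n_units:
            raise ValueError(f"variant position {pos} outside chain of {n_units}")
        chain[pos] = alt
    return chain


def simulate_cohort(
    locus: LocusDefinition,
    model: PoreModel,
    allele_a_units: int,
    allele_b_units: int,
    n_reads: int,
    variant_spec: dict[str, dict[int, str]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dwell_mean: float = 10.0,
    dwell_model: str = "geometric",
) -> tuple[list[SimulatedRead], list[dict]]:
    """Simulate a diploid cohort of reads with a ground-truth table.

    Reads alternate between alleles (A, B, A, B, ...) and, within the
    sequence of reads, between strands, deterministically given ``seed``.
    ``variant_spec`` maps allele id ("A"/"B") to {unit position: variant
    motif}, so allele-specific unit chains are reproducible across reads.
    Returns (reads, truth table) where the truth table rows carry read_id,
    allele, strand, n_units and the chain.
    """
    if n_reads < 2:
        raise ValueError("n_reads must be >= 2")
    variant_spec = variant_spec or {}
    chains = {
        "A": make_chain(locus.motif, allele_a_units, variant_spec.get("A")),
        "B": make_chain(locus.motif, allele_b_units, variant_spec.get("B")),
    }
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reads) % (2**31)
    reads: list[SimulatedRead] = []
    truth: list[dict] = []
    for i in range(n_reads):
        allele = "A" if i % 2 == 0 else "B"
        strand = "+" if i % 4 < 2 else "-"
        cfg = SimConfig(
            locus=locus,
            unit_chain=chains[allele],
            strand=strand,
            dwell_mean=dwell_mean,
            dwell_model=dwell_model,
            noise_sd=noise_sd,
            seed=int(child_seeds[i]),
        )
        rid = f"sim_{allele}_{strand}_{i:03d}"
        sim = simulate_read(cfg, model, read_id=rid)
        reads.append(sim)
        truth.append(
            {
                "read_id": rid,
                "allele": allele,
                "strand": strand,
                "n_units": sim.n_units,
                "chain": ",".join(sim.unit_chain),
            }
        )
    return reads, truth


def write_truth_tsv(truth: list[dict], path) -> None:
    """Write the cohort ground-truth table as TSV."""
    cols = ["read_id", "allele", "strand", "n_units", "chain"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
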