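"""k-mer pore models and expected-current reference squiggles.

A nanopore measures ionic current while DNA translocates; at any instant the
current is determined mainly by the ~k nucleotides occupying the pore (k ≈ 5-6
for R9.4 pores).  A *pore model* tabulates the expected current level (pA) for
every k-mer, which lets us translate a nucleotide sequence into an expected
current series (a "reference squiggle") without base calling.  Reference
squiggles for the repeat motif, its flanks, and multi-unit concatenations —
on both strands — drive all downstream dynamic-time-warping steps.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# base -> integer code used for vectorized k-mer indexing
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


class PoreModelError(ValueError):
    """Malformed or incomplete pore-model table."""


class SequenceError(ValueError):
    """Sequence contains characters outside the ACGT alphabet."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and validate against the ACGT alphabet."""
    s = seq.upper().replace("U", "T")
    for ch in set(s):
        if ch not in _BASES:
            raise SequenceError(f"non-ACGT character {ch!r} in sequence")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA sequence (empty input allowed)."""
    s = normalize_sequence(seq)
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PoreModel:
    """Expected current level per k-mer.

    Parameters
    ----------
    k : int
        k-mer length in nucleotides.
    levels : mapping
        Expected current (pA) for every one of the 4**k k-mers.
    level_sd : mapping, optional
        Per-k-mer current spread (pA); informational only.
    """

    k: int
    levels: Mapping[str, float]
    level_sd: Mapping[str, float] | None = None
    # lexicographic level array for fast vectorized lookup
    _level_array: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise PoreModelError("k must be >= 1")
        expected = 4 ** self.k
        if len(self.levels) != expected:
            raise PoreModelError(
                f"pore model has {len(self.levels)} k-mers, expected {expected} for k={self.k}"
            )
        arr = np.empty(expected, dtype=float)
        for kmer, level in self.levels.items():
            if len(kmer) != self.k:
                raise PoreModelError(f"k-mer {kmer!r} does not have length k={self.k}")
            if not np.isfinite(level):
                raise PoreModelError(f"non-finite level for k-mer {kmer!r}")
            idx = 0
            for ch in kmer:
                if ch not in _BASE_CODE:
                    raise PoreModelError(f"non-ACGT character in k-mer {kmer!r}")
                idx = idx * 4 + _BASE_CODE[ch]
            arr[idx] = level
        object.__setattr__(self, "_level_array", arr)

    def level_of(self, kmer: str) -> float:
        return self.levels[kmer]


def load_pore_model(path) -> PoreModel:
    """Load a tab-separated pore-model table.

    The table must have a header with columns ``kmer`` and ``level_mean``
    (optionally ``level_stdv``); currents are in pA.  Raises
    :class:`PoreModelError` on duplicate or missing k-mers, inconsistent
    k-mer widths, or non-ACGT characters.
    """
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - message wrapping
        raise PoreModelError(f"cannot read pore model {path}: {exc}") from exc
    cols = {c.lower().lstrip("#"): c for c in df.columns}
    if "kmer" not in cols or "level_mean" not in cols:
        raise PoreModelError("pore model table needs 'kmer' and 'level_mean' columns")
    kmers = df[cols["kmer"]].astype(str).str.upper()
    widths = kmers.str.len().unique()
    if len(widths) != 1:
        raise PoreModelError(f"inconsistent k-mer widths: {sorted(widths)}")
    k = int(widths[0])
    if kmers.duplicated().any():
        dupes = kmers[kmers.duplicated()].tolist()[:3]
        raise PoreModelError(f"duplicate k-mers in pore model: {dupes}")
    levels = dict(zip(kmers, df[cols["level_mean"]].astype(float)))
    expected = {"".join(p) for p in itertools.product(_BASES, repeat=k)}
    missing = expected - set(levels)
    if missing:
        raise PoreModelError(f"pore model missing {len(missing)} k-mers, e.g. {sorted(missing)[:3]}")
    extra = set(levels) - expected
    if extra:
        raise PoreModelError(f"non-ACGT k-mers in pore model: {sorted(extra)[:3]}")
    level_sd = None
    if "level_stdv" in cols:
        level_sd = dict(zip(kmers, df[cols["level_stdv"]].astype(float)))
    return PoreModel(k=k, levels=levels, level_sd=level_sd)


def synthetic_pore_model(k: int = 6, seed: int = 17) -> PoreModel:
    """Deterministic synthetic pore model (default stand-in for a real table).

    Levels are drawn once from N(90, 12) pA with a fixed seed, so distinct
    k-mers get well-separated, reproducible levels.  This is a synthetic
    model: it has the scale and spread of an R9.4-style table but no
    sequence-dependent structure, which is sufficient because every
    comparison downstream is a z-normalized DTW distance.
    """
    rng = np.random.default_rng(seed)
    kmers = ["".join(p) for p in itertools.product(_BASES, repeat=k)]
    levels = dict(zip(kmers, rng.normal(90.0, 12.0, size=len(kmers))))
    return PoreModel(k=k, levels=levels)


@dataclass(frozen=True)
class LocusDefinition:
    """A tandem-repeat locus: coordinates, consensus motif, and flanks.

    ``ref_units`` is the (possibly fractional) motif copy number in the
    reference assembly, e.g. 23.2 for the ABCA7 VNTR.
    """

    name: str
    motif: str
    flank_left: str
    flank_right: str
    chrom: str = ""
    start: int = 0  # 0-based half-open internally
    end: int = 0
    ref_units: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", normalize_sequence(self.motif))
        object.__setattr__(self, "flank_left", normalize_sequence(self.flank_left))
        object.__setattr__(self, "flank_right", normalize_sequence(self.flank_right))
        if not self.motif:
            raise SequenceError("motif must be non-empty")
        if not self.flank_left or not self.flank_right:
            raise SequenceError("flanks must be non-empty")
        if self.end < self.start:
            raise ValueError("locus end < start")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive UCSC-style region ``chr:start-end``.

    Returns (chrom, start0, end0) in 0-based half-open coordinates.
    """
    chrom, _, rng = region.partition(":")
    lo, _, hi = rng.replace(",", "").partition("-")
    start1, end1 = int(lo), int(hi)
    if not chrom or end1 < start1:
        raise ValueError(f"malformed region {region!r}")
    return chrom, start1 - 1, end1


def locus_from_fasta(fasta_path, region: str, motif: str, name: str | None = None,
                     flank_len: int = 250, ref_units: float = 0.0) -> LocusDefinition:
    """Build a LocusDefinition by extracting flanks from a FASTA reference.

    ``region`` is the TR interval in 1-based inclusive notation
    (e.g. ``chr19:1049437-1050028``); ``flank_len`` bases are taken on each
    side (clipped at contig ends with a warning).
    """
    from pyfaidx import Fasta

    chrom, start0, end0 = parse_region(region)
    fa = Fasta(str(fasta_path))
    seqlen = len(fa[chrom])
    lo = max(0, start0 - flank_len)
    hi = min(seqlen, end0 + flank_len)
    if lo > start0 - flank_len + 0 or start0 - flank_len < 0 or end0 + flank_len > seqlen:
        if start0 - flank_len < 0 or end0 + flank_len > seqlen:
            warnings.warn(f"flank clipped at contig end for {region}")
    flank_left = str(fa[chrom][lo:start0])
    flank_right = str(fa[chrom][end0:hi])
    return LocusDefinition(
        name=name or region, motif=motif, flank_left=flank_left,
        flank_right=flank_right, chrom=chrom, start=start0, end=end0,
        ref_units=ref_units,
    )


def load_locus(path) -> LocusDefinition:
    """Read a self-contained key-value locus file.

    Lines of ``key = value`` (or ``key: value``); keys: name, motif,
    flank_left, flank_right, and optionally chrom, start, end, ref_units.
    """
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, _, val = line.partition("=")
            elif ":" in line:
                key, _, val = line.partition(":")
            else:
                continue
            fields[key.strip().lower()] = val.strip()
    try:
        return LocusDefinition(
            name=fields.get("name", "locus"),
            motif=fields["motif"],
            flank_left=fields["flank_left"],
            flank_right=fields["flank_right"],
            chrom=fields.get("chrom", ""),
            start=int(fields.get("start", 0)),
            end=int(fields.get("end", 0)),
            ref_units=float(fields.get("ref_units", 0.0)),
        )
    except KeyError as exc:
        raise ValueError(f"locus file {path} missing field {exc}") from exc


@dataclass(frozen=True)
class ReferenceSquiggle:
    """Expected-current series for a named sequence fragment on one strand.

    ``values[i]`` is the model level of the k-mer starting at base i of
    ``source_seq``; hence ``len(values) == len(source_seq) - k + 1``.
    """

    label: str
    strand: str
    values: np.ndarray
    source_seq: str

    def __len__(self) -> int:
        return len(self.values)


def sequence_to_squiggle(seq: str, model: PoreModel, label: str = "fragment",
                         strand: str = "+") -> ReferenceSquiggle:
    """Convert a nucleotide sequence to its expected-current squiggle.

    One value per successive k-mer window, 5'->3'.  The caller is responsible
    for reverse-complementing first when a negative-strand squiggle is wanted.
    """
    s = normalize_sequence(seq)
    if len(s) < model.k:
        raise SequenceError(
            f"sequence of length {len(s)} shorter than k={model.k}"
        )
    codes = np.fromiter((_BASE_CODE[c] for c in s), dtype=np.int64, count=len(s))
    windows = np.lib.stride_tricks.sliding_window_view(codes, model.k)
    powers = 4 ** np.arange(model.k - 1, -1, -1, dtype=np.int64)
    idx = windows @ powers
    values = model._level_array[idx]
    return ReferenceSquiggle(label=label, strand=strand, values=values, source_seq=s)


def build_references(locus: LocusDefinition, model: PoreModel,
                     n_units_multi: int = 5, flank_len: int = 250
                     ) -> dict[tuple[str, str], ReferenceSquiggle]:
    """Build the full strand-specific reference-squiggle set for a locus.

    For each strand {+, -} produces:

    - ``flank_left`` / ``flank_right``: the two flanks;
    - ``unit``: one consensus motif copy;
    - ``multi_unit``: ``n_units_multi`` concatenated motif copies (the
      segmentation reference);
    - ``flank_plus_units``: left flank + ``n_units_multi`` motif copies;
    - ``units_plus_flank``: ``n_units_multi`` motif copies + right flank.

    Concatenations are squiggled as one sequence so k-mer context crosses the
    junctions.  Negative-strand squiggles are built from the reverse
    complement of the corresponding concatenated sequence.  Keys are
    ``(label, strand)``.
    """
    if n_units_multi < 1:
        raise ValueError("n_units_multi must be >= 1")
    flank_left = locus.flank_left
    flank_right = locus.flank_right
    for side, flank in (("left", flank_left), ("right", flank_right)):
        if len(flank) < flank_len:
            logger.warning(
                "%s flank of locus %s is %d bp (< target %d); using as-is",
                side, locus.name, len(flank), flank_len,
            )
    if len(flank_left) > flank_len:
        flank_left = flank_left[-flank_len:]
    if len(flank_right) > flank_len:
        flank_right = flank_right[:flank_len]
    units = locus.motif * n_units_multi
    fragments = {
        "flank_left": flank_left,
        "flank_right": flank_right,
        "unit": locus.motif,
        "multi_unit": units,
        "flank_plus_units": flank_left + units,
        "units_plus_flank": units + flank_right,
    }
    refs: dict[tuple[str, str], ReferenceSquiggle] = {}
    for label, seq in fragments.items():
        refs[(label, "+")] = sequence_to_squiggle(seq, model, label=label, strand="+")
        refs[(label, "-")] = sequence_to_squiggle(
            reverse_complement(seq), model, label=label, strand="-"
        )
    return refs
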