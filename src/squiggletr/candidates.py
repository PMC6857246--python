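"""Candidate tandem-repeat loci from a UCSC "Simple Repeats" track.

The Simple Repeats track is the Tandem Repeats Finder annotation of the
reference genome.  Candidate VNTR loci amenable to squiggle-domain
genotyping are selected with three filters: match percentage above 90
(strict), period size 20-40 nucleotides (inclusive), and more than 15 motif
copies (strict).  GC content is computed for downstream stratification
(squiggle genotyping is most valuable above ~45% GC, where base-call-domain
methods lose guanine-rich reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

# UCSC simpleRepeat schema (without the leading bin column)
_FIELDS = (
    "chrom chromStart chromEnd name period copyNum consensusSize perMatch "
    "perIndel score A C G T entropy sequence"
).split()


class TrackError(IOError):
    """Unreadable track file."""


@dataclass
class TRCandidate:
    """One simpleRepeat row (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    period: int
    copy_num: float
    per_match: float
    consensus: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if not 0 <= self.per_match <= 100:
            raise ValueError("per_match must be in [0, 100]")
        if self.period < 1:
            raise ValueError("period must be >= 1")

    @property
    def gc_content(self) -> float:
        return gc_content(self.consensus)


def gc_content(seq: str) -> float:
    """Fraction of G+C bases in a sequence."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    return (s.count("G") + s.count("C")) / len(s)


def load_simple_repeats(path) -> list[TRCandidate]:
    """Parse a UCSC simpleRepeat TSV into candidates.

    Handles files with or without a header line and with or without the
    leading ``bin`` column (auto-detected).  Malformed rows are logged and
    skipped; an unreadable file raises :class:`TrackError`.
    """
    try:
        fh = open(path)
    except OSError as exc:
        raise TrackError(f"cannot read track {path}: {exc}") from exc
    out: list[TRCandidate] = []
    with fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if lineno == 1 and any(p in {"chrom", "chromStart"} for p in parts):
                continue  # header line
            # with a bin column the first field is an integer and the second
            # the chromosome name
            if len(parts) == len(_FIELDS) + 1 and parts[0].isdigit():
                parts = parts[1:]
            if len(parts) < len(_FIELDS):
                logger.warning("%s line %d: %d fields, expected %d; skipped",
                               path, lineno, len(parts), len(_FIELDS))
                continue
            row = dict(zip(_FIELDS, parts))
            try:
                out.append(TRCandidate(
                    chrom=row["chrom"],
                    start=int(row["chromStart"]),
                    end=int(row["chromEnd"]),
                    period=int(row["period"]),
                    copy_num=float(row["copyNum"]),
                    per_match=float(row["perMatch"]),
                    consensus=row["sequence"],
                ))
            except (ValueError, KeyError) as exc:
                logger.warning("%s line %d: %s; skipped", path, lineno, exc)
    return out


def filter_candidates(candidates, min_match: float = 90.0,
                      period_range: tuple[int, int] = (20, 40),
                      min_copies: float = 15.0) -> list[TRCandidate]:
    """Keep candidates with per_match > 90, 20 <= period <= 40, copies > 15.

    Bounds follow the prose semantics "more than 90%", "between 20 and 40",
    "more than 15 copies": strict on match and copy number, inclusive on the
    period range.  Order-preserving and idempotent.
    """
    lo, hi = period_range
    return [
        c for c in candidates
        if c.per_match > min_match and lo <= c.period <= hi and c.copy_num > min_copies
    ]


def dedup_candidates(candidates) -> list[TRCandidate]:
    """Merge rows sharing an identical interval, keeping max copy number."""
    best: dict[tuple[str, int, int], TRCandidate] = {}
    order: list[tuple[str, int, int]] = []
    for c in candidates:
        key = (c.chrom, c.start, c.end)
        if key not in best:
            best[key] = c
            order.append(key)
        elif c.copy_num > best[key].copy_num:
            best[key] = c
    return [best[k] for k in order]


def write_bed(candidates, path) -> None:
    """Write kept candidates as BED6+ (name=motif, score=copy number)."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.consensus}\t"
                     f"{c.copy_num:g}\t+\t{c.period}\t{c.per_match:g}\n")
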