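"""Read chains, consensus, diploid allele calls and genotyping metrics.

Each QC-passing read becomes a chain of unit-cluster labels (one per
segmented TR unit, reversed into genomic orientation for negative-strand
reads).  Chains from one allele are summarized by a progressive multiple
alignment over the label alphabet with a per-column majority consensus.
Unit counts are split into two alleles with one-dimensional k-means (two
centers, deterministic extreme-value initialization) and each allele is
reported as median / Q25 / Q75 of its member read counts.

Accuracy against an externally validated length L_a (e.g. Southern blot)
is (1 - |L_a - mean| / L_a) * 100%, precision as the relative standard
deviation sd/mean * 100%; method-level values are medians over alleles with
at least two reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ClusterModel
from .delineation import Segmentation

GAP = "-"


@dataclass
class ReadChain:
    """Ordered unit labels for one read, in genomic orientation."""

    read_id: str
    strand: str
    chain: list[str]

    def __len__(self) -> int:
        return len(self.chain)


@dataclass
class ConsensusChain:
    """Gapped chain alignment plus per-column majority consensus."""

    aligned: list[list[str]]
    consensus: list[str]
    read_ids: list[str] = field(default_factory=list)


@dataclass
class AlleleCall:
    """One allele of a diploid call: unit-count summary over member reads."""

    allele: int
    read_ids: list[str]
    unit_counts: list[float]
    median: float
    q25: float
    q75: float
    strand_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.unit_counts)


@dataclass
class AlleleMetrics:
    """Per-allele and method-level accuracy / precision."""

    accuracy: dict[int, float]
    rsd: dict[int, float]
    n_reads: dict[int, int]
    method_accuracy: float
    method_rsd: float


def reads_to_chains(segmentations: list[Segmentation], model: ClusterModel,
                    unit_index: dict[tuple[str, int], int] | None = None,
                    labels: dict[int, str] | None = None) -> list[ReadChain]:
    """Turn per-read segmentations into cluster-label chains.

    ``unit_index`` maps (read_id, unit position) to the row of the pooled
    cluster model; when omitted, units are assumed to have been pooled in
    read order.  ``labels`` optionally renames integer cluster ids (e.g. to
    assigned motifs).  Negative-strand chains are reversed into genomic
    left-to-right orientation.
    """
    if unit_index is None:
        unit_index = {}
        pos = 0
        for seg in segmentations:
            for u in range(seg.n_units):
                unit_index[(seg.read_id, u)] = pos
                pos += 1
    chains = []
    for seg in segmentations:
        chain = []
        for u in range(seg.n_units):
            key = (seg.read_id, u)
            if key not in unit_index:
                raise RuntimeError(f"unlabeled unit {key}")
            lab = int(model.labels[unit_index[key]])
            chain.append(labels[lab] if labels else str(lab))
        if seg.strand == "-":
            chain.reverse()
        chains.append(ReadChain(read_id=seg.read_id, strand=seg.strand, chain=chain))
    return chains


def _nw_align(a: list[str], b: list[str], match: float = 1.0,
              mismatch: float = -1.0, gap: float = -1.0
              ) -> list[tuple[int | None, int | None]]:
    """Global alignment of two label sequences.

    Returns aligned index pairs, ``None`` marking a gap in that sequence.
    """
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = gap * np.arange(n + 1)
    dp[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + s, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if dp[i, j] == dp[i - 1, j - 1] + s:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
                continue
        if i > 0 and dp[i, j] == dp[i - 1, j] + gap:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    return pairs[::-1]


def _column_majority(column: list[str]) -> str:
    """Majority label of a column (gaps count as votes); ties -> gap."""
    counts: dict[str, int] = {}
    for lab in column:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else GAP


def chain_consensus(chains: list[ReadChain]) -> ConsensusChain:
    """Progressive multiple alignment of label chains + majority consensus.

    Scores: match +1, mismatch -1, gap -1.  Guide order is descending chain
    length (stable on ties); each next chain is aligned to the running
    per-column majority sequence, and the gaps it introduces are propagated
    into the rows already aligned.
    """
    if not chains:
        raise ValueError("need at least one chain")
    order = sorted(range(len(chains)), key=lambda i: (-len(chains[i]), i))
    aligned: list[list[str]] = [list(chains[order[0]].chain)]
    for idx in order[1:]:
        guide = [_column_majority(list(col)) for col in zip(*aligned)]
        chain = list(chains[idx].chain)
        pairs = _nw_align(guide, chain)
        out_rows: list[list[str]] = [[] for _ in aligned]
        new_row: list[str] = []
        for gi, cj in pairs:
            if gi is None:  # gap inserted into all existing rows
                for out in out_rows:
                    out.append(GAP)
            else:
                for row, out in zip(aligned, out_rows):
                    out.append(row[gi])
            new_row.append(chain[cj] if cj is not None else GAP)
        aligned = out_rows + [new_row]
    # restore original chain order for presentation
    rows_by_input = [None] * len(chains)
    for rank, idx in enumerate(order):
        rows_by_input[idx] = aligned[rank]
    consensus = [_column_majority(list(col)) for col in zip(*aligned)]
    return ConsensusChain(
        aligned=rows_by_input,
        consensus=consensus,
        read_ids=[c.read_id for c in chains],
    )


def diploid_call(unit_counts, read_ids=None, strands=None
                 ) -> tuple[AlleleCall, AlleleCall]:
    """Split unit counts into two alleles with 1-D k-means (two centers).

    Deterministic initialization at the extreme values, Lloyd iterations to
    convergence; ties in assignment go to the lower center.  Alleles are
    canonicalized so allele 1 has the smaller median.  With all counts equal
    the two alleles coincide.  Fewer than 2 reads yields a single provisional
    allele duplicated into both slots (flagged by identical membership).
    """
    counts = [float(c) for c in unit_counts]
    read_ids = list(read_ids) if read_ids is not None else [str(i) for i in range(len(counts))]
    strands = list(strands) if strands is not None else ["?"] * len(counts)

    def summarize(allele, members):
        vals = [counts[i] for i in members]
        return AlleleCall(
            allele=allele,
            read_ids=[read_ids[i] for i in members],
            unit_counts=vals,
            median=float(np.median(vals)),
            q25=float(np.percentile(vals, 25)),
            q75=float(np.percentile(vals, 75)),
            strand_counts={s: sum(1 for i in members if strands[i] == s)
                           for s in set(strands[i] for i in members)},
        )

    if len(counts) < 2:
        members = list(range(len(counts)))
        call = summarize(1, members)
        return call, summarize(2, members)
    arr = np.asarray(counts)
    c1, c2 = float(arr.min()), float(arr.max())
    assign = np.zeros(arr.size, dtype=int)
    for _ in range(100):
        d1 = np.abs(arr - c1)
        d2 = np.abs(arr - c2)
        new_assign = (d2 < d1).astype(int)  # ties -> lower center
        n1, n2 = (new_assign == 0).sum(), (new_assign == 1).sum()
        nc1 = float(arr[new_assign == 0].mean()) if n1 else c1
        nc2 = float(arr[new_assign == 1].mean()) if n2 else c2
        if np.array_equal(new_assign, assign) and nc1 == c1 and nc2 == c2:
            break
        assign, c1, c2 = new_assign, nc1, nc2
    g1 = [i for i in range(arr.size) if assign[i] == 0]
    g2 = [i for i in range(arr.size) if assign[i] == 1]
    if not g2:  # all counts identical: alleles coincide
        return summarize(1, g1), summarize(2, g1)
    a1, a2 = summarize(1, g1), summarize(2, g2)
    if a2.median < a1.median:
        a1, a2 = summarize(1, g2), summarize(2, g1)
    return a1, a2


def allele_metrics(calls, validated_lengths) -> AlleleMetrics:
    """Accuracy and relative standard deviation per allele + method medians.

    ``calls`` is a sequence of AlleleCall, ``validated_lengths`` the matching
    validated lengths L_a (> 0, same units as the unit counts).  Accuracy is
    (1 - |L_a - mean_a| / L_a) * 100, RSD sd_a / mean_a * 100 (population
    sd).  Alleles with fewer than 2 reads are excluded from the method-level
    medians.
    """
    accuracy: dict[int, float] = {}
    rsd: dict[int, float] = {}
    n_reads: dict[int, int] = {}
    eligible_acc = []
    eligible_rsd = []
    for call, L in zip(calls, validated_lengths, strict=True):
        if L <= 0:
            raise ValueError(f"validated length must be > 0, got {L}")
        vals = np.asarray(call.unit_counts, dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std())
        acc = (1.0 - abs(L - mean) / L) * 100.0
        r = (sd / mean) * 100.0 if mean != 0 else float("nan")
        accuracy[call.allele] = acc
        rsd[call.allele] = r
        n_reads[call.allele] = call.n_reads
        if call.n_reads >= 2:
            eligible_acc.append(acc)
            eligible_rsd.append(r)
    method_acc = float(np.median(eligible_acc)) if eligible_acc else float("nan")
    method_rsd = float(np.median(eligible_rsd)) if eligible_rsd else float("nan")
    return AlleleMetrics(accuracy=accuracy, rsd=rsd, n_reads=n_reads,
                         method_accuracy=method_acc, method_rsd=method_rsd)


def tg_absolute_units(delta_units: float, ref_units: float) -> float:
    """Convert a relative unit-count difference to absolute repeat units.

    Base-call-domain TR callers report each read's length as the difference
    from the reference sequence in repeat units; adding the reference copy
    number (23.2 for the ABCA7 VNTR) gives the absolute unit count.
    """
    if ref_units <= 0:
        raise ValueError("ref_units must be > 0")
    return float(delta_units) + float(ref_units)


def units_to_bases(units: float, motif_len: int) -> float:
    """Repeat units -> bases (multiply by motif length)."""
    return units * motif_len
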