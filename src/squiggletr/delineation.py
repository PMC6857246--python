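"""Locating and segmenting the tandem repeat inside raw signal.

The pipeline per read:

1. **detect_spanning** — window the read, search all four flank reference
   squiggles (both flanks x both strands) with open-ended MVM alignment, and
   keep the strand whose two flanks both match well and occur in a
   time-consistent order.  A read qualifying on neither strand is
   "not spanning".
2. **finemap_boundaries** — refine the coarse TR start/end with a reference
   built from flank + several TR units squiggled as one sequence, so k-mer
   context crosses the junction; the TR boundary is the signal sample matched
   to the first reference point past the flank.
3. **segment_tr** — split the TR signal into repeat units by repeatedly
   anchoring a five-unit reference at the current frontier (one end fixed,
   the other open toward the TR center), three units per cycle, running
   passes from both TR ends until they cross; conflicting units in the
   overlap are resolved by the lower re-scored single-unit DTW distance.
4. **qc_filter** — discard reads whose mean per-unit distance exceeds
   Q75 + 1.5*IQR across reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dtw import (
    Alignment,
    InfeasibleAlignmentError,
    MvmConstraint,
    mvm_align,
    mvm_align_skip,
    mvm_cost_banded,
    subsequence_search,
    symmetric_dtw_distance,
)
from .pore_model import ReferenceSquiggle
from .signal_io import (
    DegenerateSignalError,
    RawRead,
    restore_clean_amplitude,
    window_signal,
    znormalize,
)

logger = logging.getLogger(__name__)


@dataclass
class DelineationConfig:
    """Tunable parameters of TR delineation.

    ``max_flank_distance`` is the normalized MVM distance (z-units per
    reference point) below which a flank hit counts as found;
    ``samples_per_kmer`` the expected dwell used only for sizing windows and
    search margins (default 10 ~ 4 kHz / 450 b/s); windows are
    ``window_factor`` x the expected flank signal span, stepped by a third of
    the window so a whole flank is guaranteed to lie inside one window.
    """

    elasticity: int = 25
    dwell_cap_factor: float = 10.0
    max_flank_distance: float = 0.6
    max_flank_portion_cost: float = 0.55
    samples_per_kmer: float = 10.0
    window_factor: float = 1.5
    n_units_multi: int = 5

    @property
    def constraint(self) -> MvmConstraint:
        return MvmConstraint(self.elasticity)

    def effective_constraint(self, dwell_estimate: float) -> MvmConstraint:
        """Dwell cap for boundary-precision steps.

        With the all-samples-pay cost, the elasticity no longer guards
        against free stretching (every extra sample is paid for), so its
        only role is capping how many samples one reference point may
        absorb.  A cap tight relative to the dwell distribution's tail
        forces long dwells to spill into neighbouring points, distorting
        junctions and biasing unit counts; scale it with the observed
        dwell instead.
        """
        return MvmConstraint(max(self.elasticity,
                                 int(round(self.dwell_cap_factor * dwell_estimate))))


@dataclass
class SpanningReadCall:
    """A read found to span the TR, with coarse or fine boundaries."""

    read_id: str
    strand: str
    flank_left_alignment: Alignment
    flank_right_alignment: Alignment
    tr_start_sample: int
    tr_end_sample: int
    flank_distance: float
    # absolute sample span of the first/second (in time) flank hits
    first_flank_span: tuple[int, int] = (0, 0)
    second_flank_span: tuple[int, int] = (0, 0)
    dwell_estimate: float = 10.0
    coarse_only: bool = False


@dataclass
class Segmentation:
    """Per-read unit segmentation (absolute sample coordinates)."""

    read_id: str
    strand: str
    boundaries: list[int]
    unit_signals: list[np.ndarray]
    unit_distances: list[float]
    flags: list[str] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.unit_signals)

    @property
    def mean_distance(self) -> float:
        if not self.unit_distances:
            return float("nan")
        return float(np.mean(self.unit_distances))


@dataclass
class QcThreshold:
    """Outlier cutoff Q75 + 1.5*IQR on per-read mean unit distance."""

    q75: float
    iqr: float

    @property
    def cutoff(self) -> float:
        return self.q75 + 1.5 * self.iqr


def _first_flank_label(strand: str) -> tuple[str, str]:
    # In read time, a + read starts with the genomic left flank; a - read is
    # the reverse complement, so it starts with the (revcomp'ed) right flank.
    return ("flank_left", "flank_right") if strand == "+" else ("flank_right", "flank_left")


def detect_spanning(read: RawRead,
                    refs: dict[tuple[str, str], ReferenceSquiggle],
                    config: DelineationConfig = DelineationConfig()
                    ) -> SpanningReadCall | None:
    """Decide whether a read spans the TR, and on which strand.

    Returns a :class:`SpanningReadCall` with coarse TR boundaries, or None
    when no strand shows both flanks below ``max_flank_distance`` in a
    consistent order (the not-spanning outcome).
    """
    flank_len = max(len(refs[("flank_left", "+")]), len(refs[("flank_right", "+")]))
    window_len = int(config.window_factor * flank_len * config.samples_per_kmer)
    step = max(1, window_len // 3)
    windows = window_signal(read.samples, window_len, step, read_id=read.read_id)
    if not windows:
        logger.info("read %s: too short to window (not spanning)", read.read_id)
        return None
    if config.samples_per_kmer >= 4:  # noise estimable from within-dwell diffs
        for w in windows:
            w.z = restore_clean_amplitude(w.z)
    constraint = config.constraint

    def candidates(zref: np.ndarray, k_top: int = 3):
        """Top skip-MVM hits over all windows, best (then earliest) first."""
        cands = []
        for win in sorted(windows, key=lambda w: w.offset):
            try:
                aln = mvm_align_skip(zref, win.z, constraint,
                                     open_begin=True, open_end=True)
            except InfeasibleAlignmentError:
                continue
            cands.append((aln.normalized_distance, win.offset, win, aln))
        cands.sort(key=lambda t: (t[0], t[1]))
        return [(win, aln, d) for d, _, win, aln in cands[:k_top]]

    best_call: SpanningReadCall | None = None
    for strand in ("+", "-"):
        lab1, lab2 = _first_flank_label(strand)
        gated = {}
        ok = True
        for lab, first in ((lab1, True), (lab2, False)):
            ref = refs[(lab, strand)]
            try:
                zref = znormalize(ref.values).z
            except DegenerateSignalError:
                ok = False
                break
            keep = []
            for win, aln, d in candidates(zref):
                if d >= config.max_flank_distance:
                    continue
                span = (win.offset + aln.begin, win.offset + aln.end)
                jcost = _junction_portion_cost(read, refs, strand, first,
                                               span, config)
                if jcost >= config.max_flank_portion_cost:
                    continue
                keep.append((aln, span, jcost))
            if not keep:
                ok = False
                break
            gated[lab] = keep
        if not ok:
            continue
        # best time-consistent pair by summed junction cost: individual
        # candidates can tie at the noise floor, but a pseudo-hit rarely
        # pairs with a consistent partner as cheaply as the true pair
        best_pair = None
        for a1, (b1, e1), j1 in gated[lab1]:
            for a2, (b2, e2), j2 in gated[lab2]:
                if e1 >= b2:  # flanks out of order or overlapping
                    continue
                jsum = j1 + j2
                if best_pair is None or jsum < best_pair[0]:
                    best_pair = (jsum, a1, (b1, e1), a2, (b2, e2))
        if best_pair is None:
            continue
        jsum, a1, (b1, e1), a2, (b2, e2) = best_pair
        dwell = 0.5 * ((e1 - b1 + 1) / len(refs[(lab1, strand)])
                       + (e2 - b2 + 1) / len(refs[(lab2, strand)]))
        aln_left, aln_right = (a1, a2) if strand == "+" else (a2, a1)
        call = SpanningReadCall(
            read_id=read.read_id,
            strand=strand,
            flank_left_alignment=aln_left,
            flank_right_alignment=aln_right,
            tr_start_sample=e1 + 1,
            tr_end_sample=b2,
            flank_distance=0.5 * jsum,
            first_flank_span=(b1, e1),
            second_flank_span=(b2, e2),
            dwell_estimate=max(1.0, dwell),
            coarse_only=True,
        )
        if best_call is None or call.flank_distance < best_call.flank_distance:
            best_call = call
    return best_call


def _junction_portion_cost(read: RawRead,
                           refs: dict[tuple[str, str], ReferenceSquiggle],
                           strand: str, first: bool,
                           span: tuple[int, int],
                           config: DelineationConfig) -> float:
    """Per-sample cost of the flank portion of a junction-construct fit.

    A candidate flank hit is validated by anchoring the flank+units (or
    mirrored units+flank) construct at the hit's outer edge and measuring
    the dwell-tiling cost over the *flank* reference points only.  A true
    hit puts the flank portion on real flank signal (noise-level cost); a
    pseudo-hit threading through the repeat puts it on repeat signal, which
    the all-samples-pay cost exposes.  Returns inf when no alignment is
    feasible.
    """
    b, e = span
    n = read.samples.size
    units_bases = len(refs[("multi_unit", strand)].source_seq)
    if first:
        construct = refs[("flank_plus_units" if strand == "+" else "units_plus_flank", strand)]
        flank_lab = _first_flank_label(strand)[0]
    else:
        construct = refs[("units_plus_flank" if strand == "+" else "flank_plus_units", strand)]
        flank_lab = _first_flank_label(strand)[1]
    fw = len(refs[(flank_lab, strand)].source_seq)  # flank windows ~ bases
    dwell = min(40.0, max(2.0, (e - b + 1) / max(1, len(refs[(flank_lab, strand)]))))
    margin = int(2.0 * units_bases * dwell) + 1
    try:
        zref = znormalize(construct.values).z
        if first:
            s0, s1 = b, min(n, e + margin)
            zsl = znormalize(read.samples[s0:s1]).z
        else:
            s0, s1 = max(0, b - margin), min(n, e + 1)
            zsl = znormalize(read.samples[s0:s1]).z[::-1]
            zref = zref[::-1]
        if config.samples_per_kmer >= 4:
            zsl = restore_clean_amplitude(zsl)
        aln = mvm_align(np.ascontiguousarray(zref), np.ascontiguousarray(zsl),
                        config.effective_constraint(dwell), open_end=True)
    except (InfeasibleAlignmentError, DegenerateSignalError):
        return float("inf")
    # flank points are the construct's first fw reference points in this
    # orientation (for the mirrored case the construct was reversed, so the
    # flank again comes first)
    fw = min(fw, len(zref) - 1)
    cut = aln.signal_index(fw)
    if cut < 2:
        return float("inf")
    cost = 0.0
    for i in range(fw):
        lo = aln.signal_index(i)
        hi = aln.signal_index(i + 1) if i + 1 < len(zref) else aln.end + 1
        for t in range(lo, hi):
            cost += abs(zref[i] - zsl[t])
    return cost / cut


def finemap_boundaries(read: RawRead,
                       call: SpanningReadCall,
                       refs: dict[tuple[str, str], ReferenceSquiggle],
                       config: DelineationConfig = DelineationConfig()
                       ) -> SpanningReadCall:
    """Refine TR start/end using flank+units junction references.

    The start-side reference is (in read time) flank followed by several TR
    units, the end-side reference units followed by flank; both are aligned
    open-ended over a slice around the coarse boundary and the refined
    boundary is the sample matched to the first reference point past the
    junction.  On infeasible geometry the coarse boundaries are kept and the
    call stays flagged ``coarse_only``.
    """
    strand = call.strand
    constraint = config.effective_constraint(call.dwell_estimate)
    n = read.samples.size
    units_bases = len(refs[("multi_unit", strand)].source_seq)
    margin = int(1.5 * units_bases * call.dwell_estimate) + 1

    if strand == "+":
        start_ref = refs[("flank_plus_units", "+")]
        end_ref = refs[("units_plus_flank", "+")]
        start_junction = len(refs[("flank_left", "+")].source_seq)
    else:
        # - read starts with revcomp(flank_right): that is the - squiggle of
        # units_plus_flank (= revcomp(units + flank_right)); mirrored for the end
        start_ref = refs[("units_plus_flank", "-")]
        end_ref = refs[("flank_plus_units", "-")]
        start_junction = len(refs[("flank_right", "-")].source_seq)
    end_junction = units_bases

    tr_start, tr_end = call.tr_start_sample, call.tr_end_sample
    refined_start = refined_end = None
    # anchor each junction alignment with a closed begin at the outer flank
    # edge found by the coarse search (the flank is non-repetitive, so that
    # edge is reliable) and pay for every sample: an open-ended skip
    # alignment would let the periodic unit portion slip by whole units
    try:
        s0 = max(0, call.first_flank_span[0])
        s1 = min(n, call.tr_start_sample + margin)
        zslice = znormalize(read.samples[s0:s1]).z
        if call.dwell_estimate >= 4:
            zslice = restore_clean_amplitude(zslice)
        aln = mvm_align(znormalize(start_ref.values).z, zslice, constraint,
                        open_end=True)
        refined_start = s0 + aln.signal_index(start_junction)
    except (InfeasibleAlignmentError, DegenerateSignalError) as exc:
        logger.info("read %s: start finemap failed (%s)", read.read_id, exc)
    try:
        t0 = max(0, call.tr_end_sample - margin)
        t1 = min(n, call.second_flank_span[1] + 1)
        zslice = znormalize(read.samples[t0:t1]).z
        if call.dwell_estimate >= 4:
            zslice = restore_clean_amplitude(zslice)
        # mirrored: reverse the slice so the outer flank edge becomes the
        # closed begin; the junction sample is the end of the mirrored dwell
        zrev = np.ascontiguousarray(zslice[::-1])
        zref_rev = np.ascontiguousarray(znormalize(end_ref.values).z[::-1])
        aln = mvm_align(zref_rev, zrev, constraint, open_end=True)
        L = zref_rev.size
        rev_junction = L - 1 - end_junction  # original window index -> mirrored
        if rev_junction + 1 < L:
            e = aln.signal_index(rev_junction + 1) - 1
        else:
            e = aln.end
        refined_end = (t1 - 1) - e
    except (InfeasibleAlignmentError, DegenerateSignalError) as exc:
        logger.info("read %s: end finemap failed (%s)", read.read_id, exc)

    coarse_only = refined_start is None or refined_end is None
    if not coarse_only and refined_start < refined_end:
        tr_start, tr_end = refined_start, refined_end
    else:
        coarse_only = True
    return SpanningReadCall(
        read_id=call.read_id,
        strand=strand,
        flank_left_alignment=call.flank_left_alignment,
        flank_right_alignment=call.flank_right_alignment,
        tr_start_sample=tr_start,
        tr_end_sample=tr_end,
        flank_distance=call.flank_distance,
        first_flank_span=call.first_flank_span,
        second_flank_span=call.second_flank_span,
        dwell_estimate=call.dwell_estimate,
        coarse_only=coarse_only,
    )


def _score_unit(unit_sig: np.ndarray, zunit_ref: np.ndarray,
                constraint: MvmConstraint) -> float:
    """Re-score one unit slice against the single-unit reference.

    MVM with both ends fixed, normalized by reference length; falls back to
    length-normalized symmetric DTW when the slice is too short or too long
    for a feasible MVM path.
    """
    if unit_sig.size < 2:
        return float("inf")
    try:
        return mvm_align(zunit_ref, unit_sig, constraint).normalized_distance
    except InfeasibleAlignmentError:
        return symmetric_dtw_distance(zunit_ref, unit_sig) / zunit_ref.size


def _pass_cycle(zsig: np.ndarray, zref: np.ndarray, unit_len: int, k: int,
                anchor: int, n_units_ref: int, constraint: MvmConstraint,
                max_slice: int, reverse: bool) -> list[int]:
    """One segmentation cycle from one end; returns up to three new
    boundaries in local (forward) coordinates, strictly beyond ``anchor``.

    ``reverse=False``: anchor is the left frontier, alignment runs rightward
    with the start fixed.  ``reverse=True``: anchor counts samples consumed
    from the right end; signal and reference are mirrored.  The mirrored
    reference is extended by the k-1 junction-context windows (recovered from
    the squiggle's periodicity): the plain multi-unit squiggle ends k-1
    windows short, leaving its anchored end without sequence context, and on
    a periodic signal that lets the whole reverse alignment slip by one unit.
    """
    n = zsig.size
    remaining = n - anchor
    if reverse:
        u = min(n_units_ref, remaining // unit_len)
    else:
        u = min(n_units_ref, (remaining + k - 1) // unit_len)
    if u < 1:
        return []
    if reverse:
        # extended reference: windows 0 .. u*unit_len - 1 ending on a unit
        # boundary with the following unit's context; by periodicity the
        # missing k-1 tail windows equal those one period earlier
        tail = zref[(n_units_ref - 1) * unit_len - k + 1:(n_units_ref - 1) * unit_len]
        ext = np.concatenate([zref, tail])
        ref = ext[(n_units_ref - u) * unit_len:][::-1]
        sig = zsig[::-1][anchor:anchor + max_slice]
    else:
        ref = zref[: u * unit_len - k + 1] if u < n_units_ref else zref
        sig = zsig[anchor:anchor + max_slice]
    if sig.size < ref.size:
        sig = zsig[::-1][anchor:] if reverse else zsig[anchor:]
        if sig.size < ref.size:
            return []
    try:
        aln = mvm_align(np.ascontiguousarray(ref), np.ascontiguousarray(sig),
                        constraint, open_end=True)
    except InfeasibleAlignmentError:
        return []
    boundaries: list[int] = []
    trunc_len = ref.size
    for j in range(1, min(3, u) + 1):
        if reverse:
            # junction between the j-th and (j+1)-th unit from the end sits
            # at mirrored index j*unit_len - 1; the unit's first
            # (forward-time) sample is the last sample of that dwell, i.e.
            # one before the next mirrored dwell starts
            idx = j * unit_len - 1
            if idx + 1 < trunc_len:
                e = aln.signal_index(idx + 1) - 1
            else:
                e = aln.end
            bnd = n - 1 - (anchor + e)  # back to forward coordinates
        else:
            idx = j * unit_len
            if idx < trunc_len:
                bnd = anchor + aln.signal_index(idx)
            else:  # boundary past the truncated reference: end of alignment
                bnd = anchor + aln.end + 1
        boundaries.append(int(bnd))
    return boundaries


def _select_count(zsig: np.ndarray, mref_raw: np.ndarray,
                  end_raw: np.ndarray | None, unit_len: int, k: int,
                  elasticity: int, dwell_est: float, n_hint: int,
                  n_ref: int = 5) -> int:
    """Model-select the unit count by global closed-ends alignment cost.

    For each candidate count n, an n-unit reference is aligned to the whole
    TR with both ends fixed and the per-sample cost compared.  Every
    candidate aligns the same samples over a span fixed by the TR
    boundaries, so the comparison is between equal-data fits; the count
    whose reference explains the signal best wins.  The reference is the
    unit's window pattern tiled n times, terminated (when the units+flank
    construct is available) with the true units-to-flank junction windows:
    the TR slice's last k-1 windows read into the flank, and without that
    context an extra unit wins spurious credit for absorbing the edge
    mismatch.  Candidates bracket both the boundary-derived count
    ``n_hint`` and the dwell-based estimate span / (unit_len * dwell).
    """
    S = zsig.size
    n_dwell = S / (unit_len * max(1.0, dwell_est))
    lo_c = min(n_hint, int(round(n_dwell)))
    hi_c = max(n_hint, int(round(n_dwell)))
    # both hints can sit above the true count (trimmed flank hits shorten the
    # dwell estimate; phase slips inflate the boundary count), so the scan
    # must reach well below them for the elbow to be visible at all
    lo = max(1, min(lo_c - 3, int(0.7 * lo_c)))
    hi = max(hi_c + 3, int(1.15 * hi_c))
    band = int(max(600, 3 * unit_len * dwell_est))
    pattern_raw = mref_raw[:unit_len]
    use_end = end_raw is not None and end_raw.size >= n_ref * unit_len

    def build_ref(n):
        if use_end:
            if n >= n_ref:
                raw = np.concatenate([np.tile(pattern_raw, n - n_ref),
                                      end_raw[: n_ref * unit_len]])
            else:
                raw = end_raw[(n_ref - n) * unit_len: n_ref * unit_len]
        else:
            raw = np.tile(pattern_raw, n)[: n * unit_len - k + 1]
        return np.ascontiguousarray(znormalize(raw).z)

    def scan(ns):
        out = {}
        for n in ns:
            if n < 1:
                continue
            R = n * unit_len if use_end else n * unit_len - k + 1
            if R < 2 or S < R or S > R * elasticity:
                continue
            c = mvm_cost_banded(build_ref(n), zsig, elasticity, band)
            if np.isfinite(c):
                out[n] = c / S
        return out

    def elbow(costs: dict[int, float], fallback: int) -> int:
        # under noise, adding units keeps lowering the cost a little (each
        # unit adds reference points with dwell freedom), so the optimum is
        # the elbow: the per-unit improvement is large while real units are
        # still being added and collapses (typically 5-20x) once extra units
        # only soak up noise.  Walk up while each improvement stays positive
        # and within a factor ~3 of the previous one; stop at the kink.
        if len(costs) < 2:
            return fallback
        ns = sorted(costs)
        n_star = ns[0]
        prev_gain = None
        for a, b in zip(ns[:-1], ns[1:]):
            g = (costs[a] - costs[b]) / (b - a)
            if g <= 0:
                break
            if prev_gain is not None and g < 0.35 * prev_gain:
                break
            n_star = b
            prev_gain = g
        return n_star

    if hi - lo > 24:  # coarse pass first, then refine around the elbow
        coarse = scan(range(lo, hi + 1, 3))
        n_c = elbow(coarse, n_hint)
        costs = scan(range(max(1, n_c - 4), n_c + 5))
    else:
        costs = scan(range(lo, hi + 1))
    return elbow(costs, n_hint)


def _adjust_count(zsig: np.ndarray, boundaries: list[int], target: int,
                  zmref: np.ndarray, zuref: np.ndarray, unit_len: int, k: int,
                  constraint: MvmConstraint) -> list[int]:
    """Merge or split units until the partition has ``target`` units.

    Merges remove the adjacent pair whose fusion costs least in total
    re-scored distance (a unit wrongly split in two fuses almost for free);
    splits cut the unit where a closed two-unit alignment finds the
    cheapest internal junction.  Move *direction* is fixed by the externally
    selected count, so the extra-freedom bias of unconstrained merge/split
    search does not apply.
    """
    two_ref = zmref[: 2 * unit_len - k + 1]

    def cost(lo: int, hi: int) -> float:
        if hi - lo < 2:
            return float("inf")
        return _score_unit(zsig[lo:hi], zuref, constraint) * (hi - lo)

    bounds = list(boundaries)
    costs = [cost(lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:])]
    while len(costs) > max(1, target):
        best_i, best_delta, best_cost = -1, np.inf, np.inf
        for i in range(len(costs) - 1):
            merged = cost(bounds[i], bounds[i + 2])
            delta = merged - costs[i] - costs[i + 1]
            if delta < best_delta:
                best_i, best_delta, best_cost = i, delta, merged
        if best_i < 0:
            break
        del bounds[best_i + 1]
        costs[best_i:best_i + 2] = [best_cost]
    while len(costs) < target:
        best = None
        for i in range(len(costs)):
            lo, hi = bounds[i], bounds[i + 1]
            if hi - lo < max(two_ref.size, 4):
                continue
            try:
                aln = mvm_align(np.ascontiguousarray(two_ref),
                                np.ascontiguousarray(zsig[lo:hi]), constraint)
            except InfeasibleAlignmentError:
                continue
            mid = lo + aln.signal_index(unit_len)
            if not lo < mid < hi:
                continue
            ca, cb = cost(lo, mid), cost(mid, hi)
            delta = ca + cb - costs[i]
            if best is None or delta < best[0]:
                best = (delta, i, mid, ca, cb)
        if best is None:
            break
        _, i, mid, ca, cb = best
        bounds.insert(i + 1, mid)
        costs[i:i + 1] = [ca, cb]
    return bounds


def segment_tr(tr_signal: np.ndarray,
               multi_unit_ref: ReferenceSquiggle | np.ndarray,
               unit_ref: ReferenceSquiggle | np.ndarray,
               unit_len_points: int,
               k: int,
               config: DelineationConfig = DelineationConfig(),
               read_id: str = "",
               strand: str = "+",
               dwell_estimate: float | None = None,
               end_ref: ReferenceSquiggle | np.ndarray | None = None) -> Segmentation:
    """Segment a delineated TR signal into individual repeat units.

    ``multi_unit_ref`` is the strand-matched reference of
    ``config.n_units_multi`` concatenated motif copies; ``unit_len_points``
    the motif length in bases (= reference points between unit junctions) and
    ``k`` the pore-model k.  ``end_ref``, when given, is the read-time
    units-then-flank construct, whose junction windows terminate the
    references used for unit-count model selection.  Forward and backward passes each define three
    units per cycle and alternate until their frontiers cross; conflicting
    units in the overlap keep the segmentation with the lower re-scored
    single-unit distance (tie: forward).  Units are finally re-scored against
    the single-unit reference; runt segments from boundary jitter are merged
    into their narrower neighbour.
    """
    mref = multi_unit_ref.values if isinstance(multi_unit_ref, ReferenceSquiggle) else np.asarray(multi_unit_ref, float)
    uref = unit_ref.values if isinstance(unit_ref, ReferenceSquiggle) else np.asarray(unit_ref, float)
    eref = None
    if end_ref is not None:
        eref = end_ref.values if isinstance(end_ref, ReferenceSquiggle) else np.asarray(end_ref, float)
    x = np.asarray(tr_signal, dtype=float)
    n_ref = config.n_units_multi

    def flagged(flags: list[str]) -> Segmentation:
        return Segmentation(read_id=read_id, strand=strand, boundaries=[],
                            unit_signals=[], unit_distances=[], flags=flags)

    if x.size < max(2, unit_len_points - k + 1):
        return flagged(["too_short"])
    try:
        zsig = znormalize(x).z
        zmref = znormalize(mref).z
        zuref = znormalize(uref).z
    except DegenerateSignalError:
        return flagged(["degenerate"])
    if dwell_estimate and dwell_estimate >= 4:
        zsig = restore_clean_amplitude(zsig)

    n = zsig.size
    # cap each cycle's search slice at ~(n_ref + 2) units of samples at the
    # observed dwell, so cycles stay cheap on long expansions
    est_dwell = dwell_estimate if dwell_estimate else max(1.0, n / max(unit_len_points, zmref.size))
    constraint = config.effective_constraint(est_dwell)
    max_slice = max(zmref.size + 1, int((n_ref + 2) * unit_len_points * est_dwell))

    fwd_bounds = [0]
    bwd_bounds = [n]
    fwd_alive = bwd_alive = True
    while fwd_alive or bwd_alive:
        if fwd_bounds[-1] >= bwd_bounds[0]:
            break
        if fwd_alive:
            new = _pass_cycle(zsig, zmref, unit_len_points, k, fwd_bounds[-1],
                              n_ref, constraint, max_slice, reverse=False)
            new = [b for b in new if b > fwd_bounds[-1] and b <= n]
            if new:
                fwd_bounds.extend(new)
            else:
                fwd_alive = False
        if fwd_bounds[-1] >= bwd_bounds[0]:
            break
        if bwd_alive:
            consumed = n - bwd_bounds[0]
            new = _pass_cycle(zsig, zmref, unit_len_points, k, consumed,
                              n_ref, constraint, max_slice, reverse=True)
            new = [b for b in new if 0 <= b < bwd_bounds[0]]
            if new:
                # boundaries arrive outermost-first; keep descending order
                for b in new:
                    bwd_bounds.insert(0, b)
            else:
                bwd_alive = False
        if fwd_bounds[-1] >= bwd_bounds[0]:
            break
        if not fwd_alive and not bwd_alive:
            break

    fp, bq = fwd_bounds[-1], bwd_bounds[0]

    def rescore(bounds: list[int]) -> list[float]:
        return [
            _score_unit(zsig[lo:hi], zuref, constraint)
            for lo, hi in zip(bounds[:-1], bounds[1:])
        ]

    if fp <= bq:
        boundaries = sorted(set(fwd_bounds + bwd_bounds))
    else:
        # overlap region [bq, fp): pick the pass with the lower mean
        # re-scored distance over its conflicting units (tie: forward)
        def conflict_units(bounds: list[int]) -> list[tuple[int, int]]:
            return [
                (lo, hi)
                for lo, hi in zip(bounds[:-1], bounds[1:])
                if hi > bq and lo < fp
            ]

        fconf = conflict_units(fwd_bounds)
        bconf = conflict_units(bwd_bounds)
        fscore = np.mean([_score_unit(zsig[lo:hi], zuref, constraint) for lo, hi in fconf]) if fconf else np.inf
        bscore = np.mean([_score_unit(zsig[lo:hi], zuref, constraint) for lo, hi in bconf]) if bconf else np.inf
        if fscore <= bscore:
            boundaries = sorted(set(fwd_bounds + [b for b in bwd_bounds if b > fp]))
        else:
            boundaries = sorted(set([b for b in fwd_bounds if b < bq] + bwd_bounds))
    if boundaries[0] != 0:
        boundaries = [0] + boundaries
    if boundaries[-1] != n:
        boundaries.append(n)

    # merge runt units (boundary jitter around a true junction) into the
    # narrower neighbour; threshold fixed from the initial width distribution
    widths = np.diff(boundaries)
    if widths.size == 0:
        return flagged(["too_short"])
    min_width = max(2.0, 0.3 * float(np.median(widths)))
    while len(boundaries) > 2:
        widths = np.diff(boundaries)
        i = int(np.argmin(widths))
        if widths[i] >= min_width:
            break
        if i == 0:
            del boundaries[1]
        elif i == len(widths) - 1:
            del boundaries[-2]
        elif widths[i - 1] <= widths[i + 1]:
            del boundaries[i]
        else:
            del boundaries[i + 1]

    n_star = _select_count(zsig, mref, eref, unit_len_points, k,
                           constraint.elasticity, est_dwell,
                           n_hint=len(boundaries) - 1, n_ref=n_ref)
    if n_star != len(boundaries) - 1:
        boundaries = _adjust_count(zsig, boundaries, n_star, zmref, zuref,
                                   unit_len_points, k, constraint)

    unit_signals = [zsig[lo:hi] for lo, hi in zip(boundaries[:-1], boundaries[1:])]
    unit_distances = rescore(boundaries)
    flags = []
    if len(unit_signals) == 0:
        flags.append("too_short")
    return Segmentation(read_id=read_id, strand=strand, boundaries=boundaries,
                        unit_signals=unit_signals, unit_distances=unit_distances,
                        flags=flags)


def qc_filter(segmentations: list[Segmentation]
              ) -> tuple[list[Segmentation], list[Segmentation], QcThreshold | None]:
    """Discard reads whose mean unit distance exceeds Q75 + 1.5*IQR.

    Quantiles use linear interpolation between order statistics.  With fewer
    than 4 reads no meaningful threshold exists: all reads are kept with a
    warning and the threshold is None.
    """
    if len(segmentations) < 4:
        if segmentations:
            logger.warning("qc_filter: only %d reads, keeping all", len(segmentations))
        return list(segmentations), [], None
    means = np.array([s.mean_distance for s in segmentations])
    q75 = float(np.percentile(means, 75))
    q25 = float(np.percentile(means, 25))
    thr = QcThreshold(q75=q75, iqr=q75 - q25)
    kept = [s for s, m in zip(segmentations, means) if m <= thr.cutoff]
    discarded = [s for s, m in zip(segmentations, means) if m > thr.cutoff]
    return kept, discarded, thr
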