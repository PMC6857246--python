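"""Dynamic time warping machinery.

Two alignment flavours are needed:

* **MVM alignment** (Minimum Variance Matching) for matching a short
  reference squiggle (one point per k-mer) to raw signal (many samples per
  k-mer): every reference point consumes a dwell of 1..``elasticity``
  consecutive signal samples (default 25), dwells tile the aligned span with
  no gaps, and every consumed sample contributes |ref - sample| to the cost.
  The all-samples-pay property matters on tandem repeats: a variant that
  skips samples for free could stretch over a whole (periodic) repeat unit
  at almost no cost and bias unit counts downward.  Open begin/end variants
  give subsequence search inside a window.

* **Symmetric DTW** (classic "symmetric2" step pattern: diagonal weight 2)
  between two squiggle segments, used for the unit-to-unit distance matrices
  that feed hierarchical clustering.

All dynamic programs run in double precision with absolute-difference local
cost; ties break toward the lowest reference / earliest signal index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


class InfeasibleAlignmentError(ValueError):
    """No monotone path satisfies the elasticity/end constraints."""


@dataclass(frozen=True)
class MvmConstraint:
    """Elasticity E: max dwell (signal samples) one reference point may
    consume."""

    elasticity: int = 25

    def __post_init__(self) -> None:
        if self.elasticity < 1:
            raise ValueError("elasticity must be >= 1")


@dataclass
class Alignment:
    """Result of an MVM alignment.

    ``pairs[i] = (i, s_i)`` maps each reference index to the first signal
    sample of its dwell; ``distance`` is the |ref - sig| cost summed over all
    consumed samples and ``normalized_distance`` that sum divided by the
    number of consumed samples (a per-sample cost in z-units, comparable
    across alignments of different spans).
    """

    pairs: list[tuple[int, int]]
    distance: float
    normalized_distance: float
    begin: int
    end: int

    def signal_index(self, ref_index: int) -> int:
        return self.pairs[ref_index][1]


@njit(cache=True)
def _mvm_fill(ref, sig, elasticity, open_begin, shift):
    # dp[i, j]: least total (per-sample ``shift``-adjusted) cost with
    # reference point i's dwell ending at sample j:
    #   dp[i, j] = prefix_i[j] + min_{m in [j-E, j-1]} (dp[i-1, m] - prefix_i[m])
    # where prefix_i is the running sum of |ref_i - sig|.  Row 0 with an open
    # begin uses a virtual zero previous row (the first dwell may start
    # anywhere); ``beg`` propagates each cell's span start.  Sliding minima
    # use a monotone deque; strictly-greater pops keep the earliest index on
    # ties, so the earliest feasible signal index always wins.  ptr stores
    # the end sample of the previous dwell (-1 = span starts at sample 0).
    R = ref.shape[0]
    S = sig.shape[0]
    dp = np.empty((R, S))
    ptr = np.empty((R, S), np.int32)
    beg = np.empty(S, np.int32)
    beg_prev = np.empty(S, np.int32)
    prefix = np.empty(S)
    deque = np.empty(S + 1, np.int32)
    val = np.empty(S + 1)
    for i in range(R):
        acc = 0.0
        for j in range(S):
            acc += abs(ref[i] - sig[j]) - shift
            prefix[j] = acc
        if i == 0 and not open_begin:
            for j in range(S):
                dp[0, j] = prefix[j] if j < elasticity else np.inf
                ptr[0, j] = -1
                beg_prev[j] = 0
            continue
        head = 0
        tail = 0
        for j in range(S):
            m = j - 1
            if i == 0:
                v = -(prefix[m]) if m >= 0 else 0.0
                ok = True
            else:
                ok = m >= 0 and np.isfinite(dp[i - 1, m])
                v = dp[i - 1, m] - prefix[m] if ok else 0.0
            if ok:
                while tail > head and val[tail - 1] > v:
                    tail -= 1
                deque[tail] = m
                val[tail] = v
                tail += 1
            while tail > head and deque[head] < j - elasticity:
                head += 1
            if tail == head:
                dp[i, j] = np.inf
                ptr[i, j] = -2
                beg[j] = 0
            else:
                b = deque[head]
                dp[i, j] = prefix[j] + val[head]
                ptr[i, j] = b
                beg[j] = b + 1 if i == 0 else beg_prev[b]
        beg_prev, beg = beg, beg_prev
    return dp, ptr, beg_prev


@njit(cache=True)
def _mvm_fill_skip(ref, sig, elasticity, open_begin):
    # Skip-elastic MVM: each reference point matches exactly ONE signal
    # sample; consecutive matches advance by 1..E samples (skipped samples
    # cost nothing).  dp[i, j] = cost with point i matched to sample j.
    # Sliding minima over dp[i-1, j-E .. j-1] via monotone deque;
    # strictly-greater pops keep the earliest index on ties.
    R = ref.shape[0]
    S = sig.shape[0]
    dp = np.empty((R, S))
    ptr = np.empty((R, S), np.int32)
    deque = np.empty(S + 1, np.int32)
    val = np.empty(S + 1)
    for j in range(S):
        if open_begin or j == 0:
            dp[0, j] = abs(ref[0] - sig[j])
        else:
            dp[0, j] = np.inf
        ptr[0, j] = -1
    for i in range(1, R):
        head = 0
        tail = 0
        for j in range(S):
            m = j - 1
            if m >= 0 and np.isfinite(dp[i - 1, m]):
                v = dp[i - 1, m]
                while tail > head and val[tail - 1] > v:
                    tail -= 1
                deque[tail] = m
                val[tail] = v
                tail += 1
            while tail > head and deque[head] < j - elasticity:
                head += 1
            if tail == head:
                dp[i, j] = np.inf
                ptr[i, j] = -2
            else:
                dp[i, j] = val[head] + abs(ref[i] - sig[j])
                ptr[i, j] = deque[head]
    return dp, ptr


def mvm_align_skip(ref, sig, constraint: MvmConstraint = MvmConstraint(),
                   open_begin: bool = False, open_end: bool = False) -> Alignment:
    """Skip-elastic MVM alignment (the classic Minimum Variance Matching).

    Each reference point matches exactly one signal sample; matched sample
    indices are strictly increasing and advance by at most E; skipped
    samples are free.  ``distance`` sums |ref - sig| over the R matched
    samples and ``normalized_distance`` divides by R.  This is the right
    tool for *locating* a non-repetitive reference (a flank) inside raw
    signal: each point elects its best sample within its dwell, so true
    full-length matches win naturally.  It is deliberately not used for
    unit segmentation, where free skipping on a periodic signal would let
    whole repeat units vanish at almost no cost — that path uses
    :func:`mvm_align`.
    """
    ref = np.ascontiguousarray(ref, dtype=float)
    sig = np.ascontiguousarray(sig, dtype=float)
    R, S = ref.size, sig.size
    if R < 1:
        raise InfeasibleAlignmentError("empty reference")
    if S < R:
        raise InfeasibleAlignmentError(f"signal ({S}) shorter than reference ({R})")
    dp, ptr = _mvm_fill_skip(ref, sig, constraint.elasticity, open_begin)
    last = dp[R - 1]
    jend = int(np.argmin(last)) if open_end else S - 1
    total = last[jend]
    if not np.isfinite(total):
        raise InfeasibleAlignmentError(
            f"no feasible skip-MVM path (R={R}, S={S}, E={constraint.elasticity}, "
            f"open_begin={open_begin}, open_end={open_end})"
        )
    path = np.empty(R, dtype=int)
    path[R - 1] = jend
    for i in range(R - 1, 0, -1):
        path[i - 1] = ptr[i, path[i]]
    pairs = [(i, int(path[i])) for i in range(R)]
    return Alignment(
        pairs=pairs,
        distance=float(total),
        normalized_distance=float(total) / R,
        begin=int(path[0]),
        end=int(jend),
    )


def mvm_align(ref, sig, constraint: MvmConstraint = MvmConstraint(),
              open_begin: bool = False, open_end: bool = False,
              min_span: int = 0) -> Alignment:
    """Optimal MVM alignment of a reference squiggle onto a longer signal.

    Each reference point, in order, consumes 1..E consecutive signal samples;
    dwells tile the aligned span and every consumed sample pays |ref - sig|.
    With closed ends the span is the whole signal and the total cost is
    minimized.  ``open_begin`` / ``open_end`` free the span to start/end
    anywhere; the end is then chosen to minimize the *average* cost per
    consumed sample (for a fixed span the interior dwell assignment cannot
    change the span, so the least-total path per candidate end is also the
    least-average one).  Minimizing the raw total instead would collapse an
    open span to the shortest feasible one; the average-cost objective keeps
    spans honest without any tuning parameter.  ``min_span`` additionally
    rejects open spans shorter than the given sample count: on noisy signal
    a short lucky sub-span can otherwise undercut the true full-length
    match.  Both inputs should already be z-normalized by the caller.
    Raises :class:`InfeasibleAlignmentError` when the signal is shorter than
    the reference or no dwell assignment satisfies the constraints.
    """
    ref = np.ascontiguousarray(ref, dtype=float)
    sig = np.ascontiguousarray(sig, dtype=float)
    R, S = ref.size, sig.size
    if R < 1:
        raise InfeasibleAlignmentError("empty reference")
    if S < R:
        raise InfeasibleAlignmentError(f"signal ({S}) shorter than reference ({R})")

    def solve(shift: float):
        dp, ptr, begins = _mvm_fill(ref, sig, constraint.elasticity, open_begin, shift)
        last = dp[R - 1]
        if open_end:
            spans = np.arange(S) - begins + 1
            with np.errstate(invalid="ignore"):
                objective = np.where(spans >= max(min_span, 1),
                                     last / spans if shift == 0.0 else last,
                                     np.inf)
            jend = int(np.argmin(objective))  # earliest index on ties
        else:
            jend = S - 1
        if not np.isfinite(last[jend]) or not np.isfinite(
                objective[jend] if open_end else last[jend]):
            raise InfeasibleAlignmentError(
                f"no feasible MVM path (R={R}, S={S}, E={constraint.elasticity}, "
                f"open_begin={open_begin}, open_end={open_end})"
            )
        starts = np.empty(R, dtype=int)
        j = jend
        for i in range(R - 1, -1, -1):
            m = int(ptr[i, j])
            starts[i] = m + 1
            j = m
        begin = int(starts[0])
        span = jend - begin + 1
        if min_span and span < min_span and not open_end:
            raise InfeasibleAlignmentError("span below minimum")
        raw = float(last[jend]) + shift * span
        return starts, jend, begin, span, raw

    if not open_begin:
        # span is fixed by the end alone, so the least-total path per
        # candidate end is already the least-average one
        starts, jend, begin, span, raw = solve(0.0)
    else:
        # free begin: the least-average span must be found by Dinkelbach
        # iteration — re-solve with the current average as the per-sample
        # offset until the ratio stops improving.  Start from an offset
        # above any realistic per-sample cost so the first solve favours
        # long spans and satisfies the span constraint.
        lam = 2.0
        starts = jend = begin = span = raw = None
        for _ in range(10):
            starts, jend, begin, span, raw = solve(lam)
            new_lam = raw / span
            if new_lam >= lam - 1e-12:
                break
            lam = new_lam
    pairs = [(i, int(starts[i])) for i in range(R)]
    return Alignment(
        pairs=pairs,
        distance=raw,
        normalized_distance=raw / span,
        begin=begin,
        end=int(jend),
    )


@njit(cache=True)
def mvm_cost_banded(ref, sig, elasticity, band):
    """Total cost of the closed-both-ends MVM alignment, O(S) memory.

    Same recurrence as :func:`mvm_align` restricted to a corridor of
    ``band`` samples around the straight line from (0, 0) to (R-1, S-1),
    intersected with the dwell-feasibility corridor.  Returns inf when no
    path stays inside the corridor.  Used for unit-count model selection,
    where only the optimal cost is needed, not the path.
    """
    R = ref.shape[0]
    S = sig.shape[0]
    INF = np.inf
    prev = np.full(S, INF)
    cur = np.full(S, INF)
    prefix = np.empty(S)
    deque = np.empty(S + 1, np.int32)
    val = np.empty(S + 1)
    slope = (S - 1) / max(1, R - 1)
    # row 0
    acc = 0.0
    hi0 = min(S - 1 - (R - 1), elasticity - 1, band)
    for j in range(hi0 + 1):
        acc += abs(ref[0] - sig[j])
        prev[j] = acc
    lo_prev = 0
    hi_prev = hi0
    for i in range(1, R):
        center = int(i * slope)
        lo = center - band
        if lo < i:
            lo = i
        floor_tail = S - (R - i) * elasticity
        if lo < floor_tail:
            lo = floor_tail
        hi = center + band
        cap = (i + 1) * elasticity - 1
        if hi > cap:
            hi = cap
        tailcap = S - 1 - (R - 1 - i)
        if hi > tailcap:
            hi = tailcap
        if lo > hi:
            return INF
        pstart = lo - elasticity
        if pstart < 0:
            pstart = 0
        acc = 0.0
        for j in range(pstart, hi + 1):
            acc += abs(ref[i] - sig[j])
            prefix[j] = acc
        head = 0
        tail = 0
        m0 = lo - elasticity
        if m0 < lo_prev:
            m0 = lo_prev
        m1 = lo - 1
        if m1 > hi_prev:
            m1 = hi_prev
        for m in range(max(m0, pstart), m1 + 1):
            if np.isfinite(prev[m]):
                v = prev[m] - prefix[m]
                while tail > head and val[tail - 1] > v:
                    tail -= 1
                deque[tail] = m
                val[tail] = v
                tail += 1
        for j in range(lo, hi + 1):
            if j > lo:
                m = j - 1
                if m >= pstart and lo_prev <= m <= hi_prev and np.isfinite(prev[m]):
                    v = prev[m] - prefix[m]
                    while tail > head and val[tail - 1] > v:
                        tail -= 1
                    deque[tail] = m
                    val[tail] = v
                    tail += 1
            while tail > head and deque[head] < j - elasticity:
                head += 1
            if tail == head:
                cur[j] = INF
            else:
                cur[j] = prefix[j] + val[head]
        # reset previous row range and swap
        for j in range(lo_prev, hi_prev + 1):
            prev[j] = INF
        prev, cur = cur, prev
        lo_prev = lo
        hi_prev = hi
    return prev[S - 1]


def subsequence_search(ref, windows, constraint: MvmConstraint = MvmConstraint()):
    """Best open-ended skip-MVM match of ``ref`` across normalized windows.

    Returns ``(window, alignment)`` minimizing ``normalized_distance`` with
    ties broken toward the earliest window offset, or ``None`` when every
    window is infeasible or degenerate (a "not found" signal, not an error).
    """
    ref = np.asarray(ref, dtype=float)
    best = None
    for win in sorted(windows, key=lambda w: w.offset):
        try:
            aln = mvm_align_skip(ref, win.z, constraint, open_begin=True, open_end=True)
        except InfeasibleAlignmentError:
            continue
        if best is None or aln.normalized_distance < best[1].normalized_distance:
            best = (win, aln)
    return best


@njit(cache=True)
def _dtw_sym2(a, b):
    n = a.shape[0]
    m = b.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        c = abs(a[i] - b[0])
        cur[0] = prev[0] + c
        for j in range(1, m):
            c = abs(a[i] - b[j])
            diag = prev[j - 1] + 2.0 * c
            up = prev[j] + c
            left = cur[j - 1] + c
            best = diag
            if up < best:
                best = up
            if left < best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    return prev[m - 1]


def symmetric_dtw_distance(a, b) -> float:
    """Classic both-ends-fixed DTW cost with the symmetric2 step pattern.

    Local cost |a_i - b_j|, diagonal steps weighted 2; symmetric in its
    arguments and zero on identical series.  Costs are not length-normalized
    (medoids are extracted on raw costs).
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("series must be non-empty")
    return float(_dtw_sym2(a, b))


def distance_matrix(segments) -> np.ndarray:
    """Symmetric matrix of pairwise symmetric-DTW costs, zero diagonal."""
    segs = [np.ascontiguousarray(s, dtype=float) for s in segments]
    n = len(segs)
    if n < 2:
        raise ValueError("need at least 2 segments")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _dtw_sym2(segs[i], segs[j])
            dm[i, j] = d
            dm[j, i] = d
    return dm


def alignment_to_tsv(aln: Alignment, ref, sig, path) -> None:
    """Export an alignment as TSV (ref_index, sig_index, cost)."""
    ref = np.asarray(ref, dtype=float)
    sig = np.asarray(sig, dtype=float)
    with open(path, "w") as fh:
        fh.write("ref_index\tsig_index\tcost\n")
        for i, j in aln.pairs:
            fh.write(f"{i}\t{j}\t{abs(ref[i] - sig[j])!r}\n")
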