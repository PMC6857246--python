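"""Clustering of segmented repeat-unit squiggles and motif assignment.

Per DNA strand, all segmented TR-unit squiggles are compared pairwise with
symmetric DTW, agglomerated with Ward's method, and cut at the first two
branches of the dendrogram (two clusters: analysis is deliberately limited to
biclustering on the strongest squiggle difference; finer sub-clustering is
possible but needs supervised validation).  Each cluster is represented by
its medoid (partition-around-medoids centroid: the member minimizing summed
within-cluster distance), and medoids are mapped to candidate motif
sequences by nearest strand-matched reference squiggle.

Ward linkage is applied to the DTW dissimilarities directly via the standard
Lance-Williams squared-distance update (the "Ward.D2" convention) — a pinned
choice, since DTW distances are not Euclidean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .dtw import MvmConstraint, distance_matrix, mvm_align, symmetric_dtw_distance
from .pore_model import PoreModel, normalize_sequence, reverse_complement, sequence_to_squiggle
from .signal_io import znormalize

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    """Two-way partition of unit squiggles on one strand.

    ``labels`` are 0/1 per unit; ``medoids`` maps cluster id to the index of
    its medoid unit; ``units`` keeps the (z-normalized) input series.
    """

    strand: str
    labels: np.ndarray
    distances: np.ndarray
    medoids: dict[int, int]
    linkage_matrix: np.ndarray | None = None
    units: list[np.ndarray] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()))

    def medoid_signal(self, cluster: int) -> np.ndarray:
        return self.units[self.medoids[cluster]]


@dataclass
class MotifAssignment:
    """Nearest-reference motif per cluster, with the medoid's DTW distance."""

    motifs: dict[int, str]
    distances: dict[int, float]


def _pam_medoid(dm: np.ndarray, members: np.ndarray) -> int:
    """Index (into the full set) of the member minimizing summed
    within-cluster distance; earliest index on ties."""
    sub = dm[np.ix_(members, members)]
    return int(members[int(np.argmin(sub.sum(axis=1)))])


def _refine_labels(labels: np.ndarray, dm: np.ndarray,
                   n_clusters: int) -> np.ndarray:
    """Polish a 2-way cut along the principal embedding of the distances.

    One unit's pairwise DTW distances are individually noisy, and Ward's
    greedy merges can strand a borderline unit on the wrong side.  The
    classical-MDS embedding of the distance matrix averages over all pairs,
    so reassigning each unit to the nearer cluster mean along the
    between-cluster direction in that embedding is a far less noisy
    decision.  Deterministic; returns the input unchanged unless both
    clusters are non-empty and a fixed point is reached within a few sweeps.
    """
    if n_clusters != 2 or len(set(labels.tolist())) != 2:
        return labels
    n = dm.shape[0]
    d2 = dm ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    k = min(5, n - 1)
    x = v[:, -k:] * np.sqrt(np.maximum(w[-k:], 0.0))
    lab = labels.copy()
    for _ in range(20):
        mu0 = x[lab == 0].mean(axis=0)
        mu1 = x[lab == 1].mean(axis=0)
        direction = mu1 - mu0
        norm = np.linalg.norm(direction)
        if norm == 0:
            break
        proj = x @ (direction / norm)
        thr = 0.5 * (proj[lab == 0].mean() + proj[lab == 1].mean())
        new = (proj > thr).astype(int)
        if new.min() == new.max():  # refusal to empty a cluster
            break
        if np.array_equal(new, lab):
            break
        lab = new
    return lab


def rescale_units_to_reference(units, pattern, elasticity: int = 25,
                               dwell_cap_factor: float = 10.0):
    """Re-anchor one read's unit squiggles to the consensus reference scale.

    A read's TR slice is z-scaled by its own dwell-weighted statistics, so
    units pooled across reads carry small per-read gain/offset differences
    that can dominate clustering when other variation is small.  Each unit
    is registered to the consensus unit window ``pattern`` (dwell-tiling
    MVM) and a single least-squares gain/offset is fitted per read over all
    registered samples; units are returned on the reference scale.  Units
    are returned unchanged when too little registers.
    """
    from .dtw import InfeasibleAlignmentError as _Infeasible

    zpat = np.asarray(pattern, float)
    xs: list[float] = []
    ys: list[float] = []
    for u in units:
        u = np.ascontiguousarray(u, dtype=float)
        cap = max(elasticity, int(dwell_cap_factor * u.size / max(1, zpat.size)))
        try:
            aln = mvm_align(zpat, u, MvmConstraint(cap))
        except (_Infeasible, ValueError):
            continue
        for i in range(zpat.size):
            lo = aln.signal_index(i)
            hi = aln.signal_index(i + 1) if i + 1 < zpat.size else aln.end + 1
            xs.extend([zpat[i]] * (hi - lo))
            ys.extend(u[lo:hi])
    if len(xs) < 4 * zpat.size:
        return [np.asarray(u, float) for u in units]
    gain, offset = np.polyfit(np.asarray(xs), np.asarray(ys), 1)
    if not np.isfinite(gain) or gain <= 0.2:
        return [np.asarray(u, float) for u in units]
    return [(np.asarray(u, float) - offset) / gain for u in units]


def cluster_units(units, strand: str, n_clusters: int = 2) -> ClusterModel:
    """Ward-cluster unit squiggles into ``n_clusters`` (default 2) groups.

    Units are used as given and must be on a common scale: the pipeline
    passes slices of each read's z-scaled TR signal, so units pooled across
    reads stay comparable.  (Re-normalizing every ~250-sample unit by its
    own dwell-weighted mean and sd would inject spurious between-unit
    variation.)  The dendrogram is cut at ``n_clusters`` and, for the
    default two-way cut, polished along the principal embedding of the
    distance matrix (see :func:`_refine_labels`).  With fewer than 2 units
    a degenerate single-cluster model is returned, flagged ``degenerate``.
    When the top merge height is ~0 (all units identical) the model is
    flagged ``no_structure`` but still cut.  Values of ``n_clusters`` other
    than 2 are supported but experimental (sub-clustering needs supervised
    validation).
    """
    zunits = [np.asarray(u, float) for u in units]
    if len(zunits) < 2:
        labels = np.zeros(len(zunits), dtype=int)
        medoids = {0: 0} if zunits else {}
        return ClusterModel(strand=strand, labels=labels,
                            distances=np.zeros((len(zunits), len(zunits))),
                            medoids=medoids, units=zunits, flags=["degenerate"])
    dm = distance_matrix(zunits)
    condensed = squareform(dm, checks=False)
    Z = linkage(condensed, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
    flags = []
    if Z[-1, 2] <= 1e-9:
        flags.append("no_structure")
    else:
        labels = _refine_labels(np.asarray(labels), dm, n_clusters)
    medoids = {}
    for c in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == c)
        medoids[c] = _pam_medoid(dm, members)
    return ClusterModel(strand=strand, labels=np.asarray(labels), distances=dm,
                        medoids=medoids, linkage_matrix=Z, units=zunits, flags=flags)


def assign_motifs(model: ClusterModel, candidate_motifs, pore_model: PoreModel
                  ) -> MotifAssignment:
    """Map each cluster medoid to the nearest candidate motif.

    Candidates are squiggled strand-matched (reverse complemented first for
    the - strand), z-normalized, and compared to the medoid by symmetric DTW.
    Ties prefer the consensus (first listed) motif, then list order.
    """
    if not candidate_motifs:
        raise ValueError("need at least one candidate motif")
    candidates = [normalize_sequence(m) for m in candidate_motifs]
    # all references share the consensus (first candidate) multi-unit scale,
    # matching the frame the pipeline's unit squiggles are anchored to; each
    # candidate is squiggled in its own periodic context
    anchor_seq = candidates[0] * 5
    if model.strand == "-":
        anchor_seq = reverse_complement(anchor_seq)
    anchor = sequence_to_squiggle(anchor_seq, pore_model).values
    mu, sd = float(anchor.mean()), float(anchor.std())
    if sd == 0:
        sd = 1.0
    refs = []
    for motif in candidates:
        seq = motif * 2
        if model.strand == "-":
            seq = reverse_complement(seq)
        sq = sequence_to_squiggle(seq, pore_model, label="full_alt_motif",
                                  strand=model.strand)
        refs.append((sq.values[: len(motif)] - mu) / sd)
    motifs: dict[int, str] = {}
    dists: dict[int, float] = {}
    for c, medoid_idx in model.medoids.items():
        medoid = model.units[medoid_idx]
        best_d, best_m = np.inf, candidates[0]
        for motif, ref in zip(candidates, refs):
            d = symmetric_dtw_distance(medoid, ref)
            if d < best_d:  # strict: earlier (consensus-first) wins ties
                best_d, best_m = d, motif
        motifs[c] = best_m
        dists[c] = float(best_d)
    return MotifAssignment(motifs=motifs, distances=dists)


ABCA7_CONSENSUS = "GTGAGCCCCCCACCACTCCCTCCCC"


def known_variant_motifs(consensus: str = ABCA7_CONSENSUS) -> list[str]:
    """Consensus plus the known alternative ABCA7 VNTR unit motifs.

    Variants (1-based positions on the positive-strand consensus): a guanine
    insertion at position 10; a C->A substitution at position 10; and a G->A
    substitution at position 5, which on the negative strand reads as the
    C->T change at position 21 of the reverse-complement motif.
    """
    c = normalize_sequence(consensus)
    variants = [c]
    variants.append(c[:9] + "G" + c[9:])          # G insertion at 10
    variants.append(c[:9] + "A" + c[10:])          # C10 -> A
    variants.append(c[:4] + "A" + c[5:])           # G5 -> A (minus-strand C21->T)
    return variants


def dendrogram_text(model: ClusterModel) -> str:
    """Newick-like text rendering of the merge tree with branch heights."""
    if model.linkage_matrix is None:
        return ";"
    tree = to_tree(model.linkage_matrix)

    def render(node) -> str:
        if node.is_leaf():
            return f"u{node.id}:{node.dist:.4g}"
        return f"({render(node.left)},{render(node.right)}):{node.dist:.4g}"

    return render(tree) + ";"


def distance_matrix_tsv(model: ClusterModel, path) -> None:
    """Export the strand's DTW distance matrix as a square TSV."""
    n = model.distances.shape[0]
    ids = [f"u{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("unit\t" + "\t".join(ids) + "\n")
        for i in range(n):
            row = "\t".join(f"{model.distances[i, j]:.6g}" for j in range(n))
            fh.write(f"{ids[i]}\t{row}\n")
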