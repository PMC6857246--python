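# Methods

This note documents the signal model, the alignment machinery, the
delineation/segmentation procedure, the clustering and genotyping steps, and
the synthetic-data generator, together with the design decisions that were
genuinely open and the limitations we know about.

## Signal model and reference squiggles

A nanopore read is a time series of current samples; at any instant the
level is set mainly by the k nucleotides in the pore (k = 6 by default,
matching R9.4-style chemistry), and each k-mer persists for a variable dwell
(~10 samples at 4 kHz / 450 b s⁻¹).  A pore model maps every k-mer to an
expected level, so any sequence can be rendered as an expected-current
series with one value per k-mer window ("reference squiggle").  For a locus
we render, per strand: both 250-bp flanks, one consensus unit, five
concatenated units, and flank+units / units+flank junction constructs —
concatenations are squiggled as one sequence so k-mer context crosses every
junction.  Minus-strand references are squiggles of the reverse-complemented
concatenation.

The default model (`synthetic_pore_model`) is synthetic: i.i.d. N(90, 12) pA
levels per 6-mer under a fixed seed.  It reproduces the scale and spread of
a real table but none of its sequence-dependent structure; this is
sufficient because every downstream comparison is made in z-scale-normalized
signal space.  Real tab-separated tables (`kmer`, `level_mean`) load through
`load_pore_model`.

## Normalization

All comparisons are z-scale based: subtract the mean, divide by the
population (÷n) standard deviation.  Two refinements matter in practice:

* **Amplitude restoration.**  z-normalizing a noisy window divides by the
  total sd, shrinking the clean squiggle by 1/√(1+σ²) relative to a
  noise-free reference, which biases alignment toward spuriously compressed
  matches.  Within one dwell the level is constant, so the median absolute
  first difference is a robust noise estimate; the signal is rescaled so its
  noise-free part has unit variance.  The estimator needs several samples
  per dwell, so it is gated on an expected dwell ≥ 4 samples.
* **Per-read unit rescaling (clustering only).**  A read's TR slice is
  z-scaled by its own dwell-weighted statistics, so units pooled across
  reads carry small per-read gain/offset differences.  Before clustering,
  each read's units are registered to the consensus unit pattern and a
  single least-squares gain/offset per read puts them on the reference
  scale.  Re-normalizing each ~250-sample unit individually would be worse:
  its dwell-weighted mean/sd vary from unit to unit and inject spurious
  between-unit variation.

## MVM alignment: two step semantics

The elastic matcher aligns a short reference (one point per k-mer) to raw
signal (many samples per k-mer) with an elasticity E = 25 samples per
reference point.  Two formulations are deliberately kept side by side:

* **Skip-elastic** (`mvm_align_skip`): each reference point matches exactly
  one sample; matched indices advance by 1..E; skipped samples are free;
  distance is normalized per reference point.  Each point elects the best
  sample within its dwell, which makes the search robust to dwell variation
  — ideal for *locating* a non-repetitive flank.  It must not be used to
  segment the repeat: on a periodic signal, free skipping lets a whole unit
  vanish at almost no cost and biases counts down.
* **Dwell-tiling, all-samples-pay** (`mvm_align`): each reference point
  consumes 1..E *consecutive* samples, dwells tile the aligned span with no
  gaps, and every consumed sample pays |ref − sample|.  Nothing is free, so
  stretching or compressing over the periodic repeat always costs — this is
  the semantics used for junction mapping, unit segmentation, per-unit
  re-scoring and unit-count selection.

With all-samples-pay cost, an open-ended alignment cannot simply minimize
total cost (the optimum collapses to the shortest feasible span).  With a
closed begin, the span is fixed by the end alone, so selecting the end by
minimum *average* cost per consumed sample is exact.  With a free begin the
minimum-average path is found by Dinkelbach iteration (re-solve with the
current average as a per-sample offset until the ratio stops improving),
plus a minimum-span constraint so a short lucky sub-span cannot undercut the
true full-length match on noisy signal.

Under all-samples-pay the elasticity no longer guards against stretching;
its only role is capping how many samples one point may absorb.  A cap tight
relative to the dwell distribution's tail forces long dwells to spill into
neighbouring points and distorts junctions, so boundary-precision steps use
an effective cap of `dwell_cap_factor` (default 10) × the observed dwell,
while E = 25 remains the constraint for the skip-elastic search.

Both dynamic programs run in double precision with absolute-difference local
cost, O(R·S) time via monotone-deque sliding minima, and break ties toward
the earliest signal index.

## Spanning-read detection

Reads are cut into overlapping windows of 1.5 × the expected flank span
(reference length × `samples_per_kmer`, default 10), stepped by a third of
the window — a half-window step could not guarantee that some window
contains a whole flank.  Each window is z-normalized and
amplitude-restored.  For each strand, both strand-matched flank references
are searched with the skip-elastic aligner; each of the top three candidate
hits is then validated by anchoring the flank+units junction construct at
the hit's outer edge and measuring the all-samples-pay cost over the *flank*
portion of the reference only (a pseudo-hit threading through the repeat
puts that portion on repeat signal and is exposed).  The final call takes
the best time-consistent *pair* of hits per strand — individual candidates
can tie at the noise floor, but a pseudo-hit rarely pairs consistently as
cheaply as the true pair — and the strand with the lower summed junction
cost wins.  Gates (`max_flank_distance` = 0.6 per point on the skip search;
`max_flank_portion_cost` = 0.55 per sample on the validation) were
calibrated on the simulator.  A read failing both strands is reported
not-spanning.

## Boundary fine-mapping

The TR start is the sample matched to the first reference point past the
flank in a flank+units construct anchored with a *closed* begin at the outer
flank edge found by the search (the flank is non-repetitive, so that edge is
reliable; an open-ended alignment would let the periodic unit portion slip
by whole units).  The TR end uses the mirrored units+flank construct on the
reversed slice.  Infeasible geometry keeps the coarse boundaries and flags
the call `coarse_only`.

## Unit segmentation

Boundaries come from the bidirectional procedure: a five-unit reference is
aligned with the start fixed at the current frontier and the end open toward
the TR center; the first three unit junctions are recorded; the process
re-anchors at the third junction and repeats, from both TR ends, until the
passes cross.  In the overlap, conflicting units keep the segmentation with
the lower re-scored single-unit distance (ties go to the forward pass).
The mirrored reference is extended by the k−1 junction-context windows
(recovered from the squiggle's periodicity): the plain multi-unit squiggle
ends k−1 windows short, and that missing context lets a reverse alignment
slip one unit on a periodic signal.

The unit *count* is then settled by model selection: for candidate counts n,
an n-unit periodic reference (terminated with the true units-to-flank
junction windows — without that context an extra unit wins spurious credit
for absorbing the edge mismatch) is aligned to the whole TR with both ends
closed, in a banded O(S) -memory dynamic program.  Adding units never stops
lowering the cost (each adds points with dwell freedom), so the optimum is
the elbow: the per-unit improvement is large while real units are being
added and collapses 5–20× beyond the true count; the scan walks up while
each improvement stays positive and within a factor ~3 of the previous one.
Boundaries are merged (cheapest fusion first) or split (at the junction of a
closed two-unit alignment) until the partition has the selected count —
the move *direction* is fixed externally, so the extra-freedom bias of
unconstrained merge/split search does not apply.  Finally every unit is
re-scored against the single-unit reference, and reads whose mean unit
distance exceeds Q75 + 1.5·IQR across the sample (linear-interpolation
quantiles) are discarded; with fewer than four reads all are kept with a
warning.

## Unit clustering and motif assignment

Per strand, unit squiggles (read-rescaled as above; the read-time last
unit's k−1 flank-context windows trimmed so edge units do not form their own
cluster) are compared pairwise by symmetric DTW (classic symmetric2 step
pattern, diagonal weight 2, raw costs).  Ward linkage (the Lance–Williams
squared-distance update applied to the DTW dissimilarities) is cut at two
clusters, and the cut is polished along the principal classical-MDS
embedding of the distance matrix: one unit's pairwise distances are
individually noisy and Ward's greedy merges can strand a borderline unit,
while the embedding averages over all pairs.  Each cluster's centroid is its
PAM medoid (the member minimizing summed within-cluster distance,
exhaustively).  Medoids are mapped to candidate motifs by symmetric DTW
against candidate references squiggled in their own periodic context and
expressed on the consensus multi-unit scale (the same frame as the units);
ties prefer the consensus, then list order.  Analysis is deliberately
limited to biclustering per strand; finer sub-clustering is exposed behind
an experimental flag because it needs supervised validation.

For the ABCA7 VNTR the known alternative units are provided:
a guanine insertion at position 10, a C→A substitution at position 10, and
a G→A substitution at position 5 — the latter reads, on the minus strand,
as a C→T change at position 21 of the reverse-complement motif.

## Chains, consensus, diploid calls, metrics

Each QC-passing read becomes a chain of unit labels, reversed into genomic
orientation for minus-strand reads.  Chains are summarized by a small
progressive aligner over the label alphabet (match +1, mismatch −1, gap −1;
guide order by descending length) with a per-column majority consensus
(ties → gap).  Unit counts are split into two alleles by one-dimensional
k-means with two centers, initialized at the extreme values and run to
convergence (ties in assignment go to the lower center; alleles are
canonicalized so allele 1 has the smaller median); each allele is reported
as median / Q25 / Q75 with per-strand read counts.  Against a validated
length L (same units), accuracy is (1 − |L − mean|/L) × 100 % and precision
is the population RSD sd/mean × 100 %; method-level values are medians over
alleles with at least two reads.  Allele calls are in repeat units;
multiplying by the motif length converts to bases.  The relative output of
base-call-domain TR callers converts to absolute units by adding the
reference copy number (23.2 for ABCA7).

## Candidate locus selection

A UCSC "Simple Repeats" (TRF) track is filtered to loci with match
percentage strictly above 90, period 20–40 inclusive, and strictly more than
15 copies; rows sharing an interval can optionally be deduplicated keeping
the maximal copy number.  GC content is computed for stratification —
squiggle genotyping is most valuable above ~45 % GC, where base-call-domain
methods lose guanine-rich reads.

## Synthetic data

The generator emulates: per-k-mer expected current from the pore model;
per-k-mer dwell, fixed or geometric with mean `dwell_mean` (default 10
samples, floored at one sample); additive Gaussian noise with sd expressed
relative to the clean signal's spread; a per-read gain/baseline; both DNA
strands; and ground truth (strand, TR boundary samples at the first sample
of each unit's first k-mer window, unit chains with variant placement).
Cohorts alternate alleles and strands deterministically given one seed.

Not modeled: low-frequency drift, stray-current spikes, pore stalls,
modification-induced level shifts, basecall-error processes, or realistic
(sequence-dependent) dwell structure.  Passing tests therefore demonstrate
correctness of the signal-processing chain under idealized pore physics, not
performance on real flow-cell data; in particular the geometric dwell's
heavy tail (7 % of dwells exceed the nominal elasticity of 25) is already a
harsher regime than fixed dwell.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| k | 6 | nt | pore-model k-mer length |
| elasticity E | 25 | samples | MVM step constraint (paper-style) |
| dwell_cap_factor | 10 | × dwell | effective dwell cap for all-pay steps |
| samples_per_kmer | 10 | samples | expected dwell; window/margin sizing only |
| window_factor | 1.5 | × flank span | detection window length (step = 1/3 window) |
| n_units_multi | 5 | units | segmentation / junction reference size |
| max_flank_distance | 0.6 | z/point | skip-search gate (simulator-calibrated) |
| max_flank_portion_cost | 0.55 | z/sample | junction-validation gate (simulator-calibrated) |
| flank length | 250 | bp | flank reference size (configurable) |

## Numerical choices

Population-sd z-normalization; absolute-difference local cost; double
precision everywhere; earliest-index tie-breaks in every DP; linear
interpolation ("type 7") quantiles; runt segments below 0.3 × the median
unit width are merged into the narrower neighbour before count adjustment;
degenerate inputs (constant windows, TRs shorter than one unit) are skipped
or flagged rather than raised through the pipeline.

## Test problem sizes

The test suite exercises unit counts 3–200 (identity limit at dwell 1),
unit-count recovery at counts {5, 12, 40, 120} × noise {0, 0.2, 0.5} with
20 reads per condition, clustering at 50 units per motif, and diploid
cohorts of 8–14 reads — sizes chosen so the full suite runs on a single CPU
in minutes while still covering expansion-scale alleles (120 units ≈ 3 kb).

## Known limitations

* Unit-count model selection assumes the consensus motif dominates; alleles
  where a *different* unit is the majority would need the candidate motif
  supplied as the locus consensus.
* Biclustering resolves only the strongest squiggle difference per strand;
  units whose discriminating windows happen to receive very short dwells
  carry little signal, and on internally repetitive (C-run) motifs DTW can
  absorb part of a substitution's signature, so unit-label accuracy is
  ~98–100 % rather than guaranteed-perfect under heavy dwell variation.
* The spanning gate is calibrated on the simulator; real data with very
  different noise spectra may need `max_flank_distance` /
  `max_flank_portion_cost` retuned.
* Nucleotide modifications shift current levels and are not modeled; they
  would appear as extra unit sub-clusters.
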