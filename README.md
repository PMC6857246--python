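# squiggletr

Tandem-repeat length and unit-composition genotyping **directly from raw
nanopore current signal**, without base calling or alignment.

## The problem

Tandem repeats (TRs) — and VNTRs in particular, such as the GC-rich 25-bp
ABCA7 VNTR whose expansions raise Alzheimer's disease risk — are hard to
genotype from long reads: base callers degrade on low-complexity, GC-rich
repeats, expanded alleles lose reads at the base-calling and alignment
stages, and erroneous base calls obscure unit-level sequence variants.  The
raw nanopore "squiggle" (the ionic current trace) still contains the full
signal, so this package works there instead:

1. **Reference squiggles.** A k-mer pore model (expected current per k-mer;
   k ≈ 6 for R9.4 pores) translates the TR consensus motif, its 250-bp
   flanks, and multi-unit concatenations — on both strands — into expected
   current series.
2. **Delineation.** Each read is split into overlapping z-scale-normalized
   windows; Minimum Variance Matching (MVM) dynamic time warping, with an
   elasticity of 25 signal samples per reference point, locates both flanks
   and the strand, and a flank+units junction reference fine-maps the exact
   TR start/end samples.
3. **Segmentation.** A reference of five concatenated units is repeatedly
   anchored at the current frontier (one end fixed, the other open toward
   the TR center), three units per cycle, from both TR ends until the passes
   cross; a global model-selection step over n-unit periodic references
   settles the unit count, and reads whose mean unit distance exceeds
   Q75 + 1.5·IQR are discarded.
4. **Unit clustering.** Per strand, all segmented unit squiggles are
   compared by symmetric DTW, Ward-clustered into two groups, represented
   by PAM medoids, and mapped to candidate motif sequences — revealing
   alternative repeat units (e.g. the ABCA7 position-10 C→A variant).
5. **Genotyping.** Reads become chains of unit labels (reversed into
   genomic orientation for minus-strand reads); unit counts are split into
   two alleles by one-dimensional k-means with two centers, each reported
   as median / Q25 / Q75; accuracy against a validated length L is
   (1 − |L − mean| / L) × 100 % and precision is the relative standard
   deviation sd/mean × 100 %.

A synthetic squiggle generator (per-k-mer expected current, variable dwell,
additive Gaussian noise, per-read gain/offset, both strands, ground-truth
boundaries and unit chains) makes every stage testable without sequencing
data.

## Worked example

Simulate a diploid sample (12- and 40-unit alleles, noise 0.3 z-units) at an
ABCA7-like locus and genotype it:

```bash
squiggletr simulate --locus locus.txt --allele-a 12 --allele-b 40 \
    --n-reads 8 --noise-sd 0.3 --seed 7 --out sim/
squiggletr call --locus locus.txt --signals sim/ --out called/
```

The call prints (abridged):

```json
{
  "alleles": [
    {"allele": 1, "median": 12.0, "n_reads": 4, "q25": 12.0, "q75": 12.0,
     "strands": {"+": 2, "-": 2}},
    {"allele": 2, "median": 40.0, "n_reads": 4, "q25": 40.0, "q75": 40.0,
     "strands": {"+": 2, "-": 2}}
  ],
  "n_qc_pass": 8,
  "n_spanning": 8
}
```

All 8 simulated reads were detected as TR-spanning, passed QC, and the two
allele medians equal the simulated truth (12 and 40 repeat units) with zero
spread; both DNA strands support each allele.  `called/reads.tsv` holds the
per-read strand, TR boundary samples, unit count and unit-label chain, and
`called/units.tsv` the per-unit boundaries and distances.

The same operations are available as a library:

```python
import squiggletr as sq

model = sq.synthetic_pore_model()          # or sq.load_pore_model("r94.tsv")
locus = sq.load_locus("locus.txt")
reads = sq.read_fast5("run_dir/")          # fast5 or plain-text signals
sample = sq.genotype_sample(reads, locus, model,
                            candidate_motifs=sq.known_variant_motifs())
a1, a2 = sample.alleles
```

`squiggletr candidates --track simpleRepeat.tsv` filters a UCSC "Simple
Repeats" (Tandem Repeats Finder) track to loci amenable to squiggle
genotyping: match percentage above 90, period 20–40 nt, more than 15 copies.

## Scope

No base calling, no genome alignment, no event detection, no neural squiggle
prediction; the pore model is a transparent k-mer table.  See
`docs/methods.md` for the model, algorithmic choices and known limitations.
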