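"""End-to-end orchestration: reads -> segmentations -> clusters -> genotype.

Thin glue over the per-stage modules, plus the tabular/JSON writers for the
tool's outputs.  Unit squiggles are pooled per strand across all reads of a
sample before clustering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import (
    ClusterModel,
    MotifAssignment,
    assign_motifs,
    cluster_units,
    rescale_units_to_reference,
)
from .delineation import (
    DelineationConfig,
    Segmentation,
    SpanningReadCall,
    detect_spanning,
    finemap_boundaries,
    qc_filter,
    segment_tr,
)
from .genotype import AlleleCall, ReadChain, diploid_call, reads_to_chains
from .pore_model import LocusDefinition, PoreModel, build_references
from .signal_io import RawRead

logger = logging.getLogger(__name__)


@dataclass
class ReadResult:
    read_id: str
    call: SpanningReadCall | None
    segmentation: Segmentation | None
    reason: str = ""


@dataclass
class SampleResult:
    """Everything the pipeline derives for one sample."""

    reads: list[ReadResult]
    kept: list[Segmentation]
    discarded: list[Segmentation]
    qc_threshold: object
    cluster_models: dict[str, ClusterModel] = field(default_factory=dict)
    motif_assignments: dict[str, MotifAssignment] = field(default_factory=dict)
    chains: list[ReadChain] = field(default_factory=list)
    alleles: tuple[AlleleCall, AlleleCall] | None = None

    @property
    def n_spanning(self) -> int:
        return sum(1 for r in self.reads if r.call is not None)


def process_read(read: RawRead,
                 refs,
                 locus: LocusDefinition,
                 model: PoreModel,
                 config: DelineationConfig = DelineationConfig()) -> ReadResult:
    """Detect, finemap and segment the TR in a single read."""
    call = detect_spanning(read, refs, config)
    if call is None:
        return ReadResult(read_id=read.read_id, call=None, segmentation=None,
                          reason="not_spanning")
    call = finemap_boundaries(read, call, refs, config)
    tr = read.samples[call.tr_start_sample:call.tr_end_sample]
    end_label = "units_plus_flank" if call.strand == "+" else "flank_plus_units"
    seg = segment_tr(
        tr,
        refs[("multi_unit", call.strand)],
        refs[("unit", call.strand)],
        unit_len_points=len(locus.motif),
        k=model.k,
        config=config,
        read_id=read.read_id,
        strand=call.strand,
        dwell_estimate=call.dwell_estimate,
        end_ref=refs[(end_label, call.strand)],
    )
    # lift boundaries to absolute read coordinates
    seg.boundaries = [call.tr_start_sample + b for b in seg.boundaries]
    return ReadResult(read_id=read.read_id, call=call, segmentation=seg)


def genotype_sample(reads: list[RawRead],
                    locus: LocusDefinition,
                    model: PoreModel,
                    config: DelineationConfig = DelineationConfig(),
                    candidate_motifs: list[str] | None = None) -> SampleResult:
    """Run the full pipeline over a sample's reads.

    Spanning reads are segmented and QC-filtered; unit squiggles are pooled
    per strand, Ward/PAM-biclustered, optionally mapped to candidate motifs;
    unit counts feed the two-center diploid call.
    """
    refs = build_references(locus, model, n_units_multi=config.n_units_multi)
    results = [process_read(r, refs, locus, model, config) for r in reads]
    segs = [r.segmentation for r in results
            if r.segmentation is not None and r.segmentation.n_units > 0]
    kept, discarded, thr = qc_filter(segs)
    sample = SampleResult(reads=results, kept=kept, discarded=discarded,
                          qc_threshold=thr)

    from .signal_io import znormalize

    for strand in ("+", "-"):
        strand_segs = [s for s in kept if s.strand == strand]
        if not strand_segs:
            continue
        # re-anchor each read's units to the consensus reference scale so
        # per-read normalization offsets do not masquerade as clusters
        pattern = znormalize(refs[("multi_unit", strand)].values).z[: len(locus.motif)]
        units = []
        unit_index = {}
        pos = 0
        for s in strand_segs:
            scaled = rescale_units_to_reference(s.unit_signals, pattern,
                                                elasticity=config.elasticity,
                                                dwell_cap_factor=config.dwell_cap_factor)
            if scaled:
                # the read-time last unit's final k-1 windows read into the
                # flank; trim them so edge units do not form their own cluster
                last = scaled[-1]
                trim = int((model.k - 1) * last.size / max(1, len(locus.motif)))
                if last.size - trim >= len(locus.motif):
                    scaled[-1] = last[: last.size - trim]
            for u in range(s.n_units):
                unit_index[(s.read_id, u)] = pos
                pos += 1
            units.extend(scaled)
        if len(units) < 2:
            continue
        cm = cluster_units(units, strand)
        sample.cluster_models[strand] = cm
        if candidate_motifs:
            ma = assign_motifs(cm, candidate_motifs, model)
            sample.motif_assignments[strand] = ma
            labels = {c: m for c, m in ma.motifs.items()}
        else:
            labels = None
        sample.chains.extend(
            reads_to_chains(strand_segs, cm, unit_index=unit_index, labels=labels)
        )

    if kept:
        sample.alleles = diploid_call(
            [s.n_units for s in kept],
            read_ids=[s.read_id for s in kept],
            strands=[s.strand for s in kept],
        )
    return sample


# ---------------------------------------------------------------------------
# writers

def write_read_table(sample: SampleResult, path) -> None:
    """Per-read TSV: read_id, strand, boundaries, unit count, QC status."""
    kept_ids = {s.read_id for s in sample.kept}
    allele_of = {}
    if sample.alleles:
        for call in sample.alleles:
            for rid in call.read_ids:
                allele_of[rid] = call.allele
    chain_of = {c.read_id: "".join(f"[{l}]" for l in c.chain) for c in sample.chains}
    with open(path, "w") as fh:
        fh.write("read_id\tstrand\ttr_start_sample\ttr_end_sample\tn_units\t"
                 "mean_distance\tqc_pass\tallele\tchain\n")
        for r in sample.reads:
            if r.call is None:
                fh.write(f"{r.read_id}\t.\t.\t.\t.\t.\t.\t.\t{r.reason}\n")
                continue
            seg = r.segmentation
            fh.write(
                f"{r.read_id}\t{r.call.strand}\t{r.call.tr_start_sample}\t"
                f"{r.call.tr_end_sample}\t{seg.n_units}\t{seg.mean_distance:.4f}\t"
                f"{r.read_id in kept_ids}\t{allele_of.get(r.read_id, '.')}\t"
                f"{chain_of.get(r.read_id, '.')}\n"
            )


def write_unit_table(sample: SampleResult, path) -> None:
    """Per-unit TSV with boundaries, strand and cluster label."""
    with open(path, "w") as fh:
        fh.write("read_id\tunit\tstrand\tstart_sample\tend_sample\tdistance\n")
        for seg in sample.kept:
            for u in range(seg.n_units):
                fh.write(f"{seg.read_id}\t{u}\t{seg.strand}\t{seg.boundaries[u]}\t"
                         f"{seg.boundaries[u + 1]}\t{seg.unit_distances[u]:.4f}\n")


def allele_json(sample: SampleResult, metadata: dict | None = None) -> str:
    """JSON per-sample summary of the diploid call."""
    payload: dict = {"alleles": [], "n_spanning": sample.n_spanning,
                     "n_qc_pass": len(sample.kept)}
    if sample.alleles:
        for call in sample.alleles:
            payload["alleles"].append({
                "allele": call.allele,
                "median": call.median,
                "q25": call.q25,
                "q75": call.q75,
                "n_reads": call.n_reads,
                "strands": call.strand_counts,
            })
    if metadata:
        payload["metadata"] = metadata
    return json.dumps(payload, indent=2, sort_keys=True)
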