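"""Unit-squiggle clustering, medoids, and motif assignment."""

import numpy as np
import pytest

import squiggletr as sq
from squiggletr.clustering import _pam_medoid, dendrogram_text
from squiggletr.signal_io import znormalize
from tests.conftest import simulate


def units_from_read(sim):
    """Unit slices of a read's z-scaled TR region (truth boundaries)."""
    ztr = znormalize(sim.read.samples[sim.tr_start_sample:sim.tr_end_sample]).z
    t0 = sim.tr_start_sample
    return [ztr[a - t0:b - t0] for a, b in
            zip(sim.unit_boundaries[:-1], sim.unit_boundaries[1:])]


class TestClusterUnits:
    def test_noiseless_two_motif_recovery(self, locus, model6, variant_motifs):
        # 12 consensus + 8 variant units, noiseless with variable dwell
        consensus, variant = variant_motifs[0], variant_motifs[1]
        chain = [consensus] * 12 + [variant] * 8
        cfg = sq.SimConfig(locus=locus, unit_chain=chain, seed=2)
        sim = sq.simulate_read(cfg, model6)
        units = units_from_read(sim)
        truth = np.array([0] * 12 + [1] * 8)
        cm = sq.cluster_units(units, "+")
        assert cm.n_clusters == 2
        agree = max((cm.labels == truth).mean(), (cm.labels != truth).mean())
        assert agree == 1.0

    def test_identical_units_flagged_no_structure(self):
        u = np.array([0.0, 1.0, -1.0, 0.5, 2.0])
        cm = sq.cluster_units([u.copy() for _ in range(6)], "+")
        assert "no_structure" in cm.flags

    def test_single_unit_degenerate(self):
        cm = sq.cluster_units([np.array([0.0, 1.0, 2.0])], "-")
        assert "degenerate" in cm.flags
        assert cm.medoids == {0: 0}

    def test_singleton_cluster_medoid_is_member(self):
        far = np.array([50.0, -50.0, 50.0, -50.0])
        near = [np.array([0.0, 0.1, 0.0, 0.1]) + i * 0.01 for i in range(5)]
        cm = sq.cluster_units(near + [far], "+")
        singletons = [(c, np.flatnonzero(cm.labels == c)) for c in cm.medoids]
        singletons = [(c, mem) for c, mem in singletons if mem.size == 1]
        assert singletons
        c, members = singletons[0]
        assert cm.medoids[c] == members[0]

    def test_label_permutation_invariance(self, locus, model6, variant_motifs):
        consensus, variant = variant_motifs[0], variant_motifs[1]
        chain = [consensus] * 6 + [variant] * 6
        cfg = sq.SimConfig(locus=locus, unit_chain=chain, noise_sd=0.2, seed=5)
        sim = sq.simulate_read(cfg, model6)
        units = units_from_read(sim)
        perm = [7, 2, 11, 0, 5, 9, 1, 8, 3, 10, 4, 6]
        cm1 = sq.cluster_units(units, "+")
        cm2 = sq.cluster_units([units[i] for i in perm], "+")
        part1 = cm1.labels[perm]
        agree = max((part1 == cm2.labels).mean(), (part1 != cm2.labels).mean())
        assert agree == 1.0

    def test_medoid_optimality_exhaustive(self, locus, model6):
        cfg = sq.SimConfig(locus=locus, unit_chain=[locus.motif] * 8,
                           noise_sd=0.3, seed=1)
        sim = sq.simulate_read(cfg, model6)
        cm = sq.cluster_units(units_from_read(sim), "+")
        for c, med in cm.medoids.items():
            members = np.flatnonzero(cm.labels == c)
            sums = cm.distances[np.ix_(members, members)].sum(axis=1)
            assert cm.distances[np.ix_([med], members)].sum() == pytest.approx(sums.min())
            assert _pam_medoid(cm.distances, members) == med


class TestAssignMotifs:
    def test_consensus_medoid_maps_to_consensus(self, locus, model6, variant_motifs):
        consensus, variant = variant_motifs[0], variant_motifs[1]
        chain = [consensus] * 10 + [variant] * 10
        cfg = sq.SimConfig(locus=locus, unit_chain=chain, seed=3)
        sim = sq.simulate_read(cfg, model6)
        cm = sq.cluster_units(units_from_read(sim), "+")
        ma = sq.assign_motifs(cm, [consensus, variant], model6)
        truth = np.array([0] * 10 + [1] * 10)
        maj_cons = int(np.bincount(cm.labels[:10]).argmax())
        maj_var = int(np.bincount(cm.labels[10:]).argmax())
        assert ma.motifs[maj_cons] == consensus
        assert ma.motifs[maj_var] == variant

    def test_single_candidate_maps_everything(self, locus, model6):
        cfg = sq.SimConfig(locus=locus, unit_chain=[locus.motif] * 6, seed=0)
        sim = sq.simulate_read(cfg, model6)
        cm = sq.cluster_units(units_from_read(sim), "+")
        ma = sq.assign_motifs(cm, [locus.motif], model6)
        assert set(ma.motifs.values()) == {locus.motif}

    def test_tie_prefers_first_listed_motif(self, locus, model6):
        # two candidates with identical squiggles under the pore model:
        # a duplicate entry forces an exact tie, broken toward the first
        cfg = sq.SimConfig(locus=locus, unit_chain=[locus.motif] * 6, seed=0)
        sim = sq.simulate_read(cfg, model6)
        cm = sq.cluster_units(units_from_read(sim), "+")
        ma = sq.assign_motifs(cm, [locus.motif, locus.motif], model6)
        assert set(ma.motifs.values()) == {locus.motif}

    def test_requires_candidates(self, locus, model6):
        cfg = sq.SimConfig(locus=locus, unit_chain=[locus.motif] * 4, seed=0)
        sim = sq.simulate_read(cfg, model6)
        cm = sq.cluster_units(units_from_read(sim), "+")
        with pytest.raises(ValueError):
            sq.assign_motifs(cm, [], model6)


class TestExports:
    def test_dendrogram_text(self, locus, model6):
        cfg = sq.SimConfig(locus=locus, unit_chain=[locus.motif] * 5,
                           noise_sd=0.2, seed=8)
        sim = sq.simulate_read(cfg, model6)
        cm = sq.cluster_units(units_from_read(sim), "+")
        text = dendrogram_text(cm)
        assert text.endswith(";")
        assert text.count("u") == 5

    def test_distance_matrix_tsv(self, locus, model6, tmp_path):
        from squiggletr.clustering import distance_matrix_tsv

        cfg = sq.SimConfig(locus=locus, unit_chain=[locus.motif] * 4, seed=8)
        sim = sq.simulate_read(cfg, model6)
        cm = sq.cluster_units(units_from_read(sim), "+")
        p = tmp_path / "dm.tsv"
        distance_matrix_tsv(cm, p)
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 5  # header + 4 rows


class TestKnownVariants:
    def test_variant_list_contents(self):
        motifs = sq.known_variant_motifs()
        assert motifs[0] == sq.ABCA7_CONSENSUS
        assert len(motifs[1]) == 26  # G insertion lengthens the motif
        assert motifs[2][9] == "A"   # C->A at position 10
        assert motifs[3][4] == "A"   # G->A at position 5 (minus-strand C21->T)
        # the minus-strand reading: position 21 of the revcomp motif goes C->T
        rc_cons = sq.reverse_complement(motifs[0])
        rc_var = sq.reverse_complement(motifs[3])
        assert rc_cons[20] == "C" and rc_var[20] == "T"
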