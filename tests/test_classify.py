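"""Marker-combinatoric classification rules and their distance criteria."""

import numpy as np
import pytest

from synaptomap.classify import (
    SynapseRecord,
    classify_climbing,
    classify_glomerular,
    classify_molecular,
)
from synaptomap.geometry import VoxelGeometry

from conftest import make_cluster, make_cluster_set


@pytest.fixture
def g(geometry):
    return geometry


def cluster_at_x(g, x_voxels, cluster_id=0, intensity=1.0, marker="chan"):
    """Single-voxel cluster ``x_voxels`` voxels (50 nm each) along x."""
    return make_cluster([(0, 0, x_voxels)], g, marker=marker,
                        cluster_id=cluster_id, intensity=intensity)


def as_set(g, clusters, marker="chan"):
    return make_cluster_set(clusters, g, marker=marker)


class TestMolecularRules:
    def test_lone_gluD2_is_pfpc_psd95_negative(self, g):
        records = classify_molecular(
            as_set(g, [cluster_at_x(g, 0)], "GluD2"),
            as_set(g, [], "PSD-95"),
            as_set(g, [], "antigen"),
        )
        (r,) = records
        assert (r.class_label, r.subclass) == ("PF-PC", "PSD95-")
        assert not r.antigen_positive and r.antigen_intensity == 0.0

    def test_psd95_near_gluD2_yields_no_nonpfpc_record(self, g):
        # 200 nm apart (4 voxels of 50 nm): within the 300 nm criterion
        records = classify_molecular(
            as_set(g, [cluster_at_x(g, 0)], "GluD2"),
            as_set(g, [cluster_at_x(g, 4)], "PSD-95"),
            as_set(g, [], "antigen"),
        )
        (r,) = records
        assert (r.class_label, r.subclass) == ("PF-PC", "PSD95+")

    def test_distant_psd95_yields_nonpfpc_record(self, g):
        records = classify_molecular(
            as_set(g, [cluster_at_x(g, 0)], "GluD2"),
            as_set(g, [cluster_at_x(g, 10)], "PSD-95"),  # 500 nm away
            as_set(g, [], "antigen"),
        )
        labels = sorted((r.class_label, r.subclass) for r in records)
        assert labels == [("PF-PC", "PSD95-"), ("nonPF-PC", None)]

    def test_antigen_at_exactly_300nm_is_positive(self, g):
        # boundary is inclusive: 6 voxels x 50 nm = 300 nm
        records = classify_molecular(
            as_set(g, [cluster_at_x(g, 0)], "GluD2"),
            as_set(g, [], "PSD-95"),
            as_set(g, [cluster_at_x(g, 6, intensity=2.5)], "antigen"),
        )
        (r,) = records
        assert r.antigen_positive
        assert r.antigen_intensity == 2.5
        assert r.antigen_distance_nm == pytest.approx(300.0)

    def test_antigen_beyond_300nm_is_negative(self, g):
        records = classify_molecular(
            as_set(g, [cluster_at_x(g, 0)], "GluD2"),
            as_set(g, [], "PSD-95"),
            as_set(g, [cluster_at_x(g, 7)], "antigen"),  # 350 nm
        )
        assert not records[0].antigen_positive

    def test_nearest_antigen_tie_broken_by_lower_id(self, g):
        anchor = make_cluster([(0, 0, 4)], g, marker="GluD2")
        ants = [
            cluster_at_x(g, 8, cluster_id=1, intensity=9.0),  # +200 nm
            cluster_at_x(g, 0, cluster_id=0, intensity=3.0),  # -200 nm
        ]
        records = classify_molecular(
            as_set(g, [anchor], "GluD2"), as_set(g, [], "PSD-95"), as_set(g, ants, "antigen")
        )
        assert records[0].antigen_cluster_id == 0
        assert records[0].antigen_intensity == 3.0

    def test_geometry_mismatch_rejected(self, g):
        other = VoxelGeometry.from_xyz((100.0, 100.0, 100.0), 4.0)
        with pytest.raises(ValueError):
            classify_molecular(
                as_set(g, [cluster_at_x(g, 0)], "GluD2"),
                make_cluster_set([make_cluster([(0, 0, 0)], other)], other, "PSD-95"),
                as_set(g, [], "antigen"),
            )


class TestClimbingRules:
    def test_vglut2_within_criterion_makes_cfpc(self, g):
        records = classify_climbing(
            as_set(g, [cluster_at_x(g, 2)], "VGluT2"),  # 100 nm
            as_set(g, [cluster_at_x(g, 0)], "PSD-95"),
            as_set(g, [], "antigen"),
        )
        assert records[0].class_label == "CF-PC"
        assert "VGluT2" in records[0].defining

    def test_distant_vglut2_makes_noncfpc(self, g):
        records = classify_climbing(
            as_set(g, [cluster_at_x(g, 10)], "VGluT2"),  # 500 nm
            as_set(g, [cluster_at_x(g, 0)], "PSD-95"),
            as_set(g, [], "antigen"),
        )
        assert records[0].class_label == "nonCF-PC"

    def test_empty_vglut2_set_gives_all_noncfpc(self, g):
        psd = [cluster_at_x(g, i * 20, cluster_id=i) for i in range(4)]
        records = classify_climbing(
            as_set(g, [], "VGluT2"), as_set(g, psd, "PSD-95"), as_set(g, [], "antigen")
        )
        assert [r.class_label for r in records] == ["nonCF-PC"] * 4

    def test_antigen_near_vglut2_counts_for_cfpc(self, g):
        # antigen 100 nm from VGluT2 but 400 nm from PSD-95
        records = classify_climbing(
            as_set(g, [cluster_at_x(g, 6)], "VGluT2"),
            as_set(g, [cluster_at_x(g, 0)], "PSD-95"),
            as_set(g, [cluster_at_x(g, 8, intensity=1.5)], "antigen"),
        )
        assert records[0].class_label == "CF-PC"
        assert records[0].antigen_positive

    def test_every_psd95_cluster_yields_exactly_one_record(self, g):
        rng = np.random.default_rng(5)
        psd = [
            make_cluster([tuple(rng.integers(0, 30, 3))], g, cluster_id=i)
            for i in range(20)
        ]
        vg = [
            make_cluster([tuple(rng.integers(0, 30, 3))], g, cluster_id=i)
            for i in range(10)
        ]
        records = classify_climbing(
            as_set(g, vg, "VGluT2"), as_set(g, psd, "PSD-95"), as_set(g, [], "antigen")
        )
        assert len(records) == len(psd)
        assert {r.defining["PSD-95"] for r in records} == {c.cluster_id for c in psd}

    def test_shrinking_criterion_never_adds_cfpc(self, g):
        rng = np.random.default_rng(11)
        psd = [make_cluster([tuple(rng.integers(0, 40, 3))], g, cluster_id=i) for i in range(25)]
        vg = [make_cluster([tuple(rng.integers(0, 40, 3))], g, cluster_id=i) for i in range(12)]
        counts = []
        for d in (600.0, 300.0, 150.0, 50.0):
            records = classify_climbing(
                as_set(g, vg, "VGluT2"), as_set(g, psd, "PSD-95"), as_set(g, [], "antigen"),
                d_syn_nm=d,
            )
            counts.append(sum(r.class_label == "CF-PC" for r in records))
        assert counts == sorted(counts, reverse=True)


class TestGlomerularRules:
    def test_synaptic_with_antigen_near_both(self, g):
        # ELKS 150 nm from PSD-95; antigen 150 nm from both
        records = classify_glomerular(
            as_set(g, [cluster_at_x(g, 6)], "ELKS"),
            as_set(g, [cluster_at_x(g, 0)], "PSD-95"),
            as_set(g, [cluster_at_x(g, 3, intensity=2.0)], "antigen"),
        )
        (r,) = records
        assert r.class_label == "GCL-synaptic"
        assert r.antigen_positive and r.antigen_intensity == 2.0

    def test_synaptic_antigen_must_be_near_both_markers(self, g):
        # antigen within 300 nm of PSD-95 but 550 nm from ELKS: negative
        records = classify_glomerular(
            as_set(g, [cluster_at_x(g, 5)], "ELKS"),
            as_set(g, [cluster_at_x(g, 0)], "PSD-95"),
            as_set(g, [cluster_at_x(g, -6)], "antigen"),
        )
        (r,) = records
        assert r.class_label == "GCL-synaptic"
        assert not r.antigen_positive

    def test_extrasynaptic_positive_needs_30nm(self, g):
        # shared voxel -> distance 0 <= 30 nm: positive
        psd = make_cluster([(0, 0, 0), (0, 0, 1)], g, cluster_id=0)
        ant_overlap = make_cluster([(0, 0, 1), (0, 0, 2)], g, cluster_id=0, intensity=4.0)
        records = classify_glomerular(
            as_set(g, [], "ELKS"), as_set(g, [psd], "PSD-95"), as_set(g, [ant_overlap], "antigen")
        )
        (r,) = records
        assert r.class_label == "GCL-extrasynaptic"
        assert r.antigen_positive

    def test_extrasynaptic_negative_at_100nm(self, g):
        records = classify_glomerular(
            as_set(g, [], "ELKS"),
            as_set(g, [cluster_at_x(g, 0)], "PSD-95"),
            as_set(g, [cluster_at_x(g, 2)], "antigen"),  # 100 nm > 30 nm
        )
        assert not records[0].antigen_positive

    def test_extrasynaptic_boundary_inclusive(self, g):
        records = classify_glomerular(
            as_set(g, [], "ELKS"),
            as_set(g, [cluster_at_x(g, 0)], "PSD-95"),
            as_set(g, [cluster_at_x(g, 1)], "antigen"),  # exactly 50 nm
            d_extra_nm=50.0,
        )
        assert records[0].antigen_positive

    def test_partition_of_psd95_clusters(self, g):
        rng = np.random.default_rng(3)
        psd = [make_cluster([tuple(rng.integers(0, 40, 3))], g, cluster_id=i) for i in range(30)]
        elks = [make_cluster([tuple(rng.integers(0, 40, 3))], g, cluster_id=i) for i in range(10)]
        records = classify_glomerular(
            as_set(g, elks, "ELKS"), as_set(g, psd, "PSD-95"), as_set(g, [], "antigen")
        )
        assert len(records) == len(psd)
        n_syn = sum(r.class_label == "GCL-synaptic" for r in records)
        n_extra = sum(r.class_label == "GCL-extrasynaptic" for r in records)
        assert n_syn + n_extra == len(psd)

    def test_invalid_criteria_rejected(self, g):
        empty = as_set(g, [], "x")
        with pytest.raises(ValueError):
            classify_glomerular(empty, empty, empty, d_syn_nm=100.0, d_extra_nm=200.0)


class TestRecordInvariants:
    def test_intensity_positive_iff_flag(self, g):
        with pytest.raises(ValueError):
            SynapseRecord(0, "PF-PC", "PSD95-", {}, (0, 0, 0), True, 1, 0.0, 10.0)
        with pytest.raises(ValueError):
            SynapseRecord(0, "PF-PC", "PSD95-", {}, (0, 0, 0), False, None, 2.0, None)

    def test_unknown_class_label_rejected(self):
        with pytest.raises(ValueError):
            SynapseRecord(0, "mystery", None, {}, (0, 0, 0), False, None, 0.0, None)
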