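"""Shared fixtures: geometry, hand-built clusters, and pooled replicate runs.

The heavy multi-seed simulation fixtures are session-scoped so the
recovery checks (classification accuracy, fold-enrichment and
fraction-positive recovery, per-field sign pattern) share one set of
simulated fields.
"""

from __future__ import annotations

import numpy as np
import pytest

from synaptomap.geometry import VoxelGeometry
from synaptomap.quant import evaluate_against_truth, intensity_ratio_per_field
from synaptomap.scenarios import (
    GLOMERULAR_CLASS_MAP,
    MOLECULAR_CLASS_MAP,
    analyze_field,
    glomerular_scenario,
    molecular_scenario,
)
from synaptomap.segment import Cluster, ClusterSet
from synaptomap.stackio import ChannelStack

N_SEEDS = 10


@pytest.fixture
def geometry():
    """Acquisition geometry: 50 x 50 x 190 nm voxels, expansion factor 4."""
    return VoxelGeometry.from_xyz((50.0, 50.0, 190.0), 4.0)


def make_stack(data, marker="chan", voxel_xyz=(50.0, 50.0, 190.0), factor=4.0, **prov):
    return ChannelStack(
        marker=marker,
        data=np.asarray(data, dtype=np.float32),
        geometry=VoxelGeometry.from_xyz(voxel_xyz, factor),
        provenance=prov,
    )


def make_cluster(indices_zyx, geometry, marker="chan", cluster_id=0, intensity=1.0):
    """Hand-built cluster from explicit voxel indices (for distance/rule tests)."""
    idx = np.atleast_2d(np.asarray(indices_zyx, dtype=int))
    centers = geometry.voxel_centers_nm(idx)
    return Cluster(
        cluster_id=cluster_id,
        marker=marker,
        voxels=idx,
        centroid_zyx_nm=tuple(float(v) for v in centers.mean(axis=0)),
        volume_um3=len(idx) * geometry.voxel_volume_nm3 / 1e9,
        integrated_intensity=float(intensity),
        touches_edge=False,
        geometry=geometry,
    )


def make_cluster_set(clusters, geometry, marker="chan"):
    return ClusterSet(marker=marker, clusters=list(clusters), geometry=geometry)


def _molecular_runs(enrichment, field, n_seeds=N_SEEDS, seed_base=0):
    records, truths, evals = [], [], []
    for i in range(n_seeds):
        cfg = molecular_scenario(
            seed=seed_base + i, enrichment=enrichment, field_size_um=field
        )
        recs, _, truth = analyze_field(cfg, "molecular_gluD2")
        records.extend(recs)
        truths.append(truth)
        evals.append(evaluate_against_truth(recs, truth, MOLECULAR_CLASS_MAP))
    return {"records": records, "truths": truths, "evals": evals}


def _glomerular_runs(dominance, n_seeds=N_SEEDS, seed_base=0):
    records, truths, evals, field_ratios, n_psd95 = [], [], [], [], []
    for i in range(n_seeds):
        cfg = glomerular_scenario(seed=seed_base + i, dominance=dominance)
        recs, cluster_sets, truth = analyze_field(cfg, "glomerular")
        records.append(recs)
        truths.append(truth)
        evals.append(evaluate_against_truth(recs, truth, GLOMERULAR_CLASS_MAP))
        field_ratios.append(
            intensity_ratio_per_field(recs, "GCL-synaptic", "GCL-extrasynaptic")
        )
        n_psd95.append(len(cluster_sets["PSD-95"]))
    return {
        "records": records,
        "truths": truths,
        "evals": evals,
        "field_ratios": field_ratios,
        "n_psd95": n_psd95,
    }


@pytest.fixture(scope="session")
def molecular_r4_runs():
    """Reference molecular scenario (4-fold enrichment), 10 replicate seeds."""
    return _molecular_runs(4.0, (40.0, 40.0, 7.41))


@pytest.fixture(scope="session")
def molecular_r2_runs():
    return _molecular_runs(2.0, (28.0, 28.0, 7.41))


@pytest.fixture(scope="session")
def molecular_r6_runs():
    return _molecular_runs(6.0, (28.0, 28.0, 7.41))


@pytest.fixture(scope="session")
def glomerular_syn_runs():
    """AMPA-receptor-like (synaptic-dominant) glomerular scenario, 10 seeds."""
    return _glomerular_runs("synaptic")


@pytest.fixture(scope="session")
def glomerular_extra_runs():
    """NMDA-receptor-like (extrasynaptic-dominant) glomerular scenario, 10 seeds."""
    return _glomerular_runs("extrasynaptic")
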