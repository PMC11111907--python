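"""3D cluster extraction per channel, and physical distances between clusters.

Two segmentation operators mirror the two tissue contexts: a plain
intensity threshold for the molecular layer, where puncta are sparse, and
a marker-controlled watershed for the densely packed granule-cell-layer
glomeruli, where suprathreshold masks of neighboring synapses can merge.
Both apply a minimum size (to exclude pixel noise) and discard clusters
touching any stack face, so only complete synapses are measured.

Connectivity is 26-neighborhood throughout.  Integrated intensity always
sums the *original* (unthresholded) intensities of member voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .geometry import VoxelGeometry
from .stackio import ChannelStack


@dataclass
class Cluster:
    """One segmented 3D punctum.

    ``voxels`` is an ``(N, 3)`` array of (z, y, x) indices forming one
    26-connected component; ``centroid_zyx_nm`` is intensity-weighted;
    ``volume_um3`` and the centroid are on the expanded scale.
    """

    cluster_id: int
    marker: str
    voxels: np.ndarray
    centroid_zyx_nm: tuple[float, float, float]
    volume_um3: float
    integrated_intensity: float
    touches_edge: bool
    geometry: VoxelGeometry

    @cached_property
    def points_nm(self) -> np.ndarray:
        """Physical voxel centers (nm, expanded, zyx)."""
        return self.geometry.voxel_centers_nm(self.voxels)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class ClusterSet:
    """Retained clusters of one channel plus the parameters that produced them."""

    marker: str
    clusters: list[Cluster]
    geometry: VoxelGeometry
    params: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    n_excluded_size: int = 0
    n_excluded_edge: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def intensities(self) -> np.ndarray:
        return np.array([c.integrated_intensity for c in self.clusters], dtype=float)


def otsu_threshold(stack: ChannelStack) -> float:
    """Automatic threshold: Otsu on the positive-intensity histogram."""
    vals = stack.data[stack.data > 0]
    if vals.size == 0:
        return 0.0
    return float(threshold_otsu(vals))


def _edge_labels(labels: np.ndarray) -> set[int]:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1], labels[:, :, 0], labels[:, :, -1]]
    out: set[int] = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def _build_clusters(
    stack: ChannelStack,
    labels: np.ndarray,
    min_size: int,
    params: dict,
) -> ClusterSet:
    geometry = stack.geometry
    data = stack.data
    n_labels = int(labels.max())
    clusters: list[Cluster] = []
    n_small = n_edge = 0
    if n_labels:
        sizes = np.bincount(labels.ravel())
        edge = _edge_labels(labels)
        voxel_vol_um3 = geometry.voxel_volume_nm3 / 1e9
        vox_size = np.asarray(geometry.voxel_size_zyx_nm)
        objects = ndimage.find_objects(labels)
        next_id = 0
        for lab in range(1, n_labels + 1):
            if sizes[lab] < min_size:
                n_small += 1
                continue
            if lab in edge:
                n_edge += 1
                continue
            sl = objects[lab - 1]
            sub = labels[sl] == lab
            idx = np.argwhere(sub)
            idx += [s.start for s in sl]
            vals = data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
            total = float(vals.sum())
            centers = (idx + 0.5) * vox_size
            if total > 0:
                centroid = (vals[:, None] * centers).sum(axis=0) / total
            else:  # degenerate: all member intensities zero
                centroid = centers.mean(axis=0)
            clusters.append(
                Cluster(
                    cluster_id=next_id,
                    marker=stack.marker,
                    voxels=idx,
                    centroid_zyx_nm=tuple(float(v) for v in centroid),
                    volume_um3=float(sizes[lab] * voxel_vol_um3),
                    integrated_intensity=total,
                    touches_edge=False,
                    geometry=geometry,
                )
            )
            next_id += 1
    return ClusterSet(
        marker=stack.marker,
        clusters=clusters,
        geometry=geometry,
        params=dict(params),
        provenance=dict(stack.provenance),
        n_excluded_size=n_small,
        n_excluded_edge=n_edge,
    )


def segment_threshold(stack: ChannelStack, threshold: float, min_size: int = 5) -> ClusterSet:
    """Simple intensity-threshold segmentation (molecular layer).

    Suprathreshold (``>= threshold``) voxels are grouped into 26-connected
    components; components smaller than ``min_size`` voxels or touching any
    stack face are discarded.  A threshold above the stack maximum yields an
    empty set, not an error.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    mask = stack.data >= threshold
    labels = measure.label(mask, connectivity=3)
    return _build_clusters(
        stack, labels, min_size,
        {"method": "threshold", "threshold": threshold, "min_size": min_size},
    )


def segment_watershed(
    stack: ChannelStack,
    threshold: float,
    min_size: int = 5,
    min_peak_separation_nm: float = 400.0,
    smoothing_sigma_xyz_nm: Sequence[float] = (80.0, 80.0, 200.0),
) -> ClusterSet:
    """Marker-controlled watershed segmentation (granule cell layer).

    The suprathreshold mask is split at watershed lines of the Gaussian-
    smoothed image.  Watershed markers are local maxima of the smoothed
    image, greedily thinned so surviving peaks are at least
    ``min_peak_separation_nm`` apart in physical (anisotropy-aware) units.
    Size and edge exclusion are applied after splitting.  An isolated
    punctum (single maximum) reduces exactly to threshold segmentation.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    if min_peak_separation_nm <= 0:
        raise ValueError("min_peak_separation_nm must be > 0")
    mask = stack.data >= threshold
    params = {
        "method": "watershed",
        "threshold": threshold,
        "min_size": min_size,
        "min_peak_separation_nm": min_peak_separation_nm,
        "smoothing_sigma_xyz_nm": tuple(smoothing_sigma_xyz_nm),
    }
    if not mask.any():
        return _build_clusters(stack, np.zeros_like(stack.data, dtype=np.int32), min_size, params)

    vox_zyx = np.asarray(stack.geometry.voxel_size_zyx_nm)
    sx, sy, sz = smoothing_sigma_xyz_nm
    sigma_vox = np.array([sz, sy, sx]) / vox_zyx
    smoothed = ndimage.gaussian_filter(stack.data.astype(np.float64), sigma=sigma_vox)

    comp = measure.label(mask, connectivity=3)
    peaks = peak_local_max(smoothed, min_distance=1, exclude_border=False, labels=comp)

    # Greedy suppression of close peaks, per connected component (a watershed
    # can only split within one component), brightest first, in physical units.
    kept: list[np.ndarray] = []
    if len(peaks):
        heights = smoothed[tuple(peaks.T)]
        comp_of_peak = comp[tuple(peaks.T)]
        order = np.argsort(heights)[::-1]
        kept_nm_by_comp: dict[int, list[np.ndarray]] = {}
        for i in order:
            cid = int(comp_of_peak[i])
            p_nm = (peaks[i] + 0.5) * vox_zyx
            near = kept_nm_by_comp.setdefault(cid, [])
            if all(np.linalg.norm(p_nm - q) >= min_peak_separation_nm for q in near):
                kept.append(peaks[i])
                near.append(p_nm)
    markers = np.zeros_like(comp, dtype=np.int32)
    for j, p in enumerate(kept, start=1):
        markers[tuple(p)] = j
    structure = ndimage.generate_binary_structure(3, 3)
    labels = watershed(-smoothed, markers=markers, mask=mask, connectivity=structure)
    # plateau-only components receive no peak marker; keep them whole
    missing = mask & (labels == 0)
    if missing.any():
        next_label = int(labels.max())
        extra = measure.label(missing, connectivity=3)
        labels = labels + np.where(extra > 0, extra + next_label, 0).astype(labels.dtype)
    return _build_clusters(stack, labels, min_size, params)


def min_distance_nm(a: Cluster, b: Cluster, geometry: VoxelGeometry | None = None) -> float:
    """Minimum voxel-center Euclidean distance (nm, expanded) between two clusters.

    0 if the clusters share voxels.  Both clusters must come from stacks
    sharing one geometry.
    """
    geometry = geometry or a.geometry
    if a.geometry != geometry or b.geometry != geometry:
        raise ValueError("clusters have mismatched voxel geometry")
    tree = cKDTree(b.points_nm)
    d, _ = tree.query(a.points_nm)
    return float(np.min(d))


def centroid_distance_nm(a: Cluster, b: Cluster, geometry: VoxelGeometry | None = None) -> float:
    """Centroid-to-centroid distance (nm, expanded); the sensitivity-analysis
    alternative to :func:`min_distance_nm`."""
    geometry = geometry or a.geometry
    if a.geometry != geometry or b.geometry != geometry:
        raise ValueError("clusters have mismatched voxel geometry")
    return float(
        np.linalg.norm(np.asarray(a.centroid_zyx_nm) - np.asarray(b.centroid_zyx_nm))
    )


def clusters_to_dataframe(cluster_sets: Iterable[ClusterSet]):
    """Tidy export: one row per cluster with provenance and physical measures."""
    import pandas as pd

    rows = []
    for cs in cluster_sets:
        stack_id = cs.provenance.get("stack_id", "")
        for c in cs.clusters:
            z, y, x = c.centroid_zyx_nm
            rows.append(
                dict(
                    stack_id=stack_id,
                    channel=cs.marker,
                    cluster_id=c.cluster_id,
                    centroid_x_nm=x,
                    centroid_y_nm=y,
                    centroid_z_nm=z,
                    volume_um3=c.volume_um3,
                    integrated_intensity=c.integrated_intensity,
                    n_voxels=c.n_voxels,
                    touches_edge=c.touches_edge,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "stack_id", "channel", "cluster_id", "centroid_x_nm", "centroid_y_nm",
            "centroid_z_nm", "volume_um3", "integrated_intensity", "n_voxels", "touches_edge",
        ],
    )
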