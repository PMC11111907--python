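"""Per-stack metrics, hierarchical aggregation, and ground-truth evaluation.

The quantification chain mirrors the study design: cluster intensities are
normalized to the per-stack, per-channel mean; records are summarized per
(class, antigen) into fraction-positive, mean amount per positive record,
density per biological tissue volume, and total amount per field; stack
values are then averaged per mouse, so each statistical data point is one
animal.  Undefined metrics (e.g. fraction positive of an absent class)
propagate as missing values and are never coerced to 0.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import VoxelGeometry, volume_biological_um3
from .segment import ClusterSet
from .classify import SynapseRecord
from .synthgen import GroundTruthTable


def normalize_intensities(clusters: ClusterSet) -> ClusterSet:
    """Divide every integrated intensity by the channel's per-stack mean.

    The returned set has mean integrated intensity exactly 1; scale ratios
    between clusters are preserved.  Raises on an empty set (the mean, and
    hence the normalization, is undefined).
    """
    if len(clusters) == 0:
        raise ValueError(f"cannot normalize an empty cluster set ({clusters.marker})")
    mean = float(np.mean([c.integrated_intensity for c in clusters]))
    if mean <= 0:
        raise ValueError("mean integrated intensity must be positive")
    new = [replace(c, integrated_intensity=c.integrated_intensity / mean) for c in clusters]
    out = ClusterSet(
        marker=clusters.marker,
        clusters=new,
        geometry=clusters.geometry,
        params={**clusters.params, "normalized": True, "normalization_mean": mean},
        provenance=dict(clusters.provenance),
        n_excluded_size=clusters.n_excluded_size,
        n_excluded_edge=clusters.n_excluded_edge,
    )
    return out


def _select(
    records: Sequence[SynapseRecord], class_label: str, subclass: str | None = None
) -> list[SynapseRecord]:
    out = [r for r in records if r.class_label == class_label]
    if subclass is not None:
        out = [r for r in out if r.subclass == subclass]
    return out


def fraction_positive(
    records: Sequence[SynapseRecord], class_label: str, subclass: str | None = None
) -> float | None:
    """Fraction of records of a class that are antigen-positive.

    Returns ``None`` (undefined) when the class has no records.
    """
    sel = _select(records, class_label, subclass)
    if not sel:
        return None
    return sum(r.antigen_positive for r in sel) / len(sel)


def mean_positive_intensity(
    records: Sequence[SynapseRecord], class_label: str, subclass: str | None = None
) -> float | None:
    """Mean normalized antigen intensity over the antigen-positive records."""
    pos = [r.antigen_intensity for r in _select(records, class_label, subclass) if r.antigen_positive]
    if not pos:
        return None
    return float(np.mean(pos))


def total_positive_intensity(
    records: Sequence[SynapseRecord], class_label: str, subclass: str | None = None
) -> float:
    """Summed antigen intensity over positive records (per-field total)."""
    return float(
        sum(r.antigen_intensity for r in _select(records, class_label, subclass) if r.antigen_positive)
    )


def intensity_ratio_per_record(
    records: Sequence[SynapseRecord],
    class_a: str,
    class_b: str,
    subclass_a: str | None = None,
    subclass_b: str | None = None,
) -> float | None:
    """Fold ratio of mean antigen intensity per positive record, class a / class b.

    Undefined (``None``) when either class has no positive records.
    """
    a = mean_positive_intensity(records, class_a, subclass_a)
    b = mean_positive_intensity(records, class_b, subclass_b)
    if a is None or b is None or b == 0:
        return None
    return a / b


def intensity_ratio_per_field(
    records: Sequence[SynapseRecord],
    class_a: str,
    class_b: str,
    subclass_a: str | None = None,
    subclass_b: str | None = None,
) -> float | None:
    """Fold ratio of summed antigen intensity per field, class a / class b.

    Unlike the per-record ratio this captures count x amount: it equals
    the per-record ratio times the positive-count ratio exactly.
    """
    if not _select(records, class_a, subclass_a) or not _select(records, class_b, subclass_b):
        return None
    a = total_positive_intensity(records, class_a, subclass_a)
    b = total_positive_intensity(records, class_b, subclass_b)
    if a == 0 or b == 0:
        return None
    return a / b


def record_density(
    records: Sequence[SynapseRecord],
    class_label: str,
    field_volume_biological_um3: float,
    subclass: str | None = None,
) -> float:
    """Record count per biological-scale tissue volume (count / um^3)."""
    if field_volume_biological_um3 <= 0:
        raise ValueError("field volume must be positive")
    return len(_select(records, class_label, subclass)) / field_volume_biological_um3


def field_volume_biological(n_voxels: int, geometry: VoxelGeometry) -> float:
    """Biological-scale volume (um^3) of a full field of ``n_voxels`` voxels."""
    return volume_biological_um3(n_voxels, geometry)


#: (class_label, subclass) rows summarized per stack, by layer panel
PANEL_CLASSES: dict[str, tuple[tuple[str, str | None], ...]] = {
    "molecular_gluD2": (
        ("PF-PC", None), ("PF-PC", "PSD95+"), ("PF-PC", "PSD95-"), ("nonPF-PC", None),
    ),
    "molecular_vglut2": (("CF-PC", None), ("nonCF-PC", None)),
    "glomerular": (("GCL-synaptic", None), ("GCL-extrasynaptic", None)),
}


def compute_stack_metrics(
    records: Sequence[SynapseRecord],
    classes: Sequence[tuple[str, str | None]],
    field_volume_biological_um3: float,
    provenance: Mapping | None = None,
    antigen: str = "antigen",
) -> pd.DataFrame:
    """Tidy per-stack summary: one row per (class, subclass).

    Columns: counts, fraction_positive, mean_intensity_positive,
    total_intensity, density_per_um3 (biological scale).  Undefined values
    are NaN.
    """
    prov = dict(provenance or {})
    rows = []
    for class_label, subclass in classes:
        sel = _select(records, class_label, subclass)
        frac = fraction_positive(records, class_label, subclass)
        mean_int = mean_positive_intensity(records, class_label, subclass)
        rows.append(
            dict(
                stack_id=prov.get("stack_id", ""),
                mouse_id=prov.get("mouse_id", ""),
                layer=prov.get("layer", ""),
                antigen=antigen,
                class_label=class_label,
                subclass="" if subclass is None else subclass,
                n_records=len(sel),
                n_positive=sum(r.antigen_positive for r in sel),
                fraction_positive=np.nan if frac is None else frac,
                mean_intensity_positive=np.nan if mean_int is None else mean_int,
                total_intensity=total_positive_intensity(records, class_label, subclass),
                density_per_um3=record_density(
                    records, class_label, field_volume_biological_um3, subclass
                ),
            )
        )
    return pd.DataFrame(rows)


METRIC_COLUMNS = (
    "fraction_positive", "mean_intensity_positive", "total_intensity", "density_per_um3",
)


def aggregate_by_mouse(
    stack_metrics: pd.DataFrame, mouse_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Unweighted per-mouse mean of every metric over that mouse's stacks.

    ``mouse_map`` (stack_id -> mouse_id) overrides/fills the ``mouse_id``
    column; every stack must be mapped.  Undefined (NaN) stack values are
    excluded from the mean; the number excluded is reported per row.
    """
    df = stack_metrics.copy()
    if mouse_map is not None:
        unmapped = set(df["stack_id"]) - set(mouse_map)
        if unmapped:
            raise ValueError(f"stacks not mapped to a mouse: {sorted(unmapped)}")
        df["mouse_id"] = df["stack_id"].map(mouse_map)
    if (df["mouse_id"] == "").any():
        raise ValueError("every stack requires a mouse_id")
    keys = ["mouse_id", "antigen", "class_label", "subclass"]
    agg: dict = {m: ("mean",) for m in METRIC_COLUMNS}
    grouped = df.groupby(keys, dropna=False)
    out = grouped[list(METRIC_COLUMNS)].mean().reset_index()
    out["n_stacks"] = grouped.size().values
    for m in METRIC_COLUMNS:
        out[f"n_undefined_{m}"] = grouped[m].apply(lambda s: int(s.isna().sum())).values
    return out


# ---------------------------------------------------------------------------
# ground-truth evaluation
# ---------------------------------------------------------------------------


def evaluate_against_truth(
    records: Sequence[SynapseRecord],
    truth: GroundTruthTable,
    class_map: Mapping[str, tuple[str, str | None] | None],
    match_radius_nm: float = 300.0,
) -> dict:
    """Greedy nearest-centroid matching of records against planted sites.

    ``class_map`` maps each planted class to the (class_label, subclass)
    a correct pipeline should assign, or ``None`` for classes invisible to
    the panel (excluded from recall).  Returns precision, recall, class
    accuracy among matches, and a confusion table
    (planted class x assigned label).
    """
    detectable = [s for s in truth.sites if class_map.get(s.true_class) is not None]
    rec_list = list(records)
    # positions: truth anchors are (x, y, z); records store (z, y, x)
    t_pos = np.array([[s.anchor_xyz_nm[2], s.anchor_xyz_nm[1], s.anchor_xyz_nm[0]]
                      for s in detectable]).reshape(-1, 3)
    r_pos = np.array([r.anchor_centroid_zyx_nm for r in rec_list]).reshape(-1, 3)

    pairs: list[tuple[float, int, int]] = []
    if len(t_pos) and len(r_pos):
        diff = t_pos[:, None, :] - r_pos[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        ti, ri = np.nonzero(dist <= match_radius_nm)
        pairs = sorted(zip(dist[ti, ri], ti, ri))
    matched_t: set[int] = set()
    matched_r: set[int] = set()
    matches: list[tuple[int, int]] = []
    for d, ti, ri in pairs:
        if ti in matched_t or ri in matched_r:
            continue
        matched_t.add(ti)
        matched_r.add(ri)
        matches.append((ti, ri))

    n_correct = 0
    confusion: dict[tuple[str, str], int] = {}
    for ti, ri in matches:
        planted = detectable[ti].true_class
        rec = rec_list[ri]
        expected = class_map[planted]
        assigned = (rec.class_label, rec.subclass)
        label = rec.class_label if rec.subclass is None else f"{rec.class_label}/{rec.subclass}"
        confusion[(planted, label)] = confusion.get((planted, label), 0) + 1
        if assigned[0] == expected[0] and (expected[1] is None or assigned[1] == expected[1]):
            n_correct += 1

    precision = len(matches) / len(rec_list) if rec_list else np.nan
    recall = len(matches) / len(detectable) if detectable else np.nan
    accuracy = n_correct / len(matches) if matches else np.nan
    conf_df = pd.DataFrame(
        [dict(true_class=t, assigned=a, count=n) for (t, a), n in sorted(confusion.items())],
        columns=["true_class", "assigned", "count"],
    )
    return {
        "n_records": len(rec_list),
        "n_detectable_truth": len(detectable),
        "n_matched": len(matches),
        "precision": precision,
        "recall": recall,
        "class_accuracy": accuracy,
        "confusion": conf_df,
    }


def planted_fraction_positive(truth: GroundTruthTable, true_class: str) -> float | None:
    """Planted probability-positive estimate for one class (recovery oracle)."""
    sites = [s for s in truth.sites if s.true_class == true_class]
    if not sites:
        return None
    return sum(s.antigen_positive for s in sites) / len(sites)


def planted_intensity_ratio(
    truth: GroundTruthTable, classes_a: Sequence[str], classes_b: Sequence[str]
) -> float | None:
    """Planted per-site antigen fold ratio, mean(a) / mean(b), positives only."""
    antigen = truth.config.antigen_marker

    def amounts(classes: Sequence[str]) -> list[float]:
        return [
            s.channel_amounts[antigen]
            for s in truth.sites
            if s.true_class in classes and antigen in s.channel_amounts
        ]

    a, b = amounts(classes_a), amounts(classes_b)
    if not a or not b:
        return None
    return float(np.mean(a) / np.mean(b))
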