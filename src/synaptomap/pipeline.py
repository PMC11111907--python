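"""End-to-end orchestration: simulate -> segment -> classify -> quantify -> stats.

A run is described by a :class:`RunConfig`; outputs are written to a run
directory as CSV/JSON together with a machine-readable manifest of every
parameter and seed, so identical configuration reproduces identical
output trees byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import records_to_dataframe
from .quant import (
    PANEL_CLASSES,
    aggregate_by_mouse,
    compute_stack_metrics,
    evaluate_against_truth,
    field_volume_biological,
)
from .scenarios import (
    CLIMBING_CLASS_MAP,
    DEFAULT_MIN_SIZE,
    DEFAULT_THRESHOLD,
    GLOMERULAR_CLASS_MAP,
    MOLECULAR_CLASS_MAP,
    classify_panel,
    segment_channels,
)
from .segment import clusters_to_dataframe
from .stackio import ChannelStack
from .synthgen import SimulationConfig, generate_stack, with_seed

MODE_MARKERS: dict[str, tuple[str, ...]] = {
    "molecular_gluD2": ("GluD2", "PSD-95", "antigen"),
    "molecular_vglut2": ("VGluT2", "PSD-95", "antigen"),
    "glomerular": ("ELKS", "PSD-95", "antigen"),
}

MODE_CLASS_MAP = {
    "molecular_gluD2": MOLECULAR_CLASS_MAP,
    "molecular_vglut2": CLIMBING_CLASS_MAP,
    "glomerular": GLOMERULAR_CLASS_MAP,
}


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run.

    ``n_mice`` x ``stacks_per_mouse`` simulated fields are generated from
    ``base_seed`` (sub-seeds are derived deterministically per stack).
    """

    mode: str
    threshold: float = DEFAULT_THRESHOLD
    min_size: int = DEFAULT_MIN_SIZE
    d_syn_nm: float = 300.0
    d_extra_nm: float = 30.0
    n_mice: int = 3
    stacks_per_mouse: int = 2
    base_seed: int = 0
    antigen_marker: str = "antigen"

    def __post_init__(self) -> None:
        if self.mode not in MODE_MARKERS:
            raise ValueError(f"mode must be one of {sorted(MODE_MARKERS)}, got {self.mode!r}")


def preflight(run: RunConfig, available_markers: Sequence[str]) -> None:
    """Fail before any compute if the mode's required channels are missing."""
    missing = set(MODE_MARKERS[run.mode]) - set(available_markers)
    if missing:
        raise ValueError(
            f"mode {run.mode!r} requires channels {sorted(missing)} not present "
            f"in {sorted(available_markers)}"
        )


def analyze_stack(
    channels: Mapping[str, ChannelStack],
    run: RunConfig,
    layer_kind: str,
):
    """Segment + classify one stack; returns (records, cluster_sets, stage log)."""
    preflight(run, list(channels))
    cluster_sets = segment_channels(
        dict(channels), layer_kind, threshold=run.threshold, min_size=run.min_size
    )
    records = classify_panel(
        cluster_sets, run.mode, d_syn_nm=run.d_syn_nm, d_extra_nm=run.d_extra_nm,
        antigen_marker=run.antigen_marker,
    )
    log = {
        marker: {
            "clusters_retained": len(cs),
            "excluded_small": cs.n_excluded_size,
            "excluded_edge": cs.n_excluded_edge,
        }
        for marker, cs in cluster_sets.items()
    }
    log["records"] = {"n": len(records)}
    return records, cluster_sets, log


def run_pipeline(
    run: RunConfig,
    sim_config: SimulationConfig,
    out_dir: str | Path,
    evaluate: bool = True,
) -> Path:
    """Simulate, analyze and summarize a full multi-mouse run.

    Writes cluster tables, synapse records, per-stack metrics, per-mouse
    summaries, an optional ground-truth evaluation, and a manifest.
    Identical ``run`` + ``sim_config`` reproduce identical outputs.
    """
    preflight(run, sim_config.channel_order())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_clusters = []
    all_records = []
    all_metrics = []
    eval_rows = []
    stage_log: dict[str, dict] = {}
    class_map = MODE_CLASS_MAP[run.mode]

    for mouse in range(run.n_mice):
        mouse_id = f"mouse{mouse + 1}"
        for s in range(run.stacks_per_mouse):
            stack_id = f"{mouse_id}_stack{s + 1}"
            seed = (run.base_seed * 1_000 + mouse * 100 + s) & 0x7FFFFFFF
            cfg = with_seed(sim_config, seed)
            prov = {"stack_id": stack_id, "mouse_id": mouse_id, "layer": cfg.layer_kind}
            channels, truth = generate_stack(cfg, provenance=prov)
            records, cluster_sets, log = analyze_stack(channels, run, cfg.layer_kind)
            stage_log[stack_id] = log

            cdf = clusters_to_dataframe(cluster_sets.values())
            cdf["stack_id"] = stack_id
            all_clusters.append(cdf)
            rdf = records_to_dataframe(records, stack_id=stack_id)
            rdf["mouse_id"] = mouse_id
            all_records.append(rdf)

            nz, ny, nx = cfg.grid_shape_zyx
            vol_bio = field_volume_biological(nz * ny * nx, cfg.geometry)
            all_metrics.append(
                compute_stack_metrics(
                    records, PANEL_CLASSES[run.mode], vol_bio, provenance=prov,
                    antigen=run.antigen_marker,
                )
            )
            if evaluate:
                ev = evaluate_against_truth(records, truth, class_map)
                eval_rows.append(
                    dict(stack_id=stack_id, mouse_id=mouse_id,
                         **{k: v for k, v in ev.items() if k != "confusion"})
                )

    pd.concat(all_clusters, ignore_index=True).to_csv(out_dir / "clusters.csv", index=False)
    pd.concat(all_records, ignore_index=True).to_csv(out_dir / "records.csv", index=False)
    metrics = pd.concat(all_metrics, ignore_index=True)
    metrics.to_csv(out_dir / "stack_metrics.csv", index=False)
    mouse_summary = aggregate_by_mouse(metrics)
    mouse_summary.to_csv(out_dir / "mouse_summary.csv", index=False)
    if eval_rows:
        pd.DataFrame(eval_rows).to_csv(out_dir / "evaluation.csv", index=False)

    manifest = {
        "software": {"name": "synaptomap", "version": __version__},
        "run_config": asdict(run),
        "simulation": _sim_config_dict(sim_config),
        "stage_log": stage_log,
        "outputs": sorted(
            p.name for p in out_dir.iterdir() if p.suffix in (".csv", ".json")
        ) + ["manifest.json"],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonable)
    return out_dir


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sim_config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["antigen_models"] = {
        k: {"prob_positive": m["prob_positive"], "median": m["median"], "sigma": m["sigma"]}
        if isinstance(m, dict) else
        {"prob_positive": m.prob_positive, "median": m.median, "sigma": m.sigma}
        for k, m in d["antigen_models"].items()
    }
    d["marker_rules"] = {k: list(v) for k, v in d["marker_rules"].items()}
    return d
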