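"""Synthetic multi-channel stacks with planted synapses of known composition.

The generator emulates the statistical structure the downstream analysis
assumes: point-like antigen/marker sites rendered as 3D Gaussian puncta on
an anisotropic voxel grid, with Poisson shot noise and Gaussian read noise.
Each *site* belongs to a synapse class whose marker combination follows the
cerebellar staining logic:

molecular layer
    ``PF-PC(PSD95+)`` GluD2 + PSD-95, ``PF-PC(PSD95-)`` GluD2 only,
    ``PF-MLI`` PSD-95 only, ``CF-PC`` PSD-95 + VGluT2.
glomerular (granule cell layer)
    ``synaptic`` PSD-95 + ELKS, ``extrasynaptic`` PSD-95 only.

Per class, an antigen-of-interest channel is rendered at the site with a
configurable probability-positive and a log-normal amount, so that
fraction-positive and fold-enrichment values planted here can be compared
with the values the pipeline recovers.

Every random draw is derived from ``SimulationConfig.seed``; identical
configurations reproduce identical stacks bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import VoxelGeometry
from .stackio import ChannelStack

#: canonical rendering order for structural marker channels
CANONICAL_MARKERS = ("GluD2", "PSD-95", "VGluT2", "ELKS")

MOLECULAR_RULES: dict[str, tuple[str, ...]] = {
    # first marker anchors the site; the rest are offset partners
    "PF-PC(PSD95+)": ("GluD2", "PSD-95"),
    "PF-PC(PSD95-)": ("GluD2",),
    "PF-MLI": ("PSD-95",),
    "CF-PC": ("PSD-95", "VGluT2"),
}

GLOMERULAR_RULES: dict[str, tuple[str, ...]] = {
    "synaptic": ("PSD-95", "ELKS"),
    "extrasynaptic": ("PSD-95",),
}

# Densities are per um^3 on the EXPANDED scale (factor 4 assumed for the
# defaults).  Molecular values put PF-PC at 2.33x nonPF-PC with 23% of
# PF-PC sites carrying PSD-95, at ~0.56 PF-PC synapses per biological um^3.
MOLECULAR_DENSITIES: dict[str, float] = {
    "PF-PC(PSD95+)": 0.002,
    "PF-PC(PSD95-)": 0.00675,
    "PF-MLI": 0.003,
    "CF-PC": 0.00075,
}

GLOMERULAR_DENSITIES: dict[str, float] = {
    "synaptic": 0.02,
    "extrasynaptic": 0.02,
}


@dataclass(frozen=True)
class AntigenModel:
    """Per-class antigen-of-interest model.

    ``prob_positive`` is the probability a site carries the antigen;
    positive sites draw a log-normal amount ``exp(N(ln median, sigma))``.
    """

    prob_positive: float
    median: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_positive <= 1.0:
            raise ValueError(f"prob_positive must be in [0, 1], got {self.prob_positive}")
        if self.median < 0 or self.sigma < 0:
            raise ValueError("antigen amount parameters must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated acquisition field.

    Lengths are on the expanded scale: ``field_size_um`` in um (x, y, z),
    ``voxel_size_xyz_nm`` in nm.  The voxel grid is the floor of
    ``field_size / voxel_size`` per axis.  ``class_densities`` are counts
    per expanded um^3; site counts are Poisson with mean density x volume.

    Puncta are rendered as anisotropic Gaussians whose per-axis sigma is
    the quadrature sum of ``punctum_sigma_xyz_nm`` (intrinsic extent) and
    ``psf_sigma_xyz_nm`` (optical blur); the defaults give an 80 x 80 x
    200 nm rendered width.  Partner markers and the antigen are displaced
    from the site anchor by ``offset_scale_nm`` in a uniformly random
    direction.  Noise: ``y = gain * Poisson(x / gain) + N(0, read sigma)``,
    clipped at zero; setting both parameters to 0 gives a noiseless stack.

    ``edge_margin_nm = None`` auto-computes, per axis, ``3 sigma + offset +
    one voxel`` so planted puncta are complete (never edge-touching); 0
    plants uniformly over the whole field.
    """

    layer_kind: str  # "molecular" | "glomerular"
    field_size_um: tuple[float, float, float] = (53.0, 53.0, 7.41)
    voxel_size_xyz_nm: tuple[float, float, float] = (50.0, 50.0, 190.0)
    expansion_factor: float = 4.0
    class_densities: Mapping[str, float] = field(default_factory=dict)
    marker_rules: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    antigen_models: Mapping[str, AntigenModel] = field(default_factory=dict)
    antigen_marker: str = "antigen"
    marker_amount_median: float = 2000.0
    marker_amount_sigma: float = 0.4
    offset_scale_nm: float = 100.0
    punctum_sigma_xyz_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    psf_sigma_xyz_nm: tuple[float, float, float] = (80.0, 80.0, 200.0)
    noise_poisson_gain: float = 1.0
    noise_read_sigma: float = 2.0
    edge_margin_nm: tuple[float, float, float] | None = None
    channels: tuple[str, ...] | None = None
    seed: int = 0

    # ---- derived geometry -------------------------------------------------

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry.from_xyz(self.voxel_size_xyz_nm, self.expansion_factor)

    @property
    def grid_shape_zyx(self) -> tuple[int, int, int]:
        """Voxel grid: floor(field / voxel) per axis (fixed rounding rule)."""
        fx, fy, fz = (1000.0 * f for f in self.field_size_um)
        vx, vy, vz = self.voxel_size_xyz_nm
        shape = (int(fz // vz), int(fy // vy), int(fx // vx))
        if any(n < 1 for n in shape):
            raise ValueError(f"field {self.field_size_um} um is smaller than one voxel")
        return shape

    @property
    def grid_extent_xyz_nm(self) -> tuple[float, float, float]:
        """Physical extent of the realized voxel grid (nm, expanded)."""
        nz, ny, nx = self.grid_shape_zyx
        vx, vy, vz = self.voxel_size_xyz_nm
        return (nx * vx, ny * vy, nz * vz)

    @property
    def grid_volume_um3(self) -> float:
        x, y, z = self.grid_extent_xyz_nm
        return x * y * z / 1e9

    @property
    def render_sigma_xyz_nm(self) -> tuple[float, float, float]:
        return tuple(
            float(np.hypot(a, b))
            for a, b in zip(self.punctum_sigma_xyz_nm, self.psf_sigma_xyz_nm)
        )

    def resolved_margin_xyz_nm(self) -> tuple[float, float, float]:
        if self.edge_margin_nm is not None:
            return tuple(float(m) for m in self.edge_margin_nm)
        return tuple(
            3.0 * s + self.offset_scale_nm + v
            for s, v in zip(self.render_sigma_xyz_nm, self.voxel_size_xyz_nm)
        )

    def channel_order(self) -> tuple[str, ...]:
        """Fixed channel rendering order (structural markers then antigen)."""
        if self.channels is not None:
            return tuple(self.channels)
        used = {m for rules in self.marker_rules.values() for m in rules}
        ordered = [m for m in CANONICAL_MARKERS if m in used]
        ordered += sorted(used - set(ordered))
        return tuple(ordered) + (self.antigen_marker,)

    def validate(self) -> None:
        if self.layer_kind not in ("molecular", "glomerular"):
            raise ValueError(f"unknown layer_kind {self.layer_kind!r}")
        if any(f <= 0 for f in self.field_size_um):
            raise ValueError(f"field_size_um must be positive, got {self.field_size_um}")
        if any(v <= 0 for v in self.voxel_size_xyz_nm):
            raise ValueError("voxel dimensions must be positive")
        for cls, dens in self.class_densities.items():
            if cls not in self.marker_rules:
                raise ValueError(f"unknown class label {cls!r} in class_densities")
            if dens < 0:
                raise ValueError(f"density for {cls!r} must be >= 0, got {dens}")
        for cls in self.antigen_models:
            if cls not in self.marker_rules:
                raise ValueError(f"unknown class label {cls!r} in antigen_models")
        if any(s < 0 for s in self.punctum_sigma_xyz_nm + self.psf_sigma_xyz_nm):
            raise ValueError("sigmas must be non-negative")
        if self.offset_scale_nm < 0 or self.noise_poisson_gain < 0 or self.noise_read_sigma < 0:
            raise ValueError("offset and noise parameters must be non-negative")
        self.grid_shape_zyx  # raises for sub-voxel fields


def molecular_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Molecular-layer field (GluD2 / PSD-95 / antigen channels)."""
    defaults = dict(
        layer_kind="molecular",
        class_densities=dict(MOLECULAR_DENSITIES),
        marker_rules=dict(MOLECULAR_RULES),
        antigen_models={c: AntigenModel(0.5, 10000.0, 0.5) for c in MOLECULAR_RULES},
        channels=("GluD2", "PSD-95", "antigen"),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def molecular_vglut2_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Molecular-layer field imaged with the VGluT2 / PSD-95 / antigen panel."""
    overrides.setdefault("channels", ("VGluT2", "PSD-95", "antigen"))
    return molecular_config(seed=seed, **overrides)


def glomerular_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Granule-cell-layer glomerular field (ELKS / PSD-95 / antigen channels)."""
    defaults = dict(
        layer_kind="glomerular",
        class_densities=dict(GLOMERULAR_DENSITIES),
        marker_rules=dict(GLOMERULAR_RULES),
        antigen_models={c: AntigenModel(0.5, 10000.0, 0.5) for c in GLOMERULAR_RULES},
        channels=("ELKS", "PSD-95", "antigen"),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """One planted synaptic (or extrasynaptic) site.

    ``channel_centers_xyz_nm`` holds the punctum center per rendered
    channel; ``channel_amounts`` the true integrated (pre-noise) intensity.
    A channel is present iff its amount is > 0.
    """

    site_id: int
    true_class: str
    anchor_xyz_nm: tuple[float, float, float]
    channel_centers_xyz_nm: Mapping[str, tuple[float, float, float]]
    channel_amounts: Mapping[str, float]

    @property
    def antigen_positive(self) -> bool:  # convenience for recovery checks
        return any(
            amt > 0 and ch not in CANONICAL_MARKERS
            for ch, amt in self.channel_amounts.items()
        )


@dataclass(frozen=True)
class GroundTruthTable:
    """All planted sites of one field plus the configuration that produced it."""

    sites: tuple[PlantedSite, ...]
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.true_class] = counts.get(s.true_class, 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            for ch, amount in s.channel_amounts.items():
                x, y, z = s.channel_centers_xyz_nm[ch]
                rows.append(
                    dict(site_id=s.site_id, true_class=s.true_class, channel=ch,
                         x_nm=x, y_nm=y, z_nm=z, amount=amount)
                )
        return pd.DataFrame(
            rows, columns=["site_id", "true_class", "channel", "x_nm", "y_nm", "z_nm", "amount"]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# planting and rendering
# ---------------------------------------------------------------------------


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return v / norm


def plant_sites(config: SimulationConfig) -> GroundTruthTable:
    """Draw the planted-site inventory for one field.

    Site counts per class are Poisson(density x grid volume); anchors are
    uniform within the field minus the edge margin; partner markers and
    the antigen are displaced by ``offset_scale_nm`` in a random direction
    (clipped to the grid).  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0])
    extent = np.asarray(config.grid_extent_xyz_nm)
    margin = np.asarray(config.resolved_margin_xyz_nm())
    lo = np.minimum(margin, extent / 2.0)
    hi = np.maximum(extent - margin, extent / 2.0)
    volume = config.grid_volume_um3

    sites: list[PlantedSite] = []
    site_id = 0
    for cls in sorted(config.class_densities):
        density = config.class_densities[cls]
        n = int(rng.poisson(density * volume))
        if n == 0:
            continue
        anchors = rng.uniform(lo, hi, size=(n, 3))
        model = config.antigen_models.get(cls)
        markers = config.marker_rules[cls]
        for i in range(n):
            anchor = anchors[i]
            centers: dict[str, tuple[float, float, float]] = {}
            amounts: dict[str, float] = {}
            for j, marker in enumerate(markers):
                if j == 0:
                    c = anchor
                else:
                    c = anchor + _unit_vectors(rng, 1)[0] * config.offset_scale_nm
                c = np.clip(c, 0.0, extent)
                centers[marker] = tuple(float(v) for v in c)
                amounts[marker] = float(
                    np.exp(rng.normal(np.log(config.marker_amount_median),
                                      config.marker_amount_sigma))
                )
            if model is not None and model.prob_positive > 0 and rng.random() < model.prob_positive:
                c = np.clip(
                    anchor + _unit_vectors(rng, 1)[0] * config.offset_scale_nm, 0.0, extent
                )
                centers[config.antigen_marker] = tuple(float(v) for v in c)
                amounts[config.antigen_marker] = float(
                    np.exp(rng.normal(np.log(model.median), model.sigma))
                )
            sites.append(
                PlantedSite(
                    site_id=site_id,
                    true_class=cls,
                    anchor_xyz_nm=tuple(float(v) for v in anchor),
                    channel_centers_xyz_nm=centers,
                    channel_amounts=amounts,
                )
            )
            site_id += 1
    return GroundTruthTable(sites=tuple(sites), config=config)


def _axis_weights(center_nm: float, sigma_nm: float, pitch_nm: float, n: int):
    """Discrete Gaussian weights along one axis.

    Returns (lo_index, weights, total) where ``weights`` covers the clipped
    index range [lo, lo+len) and ``total`` is the weight sum over the FULL
    +-4 sigma window, so border truncation loses mass rather than being
    renormalized away.
    """
    c = center_nm / pitch_nm - 0.5  # index coordinate of the center
    if sigma_nm <= 0:
        i = int(np.clip(round(c), 0, n - 1))
        return i, np.ones(1), 1.0
    half = max(1, int(np.ceil(4.0 * sigma_nm / pitch_nm)))
    full = np.arange(int(np.floor(c)) - half, int(np.floor(c)) + half + 1)
    w = np.exp(-0.5 * ((full - c) * pitch_nm / sigma_nm) ** 2)
    total = float(w.sum())
    inside = (full >= 0) & (full < n)
    if not inside.any():
        return 0, np.zeros(0), total
    return int(full[inside][0]), w[inside], total


def render_channel(
    truth: GroundTruthTable, channel: str, config: SimulationConfig | None = None
) -> np.ndarray:
    """Render one channel of a field as a float32 ``(z, y, x)`` array.

    Each site carrying ``channel`` contributes a separable anisotropic
    Gaussian punctum whose integrated pre-noise intensity equals its true
    amount (up to truncation at the field border).  Poisson-Gaussian noise
    is applied last; with both noise parameters zero the output is the
    noiseless superposition.
    """
    config = config or truth.config
    shape = config.grid_shape_zyx
    sig_xyz = config.render_sigma_xyz_nm
    vox_xyz = config.voxel_size_xyz_nm
    if any(0 < s < v / 2 for s, v in zip(sig_xyz, vox_xyz)):
        warnings.warn(
            f"punctum sigma {sig_xyz} nm undersampled by voxels {vox_xyz} nm",
            stacklevel=2,
        )
    arr = np.zeros(shape, dtype=np.float64)
    nz, ny, nx = shape
    for site in truth.sites:
        amount = site.channel_amounts.get(channel, 0.0)
        if amount <= 0:
            continue
        cx, cy, cz = site.channel_centers_xyz_nm[channel]
        zlo, wz, tz = _axis_weights(cz, sig_xyz[2], vox_xyz[2], nz)
        ylo, wy, ty = _axis_weights(cy, sig_xyz[1], vox_xyz[1], ny)
        xlo, wx, tx = _axis_weights(cx, sig_xyz[0], vox_xyz[0], nx)
        if 0 in (len(wz), len(wy), len(wx)):
            continue
        norm = tz * ty * tx
        patch = amount / norm * wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
        arr[zlo : zlo + len(wz), ylo : ylo + len(wy), xlo : xlo + len(wx)] += patch

    order = config.channel_order()
    ch_index = order.index(channel) if channel in order else len(order)
    rng = np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 1 + ch_index])
    if config.noise_poisson_gain > 0:
        gain = config.noise_poisson_gain
        arr = gain * rng.poisson(arr / gain).astype(np.float64)
    if config.noise_read_sigma > 0:
        arr += rng.normal(0.0, config.noise_read_sigma, size=arr.shape)
    return np.clip(arr, 0.0, None).astype(np.float32)


def generate_stack(
    config: SimulationConfig, provenance: Mapping | None = None
) -> tuple[dict[str, ChannelStack], GroundTruthTable]:
    """Plant sites and render every configured channel on a shared grid.

    Returns ``(channels, truth)`` where ``channels`` maps marker name to
    :class:`~synaptomap.stackio.ChannelStack` in the fixed channel order.
    """
    truth = plant_sites(config)
    geometry = config.geometry
    prov = dict(provenance or {})
    prov.setdefault("layer", config.layer_kind)
    channels: dict[str, ChannelStack] = {}
    for marker in config.channel_order():
        data = render_channel(truth, marker, config)
        channels[marker] = ChannelStack(
            marker=marker, data=data, geometry=geometry, provenance=dict(prov)
        )
    return channels, truth


def config_to_yaml(config: SimulationConfig, path: str | Path) -> Path:
    """Persist a simulation configuration as YAML."""
    d = {
        "layer_kind": config.layer_kind,
        "field_size_um": list(config.field_size_um),
        "voxel_size_nm": list(config.voxel_size_xyz_nm),
        "expansion_factor": config.expansion_factor,
        "class_densities": dict(config.class_densities),
        "marker_rules": {k: list(v) for k, v in config.marker_rules.items()},
        "antigen_models": {
            k: {"prob_positive": m.prob_positive, "median": m.median, "sigma": m.sigma}
            for k, m in config.antigen_models.items()
        },
        "antigen_marker": config.antigen_marker,
        "marker_amount_median": config.marker_amount_median,
        "marker_amount_sigma": config.marker_amount_sigma,
        "offset_scale_nm": config.offset_scale_nm,
        "punctum_sigma_xyz_nm": list(config.punctum_sigma_xyz_nm),
        "psf_sigma_xyz_nm": list(config.psf_sigma_xyz_nm),
        "noise_poisson_gain": config.noise_poisson_gain,
        "noise_read_sigma": config.noise_read_sigma,
        "edge_margin_nm": None if config.edge_margin_nm is None else list(config.edge_margin_nm),
        "channels": None if config.channels is None else list(config.channels),
        "seed": config.seed,
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)
    return path


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["field_size_um"] = tuple(d["field_size_um"])
    d["voxel_size_xyz_nm"] = tuple(d.pop("voxel_size_nm"))
    d["marker_rules"] = {k: tuple(v) for k, v in d["marker_rules"].items()}
    d["antigen_models"] = {k: AntigenModel(**m) for k, m in d["antigen_models"].items()}
    for key in ("punctum_sigma_xyz_nm", "psf_sigma_xyz_nm"):
        d[key] = tuple(d[key])
    if d.get("edge_margin_nm") is not None:
        d["edge_margin_nm"] = tuple(d["edge_margin_nm"])
    if d.get("channels") is not None:
        d["channels"] = tuple(d["channels"])
    return SimulationConfig(**d)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Same field conditions, different random seed."""
    return replace(config, seed=seed)
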