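#!/usr/bin/env python
"""Generate example simulated fields for the two tissue contexts.

Writes a molecular-layer field (GluD2 / PSD-95 / antigen) and a glomerular
field (ELKS / PSD-95 / antigen) as multi-channel TIFF stacks with their
ground-truth tables and configurations.  Image stacks are large binaries
and go to scratch/; a truth-table sample and the configs (text) go to
results/ for inspection.

Run from the repository root:  python analysis/01_simulate.py
"""

from pathlib import Path

from synaptomap.scenarios import glomerular_scenario, molecular_scenario
from synaptomap.stackio import write_stack
from synaptomap.synthgen import config_to_yaml, generate_stack

SCRATCH = Path("scratch/sim")
RESULTS = Path("results/sim")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    for name, cfg in [
        ("molecular", molecular_scenario(seed=1, field_size_um=(16.0, 16.0, 7.41))),
        ("glomerular", glomerular_scenario(seed=1, field_size_um=(12.0, 12.0, 7.41))),
    ]:
        channels, truth = generate_stack(cfg)
        write_stack(SCRATCH / f"{name}.tif", list(channels.values()))
        truth.to_csv(SCRATCH / f"{name}_truth.csv")
        config_to_yaml(cfg, RESULTS / f"{name}_config.yaml")
        truth.to_dataframe().head(40).to_csv(RESULTS / f"{name}_truth_sample.csv", index=False)
        counts = truth.class_counts()
        print(f"{name}: {cfg.grid_shape_zyx} voxels, {len(truth)} planted sites {counts}")
        print(f"  channels: {', '.join(channels)} -> {SCRATCH / f'{name}.tif'}")


if __name__ == "__main__":
    main()
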