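# synaptomap

Single-synapse proteomic mapping for expansion microscopy of the cerebellar
cortex: 3D puncta segmentation, marker-combinatoric synapse classification,
synaptic-vs-extrasynaptic partitioning in granule-cell-layer glomeruli, and
per-animal quantification with ANOVA reporting — validated end to end on
synthetic image stacks with planted ground truth.

## The problem

Tissue expansion (MAP, ~4× linear) makes single synapses resolvable by
ordinary light microscopy, so the composition of individual postsynaptic
sites can be mapped across synapse types. The analysis this package
implements classifies each segmented cluster field by marker logic —

* molecular layer: **PF-PC** synapses are GluD2⁺ (a subset also PSD-95⁺),
  **nonPF-PC** synapses are PSD-95⁺ GluD2⁻; in the VGluT2 panel, **CF-PC**
  synapses are PSD-95⁺ VGluT2⁺ and **nonCF-PC** are PSD-95⁺ VGluT2⁻;
* glomeruli: **synaptic** clusters are PSD-95⁺ ELKS⁺, **extrasynaptic**
  clusters are PSD-95⁺ ELKS⁻

— where "positive for X" means the minimum cluster-to-cluster distance is
within 300 nm on the expanded scale (~75 nm biological), except the
deliberately strict extrasynaptic antigen criterion of 30 nm (~7.5 nm
biological). Per stack, the pipeline then computes for every synapse class
and antigen of interest:

* fraction of sites positive for the antigen,
* ratio of integrated intensity per synapse (positive sites, class A / B),
* ratio of integrated intensity per field (captures count × amount),
* cluster density per biological tissue volume,

normalizes intensities to each stack's channel mean, and averages all
stacks of one mouse so each statistical data point is one animal
(one-/two-/three-way ANOVA with Tukey, Šidák, or Dunnett post-hoc).

Because raw stacks for such studies are typically not deposited, the
package ships a first-class synthetic-data generator that plants synapses
of known class, position and antigen amount (Gaussian puncta, PSF blur,
Poisson–Gaussian noise) so every stage can be checked against ground truth:
segmentation exactness, classification accuracy, and recovery of planted
fraction-positive values and fold-enrichments.

## Worked example

```python
from synaptomap.scenarios import analyze_field, molecular_scenario
from synaptomap.quant import fraction_positive, intensity_ratio_per_record

cfg = molecular_scenario(seed=1, enrichment=4.0)   # GluD2 / PSD-95 / antigen
records, clusters, truth = analyze_field(cfg, "molecular_gluD2")
print(len(truth), "planted sites ->", len(records), "records")
print("fraction positive, PSD95+ PF-PC:", fraction_positive(records, "PF-PC", "PSD95+"))
print("PF-PC / nonPF-PC enrichment:", intensity_ratio_per_record(records, "PF-PC", "nonPF-PC"))
```

prints (seed 1):

```
149 planted sites -> 149 records
fraction positive, PSD95+ PF-PC: 0.9166666666666666
PF-PC / nonPF-PC enrichment: 4.374593068919769
```

i.e. in one 40 × 40 × 7.41 µm field every planted site was segmented and
classified, the planted 0.9 positivity of PSD-95⁺ PF-PC synapses was
estimated at 0.92, and the planted 4-fold PF-PC antigen enrichment came
back as 4.37 (single-field noise; over 10 seeds the pooled estimate is
within a few percent — see `results/recovery.csv`).

The numbered drivers under `analysis/` run the full narrative on simulated
cohorts (3 mice × 2 stacks per panel) and write their tables under
`results/`:

```bash
python analysis/01_simulate.py       # example fields + ground truth
python analysis/02_run_pipeline.py   # segment -> classify -> quantify, all panels
python analysis/03_recovery.py       # planted-parameter recovery grid
python analysis/04_stats.py          # mouse-level ANOVA + post-hoc tables
```

A `synaptomap` CLI wraps the same library
(`synaptomap simulate|segment|classify|quantify|stats|run`).

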