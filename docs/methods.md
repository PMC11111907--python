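# Methods

## Overview

`synaptomap` re-implements, as a tested pipeline, a single-synapse proteomic
mapping analysis for expanded (MAP-processed) cerebellar tissue. The analysis
chain is: 3D puncta segmentation per channel → marker-combinatoric synapse
classification with physical distance criteria → per-stack metrics
(fraction positive, intensity ratios, densities) → per-mouse aggregation →
ANOVA with post-hoc families. Because no raw microscope data are publicly
deposited for this kind of study, the pipeline is validated end-to-end on
synthetic image stacks with planted ground truth; the generator is
first-class, tested code.

## Physical scales and calibration

All image-grid quantities live on the *expanded* scale. A linear expansion
factor E converts to biological scale: `biological = expanded / E`, volumes
shrink by `E^3`. E is calibrated as the mean of post/pre length ratios over
landmark pairs (the software analogue of overlaying pre- and post-expansion
overview images). At E = 4 the two distance criteria used throughout —
300 nm for synaptic association and 30 nm for extrasynaptic association —
correspond to ~75 nm and ~7.5 nm biological scale. Density denominators use
the biological-scale field volume via a single (global-mean) expansion
factor; a per-sample mode is available
(`expansion_factor_mode` semantics: the factor is a field of
`VoxelGeometry`, so callers may supply per-stack values).

Axis convention: arrays are `(z, y, x)`, 0-based; a voxel's physical
position is its **center**, `(i + 0.5) * pitch`. The acquisition default is
50 × 50 × 190 nm (x, y, z) voxels over a 53 × 53 × 7.41 µm field.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the full optics of an Airyscan microscope:

* **Sites.** Per class, site counts are Poisson(density × field volume) and
  anchor positions are uniform — within the field minus a per-axis *edge
  margin* (default `3σ + offset + one voxel`). The margin exists because
  the analysis deliberately measures only complete synapses (edge-touching
  clusters are excluded), so the default generator plants only complete
  synapses; setting `edge_margin_nm=0` restores full-field uniformity and
  reintroduces edge losses.
* **Markers.** Each class renders a fixed marker combination (e.g.
  glomerular `synaptic` = PSD-95 + ELKS, `extrasynaptic` = PSD-95 only).
  The first marker anchors the site; partners and the antigen-of-interest
  are displaced by 100 nm (default) in a uniformly random direction — well
  inside the 300 nm criterion, so planted colocalization is unambiguous in
  sparse fields.
* **Puncta.** Separable anisotropic Gaussians whose per-axis σ is the
  quadrature sum of an intrinsic punctum size (default 0) and a PSF blur
  (default 80 × 80 × 200 nm), normalized so the integrated pre-noise
  intensity equals the site's true amount; border truncation loses mass
  rather than being renormalized away. Amounts are log-normal (σ = 0.5 for
  antigens, 0.4 for structural markers) because immunofluorescence punctum
  intensities are right-skewed.
* **Noise.** `y = gain · Poisson(x / gain) + N(0, σ_read)`, clipped at 0;
  defaults gain 1, σ_read 2. Antigen amount medians of 10⁴ (base) give the
  dimmest puncta of the log-normal ensemble peak SNR well above 10.
* **Determinism.** All draws derive from `SimulationConfig.seed` with fixed
  per-purpose substreams; identical configs reproduce identical stacks bit
  for bit.

Not modeled (and therefore not demonstrated by passing tests): glomerular
architecture (central mossy-fiber bouton, dendritic geometry, spatial
clustering of sites), chromatic shift, optical aberrations, background
autofluorescence, antibody off-target binding. Real tissue also has
spatially correlated site placement; uniform placement makes the
colocalization crosstalk estimate below *optimistic* for dense tissue.

### Default study conditions

Densities (per expanded µm³, E = 4): molecular layer PF-PC(PSD95+) 0.002,
PF-PC(PSD95−) 0.00675, PF-MLI 0.003, CF-PC 0.00075 — this fixes PF-PC at
2.33× nonPF-PC with 23% of PF-PC sites PSD-95-positive, at ~0.56 PF-PC
synapses per biological µm³, consistent with published molecular-layer
synapse densities. Glomerular: synaptic = extrasynaptic = 0.02. The
reference antigen models span the dynamic range of a stained panel:
positivity 0.9 / 0.25 / 0.5 across molecular classes with a configurable
PF-PC fold-enrichment (2/4/6 grid), and glomerular "AMPA-like"
(synaptic-dominant: 0.8 vs 0.3, 2-fold) and "NMDA-like"
(extrasynaptic-dominant: 0.2 vs 0.8, 6-fold) patterns.

## Segmentation

Molecular layer: suprathreshold (≥ t) voxels grouped by 26-connectivity;
components below `min_size` voxels discarded (pixel noise), components
touching any stack face discarded (incomplete synapses). Integrated
intensity always sums the *original* intensities of member voxels.
Granule cell layer: the same mask is split by a marker-controlled watershed
on the Gaussian-smoothed image; markers are local maxima greedily thinned to
a minimum physical separation (default 400 nm, anisotropy-aware), applied
per connected component. Components that receive no marker (plateaus) are
kept whole. An isolated punctum reduces exactly to the threshold result.

Defaults: threshold 6 (= 3 × read-noise σ; at this level the probability of
a ≥ 5-voxel 26-connected noise-only component is negligible, and puncta down
to ~2.5% of the default antigen amount distribution are still detected),
`min_size` 5 voxels, watershed smoothing σ = PSF σ. Thresholds are explicit
configuration; an Otsu-on-positive-histogram automatic mode exists for
unattended runs, and the values used are recorded in every `ClusterSet` and
run manifest.

## Distance semantics and classification

"Within d of X" uses the **minimum voxel-center distance** between clusters
(inclusive, ≤ d), computed exactly with a KD-tree and verified against the
exhaustive all-pairs oracle. Centroid distance is available as
`distance_mode`-style sensitivity alternative (`centroid_distance_nm`).
Rationale: centroid distance misclassifies large apposed clusters.

Rules (d_syn = 300 nm, d_extra = 30 nm, expanded):

* GluD2/PSD-95 panel: every GluD2 cluster → PF-PC (subclass PSD95+ iff a
  PSD-95 cluster is within d_syn); every PSD-95 cluster with no GluD2
  within d_syn → nonPF-PC. Antigen positivity is judged against the
  *defining* cluster.
* VGluT2/PSD-95 panel: every PSD-95 cluster → CF-PC iff VGluT2 within
  d_syn else nonCF-PC; antigen may associate via PSD-95 or the matched
  VGluT2 cluster. The two molecular panels are never merged into a
  four-marker classification (three imaging channels per acquisition).
* Glomerular panel: every PSD-95 cluster → GCL-synaptic iff ELKS within
  d_syn else GCL-extrasynaptic. A synaptic record is antigen-positive only
  if **one** antigen cluster lies within d_syn of the PSD-95 cluster *and*
  of an ELKS cluster of that synapse (the stricter reading; different
  antigen clusters for the two markers do not count). Extrasynaptic records
  use d_extra against PSD-95 alone.

A single antigen cluster may satisfy several nearby records; the reported
antigen intensity is the nearest qualifying cluster's, ties broken by lower
cluster id. Antigen intensities are normalized per stack (division by the
channel's mean integrated intensity) *before* classification, so ratios are
scale-free but fold differences are preserved.

## Metrics and aggregation

Per stack and class: fraction positive, mean normalized intensity over
positive records, summed intensity per field, and record density per
biological µm³. The per-field ratio factorizes exactly as
per-record ratio × positive-count ratio (tested as an identity). Undefined
metrics (no records, no positives) propagate as missing values, never 0,
and are excluded (and counted) in the per-mouse unweighted means. Each
statistical observation is one mouse.

## Ground-truth evaluation

Records are matched to planted sites by greedy nearest-centroid matching
within 300 nm (record anchor = defining cluster centroid). Reported:
precision, recall, class accuracy among matches, confusion table. Classes a
panel cannot see (e.g. PSD-95-negative PF-PC sites in the VGluT2 panel) are
excluded from recall.

## Statistics layer

Fixed-effects one- to three-way ANOVA via OLS with **Type II** sums of
squares (balanced designs unaffected; well-defined for unbalanced tables).
Post-hoc families: Tukey HSD (all pairs), Šidák (`1 − (1 − p)^m` over all
pairwise t tests, exact closed form), Dunnett (many-to-one against a
required reference level, exact multivariate-t distribution). Adjusted
p-values are clamped to be ≥ raw. Calibration is verified by simulation:
null two-way p-values are KS-uniform over 500 replicates, and a 5-SD main
effect with n = 6/group is detected in ≥ 95% of replicates.

## Validation problem sizes

Chosen so replicate recovery runs complete comfortably on one CPU:
molecular reference fields 40 × 40 × 7.41 µm (fold-grid variants
28 × 28 × 7.41 µm) and glomerular fields 20 × 20 × 7.41 µm, 10 seeds per
condition, giving pooled planted-site counts of several hundred to ~2000
per condition. Fraction-positive recovery is compared at ±0.05 (binomial SE
at these n is ≤ ~0.02) and fold-enrichment at ±15%.

## Known limitations

* **Thresholded integrated intensity is amount-dependent-biased.** A fixed
  intensity threshold clips a larger mass fraction from dim puncta than
  bright ones, so recovered fold-ratios are compressed or stretched by the
  ratio of captured fractions. At the default SNR this bias is ≤ ~6% and
  recovery stays within the ±15% band; at low amounts (peak within ~4× of
  threshold) it grows quickly. This is inherent to the thresholded-cluster
  measure, not to the implementation.
* **Distance-threshold colocalization crosstalk in dense fields.** At
  glomerular densities, bright antigen clusters (which extend far in z at a
  fixed threshold) can satisfy the 300 nm criterion for a *neighboring*
  site's record. This inflates the positive pool of the non-dominant class
  and biases its per-record mean upward — in the extrasynaptic-dominant
  scenario the synaptic/extrasynaptic per-record ratio is attenuated well
  beyond 15%. Quantitative fold-recovery is therefore validated in the
  sparse molecular geometry, while the dense glomerular scenarios carry the
  classification and qualitative per-field sign-pattern checks (which are
  robust to this crosstalk). The same caveat applies to the real analysis
  in dense neuropil.
* Watershed splitting quality depends on the smoothing σ and the minimum
  peak separation (400 nm default); coincident or sub-separation puncta
  merge by construction.
* The generator's planted classes are the panel's resolvable classes;
  PF-MLI vs PF-PC identity within nonCF-PC records is not inferred
  (impossible without genetic labels).
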