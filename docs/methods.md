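# Methods

## Scope and model

`mifcyto` analyses per-image cell-segmentation tables from multiplex
immunofluorescence (mIF) of tumor tissue — tongue squamous cell carcinoma is
the motivating setting — and stratifies patients into five tumor-immune
microenvironment immunotypes. The pipeline starts downstream of imaging:
spectral unmixing, nucleus segmentation, intensity thresholding and
tumor/stroma tissue segmentation are assumed done by the imaging software, and
marker calls arrive as booleans. Region areas are never inferred from cell
hulls (that would silently change densities); they travel in a per-image
metadata sidecar (CSV: `image_id, sample_id, stroma_area_mm2, tumor_area_mm2,
field_width_um, field_height_um`), with 1 mm² = 10⁶ µm² applied exactly.
Coordinates are centroids in µm, origin at the top-left of the field,
y increasing downward.

## Phenotype gating

Eleven markers (CD45, CK, CD4, CD8, Foxp3, CD68, CD163, CD66b, PD-1, PD-L1,
DAPI) gate each DAPI⁺ cell into exactly one of nine base labels (see
`mifcyto.phenotyping`). Conflicting multi-lineage combinations are resolved by
a fixed precedence — T-cell markers over myeloid markers over CD66b, and CD45
dominance over CK (CD45⁺CK⁺ cells are treated as leukocytes and counted as
anomalies in the log). CD45⁺CD4⁻CD8⁻Foxp3⁺ cells fall to OtherLeu: the Treg
definition requires CD4⁺Foxp3⁺. Unclassified (CD45⁻CK⁻) cells are excluded
from every denominator. The gating table is exportable (`gating_table()`) for
audit. Derived groups are unions: Leu = all CD45⁺CK⁻ labels,
panM = M1 ∪ M2, C/Tcon = CTL ∪ Tcon, allT = C/Tcon ∪ Treg; the partition
identities (panM = M1+M2 etc.) are asserted property-style in the tests.

## Parameter panel

Per sample, counts and areas are pooled across images and densities are
ratios of sums (`pooled`, the default) — robust to unequal field areas; a
`mean_of_images` mode averages per-image densities instead, since the original
report does not state its aggregation. Stromal densities (cells/mm²) use the
pooled stromal area; the tumor-cell density uses tumor-nest counts over the
pooled nest area. Leukocyte percentages are shares of the CD45⁺CK⁻ count;
checkpoint fractions are PD-1⁺/PD-L1⁺ shares of their parent subset (PD-1 on
T subsets, PD-L1 on tumor cells and macrophages only — a PD-L1⁺ neutrophil is
carried but never enters a parameter). Zero-denominator quantities are NaN
(missing), never 0. Values are stored unrounded; presentation rounding
(1 decimal, half-up) happens only in report helpers.

The 58-entry default registry is a **reconstruction** of the published
parameter axis set, whose exact enumeration is defined in prior work and not
restated: 20 densities, 10 %-of-leukocyte entries, 10 subset fractions,
7 checkpoint %-of-leukocyte expansions, 10 balance ratios, and the 100 CTL-nT
distance. It is user-editable via YAML.

## The 100 CTL-nT statistic

Per image, each CTL (any compartment — intraepithelial CTLs are included by
default, configurable upstream by filtering the table) is matched to its
nearest CK⁺ tumor cell by Euclidean centroid distance, and the statistic is
the mean of the 100 shortest per-CTL distances. With fewer than 100 CTLs all
are used (a hard failure would make sparse immunotypes unclassifiable); with
no CTL the statistic is missing. Queries run on `scipy.spatial.cKDTree`,
which is exact: equality with the all-pairs brute-force minima is asserted,
not approximated. Per-sample values average the defined per-image statistics
(median optional); undefined images are skipped with a warning.

## Immunotype decision tree

Cut points: Leu-D 2500 / 5000 / 7500 cells/mm² (the cohort mean ± 1 SD
rounded to the printed operational values; a `cohort_derived` mode recomputes
mean ± 1 sample SD from the data, clamping the lower cut above zero), C/Tcon%
and CTL% referenced to cohort means (fixed overrides allowed), and a 30 µm
CTL-nT cut. Decision order: (1) Leu-D < 2500 → V; (2) Leu-D > 7500 and
C/Tcon% > ref → I; (3) Leu-D > 5000 and CTL% > ref → II; (4) otherwise
CTL-nT > 30 µm with a verified band-like stroma-rich zone → IV, else III.
Choices made where the source description was genuinely open:

* **Which percentage gates which type.** C/Tcon% gates the top Leu band
  (type I) and CTL% the middle band (type II), both against cohort means, and
  top-band samples failing the C/Tcon% gate fall through to the CTL% gate —
  this keeps the tree exhaustive and reproduces the published case
  arithmetic. Both gates are configurable.
* **Boundary semantics.** All comparisons are strict as printed; equality at
  a cut point falls to the less-extreme branch. Asserted by boundary tests at
  exactly 2500, 5000, 7500 and 30.
* **Missing distance.** A sample with Leu-D at or above the low cut but no
  CTL anywhere has a missing statistic; it is treated as above the cut
  (absence of CTLs near tumor is the extreme of isolation) and flagged in the
  call's warnings.
* **Band verification.** The band flag is a human-supplied visual input
  (CSV column). `True` permits IV, `False` vetoes it, absent lets the
  distance criterion decide alone with a warning. Every call carries a full
  machine-readable rule trace.

Thresholds are fixed once per cohort before any call; classification is
deterministic.

## Statistics

Spearman rank correlations (pairwise-complete, average ranks for ties,
minimum 3 complete pairs, constant columns → missing) via pandas/scipy;
Kruskal–Wallis omnibus via `scipy.stats.kruskal`; the Dunn post hoc
(joint-rank z tests with tie correction, two-sided) is run **uncorrected**
and only when the omnibus p < 0.05 — a faithful-reproduction choice, with a
Holm switch off by default. Two-group contrasts use the two-sided
Mann–Whitney U test, exact when both groups have n ≤ 8 without ties and the
tie-corrected normal approximation otherwise. Count summaries round half-up
to 1 decimal. Under null simulations the battery's type-I error sits in the
binomial 99% band at α = 0.05 and the omnibus p-value passes a
Kolmogorov–Smirnov uniformity check (2000 replicates; asserted in the
acceptance suite).

## Synthetic tissue generator

Each simulated field is a 1000 × 1000 µm rectangle split by a straight
invasive front at x = 400 µm: tumor nest left (0.4 mm²), stroma right
(0.6 mm²). The half-plane geometry gives closed-form expectations (e.g. a
T-cell exclusion band of width w bounds every CTL-to-tumor distance below
by w). Placement is complete spatial randomness within compartments —
sufficient because the classifier consumes only densities and nearest
distances; a clustered placement would change neither systematically. Counts
per immune subset are Poisson(density × stromal area × mix fraction); each
sample draws one leukocyte density uniformly from its archetype range, shared
across its images (default 2 images/sample).

Archetype defaults (chosen once to be well separated across the tree, and
documented as the generator's study conditions): Leu-D ranges
I 8500–11000, II 5500–7400, III/IV 2600–4900, V 300–2400 cells/mm²; subset
mixes give type I C/Tcon ≈ 55% of Leu, type II CTL ≈ 28% with double type I's
neutrophil fraction (the published excess has no printed magnitude; doubling
is a free choice), types III/IV Treg/M2-skewed with CTL ≈ 6%, type V sparse
and myeloid-skewed. Type IV adds an 80 µm T-cell exclusion band and a denser
nest (5500 vs 4000 cells/mm²), mirroring its reported higher tumor density.
Per-sample checkpoint fractions are drawn from moment-matched Beta
distributions: PD-L1⁺/Tu mean 6.7%, SD 10.0% and PD-L1⁺/panM mean 24.0%,
SD 14.7% (cohort-calibrated; M1 and M2 share the sample's panM draw, making
their fractions perfectly correlated as observed in tissue); PD-1 fractions
(CTL 30 ± 15%, Tcon 20 ± 12%, Treg 25 ± 12%) have no printed values and were
fixed once. Optional marker noise flips each of the ten lineage/checkpoint
markers independently per cell; DAPI is never flipped (it defines an
analyzable cell). Default noise is 0 so that gating inverts the generator
exactly. All randomness flows from integer seeds through
`numpy.random.SeedSequence` spawning; identical master seeds give
bit-identical cohorts.

### What the generator does and does not emulate

It reproduces the archetypes' density bands, subset mixes, exclusion-band
geometry and checkpoint-fraction moments, so end-to-end tests demonstrate
that the pipeline arithmetic, spatial statistic and decision tree behave as
specified on data with known truth. It does **not** emulate the attraction
of CTLs to the invasive front in infiltrated tumors: under CSR the mean
nearest-tumor distance of a sparse stromal CTL population exceeds 30 µm for
type III too, so in synthetic cohorts the III/IV distinction is carried by
the band-verification flag (emitted as ground truth, `band_width_um > 0`)
exactly as the operational definition of type IV requires both the distance
criterion and visual verification. Passing recovery tests therefore validate
the classifier's logic, not the discriminative power of the 30 µm cut on
real tissue. Nuclear morphology, staining intensities and segmentation error
are out of scope.

## Problem sizes and numerics

Recovery experiments use 20 master seeds × 5 archetypes × 4 samples ×
2 images (≈ 200k cells per cohort), sizes at which Poisson noise at the
archetype range edges produces ≲ 0.5% boundary misclassifications, well
inside the ≥ 95% recovery requirement. Distances are float64 throughout; the
statistic's equality with brute force is exact, not toleranced. Percentage
sums are asserted to 1e-9; presentation rounding is decimal half-up (ties
away from zero), matching the published tables' arithmetic.

## Known limitations

* The parameter registry is a plausible reconstruction, not the original
  enumeration.
* Marker-conflict precedence is a package decision; the commercial software's
  resolution is undocumented.
* The generator's CSR placement understates CTL–tumor proximity for
  infiltrated archetypes (see above).
* Survival modelling, RECIST adjudication and treatment recommendation are
  out of scope; only printed-count arithmetic (response rates, survival
  fractions) is provided.
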