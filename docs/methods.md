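# Methods note

## The assay model

The package automates a centrosome/centriole cohesion readout from
fluorescence microscopy of blood-derived cells. The underlying biological
model: pathogenic LRRK2 kinase activity loosens the linkage between paired
centrioles (G1) and duplicated centrosomes (S/G2), shifting the distribution
of the distance *d* between the two pericentrin-positive structures outward.
The assay reduces each sample to

* per cell: *d* (μm, on the 2-D maximum projection) and the binary call
  *split* ⇔ *d* > τ with τ = 1.3 μm (strict inequality: the split class is
  defined as "more than" the threshold, so a cell at exactly 1.3 μm is not
  split);
* per sample: percent splitting = 100 × #split / #two-dot cells, and the
  deficit call percent splitting ≥ 20% (inclusive);
* per subject: vehicle and MLi2 samples, whose difference carries the
  kinase-dependence information.

Two scoring modes exist. `dual_marker_duplicated` counts only structures
positive for both pericentrin and γ-tubulin (bona fide duplicated
centrosomes; control regime ≈ 90% of cells within τ).
`single_marker_cc` counts every pericentrin dot, measuring centriole
cohesion in G1 as well (control regime: mean *d* ≈ 1.2 μm, ≈ 25% of cells
beyond τ, ≈ 60% of cells showing two dots).

### Choice of denominators

Percent splitting is computed over two-dot cells, not all included cells:
the inter-structure distance exists only when two structures are present.
One-dot cells enter only the companion statistic percent two-dot
(= 100 × #two-dot / #included), which is reported so that a shift in
splitting can be distinguished from a shift in duplication/detection. Cells
with more than two scorable structures are excluded with reason
`ambiguous_count` by default — picking a pair among ≥3 dots is arbitrary —
with `ambiguous_policy="two_brightest"` exposed for the alternative.

## Image analysis

* **Projection.** Maximum over z per channel; all downstream distances are
  2-D. Physical coordinates are pixel-center positions, `x_um = column ×
  pixel_size_um`, 0-based.
* **Nucleus segmentation.** Gaussian smoothing (0.3 μm) → Otsu threshold →
  hole filling → connected components ≥ 3 μm equivalent diameter. Touching
  nuclei are not split by watershed; the simulator guarantees a minimum
  center spacing, and on real crowded fields the border/ambiguity exclusions
  would absorb merges. Border-touching nuclei are flagged and excluded from
  scoring (truncated cells bias dot counts).
* **Mitotic exclusion.** Condensed-chromatin proxy: region mean DAPI
  intensity > 2.5 × the median nucleus intensity of the field AND (solidity
  < 0.9 OR area < half the median nucleus area). The generator renders
  mitotic figures as paired bright small blobs at 4× nuclear intensity so
  this criterion has unambiguous signal after PSF blur.
* **Spot detection.** Scale-normalized Laplacian-of-Gaussian at the expected
  dot σ (0.15 μm ≈ confocal PSF at a 63×/1.4 NA objective), local maxima
  with ≥3 px separation, threshold = max(absolute floor, 0.3 × strongest
  response, 6 × robust MAD noise of the response). The MAD term suppresses
  false maxima on blank/noisy fields (expected extreme of ~10⁶ Gaussian
  samples is ≈ 5σ). Subpixel refinement by background-subtracted center of
  mass in a 9×9 window; measured localization error on noiseless renders is
  ≤ 0.01 μm, comfortably under the 0.05 μm tolerance the scoring requires.
* **Dual-marker pairing.** Mutual nearest neighbors within 0.5 μm; the two
  markers decorate the same organelle, so larger separations indicate
  distinct structures. The paired centroid is the spot midpoint. Unpaired
  spots survive as non-dual structures (so decoy/single-positive dots are
  visible in diagnostics) but are never scorable in dual mode.
* **Cell assignment.** A structure belongs to the nucleus whose mask
  contains it (distance 0) or whose boundary is nearest, up to 5 μm;
  farther structures are dropped and counted. Exact ties go to the lower
  nucleus label, deterministically.

## The synthetic generator

`simulate_image_set` emulates coverslip fields of LCLs/PBMCs:

* nuclei as filled ellipses (mild eccentricity 0.85–1.0, uniform rotation)
  with class-specific diameter distributions — lymphocyte-like
  Normal(8.0, 0.8) μm and monocyte-like Normal(12.0, 1.2) μm, clipped at
  ±3 sd — blurred by the PSF;
* per non-mitotic cell one or two dots rendered as isotropic Gaussians
  (σ = psf_sigma_um); pair distances ~ Normal(mean, sd) truncated at 0 by
  resampling, orientation uniform in the plane, pair centered near the
  nuclear centroid;
* z-stacks are the same 2-D signal replicated over a thin z range
  (default 3 planes, 0.5 μm step) with independent per-plane noise, because
  the assay analyzes maximum projections only;
* noise: Poisson shot noise on signal + background, plus additive Gaussian
  read noise; both can be switched off for noiseless oracle fields;
* placement on a jittered grid with guaranteed center spacing of 2× the
  maximum nuclear diameter — deliberately sparse; overlap and crowding are
  out of scope;
* dual-marker mode adds a γ-tubulin channel with dots co-located with the
  pericentrin dots (0.02 μm jitter, well inside the pairing radius) plus
  Poisson(0.1)/cell/channel single-marker decoys placed 1.2–2.5 μm from the
  nucleus center, which must be rejected by the colocalization gate.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: overlapping/touching cells, kidney-bean monocyte
nuclear shapes, debris and dead cells, spectral bleed-through, 3-D PSFs,
depth-dependent aberrations, uneven illumination, and biological coupling
between cell state and dot intensity. Results on real micrographs depend on
segmentation and detection robustness that these fields do not challenge.

`simulate_cohort_scores` draws each subject's latent percent splitting from
a group-specific Normal truncated to [0, 100] (resampling), separately for
vehicle and MLi2 conditions, then binomially resamples at
`cells_per_sample` (default 175, the middle of the 150–200 band) so that
subject scores carry realistic counting error; `cells_per_sample=None`
gives the infinite-cell limit. The default cohort mirrors the study's group
sizes (10 control / 12 R1441G-PD / 9 R1441G-NMC / 7 G2019S-PD /
6 G2019S-NMC / 4 iPD). Group means are not printed in the source study;
the defaults place controls at 10 ± 3% (the ~10% dual-marker control
regime), mutation-PD groups at 40 ± 6%, NMC groups intermediate
(28–30 ± 8%), iPD at 35 ± 10%, and all MLi2 conditions back at 8–10 ± 3–4%,
reproducing the qualitative pattern: every carrier group above the 20%
deficit line under vehicle, full reversal under inhibitor.

## Blot quantification

Within-lane ratios (LRRK2/tubulin, pS935/tubulin, pS935/LRRK2,
Rab10/tubulin, pT73-Rab10/tubulin, pT73-Rab10/Rab10) are gain-free up to
per-band exposure, so cross-gel comparability is achieved by dividing by the
same ratio in the gel's internal-standard lane (the same control line run on
every gel); the standard's relative values are 1 by construction and any
per-gel scalar gain cancels exactly. Replicate lanes (independent cultures)
are averaged after normalization, since normalization must remove gel
effects first. Lanes with a zero denominator band are dropped with a
warning; a gel without a standard lane is an error naming the gel. The
LLOMe response is 100 × (pT73/Rab10[LLOMe] − pT73/Rab10[basal]) /
pT73/Rab10[basal], computed from within-gel ratios — the ratio is internally
controlled, so the cross-gel anchor would cancel anyway; samples with a
non-positive increase are flagged non-responders. pS106-Rab12 is accepted as
an optional column but no statistic is computed on it.

## Cohort statistics

Shapiro–Wilk per group (failures are logged, never auto-switch the test:
the reported statistics stay parametric), one-way ANOVA with Tukey's HSD
(studentized-range p-values via `scipy.stats.tukey_hsd`), classical paired
t on vehicle−MLi2 deltas (subjects missing a condition are dropped and
counted; all-zero deltas return t = 0, p = 1 rather than 0/0), Spearman rho
with average ranks for ties, and the ROC c-statistic computed by the rank
(Mann–Whitney) formula with ties weighted ½. The c-statistic implementation
is cross-checked in the tests against exhaustive all-pairs counting up to
n = 50 and against an independent library implementation. Test–retest
reliability is reported as the absolute percent-splitting difference between
replicate samples; no ICC is computed. No multiple-testing correction is
applied across the report tables.

## Numerical and design choices

* Strict `>` at the split threshold, inclusive `≥` at the deficit threshold
  (both follow the assay's verbal definitions).
* Distance histogram bin width 0.2 μm; edges start at 0 and extend one bin
  past the maximum, so counts always sum to the number of two-dot cells.
* Empty inputs: a blank image segments to an empty list (not an error); a
  sample with zero included cells raises, since percent splitting is
  undefined.
* Determinism: every generator consumes a single `numpy` Generator seeded
  from the config; identical config + seed is bit-identical, and derived
  seeds stay below 2³¹.
* MLi2 dosing metadata (50 nM / 2 h for LCLs, 200 nM / 30 min for PBMCs) is
  carried as annotation only and never alters computation.
* Problem sizes: the end-to-end verification runs use 2000 rendered cells
  per regime (split-fraction standard error ≈ 1 percentage point against a
  ±2 point acceptance band) and 5000 unrendered ground-truth draws for
  distribution-recovery checks; the narrative analysis scripts use 120–200
  cells per sample, matching the per-line cell counts the assay itself
  prescribes.

## Known limitations

* No watershed splitting of touching nuclei and no kidney-bean monocyte
  morphology; PBMC gating is by equivalent diameter (< 10 μm) only.
* 2-D distances underestimate true 3-D separation; this matches the
  projection-based assay definition but is not a physical distance.
* The LoG detector assumes near-diffraction-limited dots of similar
  intensity; very dim dots below the relative threshold would be missed
  (lowering `threshold_rel` trades false negatives for false positives).
* The mitotic heuristic is tuned to the generator's condensed-blob render;
  real prophase/anaphase figures are more varied.
* With decoys and close true dots, the mutual-NN gate can in principle pair
  a decoy with a true dot if the decoy falls within the pairing radius; the
  default decoy placement (≥1.2 μm from the nucleus center) makes this rare
  but not impossible — it mimics the real ambiguity of single-positive
  staining.
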