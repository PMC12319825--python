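# Methods

## Overview

`vipgradient` implements a seed-based resting-state functional-
connectivity analysis of the anterior–posterior axis of macaque area
VIP, validated end to end on a synthetic phantom with planted ground
truth.  Three seed ROIs (aVIP, mVIP, pVIP) are placed along the
intraparietal sulcus; the analysis asks which cortical territories are
functionally connected to each seed alone or to combinations of them,
and whether that territory changes gradually from anterior to
posterior.

The analysis chain is:

1. **Cleaning** of each run's masked voxel×frame matrix: framewise-
   displacement scrubbing, zero-phase Butterworth band-pass, nuisance
   regression of white-matter and ventricle traces.
2. **Connectivity**: per run, Pearson correlation of the seed ROI mean
   signal with every ipsilateral voxel, Fisher-transformed
   (z = arctanh r); per subject, across-run mean z with a one-sample
   t-test against zero (two-sided, α = 0.001 uncorrected); the subject
   map keeps mean z where significant and zero elsewhere; group map =
   unweighted across-subject mean.
3. **Surface**: each vertex of a tabular surface model copies the
   value of its unique source voxel; a seed's surface map is
   thresholded at z > 0.05 (strict, with a 0.03–0.07 robustness
   sweep); the three thresholded maps define an 8-way exclusive
   category per vertex (NONE, A, M, P, AM, MP, AP, AMP) with the
   conventional additive RGB code; composition percentages are
   computed per hemisphere and per lobar region; Spearman rank
   correlation between pairs of unthresholded group maps quantifies
   map similarity.
4. **Areal statistics**: per subject/hemisphere/area/seed, the
   fraction of the area's vertices above threshold and the mean
   supra-threshold z; per area, a Kruskal-Wallis test compares the
   three seeds' per-subject ratios (per hemisphere and pooled), with
   Benjamini-Hochberg correction across areas within each scope at
   α = 0.05; significant areas are classified by their preferred pole
   (aVIP vs pVIP).

## The phantom

No public dataset exists for this design, so the package ships a
first-class generator.  The phantom is a two-hemisphere voxel grid
(default 24×24×18 per hemisphere, ≈20,700 voxels, nominal 1.25 mm
voxels) partitioned into 8 lobar regions × 2 atlas areas, plus a VIP
ribbon of 13 consecutive coronal slices (6 voxels per slice) assigned
to the parietal region.  Seed ROIs follow the published construction:
5 voxels from each of 4 consecutive slices for aVIP and mVIP, 4 voxels
from each of 5 slices for pVIP — 20 voxels each, disjoint, ordered
anterior to posterior.

Signal model per voxel v and frame t:

    y_v(t) = w_a s_a(t) + w_m s_m(t) + w_p s_p(t)
             + g_amp g(t) + wm_amp c_v n_wm(t) + csf_amp d_v n_csf(t)
             + spike(t) + ε_v(t)

* `s_a, s_m, s_p, g` are independent band-limited Gaussian processes
  (white noise → hard DFT mask on [0.01, 0.1] Hz → unit variance).
  The hard mask puts all spectral power inside the analysis band, so
  planted correlations survive the band-pass.
* Loading triples `(w_a, w_m, w_p)` are constant within an area; the
  default design plants every one of the 8 categories at least once
  per hemisphere (anterior territory in prefrontal/motor areas,
  posterior in occipito-temporal, AM/MP belts, an AMP parietal core,
  NONE areas).  Weights are 0.5–0.8 against unit noise, i.e. per-run
  seed-voxel correlations around 0.4–0.6 — comparable to strong
  resting-state coupling.  Seed voxels load only on their own latent
  (weight 1.0), making each seed signal a clean readout.
* `n_wm, n_csf` are white traces with per-voxel couplings drawn from
  U(0.5, 1.5); they are recorded and handed to nuisance regression.
* Motion spikes occur independently per frame (default probability
  0.02), add a large shared offset, and elevate the framewise-
  displacement trace above the default 0.5 mm scrubbing threshold, so
  scrubbing removes exactly the corrupted frames.
* Defaults: 10 subjects × 8 runs × 300 frames at TR 2.0 s, matching
  the scale of the 10-animal study the phantom emulates;
  `--emulate-table1` instead draws per-subject run counts from the
  study's acquisition table (8–62 runs).

Reproducibility: every run's randomness derives from
`SeedSequence([rng_seed, subject, run])`, so a fixed spec yields
bit-identical datasets and pipeline reruns yield identical checksums.

### What the phantom does not emulate

No hemodynamic response, no spatial autocorrelation of the noise, no
head-motion geometry (only its censoring footprint), no mesh geometry
(vertices are table rows with exactly one source voxel each), and no
contrast-agent physiology — correlation analysis is symmetric under
joint sign inversion, so inverted hemodynamics would not change any
result.  Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct and calibrated, not that it
is robust to every artifact of real monkey fMRI.

## Numerical and design choices

* **Filter**: order-4 Butterworth applied forward–backward
  (zero-phase), band 0.01–0.1 Hz; series are demeaned before and after
  filtering so columns are exactly zero-mean.  An alternative low band
  (0.0025–0.05 Hz) is accepted by configuration; both published band
  variants are supported because the original mapping of band to
  dataset is unresolved.
* **Scrubbing**: framewise displacement > 0.5 mm (configurable);
  censored frames are dropped, never interpolated, and the band-pass
  runs on the concatenated kept frames.  Runs with > 50 % censored
  frames are excluded; subjects with fewer than 2 usable runs are
  dropped (the t-test is undefined).
* **Smoothing**: 1.5 mm FWHM Gaussian, mask-renormalized so constants
  are preserved at mask edges.  By default it is applied to run-level
  z-maps (`smooth_stage: map`); smoothing the 4D series instead
  (`timeseries`) is implemented and equivalent in expectation for
  these linear steps, but several times more expensive.
* **Correlation details**: |r| is clipped at 1 − 1e−7 before arctanh
  so self-correlated seed voxels stay finite; zero-variance voxels get
  z = 0 with a logged count; contralateral voxels are missing (NaN),
  never zero.  Seed aggregation is the unweighted ROI mean
  (`seed_agg: first_pc` switches to the first principal component).
* **Subject-level test**: two-sided, uncorrected α = 0.001.  Voxels
  with zero across-run variance get p = 0 (nonzero mean) or p = 1
  (zero mean).  Non-significant voxels contribute 0 to the group
  average — a documented convention; the alternative (dropping them)
  changes group values only at sparsely-significant voxels.
* **Threshold semantics**: strictly greater than z = 0.05; the
  0.03/0.05/0.07 sweep produces nested supra-threshold sets by
  construction, which the pipeline verifies and reports.
* **Kruskal-Wallis**: tie-corrected H with the χ²(2 df) approximation
  (n = 10 per group by default).  The pooled scope concatenates left
  and right hemisphere observations (2n per group), treating them as
  independent samples.  The BH family is all areas within one scope.
* **Preference**: among significant areas, the pole seed (aVIP or
  pVIP) with the higher pooled mean ratio wins; a relative difference
  below 10 % counts as "both"; areas significant in exactly one
  hemisphere are judged by mean supra-threshold z instead.  The middle
  seed is never a preference pole — it is the gradient's midpoint.

## What the recovery tests check

`score_recovery` carries the planted per-voxel category to the surface
through the projection and compares it with the estimated category
map: overall accuracy, an 8×8 confusion table and per-category
sensitivity.  On the default phantom the pipeline recovers ≈91 % of
vertex categories; the residual errors sit at area borders, where the
1.5 mm smoothing kernel legitimately mixes neighboring areas' signals
(NONE and AP categories lose the most).  The gradient signature —
Spearman similarity between the aVIP and mVIP maps exceeding that
between aVIP and pVIP — follows from the planted AM/MP overlap belts.

The seed-bearing VIP ribbon is excluded from the "planted AMP areas
are non-significant" recovery check: its 60 seed voxels are perfectly
correlated with their own seed, which makes the three within-area
ratios systematically unequal for reasons unrelated to the planted
area-level design.

Problem sizes used by the automated checks: the test suite runs most
properties on a ~1.9k-voxel phantom (4 subjects × 4 runs) and the full
end-to-end recovery on the default ~20.7k-voxel phantom, 5 replicate
seeds; `scripts/acceptance.py` uses 3 replicate seeds.  Null
calibration (all loadings zero) verifies that the subject-level
α = 0.001 mask flags ≤ 0.5 % of truly unconnected voxels.

## Known limitations

* The vertex model has no geometry, so no cluster-level or
  smoothing-aware inference on the surface is possible (none is used).
* Group-level inference is a fixed convention (masked mean), not a
  random-effects model.
* The pooled-hemisphere Kruskal-Wallis treats hemispheres of one
  animal as independent, which is anticonservative under strong
  inter-hemispheric correlation; a per-animal-average alternative can
  be obtained by pre-averaging the ratio table.
* With 8 runs per subject the per-subject t-test (df = 7) is the
  power bottleneck; at 4 runs (df = 3) detection of weak loadings
  (w ≈ 0.5) degrades sharply.
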