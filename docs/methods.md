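# Methods

## The model

Activation network mapping treats each included study as a single
experiment summarised by its reported peak coordinates. The inferential
object is not the peaks themselves but the resting-state network they
seed: in a normative connectome of N participants, the seed-to-voxel
Fisher z maps of one study form a sample of size N, and "the study's
network" is the set of voxels whose z values are significantly positive
across that sample. Group-level maps then aggregate over the E studies of
a group in two complementary ways:

- **Overlap branch.** Per study: voxelwise one-sample t across the N
  participants' z values, binarized at a fixed critical t; group network =
  voxels significant in strictly more than a fraction f of studies. The
  strictness matters: with f = 0.60 and E = 18, count 10 (55.6%) fails and
  count 11 (61.1%) retains, so the minimal retaining count is 11.
- **t branch.** Per study: the participant-mean Fisher z map; group map =
  voxelwise one-sample t of the E mean maps against zero, df = E − 1,
  thresholded at the same critical t.

Assumptions worth stating explicitly: studies are treated as exchangeable
experiments (no weighting by sample size or quality); all peaks of a study
feed one seed (no per-contrast splitting); and the connectome stands in
for the population the studies sampled.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `radius` | 6 mm | sphere radius around each peak; closed ball on voxel-center distance in world mm |
| `t_threshold` | 5.66 | fixed critical t applied at both statistical levels |
| `alpha` | 0.05 / n_mask_voxels | voxelwise Bonferroni level, used when `threshold_mode="alpha_derived"` |
| `overlap_fraction` | 0.60 | strict retention fraction (count/E > f) |
| `contrast_mode` | `set_difference` | or `proportion_test` / `two_sample_t` |
| `similarity_operands` | `unthresholded` | overlap-fraction vs t volumes; `binarized` switches to retained masks |
| `include_seed_voxels` | true | whether a seed's own voxels keep their z values in its maps |
| `tal_transform` | `lacadie` | Talairach→MNI affine; `brett` selects the piecewise transform |

The fixed threshold 5.66 is kept as an opaque constant applied at both
levels, although the two levels have very different degrees of freedom
(participants − 1 per experiment vs. experiments − 1 at the group level)
and no standard Student-t quantile reproduces it exactly: for the
full-size 285,903-voxel mask, 0.05/285,903 = 1.7488 × 10⁻⁷ and the
two-sided critical value at df = 999 is 5.26. `threshold_mode="alpha_derived"`
exposes the df-consistent alternative, and both the alpha and the derived
quantile are reported by the acceptance script so the discrepancy stays
auditable.

Design choices made where the procedure was genuinely open:

- **Sphere membership** is a closed ball (≤ radius) on voxel centers — the
  common voxelization convention, and exactly testable against lattice
  enumeration (a 6-mm ball on a 2-mm grid has 123 voxels).
- **Seed combination** is a plain voxelwise union of the study's spheres on
  the pipeline grid; no external meta-analysis service is involved.
- **Contrast default** is the set difference of retained masks, because the
  group-comparison tables this style of analysis produces are defined on
  membership, not on a named statistic; two inferential modes
  (two-proportion z on overlap counts, Welch t on experiment-mean z maps)
  are provided for users who want p-values.
- **Similarity operands** default to the information-richer unthresholded
  volumes (overlap fraction vs. t); the manifest records the choice.
- **Seed voxels** stay in their own z maps by default: their
  self-correlation is informative for overlap with the seed region.

## Numerical policy

Voxelwise statistics read in-mask voxels only; out-of-mask voxels are
stored as 0 with the mask carried separately, so no NaN ever enters an
overlap count. Zero-variance voxel series get z = 0, and zero-variance
stacks get t = 0, both counted and logged — this keeps degenerate
synthetic inputs (constant series, all-zero stacks) well defined. Perfect
correlations are clipped at |r| = 1 − 10⁻⁷ before atanh so z stays finite.
Binarization and the overlap rule are strict (>). Peak extraction breaks
value ties by world-coordinate lexicographic order and rounds nearest-voxel
lookups half-away-from-zero, so reports regenerate byte-identically. All
pipeline volumes must share one grid; a mismatch is an error, never a
silent resample. Input NIfTIs are reoriented to canonical RAS+ on load.

The Talairach→MNI default inverts the published MNI→Talairach affine
numerically, so the round trip is exact to machine precision; the
piecewise alternative applies each hemisphere-of-z branch's inverse and is
exact within a branch (points near z = 0 can cross branches, a property of
the transform itself).

## The synthetic connectome

The generator emulates the *statistical role* of a preprocessed
resting-state reference sample: per participant, every in-mask voxel is
white Gaussian noise (σ_n), and each planted network adds its own latent
Gaussian series (σ_s) to all its voxels, giving expected within-network
correlation ρ = σ_s²/(σ_s²+σ_n²) and zero cross-network correlation.
Study foci are drawn from the target network's voxel centers with
isotropic jitter bounded by `foci_jitter_mm` (a jittered point whose
nearest voxel leaves the brain mask falls back to its unjittered center).
Per-entity RNG substreams — keyed (seed, role, index) — make generation
bit-reproducible and stable under growing the roster.

It deliberately omits hemodynamics, temporal autocorrelation, spatial
smoothness, motion and anatomy. Consequently, passing the recovery tests
shows the *pipeline logic* is correct — seeds land where foci are planted,
the statistics find genuinely correlated voxels and reject independent
ones, the overlap rule and contrasts behave as specified — but says
nothing about robustness to the noise structure of real fMRI, which an
analysis on a real connectome would have to establish separately.

The reference scenario used by the tests and the acceptance script is a
24³ grid at 4 mm with an inscribed-ellipsoid brain mask (~7,200 voxels),
24 participants with T = 120 timepoints, three disjoint 4×4×4-voxel
networks at σ_s = σ_n = 1 (ρ = 0.5), and 18 three-focus studies per group
with 2 mm jitter — NT studies all target one network, ASD studies another,
the third is untargeted. These sizes keep a full two-group run around ten
seconds on one CPU while leaving the fixed t = 5.66 threshold a genuinely
strict cut for N = 24 (the planted signal reaches t ≈ 29 at network
voxels, noise voxels survive with probability ≈ 4 × 10⁻⁶). With a single
target network per study and the strict 60% rule, at most one network per
group can be retained from 18 studies; the scenario uses that to make the
expected contrast exactly one network.

A known behaviour at small scale: because all of a group's studies seed
the same network, their experiment-level mean z maps are highly correlated
across studies, so the t branch (df = 17 over near-identical maps) retains
many weakly-connected voxels beyond the planted network. This is the df
inconsistency of the fixed threshold made visible, and it is why recovery
is scored on the overlap branch; the t branch is validated by its oracle
and degenerate-case tests and reported through the similarity statistic.

## Known limitations

- Real AAL/Brodmann atlases are not bundled; labeling takes any
  grid-aligned integer NIfTI + TSV lookup.
- No cluster-extent, FDR or permutation inference — the method is
  voxelwise fixed-threshold by construction.
- Peak-table row selection in published analyses (near-duplicate rows, map
  ordering) is under-specified; `find_peaks` uses an explicit, deterministic
  rule (strict 26-neighbourhood maxima, 8-mm greedy suppression,
  lexicographic ties) instead of guessing.
- Anatomical peak locations and the published similarity values (0.65 NT,
  0.45 ASD) depend on the real 1000-participant connectome and are not
  reproducible from synthetic data; the package reports its own computed
  similarities instead.
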