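# Methods

This note documents the models, conventions and numerical choices behind
`fibropet`: what the quantification chain assumes, what the digital phantom
does and does not emulate, and where the design was genuinely open.

## Quantification chain

### Lung segmentation

Manual 3D lung regions are replaced by an automatic procedure so results
are reproducible and testable:

1. body silhouette = largest connected component above −500 HU, hole-filled;
2. lung candidates = voxels below −300 HU inside the body;
3. keep the largest one or two candidate components above 0.05 mL (two
   components when the left and right fields are disjoint);
4. binary closing (ball radius 4 voxels) followed by hole filling, clipped
   back to the body.

Step 4 is what keeps dense consolidations inside the lung region: a large
lesion surrounded by a thin aerated shell is a "hole" only while the shell
is unbroken, and CT noise (SD 30 HU) breaks a 2-voxel shell somewhere along
a big lesion almost surely. A closing radius of 4 voxels bridges those
breaks; it is configurable, and radius 4 at the default 0.25 mm grid (1 mm)
is small against the ~5 mm lung semi-axes. The candidate threshold −300 HU
sits near the midpoint of aerated lung (−600) and soft tissue (+40), which
keeps the PSF-blurred boundary crossing within a fraction of a voxel of the
true pleura (Dice ≥ 0.99 against the phantom's analytic lungs).

Voxels inside the anatomical lung but outside the −800..300 HU analysis
range stay in the region for mean-lung-density purposes and are classed
out-of-band. The −100 HU value shared by the two density bands is assigned
to the high-density class (half-open split), so the classes partition the
lung exactly.

### Uptake metrics

PET volumes carry activity concentration at acquisition start,
decay-uncorrected; every metric first references activity back to the
injection time with the F-18 half-life (109.77 min, physical constant).
Keeping the correction explicit in the analysis (rather than baked into the
volumes) makes it testable: one half-life gives exactly a factor 2.

Tissue density is 1 g/mL throughout, giving the voxelwise identity
SUV = %ID/g × weight / 100 that the tests assert to float precision.

* **MLV threshold.** The baseline threshold is mean + 2 SD of day-0 FDG
  lung SUVs. The scope of that SD is genuinely ambiguous (across-animal SD
  of per-animal SUVmean, or the voxel-level spread); the default pools the
  lung voxels of all baseline scans, because only that choice makes the
  threshold an honest 2-SD upper tail of healthy-lung voxels — control
  scans then exceed it on ~2.3% of voxels by construction, at any noise
  level. The across-animal scope remains available (`sd_scope="animal"`).
  The threshold is strict (`>`): it is an exceedance bound.
* **HLV.** Defined on FMISO only (the code refuses FDG scans). The printed
  form "background × 1.4" is read voxelwise — a voxel is hypoxic iff its
  value is ≥ 1.4 × the background-region mean — because a scalar ratio
  cannot delineate a voxel set, and the voxelwise tissue-to-background cut
  at 1.4 is the standard FMISO convention. The comparison is ≥ (a ratio
  convention, unlike the MLV bound). Both conventions are configurable.
* **Background region.** No anatomical definition is imposed; the phantom
  emits a paraspinal muscle mask and real studies supply their own. LTBR is
  scale-invariant (identical on kBq/mL, %ID/g or SUV maps).
* **Density-gated uptake** reports the class mean over aerated and
  high-density voxels separately; an absent class is reported as missing,
  never as zero.

### Longitudinal statistics

FDG and FMISO sessions run on consecutive days; analyses merge day pairs
8/9, 15/16, 22/23 onto nominal days 9, 16, 23. The progression score is
ΔCT^D9–D23 = MLD(D23) − MLD(D9), accepting the nearest imaging day within
±1. Fold changes are ratios of group means; for MLD they are computed on
the HU + 1000 scale, a physical-density proxy (water = 1000) — a ratio of
signed HU values has no meaning. Correlations are Pearson (the predictive
analyses are linear fits; Spearman is available). Group comparisons are
two-sided Mann-Whitney (exact for small tie-free samples, matching
exhaustive enumeration) or Kruskal-Wallis for >2 groups; all-tied inputs
return p = 1. No multiple-testing correction is applied; raw p-values carry
the 0.05/0.01/0.001 star convention.

## The phantom

### Anatomy and imaging

A soft-tissue cylinder (40 ± 30 HU) on a 96³ grid of 0.25 mm voxels
contains two ellipsoidal aerated lung fields (−600 ± 50 HU, ~1.1 mL
combined) and a dorsal paraspinal muscle region used as the PET background.
CT and PET have separate point-spread functions (0.4 mm and 1.2 mm FWHM
Gaussian) reflecting the order-of-magnitude resolution gap between the two
scanners; noise is multiplicative Gaussian on PET (CV 5%) and additive on
CT (SD 30 HU), both after blur, plus pre-blur tissue texture. Volumes are
emitted as already-reconstructed, calibrated images: no sinogram,
attenuation or motion physics.

### Disease model

Consolidations are a few blob-shaped lesions seeded in the lung interior
(kept ≥ 0.75 mm inside the pleura so they remain enclosed by aerated
tissue). The lesion-volume time course rises from onset (day 7) through
milestones {day 9: 25%, day 16: 90%, day 23: 100%} of the end-of-study
volume — the rise-then-stabilise shape of the model's fibrotic phase.
Ground truth is defined on the noiseless blurred CT: a voxel is lesional
iff its HU reaches the −100 HU consolidation band inside the lung, and blob
radii are solved by bisection so the realized burden matches the trajectory
(the realized lesion is therefore exactly what a perfect reader of the
emitted CT would call consolidated, and the aerated fraction equals
100 × (1 − burden) up to PSF effects).

Each animal draws an aggressiveness multiplier (log-normal, unit mean,
σ = 0.25) that scales *post-day-9* growth only: day-9 anatomy is common to
the arm while outcomes diverge. Cohorts draw these multipliers by shuffled
quantile-midpoint stratification, which preserves the across-animal spread
(the substrate of the early-marker correlations) while freeing group means
of Monte-Carlo noise.

The hypoxic halo is the territory destined to consolidate: the untreated
end-of-study lesion extent dilated by a 0.5 mm shell, minus the current
lesion. It is aerated on CT by construction, FMISO-avid from day 9, and
every voxel that consolidates between day 9 and day 23 was halo at day 9 —
the phantom's encoding of peri-lesional hypoxic patches that later fibrose.
Halo intensity couples to aggressiveness (coefficient 0.5 on the excess),
so day-9 FMISO uptake carries the progression signal that day-9 CT and
day-9 FDG (onset day 15, lesion-only) lack.

### Uptake and therapy

True %ID/g is piecewise constant by tissue class. Both tracers use a
neutral soft-tissue background equal to normal lung (FDG 1.0, FMISO
0.5 %ID/g) so pleural partial-volume spill cancels out of group ratios;
absolute levels are conventions, as only fold changes are anchored.
Lesion/halo multipliers switch on at the tracer's onset day (FMISO day 9 in
lesion and halo; FDG day 15, lesion only).

Therapy (from day 9) has two calibrated effects: a growth multiplier
(0.172, both arms — both produce the same 1.2× CT effect) applied to
post-day-9 lesion growth, and per-arm per-tracer multipliers on the
lesion/halo uptake excess from the first post-treatment session
(pirfenidone FDG 0.015 / FMISO 0.22; nintedanib FDG 0.33 / FMISO 0.23).
The uptake multipliers are required, not optional: a pure growth effect
cannot push treated lung FDG *below* control, which is what a 2.9-fold
decrease from a 2.6-fold elevation implies; the near-zero pirfenidone FDG
multiplier encodes metabolically silent residual consolidations. Day-8/9
scans are treatment-naive. All defaults were calibrated by running the
full pipeline (not the truth values) on 8-animal arms and averaging three
seeds; recovered fold changes sit within ±2% of the nine targets, and the
ground-truth ratios within ~5% of them (truth and recovery differ by
residual partial-volume effects).

### What the phantom does not emulate

Respiratory/cardiac motion, attenuation and scatter, airway trees and
vasculature, heterogeneous lesion texture, kinetic (time-activity)
behaviour, body-weight variation (fixed 20 g), and inter-animal baseline
uptake variability (scan-level dose jitter exists but defaults to 0 because
any scan-level random effect makes the day-0 mean+2SD threshold's
false-positive rate heavy-tailed in small cohorts). Passing tests therefore
show that the chain is correct and well-calibrated on images with this
statistical structure — not that it is robust to motion artefacts, kinetic
confounds or anatomical variability in real scans.

## Numerical choices and degenerate inputs

* Lesion bisection: 14 halving steps on a monotone voxel count, upper
  bracket at the destiny solve so results are independent of which sessions
  are generated; if the allowed interior saturates, the largest feasible
  lesion is used (burden additionally capped at 0.45).
* Determinism: every random stream is keyed by (animal seed, day, channel),
  so identical seeds give bit-identical volumes and subsets of sessions
  reproduce exactly.
* Problem sizes in the validation suite: unit tests run on a 64³ grid with
  the same field of view; the end-to-end checks use the default 96³ grid
  with 8–10 animals per arm and two sessions, and the replicate-based
  prediction check uses 20 cohorts — sizes chosen to exercise the full
  chain at the study's own scale.
* Degenerate inputs raise rather than guess: empty masks, zero doses or
  weights, negative elapsed times, overlapping density bands, FDG scans
  passed to the hypoxic-volume routine, all-tied group comparisons
  (p = 1 by convention), constant vectors in correlations.

## Known limitations

The calibration anchors group-mean contrasts at the final session; interim
sessions (day 9/16 levels) follow from the trajectory shape and are only
direction-checked. MLV/HLV absolute volumes depend on the phantom's noise
level and are validated as directions and bounds, not magnitudes. The
segmentation is tuned for mouse-lung geometry at 0.2–0.5 mm voxels; human
or rat data would need re-tuned thresholds and closing radius.
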