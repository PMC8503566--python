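# Methods

## Problem and model

`mvba` asks whether an individual's brain differs focally from a reference
group, using several co-registered MRI contrasts at once.  The design is a
single-case versus control-group contrast at every voxel: one patient value
$x_1$ against $N$ control values with mean $\bar{x}_c$ and sample standard
deviation $s_c$,

$$ t = \frac{x_1 - \bar{x}_c}{s_c\,\sqrt{1 + 1/N}} , $$

the pooled-variance two-sample t statistic with group sizes $(1, N)$.  All
inference is by permutation: under the null hypothesis that the patient is
exchangeable with the controls, every assignment of the "patient" label to
one of the $N+1$ subjects is equally likely.  A 1-vs-$N$ design admits
exactly $N+1$ distinct relabelings, so the permutation scheme enumerates
all of them whenever the requested permutation count allows (an exact
test); only when $N+1$ exceeds the request are assignments sampled without
replacement, identity first.  The per-analysis run log records the scheme
size and whether it was exhaustive.

Statistic maps are spatially enhanced with threshold-free cluster
enhancement.  For voxel $v$,

$$ \mathrm{TFCE}(v) = \sum_{h}\, e(v,h)^{E}\, h^{H}\, \mathrm{d}h , $$

where $e(v,h)$ is the size of the face-connected component containing $v$
in the excursion set $\{t \ge h\}$, with the standard volumetric exponents
$H = 2$, $E = 0.5$ and 6-connectivity.  The height integral is discretized
into `n_steps` equal steps up to the map maximum (`dh = max/n_steps`,
default 100 steps).  Because `dh` is tied to each map's own maximum, the
transform is a fixed function of the map and positive rescaling by $c$
scales every TFCE value by exactly $c^{H+1}$.

Family-wise error is controlled by the permutation distribution of the
in-mask TFCE maximum: the corrected p-value at $v$ is the fraction of
permutations (identity included, ties counted against rejection) whose
maximum reaches the observed TFCE at $v$.  This makes $p \ge 1/n_{\rm perms}$
and the procedure valid (never anti-conservative) by construction.  Note
the discreteness consequence: with $N$ controls the smallest attainable
p-value is $1/(N+1)$, so findings at $\alpha = 0.05$ require $N \ge 20$.

All tests are one-tailed.  A decrease analysis negates the data before
computing $t$; negative statistics are clamped to zero before TFCE.
Per-modality, per-direction analyses are reported separately and are not
corrected across directions or modalities.

## Non-parametric combination

The multimodal analysis combines FLAIR, FA, MD and NDI with the
non-parametric combination framework over *synchronized* permutations: the
same label assignment is applied to every modality.  Each modality's
statistic tensor is converted per voxel into empirical p-value analogs
(u-values) by self-inclusive rank,
$u_j = \#\{i : T_i \ge T_j\}/n_{\rm perms}$, and the modalities of each
permutation are combined voxel-wise with the Stouffer function

$$ T = \frac{1}{\sqrt{K}} \sum_{k=1}^{K} \Phi^{-1}(1 - u_k), \qquad K = 4 . $$

u-values are clamped above at $1 - 1/(2 n_{\rm perms})$ before the normal
quantile so the transform stays finite; the lower bound $1/n_{\rm perms}$
arises from self-inclusive counting.  The combined maps then receive the
same TFCE + max-statistic FWER treatment as a univariate analysis; TFCE is
applied to the combined map of each permutation, not to the per-modality
maps before combination (the single-combined-map reading of the workflow).
u-values are computed by a per-voxel rank (O(P log P)); the naive O(P²)
counter is kept in the test suite as an oracle.

Directionality: pathology raises FLAIR and MD and lowers FA and NDI, so
FLAIR and MD are multiplied by −1 and all four modalities are tested for a
concordant decrease.  GMC shifts in either direction depending on the
pathology and is therefore excluded from the combination (it remains
available univariately).  WMC is used only for brain-mask construction.

A property worth stating explicitly because it is easy to get wrong: a
$K = 1$ combination is *not* equivalent to the univariate analysis of that
modality.  The rank transform erases the magnitude of the statistic — every
permutation's u-map has the same marginal value set — so a single-modality
NPC retains only the spatial arrangement of ranks and has markedly less
power than the t-based analysis.  NPC's power comes from cross-modality
concordance: a voxel that is top-ranked in all four modalities
simultaneously is very unlikely under the null.  The test suite verifies
the true invariances instead (modality-order symmetry, invariance to
strictly monotone per-modality transforms).

## Preprocessing

The pipeline assumes spatially normalized, co-registered volumes on one
grid; headers are carried through but never used to resample.

- **FLAIR intensity normalization.**  FLAIR is not quantitative, so each
  scan is rescaled to make the robust mean (mean of values between the
  5th and 95th percentile, inclusive, linear-interpolated percentiles) of
  cerebellar white matter equal 1000.  The cerebellum serves as reference
  because focal pathology rarely involves it.  The operation is idempotent
  and invariant to positive rescaling of the input.
- **Smoothing.**  Separable Gaussian, default FWHM 8 mm
  ($\sigma = \mathrm{FWHM}/(2\sqrt{2\ln 2})$ per axis in voxel units),
  constant-zero boundary padding.
- **Brain mask.**  Per subject, voxels with GMC + WMC $\ge 0.5$ ("below
  0.5" excluded, so exactly 0.5 is retained); subject masks are averaged
  and binarized at mean $\ge 0.5$ (majority vote — the averaging threshold
  is a genuinely open choice and is exposed as `group_mask_threshold`).
- **Masking.**  Applied after smoothing; NaN inside the brain mask is an
  error rather than a silent zero, since silent zeros corrupt the control
  variance.

Ground-truth masks for electrode-localized cases are unions of 4 mm-radius
spheres around contact coordinates; a voxel is included iff its center
(voxel index × voxel size from the grid origin corner) lies within the
radius, inclusive.

## Synthetic cohorts

The generator emulates already-normalized multimodal data: each volume is
stationary Gaussian-smoothed white noise, restandardized so its sample SD
equals the modality's target exactly, around a modality-specific baseline
(FLAIR 250 a.u., FA 0.45, MD 8×10⁻⁴ mm²/s, NDI 0.55, GMC 0.45, WMC 0.35;
noise SDs 25, 0.04, 8×10⁻⁵, 0.05, 0.04, 0.04; correlation length 6 mm
FWHM).  Unit-range modalities are clipped to [0, 1]; baselines keep
clipping negligible.  The default grid is 32³ voxels at 2 mm — desk scale;
the statistical properties under test (exchangeability, FWER control,
relative power) are scale-free.  Tissue baselines sum to 0.8 so the
0.5-threshold mask keeps the interior; zero-padded smoothing erodes the
volume edge, giving the group mask a boundary.  Cerebellar WM is a config
box, standing in for an atlas segmentation.

Every volume is a pure function of `(seed, subject index, modality)`; the
null patient is simply the next subject draw, which makes patient-control
exchangeability exact — precisely the premise of the permutation test.
Lesions add a constant signed effect (in units of the modality's noise SD)
inside a sphere, with the pathology sign convention enforced (FLAIR/MD up,
FA/NDI down, GMC free).

What the generator does not model: anatomy, partial-volume effects,
non-stationary noise, inter-modality correlation within subject, scanner
artifacts, registration error.  Passing simulation suites therefore
demonstrates the statistical machinery is correct and calibrated under its
own assumptions, not clinical sensitivity on real MRI.

## Simulation suites and problem sizes

The statistical suites analyze the generator's fields directly: the
generator's 6 mm smoothness stands for the smoothed normalized data, so
re-applying the 8 mm kernel inside the suites would both double-smooth and
blur the planted sphere into a halo that the overlap metrics then punish.
The preprocessing chain is exercised by its own unit suites and by the
end-to-end pipeline tests, which run it in full.

Chosen problem sizes (all on 32³ grids): FWER suite, 200 null cohorts with
30 controls and the exhaustive 31-assignment scheme, for the univariate
decrease analysis and the 4-modality NPC; multimodal-gain suite, 50
replicates of a 1.5-SD concordant lesion (radius 8 mm) with 20 controls,
comparing NPC against each univariate analysis; recovery suite, 20
replicates of a 5-SD lesion requiring Dice ≥ 0.5.  The suites use a TFCE
grid of 32 height steps — the step count only coarsens the height integral
identically for every permutation, so exchangeability and the power
comparison are unaffected; closed-form TFCE checks use 200 steps.

## Numerical choices and degenerate inputs

- t at zero-variance voxels is set to 0 and counted in the run log
  (such voxels are masking artifacts; ±∞ would poison TFCE).
- The permutation t tensor is computed from leave-one-out sums after
  centering by the column mean, so the whole tensor costs barely more
  than one map and cancellation is controlled.
- Findings use strict `p < alpha`; tie counting in both the u-values and
  the FWER p-map uses `>=` (ties favor the null).
- NPC accumulates modalities in sorted name order so the mathematically
  symmetric sum is also bitwise order-independent.
- `robust_mean` falls back to the plain mean with a warning if a
  pathological percentile window retains nothing; Dice of two empty masks
  is defined as 0 with a warning.
- "Visual concordance" is operationalized as ≥ 1 overlapping voxel
  (configurable); cohort percentages are rounded to integers.

## Known limitations

- Exhaustive 1-vs-N schemes cap the permutation count at N+1; requesting
  10,000 permutations with 62 controls yields the 63 distinct relabelings.
  This is the exact test; tools that report more permutations for this
  design are resampling the same 63 assignments.
- The NPC TFCE placement (combined map per permutation) is one of two
  defensible readings of the workflow; applying TFCE per modality before
  combination would be a different estimator.
- No covariates, variance smoothing, or cluster-extent alternatives; the
  design is a bare two-group contrast.
- Manifest-driven runs require already co-registered volumes; nothing is
  resampled.
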