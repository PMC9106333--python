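# Methods

## Model and procedure

### Tracing arm

A retrograde injection case is summarised by per-area labeled-cell counts
`c_i` over the analysis groups of a cytoarchitectonic parcellation. The
connectivity strength `CS_i = c_i / c_total` is a composition (sums to 1), so
all inference is joint across areas by construction.

The chance model assumes a labeled cell is equally likely to sit anywhere in
the parcellated volume: cells fall into area *i* with probability equal to
its volume fraction `p_i`. One null replicate is a multinomial draw of
`c_total` cells over groups, converted to CS. Per group we summarise the
Monte-Carlo distribution by mean, sd and the central interval at `ci_level`
(default 0.95), using empirical percentiles with linear interpolation between
order statistics. Under this model the CS moments are known exactly —
`E[CS_i] = p_i`, `sd[CS_i] = sqrt(p_i (1 - p_i) / N)` — which is the oracle
the tests check the sampler against.

An area is **above chance** when observed `CS_i` strictly exceeds the upper
CI bound; ties are not flagged. This is a one-sided criterion on a central
interval (expected exceedance `(1 - ci_level)/2` = 2.5% per group under the
null), chosen because only elevated connectivity is of interest. The excess
ratio `CS_i / E_null[CS_i]` is reported for every group, flagged or not.

Replicate cases are compared by Spearman rank correlation over groups
(average ranks on ties, delegated to scipy). The p-value is a two-sided
label-permutation test (default 10^4 permutations, add-one corrected), an
explicit design choice since no method is implied by a rank correlation
alone.

Grouping of raw atlas areas into analysis groups happens *before* any
statistics; counts, CS and nulls all live at the group level. The shipped
grouping table maps 27 raw frontal/insular area names onto the 19 analysis
groups (13 frontal: 10, 25, 14, 11, 13, 24, 32, 46, 9, 8, 6m, 6d, 6v; 6
insular: OPAl, OPro, AI, DI, GI, IPro). Published atlases do not come with a
canonical volume table at this grouping, so volumes are treated as input
data; the shipped `default_parcellation.csv` carries synthetic but plausible
macaque area volumes (group fractions 0.012–0.122) and is used by the demos
and tests. Whether the supplied volumes are grey-matter or full-area volumes
is the caller's choice; the null simply uses whatever volume column arrives.

### Imaging arm

Seeds are spheres defined in world millimetres; a voxel belongs to a seed iff
its centre is within the radius (exact under anisotropic voxel sizes, which
are read from the affine), intersected with the brain mask. The seed series
is the unweighted mean over seed voxels. Each in-mask voxel with non-zero
temporal variance gets `z = arctanh(r)` of its Pearson correlation with the
seed series; `|r|` is clipped at `1 - 1e-7` so z stays finite. Zero-variance
voxels are marked invalid and excluded everywhere.

The seed-to-mask strength is the mean of `|z|` over the mask's valid voxels
("absolute average"). The alternative reading `|mean z|` is selectable
(`convention="abs_mean"`); mean-of-|z| is the default because it is directly
comparable with a chance level that cannot be negative. The chance null
permutes the valid-voxel z values uniformly across the brain volume and
recomputes the strength — equivalently, it scores a uniformly random
same-size voxel subset, which is how it is implemented (sampling without
replacement; the full-brain mask case degenerates to sd 0 automatically).
Summaries and flagging mirror the tracing arm. Seed/mask overlap fractions
are always computed and reported, never silently excluded.

### Preprocessing

Minimal per-voxel cleaning for the FC pipeline, all restricted to in-mask
voxels (out-of-mask voxels pass through untouched):

- **Detrend + grand-mean scaling**: least-squares removal of intercept and
  linear trend per voxel, then scaling by `target / g` with `g` the in-mask
  mean of the original intensities and `target = 100` (an arbitrary
  documented constant; scaling is skipped for zero-mean input).
- **Band-pass**: zero-phase Butterworth (order 2, applied forward-backward)
  with an exact FFT-mask alternative; presets 0.01–0.08 Hz (human profile)
  and 0.01–0.1 Hz (macaque profile); DC always removed; band edges validated
  against Nyquist.
- **Nuisance regression**: OLS residuals against regressors plus intercept;
  rank-deficient designs are rejected with the collinear columns named.
- **Spatial smoothing**: Gaussian kernel specified as FWHM in mm
  (`sigma = FWHM / (2 sqrt(2 ln 2))` per axis, converted to voxel units),
  mask-normalised (data and mask convolved separately and divided) so no
  signal bleeds across the brain edge and constants are preserved.

The pipeline applies detrend+scale, then smoothing, then band-pass. All
three operators are linear in the data and act on disjoint axes, so this
sequence realises the conventional detrend / smooth / normalize / band-pass
ordering; nuisance regression is available as a separate step for callers
with regressor tables.

## Synthetic data

The tracing generator draws multinomial counts with probabilities
proportional to `volume_fraction_i x enrichment_i` (renormalised); enrichment
1 everywhere reproduces the chance model exactly, which is tested by
two-sample comparison. The BOLD generator builds K latent network signals by
FFT-masking white noise into 0.01–0.08 Hz, orthogonalising (QR) and variance
normalising; voxel series are `baseline + sum_k loading_vk s_k + (1/snr) e`,
with smooth non-negative loading fields (Gaussian bumps, per-voxel loading
sums capped at 1) inside an ellipsoidal brain mask. Reference SNR is 1.0.

The demo layout plants one salience-like network spanning a "caudal 47/12"
seed site and two target masks ("dACC", "AI"), one distractor network with
its own seed ("area 44"), and five off-network seeds, on a 20x20x20 grid of
2 mm voxels with T = 300 volumes at TR = 2 s. Two layout choices deserve
explanation:

- **Mask purity.** A seed's series always carries a chance correlation with
  any latent signal (sd about `1/sqrt(m)` with `m` the number of resolvable
  Fourier modes in the band — about 84 here), and that chance correlation
  shifts every voxel of a network-pure mask *coherently*. A voxel-permutation
  null is an exchangeability null and cannot represent coherent map shifts,
  so against high-loading masks it is anti-conservative. The demo therefore
  places masks in the network's penumbra (bump peak 0.3 vs 0.9 at the seed
  site), where coherent chance shifts stay below the detection threshold
  while the planted seed's true effect (z around 0.3, about 2.7x the chance
  level) remains far above it. This is a real limitation of voxel-permutation
  nulls on spatially coherent maps, not an artifact of the simulation.
- **Seed placement.** Off-network seed centres are kept at least ~12.5 mm
  from every loading bump so that, at the default 3 mm radius, signal leakage
  into the seed sphere is negligible against the noise floor.

What the generator does *not* emulate: hemodynamics, motion, physiological
noise, spatial autocorrelation of the noise floor, multi-subject variability,
and template-space anatomy. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the generative model's
assumptions — not that real acquisitions satisfy those assumptions (real
data violate exchangeability more, in the direction discussed above).

## Numerical choices

- CI bounds: `numpy.quantile` linear interpolation; bounds are additionally
  clamped to bracket the Monte-Carlo mean so the summary invariant
  `ci_low <= mean <= ci_high` holds even in degenerate cases.
- RNG: one integer master seed per analysis; per-case/per-seed substreams are
  derived as `SeedSequence([seed, seed XOR crc32(tag)])`, so adding or
  reordering cases never perturbs another case's draws, and all outputs are
  bit-reproducible (tested byte-for-byte on the result CSVs).
- Multinomial null draws are accumulated in 10^5-replicate chunks (exact
  running moments + float32 draw matrix for the percentiles) to bound memory
  at the full 10^6-replicate profile.
- Fisher clipping at `|r| = 1 - 1e-7` maps perfect correlation to z about
  8.38 rather than infinity.
- Permutation subsets use generator `choice(..., replace=False)` per
  replicate; with mask size equal to the valid brain this reduces to a
  permutation of the full set and the null collapses to the observed value.

## Problem sizes and defaults

The null default of 10^6 replicates is the full-length profile; the package's
tests and the acceptance script run the same code at 10^4–10^5 replicates and
20 or 50 RNG replicates of the imaging study, sizes at which every Monte-Carlo
tolerance used in the tests (3 Monte-Carlo SEs, 5% on sds) is already sharp.
Tracing cases default to 2000 cells, in the range of retrograde counts in
frontal-cortex cases.

## Known limitations

- The voxel-permutation chance null understates variability for spatially
  coherent maps (see mask-purity note); observed off-network flag rates run
  slightly above the nominal 2.5% (about 3–6% in the shipped configuration).
- The tracing null conditions on the observed total count and ignores
  overdispersion across sections or animals; the type-I rate is calibrated
  only under multinomial sampling.
- Strict-exceedance flagging plus discrete counts makes per-group exceedance
  slightly conservative for small expected counts.
- `detrend` assumes a single continuous run; multi-run concatenation must be
  handled by the caller.
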