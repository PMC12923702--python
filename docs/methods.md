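# Methods

This note documents the models, estimators, and design choices behind
`taskfc`, and what the synthetic experiments do and do not establish.

## The analysis chain

The package implements a task-fMRI case-control analysis chain over
parcellated BOLD timeseries (by default 214 regions: 200 cortical parcels
in 8 canonical networks plus 14 subcortical regions, with a ninth
ventromedial "reward" network, VMN, that overlaps cortical membership):

1. **Task design.** Each condition's events (onset, duration, seconds)
   become a per-second boxcar, convolved with the canonical double-gamma
   HRF, h(t) = g(t; 6, 1) − g(t; 16, 1)/6 on a 32 s grid (unit peak,
   maximum near 5 s, undershoot near 15 s), and sampled at volume starts
   t = v·TR. A condition's volumes are those where the regressor reaches
   ≥ 50% of its maximum (configurable); this captures the HRF-lagged
   plateau of each block or trial. Both the convolved-threshold selection
   and the raw boxcar reading are supported; the convolved form is the
   default.
2. **miFC.** Connectivity between regions i, j is the mutual information
   I(X_i; X_j) in bits, estimated by a plug-in histogram on equiprobable
   (quantile) bins of each marginal (default 8 bins). Timeseries are
   z-scored (sample SD) before estimation; condition-restricted segments
   are re-z-scored after restriction so the estimator's input contract
   holds. Condition contrasts are entrywise differences of condition
   miFC matrices.
3. **Group inference.** Edge-wise two-sample t statistics (pooled
   variance; Welch by flag) with max-T permutation familywise control:
   labels are shuffled, max |t| over edges recorded per shuffle, and
   p_fwe = (1 + #{max ≥ |t|})/(n_perm + 1), two-tailed. Direction
   proportions, per-region degree over significant edges, eigenvector
   centrality (leading eigenvector of the nonnegative whole-task miFC
   matrix, Perron-oriented), and Cohen's d accompany the tests.
4. **Brain states.** Demean, band-pass 0.02–0.1 Hz (2nd-order
   Butterworth, zero-phase), Hilbert transform; at each volume the
   pairwise phase coherence is cos(θ_n − θ_p); each volume is labelled
   with the template network of highest within-template mean coherence
   (upper triangle, diagonal omitted; ties break to the first template in
   fixed order and are counted). Metrics: per-state lifetime (total
   assigned duration = probability × run duration, by definition) and
   probability; LZ76 phrase-count complexity and block-decomposition
   complexity of the 4-bit big-endian binarized label sequence; and
   transition (block) entropy H = −Σ p log2 p of the empirical
   (N+1)-gram distribution for orders N = 0..4.
5. **Receptor PLS.** Two molecular predictors (per-region receptor
   availabilities, z-scored then min-max rescaled to [0, 1]) against four
   functional responses (per-task eigenvector-centrality group
   differences, A−B orientation, and per-task degree maps;
   column-standardized) via PLS2 (NIPALS with deflation). Per component:
   share of the X'Y cross-covariance (squared singular values of the
   original centered cross-covariance — they partition ‖X'Y‖²_F exactly)
   and share of Y variance; VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² /
   Σ_a SS_a) so Σ VIP² = p. Spatial inference uses spin permutations:
   a uniform random rotation applied to one hemisphere's spherical
   centroids and its mirror image to the other, re-assignment by the
   minimum-total-distance bijection (Hungarian algorithm), and
   within-class permutation for subcortical regions, which cannot be
   rotated. The component-significance statistic is the cross-covariance
   magnitude the component captures (squared singular value of centered
   X'Y): alignment between predictor and response maps is what it
   measures, whereas share-type statistics are insensitive when the
   response block is internally low-rank (spins preserve Y's internal
   structure exactly). Spin p-values are two-tailed permutation
   probabilities (1 + #{|null| ≥ |emp|})/(n + 1).

## Synthetic cohort generator

The generator emulates a two-group (22 vs 25 subjects), two-task study:
an event-related monetary-incentive-delay task (84 trials; 4 s
anticipation drawn evenly from reward/neutral/loss, 1 s target, 2 s
outcome, 3 s ITI; 430 volumes at TR 2 s) and a block cue-reactivity task
(7 drug + 7 neutral 20 s blocks with 10 s rests; 220 volumes). Trial and
block timings are configurable stand-ins for a typical design, chosen so
every condition of interest yields at least 64 selected volumes (the
8-bins × 8-samples estimator floor).

Per subject and task: a hidden semi-Markov state sequence over the 9
networks (dwell = 10 s minimum plus an exponential with 20 s mean; no
self-transitions) marks the episodically dominant network. Each network
has a unit-SD band-limited (0.02–0.1 Hz) latent at 1 s resolution whose
amplitude is multiplied by 6 while dominant. A region's neural signal
is its own network latent(s) plus 0.15-weighted cross-network couplings
plus unit-free band-limited region noise (SD 2). Group effects multiply
specific network-pair couplings per group; condition effects do the same
only inside that condition's event windows (at neural time, before the
HRF — matching the causal ordering the convolved regressor assumes).
The neural signal is convolved with the canonical HRF, sampled at the
TR, rescaled to unit typical SD, and white measurement noise (SD 0.5)
is added.

Parcel geometry follows the spherical-registration convention: each
hemisphere's cortical parcels tile a full unit sphere (a deterministic
golden-angle lattice), with the left hemisphere the mirror image of the
right, so spherical rotations map a hemisphere onto itself; subcortical
centroids are mirrored interior points. Receptor maps are
Gaussian-process draws with a squared-exponential kernel (chordal
distance, length scale 0.5) evaluated in per-hemisphere mirror-aligned
coordinates, uniform homotopic cross-hemisphere coupling (0.5), an
independent white subcortical block (distinct nuclei, not samples of a
smooth sheet), and a 0.2 white nugget modelling parcel-level
measurement noise; draws are shifted by a fixed +5 SD to be
nonnegative, and VMN regions are multiplied by an enrichment factor
(3 for the MOR-like map, 2 for the D2DR-like map). This covariance is
exactly invariant under mirrored rotations of the two hemispheres, which
is what makes the spin null well-calibrated on synthetic maps: a naive
single-sphere GP couples the hemispheres through raw 3-D proximity, a
structure no rotation pair preserves, and inflates every spin test.

Calibration of the dominance episode (boost 6, region-noise SD 2) was
fixed at design time so that the generator actually exhibits its central
designed property — recoverable episodic network dominance: weaker
boosts leave every template phase-locked through its own latent and the
dominant state cannot win by a reliable margin. The scale of the BOLD
output is normalized because the HRF amplifies the infra-slow band about
five-fold, which would otherwise make the nominal measurement noise
negligible.

What the generator does **not** emulate: voxel-level structure,
physiological noise spectra (cardiac/respiratory), motion artefacts,
scanner drift, spatial smoothness of the *timeseries* (regions are
conditionally independent given the latents), or empirically realistic
receptor maps. Passing recovery and calibration tests therefore shows
the chain is correct and well-calibrated under its own model — not that
effect sizes or edge counts transfer to real cohorts.

## Statistical design choices

* **MI estimator.** The histogram plug-in on quantile bins is exact-
  deterministic, invariant under monotone transforms, and fast enough
  for all 22,791 edges of a 214-parcel atlas. Its known cost: it
  estimates the MI of the *binned* variables. For a bivariate Gaussian
  with ρ = 0.8 the population 8-bin quantile-binned MI is 0.636 bits vs
  the continuous 0.737 bits (−13.7%) — a quantization floor, not
  sampling error; sampling bias at T = 50,000 is only ~0.0007 bits.
  All pipeline claims are comparative (group and condition differences
  under a fixed binning), which this bias does not reorder. For
  absolute continuous-MI estimates the `scheme="knn"` (Kraskov) variant
  is provided and lands within ~1% on the same benchmark.
* **max-T.** p-values use the (b+1)/(n+1) estimator (never zero), and
  the permutation null adapts to between-edge dependence — which is why
  the planted-edge power study models a shared subject-level variance
  component (ρ = 0.5 of edge variance): realistic FC matrices are
  dominated by subject-level effects, and the adaptive null is what
  preserves power there. The power-study family (28 edges, 20 planted
  at d = 1.2 with n = 22 vs 25) was sized by an a-priori noncentral-t
  power analysis targeting ~0.85 expected sensitivity; with independent
  edges and large families the same effect is not detectable (power
  0.36 at 1,225 edges), which is a property of familywise correction,
  not of this implementation.
* **Eigenvector centrality** is computed per subject on the whole-task
  miFC matrix (nonnegative, so the Perron eigenvector is well-defined)
  via dense symmetric eigendecomposition; group difference is A-mean
  minus B-mean, orientation recorded in output metadata.
* **State lifetime** follows the total-duration definition (hence
  exactly proportional to probability); a mean-consecutive-dwell
  variant (`mean_dwell_time`) is provided separately and labelled
  distinctly. **Transition entropy** uses the block-entropy (joint
  (N+1)-gram) reading by default; a conditional-entropy variant
  (H(next | previous N) = H_{N+1} − H_N) is available behind a flag.
* **BDMC table.** True Coding Theorem Method values for 12-bit blocks
  are not redistributable here; the packaged table is a clearly labelled
  synthetic stand-in computed deterministically from each block's LZ76
  phrase count plus its adjacent-bit-pair entropy (K̃ = 2·C_LZ76 + H₂).
  It is monotone in structural complexity (periodic < random — which a
  pure bit-entropy fallback would violate for alternating blocks) but
  is not calibrated to algorithmic probability; BDMC values are
  comparable within this package only.
* **State-recovery scoring.** Recovered labels lag the neural ground
  truth by the haemodynamic response; accuracy is scored after shifting
  by round(5 s/TR) volumes (the HRF peak), and volumes within 2 volumes
  of a ground-truth transition are excluded (filter and HRF smearing
  make labels near switches undefined in principle).
* **PLS conventions.** Covariance shares come from the SVD of the
  original centered X'Y so shares sum to ≤ 100%; Y-variance shares come
  from the sequential NIPALS regression. Y columns are standardized
  before fitting because the four responses are on incommensurate
  scales (counts vs centrality differences). Component sign is fixed by
  making the largest-|w| weight positive. The spin-null matching rule
  (optimal bijection by total distance) is deterministic given the
  rotation; exact matches to other published matching rules are not
  guaranteed. Parcel-level spins retain a small irreducible
  anti-conservatism from resampling displacement (~0.14 chordal at 100
  parcels per hemisphere; observed mean null p ≈ 0.45 instead of 0.5
  for smooth independent maps), which the nugget in realistic maps
  keeps within the calibration tolerance of the test suite.
* **Determinism.** Every random draw flows from a single seed through
  named `SeedSequence` substreams (cohort, per-task edge permutations,
  dynamics permutations, spins); re-running a config reproduces
  byte-identical outputs, which the manifest checksums verify.

## Problem sizes used in the test-suite experiments

Null-calibration cohorts use 50 regions and 150 volumes (27-trial MID
variant) so that 500 full generate→miFC→max-T cycles run in minutes;
state-recovery and PLS experiments use the full 214-region default; the
end-to-end determinism check runs the full study size (47 subjects, 214
regions, both tasks, 1,000 permutations, 1,000 spins) twice. Spin-test
calibration re-uses one fixed set of spin maps across replicates (maps
depend only on geometry and seed, not on data).

## Known limitations

* The plug-in miFC values are binning-dependent (bits at 8 bins); use
  the k-NN scheme when absolute MI matters.
* The spin null treats subcortical regions as freely exchangeable,
  which ignores their spatial autocorrelation; this is the conventional
  fallback for non-spherical structures.
* BDMC uses a synthetic complexity table (above); LZC and transition
  entropy carry no such caveat.
* The generator's group effects act through network-pair coupling gains
  only; region-level or variance effects are out of its vocabulary.
* With overlapping templates (VMN), a region's contributions are
  counted in every network it belongs to, both in state templates and
  in network score averaging.
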