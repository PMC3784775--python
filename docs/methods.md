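# Methods

This note documents the models and procedures implemented in
`leechdendro`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not establish.

## Synthetic sessions

The generator (`leechdendro.synth`) emulates a semi-intact leech
preparation: 24 identified motoneurons (cells CV, L, 3, 109, 102, 119 on
the left/right DP and MA nerves of two ganglia; an extended roster adds
intermediate units 110 and 10), 25 Hz head/tail bead kinematics with a
reference point M at the dissected ganglion, sucker attachment traces,
and two connective channels (RC, CC).

**Behavior schedule.** A target mix of time fractions is laid out as
episodes covering the whole session; crawling episodes are integer
multiples of the crawl period (default 40 s, typical episode 4 cycles),
swimming/pseudo-swimming episodes ~60 s; the stationary remainder is
Dirichlet-distributed into the gaps and the episode order is shuffled by
the seed.

**Firing rates.** Each unit is an inhomogeneous Poisson process sampled
by Lewis–Shedler thinning from a per-unit substream of the master seed
(so enlarging the roster never perturbs existing trains).  Within
oscillatory behaviors the rate profile is a half-wave rectified sinusoid
— the simplest form producing the anti-phase contractor/elongator
structure of crawling — scaled by π/2 so the mean over the active phase
equals the tabulated rate; elsewhere profiles are piecewise constant.
The contraction/elongation phase tables (Hz):

| cell | class      | contraction | elongation |
|------|------------|-------------|------------|
| 3    | contractor | 5.72        | 0          |
| L    | contractor | 0.71        | 0          |
| CV   | elongator  | 0.18        | 1.56       |
| 102  | elongator  | 0.10        | 1.40       |
| 109  | elongator  | 0.20        | 2.12       |
| 119  | inhibitor  | 0.05        | 1.00       |

102 mirrors CV and the inhibitor 119 follows the elongators (no measured
values exist for them); intermediate units fire at 50% of their class
maximum in both phases.  During swimming cell 3 oscillates up to ~10 Hz
at the swim frequency (default 1.5 Hz) with 102 in phase and 109/119 in
anti-phase, while L and CV stay below 0.5 Hz; during pseudo-swimming
cells 3, 102, 109 oscillate between 1 and 3 Hz (0.5–2 Hz admissible
frequency), with 119 joining the cell-3 arm and 102 drifting out of
phase.  Exploring and peristalsis rates are placeholders (no measured
values; flagged in the config).

**Doubly-stochastic structure.** Plain piecewise-Poisson trains do not
reproduce two robust features of the recordings the analysis relies on:
movement elevates the *pairwise covariance* of all nerves, and resting
⟨AFR⟩ varies slowly while resting units stay uncorrelated.  Two
lognormal envelopes (mean 1) supply these: during movement every unit's
rate is multiplied by one shared "vigor" envelope (log-sd 0.5,
correlation time 10 s) plus a small common tonic drive (0.75 Hz);
at rest each unit follows its own independent envelope (log-sd 0.5,
8 s) times a population-wide excitability drift (log-sd 0.5, 120 s).
The drift is much slower than the 50 s covariance window, so it moves
the resting ⟨AFR⟩ around without creating within-window covariance —
which is precisely why ⟨ρ⟩ outperforms ⟨AFR⟩ as a rest classifier here,
as it does on real recordings.  Setting the envelope sds to zero yields
homogeneous Poisson trains (used by the dispersion and rate-recovery
tests).

**Kinematics and suckers.** Rest is constant position plus white
position noise calibrated through the velocity pipeline's gain so the
smoothed rest *speed* has RMS `velocity_noise_sd` (default 2.5 pix/s —
the σ of the 3σ stationary rule).  Crawling moves each bead out and back
by 200 px per cycle (head sucker released while elongating); swimming
oscillates both bead ordinates (±20 px) at the swim frequency with both
suckers detached; pseudo-swimming oscillates only the head with the tail
attached.  Peristalsis is deliberately sub-threshold slow motion in
state 0.

**Twin APs.** Connectives carry independent 1 Hz Poisson clutter; around
each head detachment, pairs with exact lag `twin_delay` (default 6 ms,
admissible 4–6) are injected — a rate ramp starting 8 s before the
detachment and a burst (~8 pairs/s for 1 s) at it — traveling tail→head
(caudal electrode leads).

## Analysis pipeline

**Rates and covariance** (`rates`): counts on half-open bins divided by
the bin width; the windowed unbiased cross-covariance uses the exact
1/(N−|m|) normalization, subtracts within-window means, averages lags
m ∈ [−5, 5], assigns the value to the window center, advances by one bin
by default, and drops incomplete windows at the record edge.  A
brute-force double-loop oracle pins the implementation to 10⁻¹⁰.

**Dendrograms** (`dendro`): Pearson distance (entries clipped to
[0, 2]), scipy agglomerative linkage.  Complete linkage is the default
(less noise-sensitive, valid for non-Euclidean dissimilarities); single
linkage is provided because parts of the original analyses used it — the
two disagree only in how loose units attach, and both are exercised
against an O(L³) oracle.  Zero-variance units are dropped with a warning
rather than assigned d = 1 (their correlation is undefined).  scipy's
deterministic merge order serves as the tie-break.  Episode
concatenation is raw (the Pearson distance is scale-invariant).
Cross-experiment average dendrograms average the rates of same-identity
cells within an experiment, then average the per-experiment
dissimilarity matrices element-wise over experiments (the averaging
order is not fully determined by precedent; element-wise matrix
averaging is the simplest choice that commutes with the idempotence
requirement).  `cut_tree(k)` undoes the k−1 highest merges.

**Similarity** (`simil`): pair counts from the contingency table;
B_k as the standard Fowlkes–Mallows geometric mean (the occasionally
printed extra *n* in its denominator is a typo in the source
literature); entropies and mutual information in bits.  Degenerate
conventions: identical partitions score exactly 1 (bypassing float
round-off); FM is 0 when no pairs are co-clustered; NMI is 0 (with a
warning) when exactly one entropy vanishes.

**Template matching** (`classify`): each 100 s window (2 s step) yields
a dendrogram over the template's leaves, cut and scored against the
template's cut.  Cut levels follow the behavior (k = 2 crawling, k = 6
swimming/pseudo-swimming).  The index is also paired per behavior:
NMI for k = 2 and Fowlkes–Mallows for k = 6, because each index's
*chance baseline* depends on cut coarseness — two unrelated balanced
2-cuts of 24 units share about half their pairs (FM ≈ 0.6 under the
null) while NMI at k = 6 with only 24 elements has a null mean near 0.5;
the chosen pairing keeps both null distributions safely below the 0.5
detection threshold that the swimming observations motivate.  Windows in
which a template unit never fires score 0 (the signature is absent).
Episode extraction takes maximal above-threshold runs, optionally
bridging brief dips (`merge_gap`) and eroding by half the window width
(`erode`), since a window overlapping an episode by half its width
genuinely carries the episode's signature.

**Window ground truth.** For rate computations (TPR/FPR), a window
counts as positive when it lies entirely inside an episode of the target
behavior and negative when it has zero overlap; boundary-straddling
windows have no single true label (and legitimately score high when
half-filled with the behavior) and enter neither tally.

**Discriminants**: Gaussian classifiers on the strict upper triangle of
the windowed covariance matrices (276 features for 24 units), PCA to
100 components when wider than that; linear (pooled full covariance),
diaglinear (pooled diagonal), quadratic, diagquadratic; empirical
priors; singular covariances raise with advice to reduce by PCA.  When
classifiers are compared, the discriminant kind is selected in ROC
space among the four variants, mirroring how such classifier families
are compared in practice.

**Twin detection** (`twinap`): candidate RC/CC pairs within the lag band
(edges padded by 1 µs against float round-off), processed by earliest
spike time with each spike used at most once — a deterministic greedy
rule chosen because no pairing rule is canonical; clutter spikes that
fall in the band are accepted (no waveform information in scope), which
bounds precision rather than recall.

## Experiment sizes

The test suite and acceptance script run on: 1200 s sessions (10 for the
recovery rates in the acceptance script, 5 in the test suite), one
2400 s training session providing 5 crawling template episodes, 3
repertoire sessions per classifier-ordering experiment, 10 seeds for
twin-AP recall/precision, and 100 seeds for the Poisson-dispersion
check.  All seeds are fixed (tests) or derived from `--seed`
(acceptance), making every reported number an exact rerun.

## Limitations

* Synthetic units within a functional class share one rate profile, so
  within-class sub-structure of real dendrograms (e.g. stronger
  left/right or adjacent-ganglion pairing) is not modeled; tests about
  sub-cluster identity below the class split would be meaningless here.
* Rest/movement envelopes are lognormal with fixed timescales; real
  excitability drifts are not stationary processes.
* Spike sorting is upstream of this package: the generator emits sorted
  spike times, and sorting errors (lost or merged units) are not
  simulated.
* The swimming 6-cut contains noise-driven blocks (the quiet L/CV
  units), so its max similarity against non-swimming windows is a max
  over thousands of null draws and fluctuates around 0.45–0.53 across
  master seeds.
* Peristalsis and exploring rates are placeholders; analyses of those
  behaviors characterize the pipeline, not the biology.
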