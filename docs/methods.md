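# Methods

`tvconn` is a fully synthetic benchmark for recovering time-varying directed
cortical connectivity from scalp EEG.  Everything in the pipeline — the
ground-truth network, the head model, the scalp data, the inverse solution,
the region-of-interest (ROI) time-series extraction, and the adaptive MVAR /
PDC estimators — is generated and evaluated by the package itself, so every
estimate can be scored against a known truth.

## Ground-truth network

The generative model is a 10-region visual spatial attention network
(V1 input; bilateral visual areas, intraparietal sulcus and frontal eye
fields; right temporoparietal junction, ventral frontal cortex/anterior
insula and middle frontal gyrus) driven as a time-varying MVAR process at
`fs = 256 Hz`:

    y(n) = sum_{k=1..p} A_k(n) y(n-k) + e(n)

Trials are 1200 ms long with a 200 ms pre-stimulus baseline (307 samples,
51 baseline samples).  The directed coupling schedule (the versioned fixture
`datasets/attention_model.json`) realizes 23 of the 90 possible ordered
region pairs:

* six interhemispheric couplings (VA, IPS, FEF left<->right), stationary with
  strength 0.5;
* the V1 input edges (lag 4 ms = 1 sample) and fifteen stimulus-driven /
  top-down edges (lag 16 ms = 4 samples), each with a stationary baseline of
  0.2 plus a raised-cosine bump of 200 ms duration, onset 100 ms
  (stimulus-driven and input) or 300 ms (top-down) after stimulus onset.

**Bump amplitude.** The bump peak is 0.15.  Larger peaks are impossible for
this edge set: the stationary baseline alone (0.2 web + 0.5 interhemispheric
pairs) has a companion-matrix spectral radius of 0.93, and any peak of 0.25
or more pushes the radius above 1 while the stimulus-driven bumps overlap.
With 0.15 the worst-case radius is 0.976, and stability is asserted at every
time bin when the model is built.  A consequence worth keeping in mind when
reading the benchmark results: the theoretical squared-PDC values of existing
connections are small (at most ≈ 0.19), so the error scores of competing
estimators sit close to the trivial all-zero predictor and discriminate the
estimators less sharply than a larger-amplitude network would.

**Visual input.** V1 carries a fixed AR(10) process
(`datasets/ar_input.json`) built from four complex pole pairs
(10 Hz/0.95, 20 Hz/0.8, 35 Hz/0.72, 55 Hz/0.68) and two real poles
(0.96, 0.7).  The resulting spectrum decays roughly as 1/f with an
alpha-band resonance, and Schwarz's Bayesian Criterion applied to a long
realization recovers order 10 — the two properties the fixture was designed
around.  Each trial draws an independent input realization (whether a real
experiment would share the input across trials is unknowable; independent
draws mimic trial-to-trial EEG variability).

**Innovation scaling.** At each time point the innovation standard deviation
is set from the instantaneous noise-free signal power of the MVAR-driven
channels so that the signal-to-innovation power ratio is 20 (a power ratio,
chosen for consistency with the scalp-level SNR definition below).  V1
receives no innovation; its series is the input process itself.  Because of
this, the nine driven channels carry the nominal ratio, which the acceptance
script verifies empirically across 1,000 trials.

## Forward model

The head is an analytic three-shell sphere (brain/skull/skin radii
80/85/92 mm, relative conductivities 1, 1/80, 1 — the classical worst-case
skull ratio).  Scalp potentials of a current dipole are computed from the
spherical-harmonic series: per degree, the radial two-point boundary problem
(continuity of potential and radial current at both interfaces, insulating
outer boundary) is solved as a 5x5 linear system, and the dipole's
free-medium expansion supplies the source coefficients.  Sixty terms leave a
relative truncation error below 1e-6 for the default geometry (the terms
decay like (b/R)^n ≈ 0.74^n).  The expansion machinery is validated against
the exact infinite-medium dipole formula, and the full three-shell solution
against the layered-sphere EEG model in MNE (pattern correlation > 0.999,
one consistent unit factor across dipoles).

The source space is a Fibonacci lattice on a sphere at 85% of the brain
radius, triangulated by its convex hull (Euler characteristic 2), with an
optional radial spherical-harmonic perturbation ("folding", default degree
20, order 10) so that surface normals — and therefore minimum-norm signs —
vary across neighbours the way cortical orientations do.  Desk defaults are
2,000 vertices and 64 electrodes; the factorial study uses 1,000 vertices,
32 electrodes and 6 mm folding.  Ground-truth regions are placed by a
documented affine map (centre the ten MNI coordinates, scale isotropically
to 80% of the source radius) followed by nearest-vertex assignment, which
must be collision-free.

Scalp data follow `D = scale * G S + e` with average-referenced `G`.  The
white sensor noise is re-referenced and then rescaled so the realized ratio
of mean signal power (over trials, time, electrodes) to noise variance
equals the requested SNR exactly.  `scale` defaults to setting the peak
noise-free amplitude to 50 (microvolt-scale realism; it only fixes units and
cancels in all analyses).

## Inverse solution

sLORETA with the regularization rule `lambda = 1/SNR^2`, where the true
simulated scalp SNR is used.  The noise covariance is the per-sensor
baseline variance over all trials (off-diagonals discarded), diagonally
loaded by 0.1 x mean diagonal, and scaled to unit mean diagonal before
entering the Gram matrix; the kernel uses a pseudoinverse so the
average-reference rank deficiency is handled for any lambda.  Vertex
estimates are standardized by sqrt(diag(K_mne G)), which gives the
noiseless single-source zero-localization property checked in the tests.
One shared kernel serves all trials of a dataset.

## ROI extraction and dipole selection

ROIs grow geodesically (edge-weighted Dijkstra) from each ground-truth
vertex to 45 members by default.  Member series are sign-aligned to the
ROI's dominant normal direction (first principal direction of the member
normals, overall sign fixed by majority scalar product) before any
data-driven operation; this mimics standard practice and means roughly half
of random orientation flips are corrected, while an ROI whose dominant
direction opposes the true dipole keeps a globally flipped series — exactly
the failure mode the benchmark is meant to expose.

Selection strategies: ground-truth vertex (GT1); highest correlation with
the true series (GT2); highest correlation with the ROI mean (DD1); highest
power (DD2); largest-magnitude entry of the first left singular vector of
the members x time matrix (DD3; the "row singular vector" reading of the
SVD criterion); resolution index closest to 1 (DD4); highest ratio of mean
outflow to mean inflow cross-talk from the resolution matrix (DD5).
Strategies score trial-averaged, sign-flipped series (averaging suppresses
sensor noise and matches the shared-kernel design); ties break to the lowest
vertex index.  Selections are scored by Euclidean and geodesic distance,
Pearson correlation, and the MSE after an affine (gain + offset) fit to the
true series — the affine fit absorbs the ~1e-3 amplitude attenuation of
minimum-norm estimates so that shape, not scale, is scored.

## Time-varying MVAR estimation

Both filters track the random-walk state model `Atilde(n+1) = Atilde(n) +
v(n)` with the measurement built from the `p = 8` past samples and update
constant `UC = 0.02`.  The state is kept as the (m p, m) coefficient matrix
with one shared (m p, m p) covariance; state noise is isotropic with
magnitude `UC * trace(P)/dim`, and the residual covariance is tracked by
exponential smoothing with constant `UC`.  Estimates for bins `n <= p` are
back-filled with the first valid estimate so all grids span the full record.

* **CKF** (single trial) pools one scalar innovation variance
  (trace of the smoothed residual covariance / m) across channels.
* **GLKF** (multi-trial) stacks all trials into one measurement block per
  bin sharing the state, solves the full (r, r) innovation system, and uses
  per-channel residual variances in the state update (the shared covariance
  is propagated with the pooled-variance gain).  Because of the different
  innovation-variance handling the GLKF does not reduce to the CKF for a
  single trial.

Because one innovation variance is shared across channels (CKF) or assumed
comparable (GLKF), both filters standardize each channel by its standard
deviation before filtering and map the estimates back exactly
(`A_k = D A'_k D^{-1}` under `y' = D^{-1} y`); a global MVAR process is
invariant under this transformation, and it makes the filters
scale-equivariant, which matters because sLORETA amplitudes are arbitrary.

Multi-trial aggregation strategies: CKF-1 averages per-trial coefficient
trajectories before the PDC transform; CKF-2 averages per-trial squared-PDC
tensors (bounded in [0, 1] but no longer column-normalized; no
re-normalization is applied); GLKF transforms its single multi-trial
trajectory.

## PDC and figures of merit

Squared PDC is computed from `Abar(f, n) = I - sum_k A_k(n) exp(-i 2 pi
(f/fs) k)` with the Hermitian column normalization, on an integer 1-40 Hz
grid by default (the factorial study uses a coarser 2-38 Hz, 4 Hz-step grid
purely for speed; the rankings it reports are insensitive to the grid).
The theoretical reference PDC is the same code path applied to the exact
coefficient schedule — note that the schedule contains no self- (diagonal)
dynamics, in particular none of V1's AR(10) structure, a deliberate
convention inherited by the error scores below.

`MSE_MVAR` averages squared coefficient errors over time bins, all lags of
the order-8 grid (the truth is zero-padded from its true order 4), and the
masked region pairs; for CKF-2, which has no single trajectory, the
trial-mean of per-trial coefficient MSEs is reported.  `MSE_PDC` averages
squared PDC differences over frequency, time and masked off-diagonal pairs.
Both are computed separately for the 23 existing and 67 non-existing
ordered pairs.

## Factorial study

`run_factorial_study` shares one simulated source dataset and one head model
across all cells; every (SNR, realization) redraws only the scalp noise and
recomputes the noise covariance, kernel, selection and fits (the repetition
restarts from the simulated scalp recordings).  Dipoles are selected once
per realization on the full trial set, and trial-count cells fit the leading
trials; per-trial CKF fits are computed once and reused across trial counts.
Seeds fan out from the master seed through a spawned `SeedSequence` counter.
The desk-scale configuration used by the acceptance checks is 20
realizations of SNR {3, 10} x trials {5, 40} on the 1,000-vertex mesh with
selections {GT2, DD1, DD2, DD3} — sized so a full run takes a few minutes
on one CPU.

## What the benchmark does and does not establish

The simulator reproduces the structural challenges of source-space
connectivity — deep vs. superficial sources, skull smearing, inverse
cross-talk, orientation sign flips, trial-varying input — but not real
anatomy (spherical shells instead of BEM surfaces), background brain noise
in non-network dipoles, or real electrode geometry.  Two observed outcomes
deserve explicit caveats:

* On existing connections the GLKF is penalized around the V1-sender pairs:
  it recovers V1's genuine AR(10) self-dynamics most accurately, but the
  theoretical reference by convention contains no diagonal dynamics, so the
  better the diagonal estimate, the larger the apparent PDC "error" in
  V1's column.  Noisier single-trial estimates are sheltered from this.
* At desk scale the data-driven selections DD1/DD2/DD3 produce PDC error
  medians within < 1% of each other — the coarse mesh makes the ROI members
  nearly interchangeable — so strict orderings among them are not
  statistically meaningful at this resolution.

## Numerical choices

Lead-field series truncation 60 terms (warning if the last term exceeds
1e-6 of the accumulated field); kernel pseudoinverse with default rcond;
innovation-variance floor 1e-12; divergence guard aborts a simulation when
any amplitude exceeds 1e8 and names the time bin; selection ties break to
the lowest vertex index; constant series yield NaN correlations, which
selection ignores and scoring reports as missing.
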