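# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data it validates against, and the
numerical and design choices made where the field's conventions leave room.

## Preprocessing

Recordings are microvolt channel × sample matrices with a known sampling
rate (EDF via mne, or a delimited text matrix with a JSON sidecar). The
canonical montage is the 16-electrode 10–20 subset FP1, FP2, F3, F4, C3,
C4, P3, P4, O1, O2, F7, F8, T3, T4, T5, T6, in that fixed node order;
other montages are configurable.

* **Filtering.** Butterworth bandpass (default order 4, 4–30 Hz broadband;
  theta 4–8, alpha1 8–10, alpha2 10–13, beta 13–30 Hz rhythms) applied
  forward and backward (`sosfiltfilt`). Zero-phase filtering is chosen
  deliberately: the downstream measure is built entirely on phase, and
  although a causal filter's group delay would be common to all channels,
  avoiding any phase distortion removes a class of subtle artefacts at
  epoch edges. The effective magnitude response is the square of the
  design order, matching common EEG practice.
* **Decimation.** Integer-factor subsampling only (250 → 125 Hz by
  default); the 4–30 Hz broadband filter is the anti-alias guard for the
  62.5 Hz target Nyquist. Resampling by a non-integer ratio is refused
  rather than silently interpolated.
* **Segmentation.** Fixed windows (default 4 s) with fractional overlap
  (default 50%); epoch count = floor((N − window)/step) + 1 and a trailing
  partial window is discarded — padding would fabricate samples exactly
  where the analytic-signal phase is least reliable.
* **Ordering.** The pipeline epochs first and band-filters each epoch
  (`band_filter_stage="after_segment"`); filtering the continuous recording
  before segmentation is available behind the same config switch. The two
  orders differ only through filter transients at epoch edges, which the
  PLI edge trim (below) also suppresses.
* **Artifact removal** is a pass-through hook: the synthetic cohorts are
  generated artifact-free, and ICA component selection on real data is
  analyst-dependent; users of patient data should replace the hook.

A note on commutation: filtering at 250 Hz then decimating agrees with
decimating then filtering at 125 Hz only to ≈1% interior relative RMS, not
to machine precision — the two rates yield different bilinear-transform
approximations of the same analogue prototype. The property tests assert
the ≈1% bound.

## Phase Lag Index

Per epoch, each channel's instantaneous phase is the angle of its analytic
signal (FFT-based Hilbert transform). For each unordered pair the wrapped
difference Δφ(t) = arg e^{j(φ₁−φ₂)} is formed, the first and last 10% of
samples are trimmed (configurable) because analytic-signal estimates are
unreliable at window edges, and

PLI = | mean_t sign Δφ(t) | ∈ [0, 1].

Choices and caveats:

* **sign(0) = 0** (mathematical signum), so identical signals give exactly
  PLI = 0. Because FFT round-off turns amplitude-scaled copies of one
  signal into O(1e−15) pseudo-random phase differences, a numerical dead
  zone treats |Δφ| ≤ 1e−9 rad as zero; without it, an exactly-zero-lag pair
  of 500 samples would read PLI ≈ 0.05 from rounding noise alone.
* **Finite-sample bias.** |mean sign| is positively biased under the null;
  the bias scales like √(2/(π·n_eff)) with n_eff the number of independent
  sign stretches, which shrinks as the band widens or the epoch lengthens.
  Measured null epoch means at 500 samples: ≈0.2 (theta, 4 Hz wide),
  ≈0.27 (alpha1, 2 Hz wide). Group comparisons are unaffected as long as
  both groups share epoch length and band, but absolute epoch-level PLI
  values must not be read as evidence of coupling without a null reference.
* Phase is computed per epoch (each epoch yields its own adjacency matrix);
  computing phase on the continuous recording first is possible by
  segmenting after band-filtering, but the per-epoch default matches the
  epoch-as-analysis-unit design.

## Weighted networks and metrics

A connectivity matrix is thresholded proportionally: the k =
round_half_up(f · N(N−1)/2) largest upper-triangle weights are kept as
edges with their PLI values, for f = 0.25 … 0.35 in 0.01 steps (11
networks; 30…42 edges for N = 16). Ties at the cut are broken by
lexicographic (i, j) order for determinism. Thresholding *verifies* rather
than repairs isolated nodes (they are counted and reported); the threshold
range itself is conventionally chosen to avoid them.

* **Clustering** is the Barrat weighted coefficient (ordered neighbour-pair
  sum, strength-times-(degree−1) normalisation). It lies in [0, 1], equals
  the binary clustering coefficient when all weights are equal, and is 1 on
  any pure triangle. Nodes with degree < 2 contribute 0 and remain in the
  N-node average C_w.
* **Path length** uses edge length 1/w (strong connections are short) and
  Dijkstra over all pairs; L_w is the mean over ordered pairs. If the
  graph is disconnected the mean is over reachable pairs and the result
  carries a `disconnected` flag plus the unreachable-pair count — this
  keeps σ computable while keeping the anomaly visible, instead of the
  infinite or harmonic-mean conventions.
* **Null model.** Maslov–Sneppen double-edge swaps (a–b, c–d) → (a–d, c–b),
  rejecting self-loops and duplicates, with each edge keeping its weight:
  node count, edge count, degree sequence and the weight multiset are all
  conserved (asserted per surrogate in tests). Defaults: 10 successful
  swaps per edge, attempt budget 100× the target; if no valid swap exists
  (e.g. a 3-node path) the input topology is returned flagged. 50
  surrogates per network by default; surrogate child seeds are derived
  from the master seed via `numpy.random.SeedSequence`, so results are a
  pure function of (inputs, seed). Surrogates are generated per thresholded
  network, not shared across the sweep.
* **Small world.** σ = (C_w/C_w^rand)/(L_w/L_w^rand) with the surrogate
  means in the denominators. The two Watts–Strogatz-style preconditions
  (C_w > C_w^rand, L_w ≥ L_w^rand) are recorded as booleans per network.
  If no surrogate contains a triangle (C_w^rand = 0) σ is flagged
  undefined rather than inflated. Metrics are averaged arithmetically over
  the 11-threshold sweep.

## Group statistics

Classical one-way fixed-effects ANOVA per edge (120 tests) and per metric
(C_w, L_w, σ), implemented through explicit sums of squares so the
degenerate cases are pinned down (all observations equal → F = 0, p = 1;
zero within-group variance with unequal means → F = ∞, p = 0); for two
groups F equals the squared pooled-variance t, which the tests verify
against scipy. Significance is uncorrected p < α (default 0.05) to match
prevailing practice in this literature; `correction="fdr_bh"` applies
Benjamini–Hochberg via statsmodels, and is recommended whenever the 120
edgewise tests are interpreted individually.

**Unit of analysis.** The pipeline supports `epoch` (every 4 s epoch is an
observation) and `subject` (subject-mean PLI matrices). Epoch is the
package default for fidelity to common usage, but 50%-overlapping epochs
from one subject are serially dependent, so epoch-level ANOVA is
anti-conservative; the statistical-calibration tests therefore run at the
subject unit, where the null per-edge rejection rate measures 0.056 over
2400 tests at α = 0.05 (within binomial expectation). Results tables log
the unit used.

The frontal topology summary counts a significant edge as frontal-related
iff at least one endpoint is in {FP1, FP2, F3, F4, F7, F8}, and reports
k/m ratios per band plus the count of edges higher in the first group.

## Synthetic cohorts

Each channel is a sum of one narrowband oscillation per rhythm plus white
noise (no 1/f shaping, head geometry or artifact simulation — see
limitations). Carriers are cosines whose instantaneous frequency performs a
reflected random walk within the band (span = bandwidth/4 around the band
centre); a pure-sinusoid mode exists for analytic tests. Planted coupling
sets a target channel's band phase to the source's phase minus a fixed lag
minus von Mises jitter with concentration κ, piecewise-constant over 0.25 s
blocks: the marginal jitter distribution is exactly von Mises (closed-form
expected PLI = |2P(Δφ ∈ (0, π)) − 1|, available as `expected_pli`) while
varying slowly enough to survive band-pass filtering. Zero-lag mixing is
invisible to PLI by construction, which the tests use to emulate the
volume-conduction robustness claim.

Generator defaults mirror the clinical acquisition protocol: 250 Hz, 600 s
per subject, the 16-electrode montage, oscillation amplitude 1 and
background noise SD 0.5 per band layer. The stock two-group scenario
(`default_cohort_spec`) plants lag π/4 couplings with κ = 6 (expected PLI
≈ 0.93) versus κ = 1 (≈ 0.41): the HGAD-like group is stronger on three
frontal alpha2 edges and weaker on one theta and one alpha1 edge, with one
equal-strength beta edge as a planted non-difference — the direction
pattern, not any particular magnitude, is the recovery target. The whole
cohort is a pure function of `(CohortSpec, master_seed)`.

What passing tests on this generator do **not** show: performance under
real EEG nuisance structure (1/f background, artifacts, volume-conducted
sources with finite lag, non-stationarity, electrode noise correlations).
They validate the estimator chain, the graph machinery, the statistics'
calibration, and the pipeline's determinism.

## Validation problem sizes

The test suite and acceptance script run desk-scale versions of the
analysis, chosen as the smallest sizes at which each claim is informative:
12–30 s recordings and 2–8 subjects per group for structural and recovery
checks; 5 replicate null cohorts of 8 subjects per group × 20 s (2400
edgewise tests) for calibration; 1000 random graphs on ≤ 6 nodes for the
exhaustive metric oracles; 3–50 surrogates depending on whether topology
conservation or σ stability is at stake. Full-protocol sizes (600 s, tens
of subjects) run with the same code paths.

## Known limitations

* Epoch-level inference ignores within-subject dependence (see above);
  prefer the subject unit for confirmatory claims.
* PLI's finite-sample bias makes absolute connectivity values
  length- and bandwidth-dependent; compare only like with like.
* The proportional threshold assumes enough strictly positive weights;
  matrices with many exact zeros are refused rather than padded.
* Disconnected thresholded networks are summarised by reachable-pair path
  length; σ comparisons across networks with different disconnection
  patterns should be treated cautiously (the flag is propagated).
* The generator's oscillations-plus-white-noise model is deliberately
  minimal; it is a test harness, not a forward model of EEG.
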