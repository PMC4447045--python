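# Methods

`usvmuse` localizes mouse ultrasonic vocalizations (USVs) recorded by a
four-microphone overhead array, attributes each call to one of several freely
moving animals, and computes the vocal-interaction statistics used to study
courtship. This note documents the models and procedures, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the simulator-based validation does and does not demonstrate.

## Recording model and coordinate conventions

The arena is a 66 cm square; its floor polygon is annotated in meters with
the origin at one floor corner. Microphones are 3D points above the floor
(defaults: the four corners at 66 cm height). Audio is sampled at 450 450 Hz;
video at 29 Hz, synchronized through an affine audio-clock-to-frame model
(the audio sample clock is authoritative). Propagation delays use full 3D
Euclidean distances to points on the floor plane, with speed of sound c =
343 m/s by default (a config key, because c depends on ambient temperature).

## Segmentation: multitaper harmonic F-test

Each channel is analyzed at three window lengths (NFFT = 128, 256, 512
samples) with 43 DPSS tapers at time-bandwidth NW = 22 and 75% window
overlap. At each time-frequency point, Thomson's harmonic F-test compares
the regression of the eigencoefficients on the tapers' DC responses against
the residual broadband power; under the noise null the statistic is
F(2, 2K−2), thresholded at p < 0.05. Everything below 30 kHz is discarded as
non-vocal.

Per-scale masks are resampled to a common grid (time pitch of the shortest
window, frequency pitch of the longest) and combined by **union across
scales, intersection across channels**. The intersection is a deliberate
choice: per-pixel false positives are independent across channels, so
requiring significance on all K microphones drives the noise pixel density
from α to roughly α^K, while a real call in this small arena is loud on every
microphone. A union across channels at α = 0.05 would give ~40% noise pixel
density, and the subsequent gap-filling would fuse the entire record into a
single region.

The binary image is dilated with a 15 × 7 (time × frequency) box to repair
small gaps, 8-connected components are found, and a component survives only
if it contains strictly more than 1500 *original* hot pixels (dilation
repairs connectivity but cannot create mass). Bounding boxes come from the
original hot pixels. Time-overlapping segments are merged as harmonics when
the overlap exceeds 90% of the shorter segment and, in at least 90% of the
overlapped contour bins, the frequency ratio is within 10% of a factor of
two or three.

The 75% overlap (hop = NFFT/4) was chosen over 50% because the 1500-pixel
region criterion must be consistent with the grid pitch: at 50% overlap a
35 ms call carries only ~1200–1450 common-grid hot pixels and would be
dropped. At 75%, calls of roughly 25 ms and longer pass. Calls shorter than
~25 ms with narrow bandwidth still fall below the criterion — a known
resolution floor of this configuration, in line with the system's general
bias against short signals.

## Snippets

Each segment is cut into 5 ms bins starting at the segment onset. The
frequency contour is the per-bin median of hot-pixel frequencies (robust to
speckle and bounded by the hot-pixel support; a max-power ridge tracker is a
noted alternative). Each bin yields a candidate snippet: all channels sliced
over the same 5 ms, band-passed to contour ± 1 kHz with a frequency-domain
amplitude mask (200 Hz cosine roll-off). The mask is purely real, hence
exactly zero-phase — mandatory, since localization lives in inter-channel
delays. Candidates with fewer than 11 hot pixels in their 5 ms × 2 kHz tile
are discarded; a signal is localizable only with at least 3 retained
snippets. Harmonic-merged segments are tiled per harmonic branch, so one
time bin can contribute several snippets at different center frequencies
(which is how a ~47 ms harmonic stack yields more snippets than its 5 ms
bin count).

## Localization: reduced steered response power

For a candidate floor position, each microphone's hypothesized delay is
τ_k = ‖r_g − r_k‖/c. The reduced steered response power sums, over the six
unordered microphone pairs, the cross-correlation of the pair evaluated at
the implied delay difference; self terms are constant in position and the
two orders of a pair are mirror images, so the reduced form loses nothing
(the full SRP is recoverable as 2·RSRP + Σ_k r_kk(0), which is asserted in
tests). Cross-correlations are computed once per snippet by FFT over the
geometrically possible lag range (max inter-microphone delay difference over
the floor plus a 5-sample margin) and evaluated at grid points by linear
interpolation.

Implementation choices:

* Cross-correlations are **circular** over the snippet length,
  r_ik(p) = Σ_n v_i[(n+p) mod N] v_k[n] for pair (i, k), i > k, computed by
  FFT and matching a brute-force time-domain oracle to 1e−10. A channel that
  receives the signal later peaks at positive lag, consistent with evaluating
  at (τ_i − τ_k)/Δt. Circularity is substantive, not cosmetic: a zero-padded
  *linear* correlation carries a triangular envelope (N − |p| overlapping
  samples at lag p) that biases near-tonal snippets toward zero lag — every
  pair then votes for the array's symmetry point, and near-constant-frequency
  calls mislocalized by ~25 cm until this was fixed. The circular form
  weights all admissible lags evenly; the lag range must satisfy
  max_lag < N, which holds for the default geometry (≈640 samples vs the
  2252-sample snippet).
* Correlations are raw (unnormalized); correlation-coefficient maps are a
  visualization concern only.
* The estimate is the in-polygon argmax on a 0.25 mm lattice — about ten
  times finer than the 2.6 mm wavelength at 130 kHz. Exhaustive search over
  the full arena (~7M points) is available behind a flag; the default is a
  three-level coarse-to-fine search, 2 mm → 0.5 mm → 0.25 mm, refining around
  the top 1% of cells and snapping all levels to a shared absolute lattice so
  the refined argmax coincides with the exhaustive one (asserted on
  fixtures). The first level must not undersample the RSRP peak, whose width
  is set by signal bandwidth (~3 mm for a broadband transient); a 5 mm first
  level was tried and missed the peak on ~30% of noiseless clicks.
* Argmax ties break deterministically to the smallest grid index.

Known behavior, not a bug: a snippet whose 2 kHz band is nearly constant in
frequency (sweep rates below ~100 Hz/ms) is intrinsically ambiguous — the
admissible delay range spans tens of carrier periods, and all six pairs share
the same carrier, so ghost intersections of the per-pair ambiguity lattices
can out-power the true position by a sliver. Such snippets can land tens of
centimeters away even without noise. Frequency-modulated snippets decorrelate
the lattice and localize well. Consensus building and the assignment gates
below are the system's defenses; they reject most, but not all, such
failures.

## Caller assignment

Per-snippet estimates are cleaned with an MCD-style robust location/scatter
fit (scikit-learn's MinCovDet): points whose squared robust Mahalanobis
distance exceeds the χ²(2) 0.975 quantile are outliers. Because the raw MCD
scatter over-trims small samples, the gate is re-evaluated against the
consistency-corrected classical scatter of the current inliers until the
inlier set stabilizes (the correction divides by F_{χ²(4)}(q)/0.975, the
expected shrinkage of a χ²-truncated Gaussian scatter). At least three
inliers are required; the consensus is the classical mean and covariance of
the inliers, ridge-regularized by 1e−8 m² · I when singular (collinear
estimate clouds do occur).

The consensus defines a bivariate Gaussian source density over the cage.
Each mouse's density D_n is the pdf at its **nose** (centroid + ½ major axis
along heading — estimates cluster at the head; evaluating at the centroid is
the documented alternative), using the animal's position in the video frame
containing the signal midpoint. The mouse probability index is
MPI_n = D_n / Σ_i D_i. A signal is assigned only when max MPI > 0.95
(strict) *and* that mouse's density exceeds 1 m⁻² (strict); otherwise it is
unassigned with a reason code: `ambiguous` (MPI too flat), `low-density`
(source far from everyone, or a degenerate thin consensus), `diffuse`
(at most half the snippets form the consensus — overlapping calls), or
`all-far`. The thresholds are config keys.

## Simulator

The simulator emulates the study conditions end to end: FM calls with
piecewise-linear contours in 30–130 kHz (defaults: 30–80 ms duration,
55–90 kHz start, sweeps up to ±15 kHz — a realistic adult courtship
repertoire), rendered at each microphone with exact band-limited
fractional-sample delays (FFT phase ramp), 1/d amplitude decay, and white
Gaussian noise at a stated SNR referenced to the nearest microphone.
Trajectories are Ornstein–Uhlenbeck velocity walks with wall reflection
(median speeds under 0.6 m/s); chase bouts are scripted (the female runs an
arc, the male tracks her position 0.5 s behind). Event trains are Poisson
per animal, with optional male→female coupling (a response within a
configured latency window with configured probability). Every stochastic
operation takes an explicit seed; fixed seeds give byte-identical sessions.

The simulator does **not** model reverberation (the real arena is lined with
acoustic foam), directional microphone response, body shadowing, or call
amplitude directionality. Passing tests therefore demonstrate correctness of
the algorithms under the stated propagation model, not performance on any
particular recording rig.

## Behavior statistics

* **Triggered averages**: responses of one sex in 1 s bins within ±30 s of
  each of the other sex's calls, normalized per trigger; triggers within 30 s
  of the record edges are excluded.
* **Shuffle null**: each of 1000 shuffles redraws the trigger times uniformly
  over the valid span (counts preserved, response train fixed) and recomputes
  the group-average curve. The verdict statistic is the curve maximum over
  bins — exchangeable between observation and shuffles, so the test is
  exact; significance requires that at most one shuffled maximum reaches the
  observed one (empirical p ≈ 2/1001; the binomial 95% upper bound on 1/1000
  is ~0.006). Ties count against significance, so a degenerate observation
  identical to its shuffles is never significant. Redrawing uniformly rather
  than permuting inter-event intervals is a documented choice.
* **Vocal sequences**: an initiator call answered within 1 s by one specific
  opposite-sex animal; events answered by two different animals are
  ambiguous and skipped, and an initiator that itself continues an exchange
  of the same pair within the window does not start a new sequence. Edge
  sequences (within 30 s of record boundaries) are flagged and excluded from
  kinematics but retained for chase-correlation counts.
* **Chase heuristics**: for candidate intervals with a known chased female,
  the chasing male must start within 20 cm and overlap her earlier path —
  operationalized as ≥20% of chase frames with the male within 5 cm of the
  female's positions 0–1 s earlier (full-track lookback, so short bouts see
  the pre-bout path). Same-pair bouts separated by ≤0.3 s merge; merged
  chases must exceed 0.17 s. The procedure is idempotent.
* **Association**: a sequence belongs to a same-pair chase containing its
  onset, else to the previous same-pair chase if within 30 s after its end,
  else to the next if within 30 s before its onset, else it is unassigned —
  a partition, asserted in tests. Outside rate uses (60 s − chase duration)
  as denominator (the source wording is ambiguous; this reading is fixed
  here).
* **Receptivity**: in-chase male calls are `interaction` when the chased
  female answers within 1 s and `male-only` when *nothing* (assigned or
  unassigned) follows within 1 s; calls followed only by other events belong
  to neither class. Female speeds at call time are compared by Mann–Whitney,
  reported as medians with 75th–25th percentile ranges.
* Relative-position maps use 1 cm bins (a finer figure is configurable but
  physically pointless at mouse scale) and a 10 cm ROI for the
  anterior/posterior proportion.

## Validation experiments and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`) regenerate all
headline numbers from a seed:

* RSRP oracle equivalence on a 50×50 grid (FFT vs brute-force correlations).
* 100 noiseless broadband clicks at random floor positions, coarse-to-fine to
  the 0.25 mm lattice; median error is reported in mm.
* Caller assignment in a simulated four-mouse environment, following the
  controlled single-vocalizer design: four 20 s sessions each with one
  identified caller moving on an Ornstein–Uhlenbeck trajectory, up to 120
  calls rendered at its nose at 15 dB SNR, and for every call three virtual
  mice placed uniformly at random on the floor. Accuracy (fraction of
  assignments that name the real caller) and yield (assigned / localized)
  are swept over MPI thresholds with the 1 m⁻² density gate active. The
  sample size is a precision choice: testing a 95%-accuracy operating point
  needs the binomial standard error below ~2.5%, i.e. at least ~60 assigned
  signals, which a 60-event run cannot provide. A
  free-mixing session where all four animals vocalize was tried first and
  measures lower (~90%) because nose-to-nose proximity events are
  intrinsically ambiguous; the virtual-mouse protocol isolates the
  localization/assignment chain from social proximity.
* Segmentation recall on 40 injected calls ≥100 ms apart at 15 dB, with
  contour-containment checks, plus per-scale noise false-positive rates on a
  signal-free record.
* Permutation-test calibration: 200 replicates of independent Poisson trains
  (1000 shuffles each) for the type-I rate; fully coupled trains must always
  fire with the peak in the [0, 1) s bin.
* A scripted session for the chase/sequence/association pipeline.

These sizes keep the full validation under ~15 minutes on one core while
leaving the study conditions (sample rate, array geometry, thresholds, SNR)
at their defaults.

## Known limitations

* Constant-frequency calls can mislocalize grossly (see above); the
  assignment gates catch most but not all cases. When a ghost consensus is
  tight, it passes both the MPI and density gates, and a randomly placed
  animal near the ghost is then misassigned — the dominant residual error
  mode in the simulated validation. Measured: pooled over three independent
  120-event runs of the virtual-mouse experiment, 177/193 assigned signals
  (91.7% ± 2.0%) named the real caller at MPI > 0.95, with per-run values of
  95.2%, 92.5% and 87.5%; the shortfall relative to a real-repertoire system
  is concentrated in calls sweeping slower than ~100 Hz/ms, which make up
  roughly a fifth of the simulator's default (uniform-sweep) repertoire. The
  threshold sweep is nonetheless monotone in every run (raising the MPI
  threshold raises accuracy and lowers yield).
* Conversely, near-noiseless snippet estimates can quantize onto the fine
  search lattice, giving a near-singular consensus covariance whose density
  at the (centimeters-away) true nose falls below 1 m⁻²: a correct
  localization rejected as `low-density`. This costs yield, not accuracy; a
  covariance floor at the system's resolution would recover it but is not
  part of the published method.
* Calls shorter than ~25 ms with narrow bandwidth fall below the 1500-pixel
  region criterion at this grid resolution.
* The segmentation's channel-intersection rule assumes all microphones are
  live; a dead channel suppresses detection entirely (snippet-level dead
  channels are handled separately).
* No reverberation or directionality in the simulator; real-world accuracy
  will differ.
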