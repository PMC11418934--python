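# Methods

This note documents the models, parameters and numerical choices behind
`lidscope`, and what the synthetic benchmarks do and do not demonstrate.

## Signal chain and units

All streams are aligned on the IMU clock (the highest-rate stream,
nominally 200 Hz) by nearest-preceding sample (zero-order hold). We chose
zero-order hold over interpolation because annotation and cluster labels
are categorical and keypoints arrive at 30–40 fps; interpolating them
would manufacture sub-frame information. Time is in seconds, acceleration
in g, angular velocity in deg/s, keypoints in pixels, calcium centroids in
micrometres (the field-of-view scale fixes µm as the distance unit for the
spatial correlation analysis).

## Inertial features

Raw 6-channel data are denoised by a 7th-order median filter followed by
Gaussian smoothing. The Gaussian width is not pinned down by any published
constant; we default to σ = 25 ms (5 samples at 200 Hz), wide enough to
suppress residual quantization ripple and narrow enough to leave 4–8 Hz
movement content intact. It is configurable.

Gravitational acceleration (GA) per axis is a median filter followed by a
first-order 0.5 Hz Butterworth low-pass applied forward–backward
(zero-phase; effective magnitude response is the squared first-order
response, i.e. −40 dB at 5 Hz). Body acceleration is defined by the
decomposition `BA = filtered accel − GA` per axis, with total BA its
Euclidean norm. The decomposition convention makes two properties exactly
testable: `GA + BA` reconstructs the filtered signal sample-by-sample, and
|GA| ≈ 1 g for a stationary sensor at any orientation. An alternative
reading — BA as an independently band-passed signal without subtraction —
is possible; the subtraction convention was adopted because it guarantees
the decomposition identity.

Head rotation events are contiguous runs where the dorsoventral angular
velocity stays ≥ 10 deg/s in magnitude with constant sign; each event
carries its trapezoidal time-integral as the cumulative angle, and events
break at zero crossings (one left–right wiggle = two events). Plain
integration over the supra-threshold run is used; no extra smoothing of
event boundaries.

The movement threshold is 0.05 g (ln 0.05 = −3 log units), the valley of
the bimodal distribution of ln BA in open-field recordings. The estimator
(`estimate_bimodal_threshold`) finds the minimum of a Gaussian-KDE density
between the two largest modes and falls back to 0.05 g with a warning when
the distribution is unimodal.

## Discretization, EMD and segmentation

Default bin edges: BA {0.05 g}; GA_AP {−0.4, 0}; θ head {−165, −25, +25,
+165}°; θ axial {90}°. Values exactly on an edge go to the **upper** bin
(documented, tested convention). A missing axial angle (no pose stream)
falls in the straight-trunk bin.

Histograms are kept per feature (one simplex each), and the distance
between two windows or segments is the **unweighted sum of the four 1-D
EMDs** with unit ground distance between adjacent ordered bins. Whether
the four features should be jointly histogrammed or weighted is genuinely
open; per-feature summation was chosen because it keeps each feature's
contribution bounded by (bins − 1) and is exactly computable as the L1
norm of cumulative-histogram differences (verified against a
linear-program transport oracle to < 1e-9). Similarity for clustering is
the negative distance.

Windows are 250 ms with 80% overlap (50 ms step). The change signal is the
EMD between consecutive windows; change-points are its local maxima above
a threshold that defaults to the session mean of the signal (the published
realized value of that mean on real data, 0.005, can be passed as a fixed
constant instead — we treat it as a realized average, not a universal
constant). Peaks closer than one window length are unresolvable and only
the highest is kept. Segments shorter than 100 ms are merged into the
neighbor with the more similar histogram; segment boundaries are sample
indices, so segments tile the session exactly.

## Clustering, library, matching

Affinity propagation runs on the precomputed similarity matrix with
damping 0.9, max 1000 iterations and a fixed random state; the preference
defaults to the median similarity, so the cluster count is data-dependent
(on the four-condition synthetic study it lands in the tens, comparable in
spirit to the published library, but no target count is enforced).
Non-convergence raises with damping/iteration diagnostics rather than
returning silently.

Rest/move labels: a cluster is "rest" when more than half of its member
samples fall below the movement threshold. Presence: a cluster is present
in a condition when its mean per-session occupancy reaches 3 s per 600 s
session (0.5% of the duration; scaled for other durations). Matching
assigns each new segment (or exemplar) to the library cluster with the
closest exemplar by EMD; match quality is a rank-sum comparison of matched
vs randomly assigned EMDs. Exemplar-to-exemplar matching is the default;
segment-level matching is available through the same function.

ROC separability thresholds all pairwise segment EMDs to classify
same/different cluster and reports the best balanced accuracy over
thresholds, with a label-permutation null (~0.5).

## Dyskinesia mapping

Cluster occupancy and annotation occupancy are binarized on the 50 ms
window grid (the segmentation step) before Pearson correlation — the
correlation timebase is not dictated by anything upstream, and the window
step is the natural common grid. The null circularly shifts the annotation
series (preserving both marginals and autocorrelation, unlike i.i.d.
permutation) with 1000 draws and α = 0.001 per direction, both
configurable. The cohort rule (≥ 2 positive mice, positives ≥ negatives
+ 2, ties broken by positive count then mean r) is deterministic given the
significance table. Uncorrelated moving clusters become *other N* if
present in the intact-vehicle condition, else *path rot*.

The classifier is a linear SVC over per-window fractional occupancy of the
*axial+limb* and *axial alone* groups (1 s non-overlapping windows labeled
by the majority annotation). Evaluation is leave-one-mouse-out; within
each fold the training and test windows are balanced by repeated random
subsampling (default 5000 draws; the study pipeline uses 200 draws, which
is already within 0.5% of the asymptotic accuracy on the synthetic study)
and the accuracy is averaged over draws. Chance level comes from label
permutation. The per-window feature construction is an implementation
choice: windows are the finest unit on which occupancy fractions are
non-degenerate.

## Neural ensembles

Event detection: external event trains are first-class inputs and pass
through unchanged. The built-in detector is deliberately simple — offset
correction to strictly positive values, running 20th-percentile baseline
(window = drift parameter × trace length, default 0.2), matched filter
with the exponential decay kernel (τ = 400 ms), Gaussian band-limiting of
the detection statistic at σ = τ/2, and peaks above median + 3×MAD with
equal prominence and a one-τ refractory distance. The median centering
matters: the residual rides above zero by construction, and thresholding
absolute height would multiply the false-positive rate by an order of
magnitude. On pure noise the detector yields < 0.005 events/s; planted
transients at 5× noise are localized within ±2 frames. A full generative
deconvolution (time-varying baseline model, amplitude autocalibration) is
intentionally out of scope: the analyses downstream consume event trains,
not the deconvolution itself.

Rates: the resting rate counts only rest bouts ≥ 500 ms (the immobility
criterion); it is NaN when no bout qualifies, which is the expected
outcome for fully dyskinetic sessions. Behavior-related neurons: Pearson r
between per-frame event counts and binary group occupancy on the calcium
clock, against ≥ 1000 circular shifts of the occupancy (shift ≥ 10 s),
positive tail at α = 0.05 without multiplicity correction (configurable);
the choice of test and α is not externally fixed, so the null calibration
is itself part of the test suite. Overlap uses the union (Jaccard × 100)
denominator — forced by the convention that 100% means complete overlap
(a sum denominator would cap identical sets at 50%) — and subtracts the
mean overlap of size-matched random sets. Spatial profiles correlate the
raw traces (not event trains) and average within nine logarithmic bins
over 15–750 µm.

## Synthetic data

The generator draws a semi-Markov state sequence (gamma dwell times,
explicit minimum 0.3 s so every state is detectable above the 100 ms
segment floor) and synthesizes each stream from per-state targets. Body
acceleration is a ~4 Hz quadrature oscillation (circular head motion) with
a slowly varying log-normal envelope plus a band-limited residual; the
quadrature construction keeps |BA| pinned near the envelope, so a state's
movement regime does not flicker across the 0.05 g threshold — flicker is
a property of real data the benchmark deliberately excludes, because
recovery criteria are only meaningful when the planted states are
well-posed. The envelope is calibrated against the package's own
measurement pipeline (two fixed-point passes), so realized per-state mean
BA tracks the target within a few percent. Gravity is a unit-norm vector
with the prescribed AP component; rotations are non-overlapping half-sine
gyro pulses of prescribed total angle, or a sustained angular velocity for
pathological rotation. Keypoints are placed on a rigid skeleton
parameterized directly by the target axial angle, making the pose→angle
inverse exact up to jitter; 2% of frames receive low likelihoods to
exercise the interpolation path.

Calcium activity is inhomogeneous Poisson per frame (baseline rate ×
per-state multiplier), convolved with the τ = 400 ms kernel, plus slow
sinusoidal drift, Gaussian noise, and optionally a shared latent drive
with spatial covariance exp(−d/λ) that produces distance-decaying pairwise
correlations.

The four-condition mini-study (`paper_like_scenario`) emits
intact/lesioned × vehicle/L-DOPA cohorts (default 3/3/3/4 mice, 240 s
sessions — sizes chosen so the full pipeline, including affinity
propagation over ~4000 pooled segments, runs comfortably on a laptop
core); only the lesioned-L-DOPA cohort contains the dyskinetic states and
annotations. Because its states are well separated, the study classifier
reaches ~100% — the synthetic benchmark demonstrates calibration and
recovery, not the harder class overlap of real recordings.

What passing tests show: the pipeline recovers planted structure
(change-points, clusters, tuned neurons, spatial decay) under controlled
noise, and its null calibrations (shuffled labels, circular shifts,
size-matched sets, homogeneous rates) behave nominally. What they do not
show: performance under real tracking failures, sensor drift, overlapping
behavioral categories, or neural nonstationarity.

## Degenerate inputs and tie-breaks

Degenerate pose frames (keypoint collapse onto the hindlimb midpoint)
yield a gap that inherits the previous valid value. Constant series make
correlations undefined and are flagged, never imputed. Empty neuron sets,
zero moving time, and absent qualifying rest bouts return NaN with a
warning. Boundary values at bin edges go to the upper bin; a presence
occupancy exactly at threshold counts as present; a rest probability of
exactly 0.5 is "move".
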