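# Methods

## PAD scoring and nearest-emotion classification

The questionnaire model is a bipolar semantic-differential scale: each item
is an integer rating in −4..+4, each item belongs to exactly one of the
pleasure, arousal and dominance dimensions, and a dimension's score is the
arithmetic mean of its items after sign-flipping reverse-keyed ones. The
default layout is 12 items, 4 per dimension, which puts scores on a
quarter-step grid — the granularity visible in the bundled reference
cohort (one of whose rows carries the off-grid value 0.57; validation is
therefore strict on the rating grid but tolerant of any in-range score).
Item count, dimension assignment and reverse keys are configurable.

Classification is a nearest-centroid rule in PAD space: Euclidean distance
to each of 14 basic emotions' reference coordinates, argmin wins. Ties
(equal distances within 1e−12 relative tolerance) go to the lower table
index, making the assignment invariant to table permutation except on
exact ties. Each emotion carries a fixed tendency label; positive =
{Joy, Optimism, Relaxation, Surprise, Dependence}. Eleven of the fourteen
labels are attested by the reference cohort's printed (state, tendency)
pairs; the three unattested emotions (Optimism, Disgust, Hostility) are
assigned by the sign of their reference pleasure coordinate. The mapping
is data, not logic — `default_emotion_table(positive=...)` accepts any
partition.

**Known divergence.** The pure distance rule disagrees with the reference
cohort's printed state labels on 12 of its 42 rows
(4, 5, 10, 16, 20, 22, 26, 30, 35, 36, 38, 42). Most disagreements are
between near-neighbour negative states (e.g. printed Anxiety at the origin
where Sadness is nearer); two rows printed as positive states (36, 38)
reclassify to the negative state Anxiety. No adjustment rule is applied —
the implementation is the pure argmin, and the divergent rows are asserted
as documented expected differences in the test suite. Consequently the
negative-tendency share is 66.7 % when the printed states are mapped
through the lookup, and 71.4 % when states are recomputed from the scores.

## Cohort descriptives

Conventions chosen to match standard survey reporting (and verified to
reproduce the reference cohort's published aggregates exactly):

* standard deviation uses the sample (n−1) denominator — the population
  formula does not reproduce the published values (0.783 vs 0.774 for the
  pleasure column), and a test asserts the discrimination;
* the even-n median is the mean of the two middle order statistics;
* display rounding is half-away-from-zero, 3 decimals for moments and
  1 for percentages. Two published sign shares (28.5 %, 42.8 %) appear
  truncated rather than rounded (the underlying fractions 12/42 and 18/42
  round to 28.6/42.9 under any standard rule) and are treated as printing
  artifacts, excluded from reproduction targets.

Group profiles cross-tabulate tendency by one demographic attribute;
empty categories are kept with zero counts and modal categories break
ties alphabetically.

## EEG band energies

Band energy is computed by short-time Fourier analysis: 1 s Hann-tapered
windows with 50 % overlap (configurable), energy of band b =
Σ|X(f)|² over bins with f ∈ [low, high). Default edges are the clinical
conventions δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz. The recording's
DC offset is removed once, globally, rather than per window: per-window
demeaning interacts with the taper and biases the lowest band down by
several percent for broadband signals, which would break the white-noise
flatness property (band energy proportional to the band's bin count) that
the test suite checks to within 3 standard errors across seeds.

Custom band edges are supported; the five canonical band names are fixed
because the downstream feature vector is the (δ, θ, α, β, γ) tuple.

Filtering uses a zero-phase 4th-order Butterworth band-pass — the common
choice for EEG energy work. Zero-phase application squares the magnitude
response; at 50 Hz mains with a 0.5–45 Hz passband the steady-state power
suppression is |H(50)|⁴ ≈ 6 %, and the test asserts exactly this derived
figure rather than a nominal stopband number. Artifact handling is
peak-amplitude window rejection (windows whose absolute amplitude exceeds
a threshold are excluded before feature computation); independent-
component cleaning is out of scope because the targeted consumer-grade
devices perform it on-board.

Energies are device-relative; no absolute calibration is attempted since
features are standardized before classification.

## Tendency classification

Standardization (mean 0, sd 1 with the n−1 convention; zero-variance
columns centered with a warning) and PCA (smallest leading component set
with cumulative explained variance ≥ 0.95 by default) are both fitted on
training rows only and applied to test rows — a leakage test asserts that
perturbing a test row cannot change any train-side result. The split is
stratified 70/30 with test size ⌈0.3 n⌉ (13 of 42), deterministic in the
seed. Kernels: linear, polynomial (degree 3), Gaussian and sigmoid, with
regularization weight C = 1 and kernel width 1/(n_features · variance) —
the standard defaults, all configurable. "Success rate" is per-class
recall per partition; overall accuracy is reported alongside. A kernel
that assigns no sample to a class gets a failure marker (printed as an
en-dash) instead of a recall.

## Synthetic data generator

The generator emulates a quota-sampled visitor study:

* **Demographics.** Category counts are the largest-remainder allocation
  of the marginal proportions (gender 73.8 % female; age groups 28.6 /
  23.8 / 23.8 % for 15–18 / 26–35 / 36–45 with the remaining 23.8 % split
  evenly between 19–25 and 46–50; education, occupation and income as
  reported for the reference study; seat position and travel mode have no
  reported marginals, so the defaults are invented with the reported modal
  categories — position 8 and family travel). Attributes are sampled
  independently: only marginals are reported for the emulated study, so
  no joint structure is claimed, and profile tests read back the
  generator's own bookkeeping. Counts are exact by construction;
  assignment to visitors is randomized by the seed.
* **PAD scores.** A latent basic emotion is drawn from a prior (default:
  uniform over the eleven emotions plausible for a melancholic film; a
  `reference_like` preset reweights toward the reference cohort's observed
  state mix). P, A, D are independent normals around the latent emotion's
  coordinates with sd 0.75 by default — a value chosen once as realistic
  questionnaire scatter that produces a reference-like mix of states —
  clipped to ±4 and rounded to the 0.25 grid.
* **EEG.** The signal is a sum over bands of band-limited Gaussian noise,
  each component rescaled so its sample variance equals
  baseline_power(b) × class_multiplier(b, tendency) × visitor jitter,
  plus a broadband noise floor (variance 1). Baseline powers
  (δ 54.9, θ 11.7, α 20, β 53.9, γ 26.8) follow the magnitudes quoted for
  the emulated study's band energies, with the unreported α placed between
  θ and γ. Per-visitor jitter is lognormal with σ = 0.35 (individual
  differences); the default positive-class multiplier on β and γ is
  e^{2·0.35} ≈ 2.0, i.e. a two-pooled-SD shift on the log-power scale *by
  construction*. This is a statistical stand-in, not a biophysical model:
  it has the spectral structure the band-energy features measure and
  nothing else (no 1/f background, no transients, no non-stationarity), so
  passing recovery tests demonstrate the pipeline's correctness under its
  own assumptions, not field performance on real EEG.

Defaults are 60 s recordings at 512 Hz; validation and acceptance tests
run 5–30 s at 128–256 Hz (well above the 90 Hz Nyquist requirement of the
45 Hz band edge), sizes chosen to keep full multi-seed sweeps in seconds
to minutes.

## Null-calibration check

The classifier's null behaviour is tested on cohorts with
class-indistinguishable EEG and independently shuffled labels. Because a
label-independent classifier's expected accuracy is the chance agreement
Σ_c q_c·p_c (q = its prediction marginals, p = the label marginals) — which
equals the majority-class base rate only in the degenerate all-majority
case — the test pools predictions over 20 seeds and asserts the pooled
accuracy lies inside the 95 % binomial interval around that chance rate.

## Determinism and manifests

Every run writes a manifest with the seed, the analysis settings, a hash
of those settings, and library versions. Filesystem paths are deliberately
excluded from the hashed settings so that the same analysis in two
locations yields byte-identical report bundles; input files are recorded
by basename. No output embeds a timestamp.

## Limitations

* The emotion-to-tendency mapping is taken from one observed cohort plus a
  sign rule for three unattested emotions; other stimuli could warrant a
  different partition (it is configurable).
* Published per-kernel success rates for the emulated study cannot be
  reproduced because its raw EEG is unpublished; the classifier deliverable
  is the report format plus property-level behaviour on synthetic cohorts.
* The PAD scale's item wording and psychometrics are out of scope; the
  scoring layer is structural (items, keys, means) only.
* EDF input is supported only when mne is installed; CSV is the primary
  interchange format.
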