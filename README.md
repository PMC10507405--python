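# padeeg

Tools for measuring the emotions of museum visitors (or any small cohort)
from two complementary signals:

* **Psychological**: responses to a pleasure–arousal–dominance (PAD)
  questionnaire are scored to a (P, A, D) triple on a −4..+4 scale and
  classified to the nearest of 14 basic reference emotions by Euclidean
  distance in PAD space; each basic emotion carries a binary
  positive/negative *emotional tendency*.
* **Physiological**: single-channel EEG is reduced to the mean spectral
  energies of the five classical bands (δ 0.5–4 Hz, θ 4–8, α 8–13,
  β 13–30, γ 30–45), and support-vector machines with linear, polynomial,
  Gaussian and sigmoid kernels predict the tendency from those energies
  after standardization and PCA.

A synthetic-data generator produces complete study datasets — quota-sampled
demographics, PAD scores drawn around latent basic emotions, and
band-structured EEG whose band powers differ by tendency class — with full
ground truth, so every stage of the pipeline can be validated end to end
without access to raw recordings.

## The model

A visitor's PAD score is compared against each reference emotion *n* with
coordinates (pₙ, aₙ, dₙ):

    Lₙ = √((P − pₙ)² + (A − aₙ)² + (D − dₙ)²),   n = 1..14

The emotion minimizing Lₙ is assigned (ties broken by table index), and its
tendency label — positive for {Joy, Optimism, Relaxation, Surprise,
Dependence}, negative for the other nine — becomes the visitor's tendency.

For the EEG route, band energy is the sum of squared rFFT magnitudes over a
band's frequency bins in 1 s Hann-tapered windows (50 % overlap), averaged
over the monitoring period. Features are standardized, projected onto the
principal components explaining ≥ 95 % of training variance, and fed to
SVMs; per-class *success rates* (recalls) are reported separately for the
training and test partitions of a stratified 70/30 split.

## Worked example

The package bundles a 42-visitor reference cohort (PAD scores with printed
state and tendency labels). Summarize it:

```bash
python -c "from padeeg import load_reference_cohort, write_cohort; \
           write_cohort(load_reference_cohort(), 'cohort.csv')"
padeeg report --cohort cohort.csv --out-dir out
```

```
Cohort summary (n = 42)

Dim      Mean      SD  Median    >0 %    =0 %    <0 %
P       0.055   0.783   0.250    54.8    16.7    28.6
A      -0.048   1.302  -0.250    42.9     4.8    52.4
D       0.113   1.113   0.125    50.0    11.9    38.1

Tendency: 12 positive, 30 negative (71.4% negative)
```

Pleasure is mildly positive on average (mean 0.055, more than half the
cohort above 0), arousal mildly negative, and dominance mildly positive;
the cohort's tendency is predominantly negative. (This recomputed tendency
share uses the pure distance rule; mapping the cohort's *printed* state
labels through the tendency lookup instead gives 28/42 = 66.7 % negative —
see `docs/methods.md` for the rows where the two differ.)

A full synthetic study, EEG included:

```bash
padeeg simulate --n 42 --seed 7 --out-dir sim --duration 20 --sampling-rate 256
padeeg run-all --cohort sim/cohort.csv --eeg-dir sim/eeg --out-dir sim/out --seed 7
```

```
Success rates of support-vector-machine tendency classification
(train n=29, test n=13, 4 principal component(s))

Method                     Positive class          Negative class
                         Train        Test       Train        Test
linear                   0.625       0.750       0.952       1.000
polynomial               0.250       0.500       1.000       1.000
gaussian                 0.625       0.750       0.952       0.889
sigmoid                  0.625       0.750       0.905       1.000
```

With the generator's default class effect (β/γ band powers roughly doubled
for positive-tendency visitors), the majority (negative) class is recovered
nearly perfectly on held-out data while the minority class is harder — the
typical picture for a 42-person cohort. A kernel that never predicts some
class shows an en-dash instead of a rate.

## Layout

| module | contents |
| --- | --- |
| `padeeg.emotions` | PAD scoring, reference table, nearest-emotion classification |
| `padeeg.report` | cohort descriptives, tendency shares, demographic profiles |
| `padeeg.eeg` | band-pass filtering, artifact rejection, band spectral energies |
| `padeeg.classify` | standardization, PCA, stratified split, SVM evaluation |
| `padeeg.simulate` | synthetic cohorts with ground truth |
| `padeeg.io`, `padeeg.pipeline`, `padeeg.cli` | file formats, end-to-end runs, CLI |
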