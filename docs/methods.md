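# Methods

## Problem and pipeline

The package classifies three mental states (focused, unfocused, drowsy)
from multichannel EEG. The working assumption is physiological: the
states differ in the relative power of the canonical EEG rhythms —
drowsiness shifts power toward slow waves (theta 4–8 Hz, alpha 8–13 Hz),
sustained attention toward beta (13–30 Hz). A single time–frequency
representation captures this imperfectly, so three complementary wavelet
filter banks are applied to every 30 s window of every channel, and
per-subband feature vectors are classified.

Pipeline: segmentation → three decompositions → 27 features per subband
per channel → mRMR ranking of feature types → fusion of the top-k types
from each transform's best subband → random-search-optimised ensemble →
cross-validated evaluation and iterative majority voting.

## Segmentation

Windows are contiguous from the start of the recording and
non-overlapping by default; a trailing remainder shorter than one window
is dropped, so every segment has exactly `round(window_seconds * fs)`
samples (3840 at the 30 s / 128 Hz reference). This guarantees uniform
inputs for the filter banks at the cost of discarding at most one
partial window per recording. Channel order is file order: no
re-referencing or montage logic is applied. The optional zero-phase
band-pass (Butterworth, forward–backward with Gustafsson initial
conditions to suppress edge transients in short windows) is off by
default, since the reference recordings are band-limited to 0.2–43 Hz in
hardware.

## The three filter banks

**MDWT.** `pywt.wavedec`/`waverec` with db2 and 4 levels by default
(any discrete orthogonal wavelet name is accepted), symmetric boundary
extension. Subbands are indexed SB-1 = level-1 detail (highest octave,
32–64 Hz at 128 Hz) down to the approximation (0–4 Hz) — the SB-1-first
convention is used for all three transforms and is configurable at the
container level, since tables of per-subband results are meaningful under
either convention. Note that db2's 4-tap filters are not very frequency
selective: a mid-band tone puts ~65–75 % (not ≥ 80 %) of its energy into
its nominal dyadic band; longer wavelets (db8) reach > 90 %. This is a
property of the wavelet, not of the cascade.

**TQWT.** A two-channel oversampled filter bank iterated on its low-pass
output, realised directly in the frequency domain. The design equations
map the quality factor and oversampling rate to the channel scalings:
β = 2/(q+1), a = 1 − β/R, with the exact inverses q = (2−β)/β and
R = β/(1−a). At each stage the input spectrum (length N) is split by
power-complementary tapers into a low-pass spectrum of length
2·round(aN/2) and a high-pass spectrum of length 2·round(βN/2); the
transition shape is the 2-vanishing-moment Daubechies frequency response
θ(ω) = ½(1+cos ω)√(2−cos ω), which satisfies θ(ω)² + θ(π−ω)² = 1 and
therefore makes the bank a tight frame. Analysis and synthesis are exact
transposes, so reconstruction is at machine precision and subband
energies add up to the signal energy exactly. Per-stage input lengths
are recorded in the subband container; tampered subband lengths are
rejected at reconstruction.

**FAWT.** The analytic filter bank with rational sampling-rate changes:
p/q (default 3/5) for the low-pass channel and r/s (default 2/3) for the
one-sided high-pass channel. The frequency edges follow, with α1..α4 =
p, q, r, s,

    ωp = ((1−β)π + ε)/p,  ωs = π/q,
    ω0 = ((1−β)π + ε)/r,  ω1 = pπ/(qr),  ω2 = (π−ε)/r,  ω3 = (π+ε)/r,

validated at construction (each violated inequality is reported by
name). β and ε are perfect-reconstruction factors with defaults β = r/s
and ε = ((q−p)/(q+p))π, both overridable; ε = 0 is accepted as a valid
degenerate design point but decomposition requires ε > 0. The
implementation is again a frequency-domain tight frame: the high-pass
channel collects only the positive-frequency band [ω0·r, ω3·r) of the
input grid — including the bins just above Nyquist, which carry the
conjugate reflection of the taper — into a complex analytic subband;
at synthesis the conjugate-mirrored contribution is added back, which
restores unit gain across the upper taper for real signals.
Reconstruction is machine-precision in practice. High-pass subbands are
exported as real signals (2 × the real part of the analytic pair) for
feature extraction; the complex form is retained in the container.

Odd-length inputs to TQWT/FAWT are zero-padded by one sample (recorded
in the container) and truncated after reconstruction.

## The 27 features

With N the length, d_i = x_{i+1} − x_i, g_i = x_{i+2} − x_i, σ the
sample standard deviation (N−1 divisor), and quartiles by linear
interpolation:

| # | feature | definition |
|---|---------|------------|
| 1 | std | σ |
| 2 | Hurst exponent | corrected R/S slope (below) |
| 3 | average energy | Σx²/N |
| 4 | wavelength | Σ\|d_i\| |
| 5 | V-order | (Σ\|x\|^v/N)^{1/v}, v = 2 |
| 6 | skewness | m₃/m₂^{3/2} |
| 7 | kurtosis | m₄/m₂² (not excess) |
| 8 | Hjorth mobility | √(var d / var x) |
| 9 | Higuchi FD | curve-length slope, kmax = 10 |
| 10 | Lyapunov exponent | Rosenstein method (below) |
| 11 | DASDV | √(Σd²/(N−1)) |
| 12 | abs sum of exponential root | \|Σ\|x\|^{0.75}\| |
| 13 | abs sum of square root | \|Σ\|x\|^{0.5}\| |
| 14 | normalised 1st difference | (Σ\|d\|/(N−1))/σ |
| 15 | normalised 2nd difference | (Σ\|g\|/(N−2))/σ |
| 16 | mean of square root | Σ\|x\|^{0.5}/N |
| 17 | difference variance | var(d) |
| 18 | log energy | Σ log(x² + 10⁻¹²) |
| 19 | absolute energy | Σx² |
| 20 | simple square integral | Σ\|x\|² (≡ 19; kept as its own entry) |
| 21 | slope sign changes | #{i : d_{i−1}d_i < 0} |
| 22 | peak amplitude | max x |
| 23 | minima | min x |
| 24 | peak-to-peak | max x − min x |
| 25 | zero-crossing rate | sign changes / (N−1) |
| 26 | IQR | Q3 − Q1 |
| 27 | trimean | (Q1 + 2Q2 + Q3)/4 |

Fractional powers act on |x| (features 12, 13, 16), since negative
samples would otherwise be undefined. The feature list 22–24 resolves a
duplicated "peak amplitude" entry in the conventional listing as
maximum, minimum and peak-to-peak. Degenerate inputs never yield NaN:
σ = 0 makes features 14–15 return 0 with a warning, moment ratios return
0 on constant signals, the Lyapunov exponent of a constant signal is 0,
and the additive 10⁻¹² floors the log-energy sum.

**Hurst.** Rescaled-range analysis over ~10 logarithmically spaced block
sizes in [10, N/2], averaged over non-overlapping blocks, with the
Anis–Lloyd–Peters small-sample correction: H = 0.5 + slope of
log(R/S) − log E[R/S] against log n. The correction matters: raw R/S at
these block sizes is biased to ~0.55–0.6 on white noise, while the
corrected estimator centres at 0.5 (verified over 50 seeds).

**Lyapunov.** Rosenstein's nearest-neighbour divergence method:
embedding dimension 10, delay 1, Theiler window equal to the mean period
(spectral centroid of the power spectrum), least-squares slope over the
first 20 divergence steps. Analysis is capped at the first 512 samples
of the subband — divergence curves on these signals saturate well within
that horizon, and the cap keeps the O(M²) neighbour search proportionate
to the feature's role as one of 27 descriptors. All estimator parameters
(v, kmax, embedding settings, caps, exponent) are overridable per
`FeatureSpec`.

## Ranking and fusion

Greedy mRMR in the MID (difference) form: the first pick maximises the
relevance I(f; y); each later pick maximises I(f; y) − mean_{s∈S} I(f; s)
over the already selected set S. MID rather than the quotient variant is
used because it is stable when redundancy approaches zero. Mutual
information is the plug-in estimate on 10 equal-frequency bins,
computed in nats and reported in bits. Ranking granularity is the
feature *type* (27 candidates): a type's relevance is the mean over its
channel columns, and the redundancy between two types is the mean MI
between their same-channel column pairs (pairing by channel keeps the
estimate focused on the feature relationship rather than cross-channel
covariance). Per-column ranking of all channels × features is available
via `granularity="column"`. Ties break by the printed feature-list
order; constant feature types get relevance 0 and are forced to the end
of the ranking. Fusion concatenates each transform's top-k types (all
channels retained), k = 4 by default — on both the reference data and
the synthetic study, importance flattens after roughly four types.

The fusion inputs default to the best subband per transform, discovered
by cross-validated accuracy over all subbands (the per-subband
accuracy-table logic); a fixed assignment (MDWT SB-1, TQWT SB-1, FAWT
SB-7 — the best subbands on the reference data) is available when
discovery is disabled. Null-data control runs use the fixed assignment:
with no class signal, "best subband by CV" is pure noise-chasing.

**Selection split.** Ranking 27 candidate feature types (and picking the
best of up to eight subbands) on the same labels the classifier is later
scored on leaks label information into the reported accuracy — a few
percentage points even on data with no class signal at all, as a label-
permutation experiment confirms. The end-to-end pipeline therefore
reserves a stratified selection split (default 25 % of segments) for
subband discovery and mRMR ranking, and evaluates only on the disjoint
remainder. The individual staged operations are agnostic to this — the
CLI `rank` command ranks whatever matrix it is given — but the pipeline's
reported accuracies are selection-bias-free by default
(`selection_fraction=0` restores the all-data staged behaviour).

## Classification and evaluation

Bagging is implemented directly: L bootstrap resamples of size M (with
replacement), one base estimator each, majority vote; a resample that
collapses to one class is redrawn (bounded retries). Random-subspace
ensembles reuse the same voting machinery with per-learner feature
subsets; RUSBoost is SAMME-style boosting with per-round random
undersampling of majority classes to the minority count. Base estimators
(decision trees, kNN, LDA) come from scikit-learn.

The "optimizable ensemble" is a seeded random search over the five
families with L ∈ [10, 500] (log-uniform), boosting learning rate ∈
[10⁻³, 1] (log-uniform), tree split limit ∈ [1, M−1] (log-uniform),
subspace dimension ∈ [1, d/2] and kNN k ∈ [1, 20]; the objective is mean
CV accuracy and the argmax becomes the meta-classifier. A random search
with a fixed budget stands in for a black-box optimiser; Bayesian search
is out of scope.

Evaluation pools out-of-fold predictions under HOCV (stratified 80:20),
FFCV or TFCV (stratified shuffled k-fold), and computes one-vs-rest
confusion metrics per class: recall = Tp/(Tp+Fn), specificity =
Tn/(Tn+Fp), precision = Tp/(Tp+Fp), F1 = harmonic mean, plus overall
accuracy from the full confusion matrix. A legacy formulation of these
metrics swaps the roles of Tp and Tn in recall and specificity; the
conventional definitions are the default and `paper_eq11=True`
reproduces the swapped variants. Folds are stratified over segments by
default (group-by-subject folding is a caveat worth noting: pooled
segment folds let within-recording correlation inflate accuracy
relative to a strict subject-independent protocol). The pipeline
evaluates the selected model on folds with a seed independent of the
ones the search scored, so the reported accuracy carries no
best-of-budget selection bias — this is what keeps null-data accuracy
honestly at chance.

IMV (iterative majority voting) runs TFCV `rounds` times (default 10)
with consecutive fold seeds and reports the best overall accuracy and
the best single-fold accuracy; by construction these are maxima, i.e.
optimistic summaries, and are reported as such.

## Synthetic data

Each channel is an independent sum of band-limited Gaussian noise
components (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–43 Hz), synthesised in the frequency domain with random phase, over a
1/f pink-noise floor restricted to the emulated device bandwidth
(0.2–43 Hz — unbounded 1/f would put a third of its power below
0.03 Hz, which no EEG front-end records). Components are scaled so their
*expected* variance matches the profile; normalising each realisation
exactly would stamp every recording with its own gain, and since a
recording belongs to a single state, pooled-fold classifiers would read
that fingerprint as class signal even on null data. With expected-power
scaling, segments are i.i.d. draws of a stationary process and the null
configuration is genuinely uninformative. Total RMS is 20 µV; a
per-subject multiplicative gain (SD 10 %) models inter-subject amplitude
variation. Default profiles: drowsy
θ/α-dominant (α:β = 5), focused β-dominant, unfocused flat; the null
configuration gives every state the flat profile. Seeds derive from a
master seed plus a stable hash of (subject, session, state), so datasets
are reproducible and extensible.

What the generator does *not* model: artifacts (blinks, EMG), volume
conduction and channel covariance, within-block non-stationarity, and
the subtler spectral differences of real mental states. Passing the
end-to-end checks therefore demonstrates that the pipeline recovers
rhythm-power class structure when present and reports chance when
absent — not that real focused/unfocused states (whose spectra overlap
heavily) are separable at the same accuracy.

## Study sizes and numerical choices

The default synthetic study uses 60 segments per class (3 sessions ×
10 min per state) for the separable condition and 120 per class for the
null control — the larger null sample keeps the binomial noise of the
chance-level estimate (σ ≈ 0.025 at n = 360) small relative to the
width of the chance band. The acceptance script runs subband discovery
with a 50-tree bagged probe, a search budget of 8 (4 on null data) and
5 IMV rounds; these sizes are the package's default study scale and can
be raised freely through the config.

Other numerical choices: non-integer ideal subband lengths round to the
nearest even integer (TQWT) or the next even integer (FAWT low-pass, so
the taper always fits under the subband Nyquist); the synthesis banks
use the stored actual lengths; MI discretisation uses quantile bin
edges with duplicate edges collapsed; random streams everywhere are
`numpy.random.default_rng` seeded from explicit integers, and the whole
train/evaluate path is bit-reproducible for a fixed seed.

## Known limitations

* Segment-pooled CV overstates accuracy relative to subject-independent
  evaluation; group folding is available but not the default.
* The MDWT default db2 trades frequency selectivity for time
  localisation; rhythm attribution of its subbands is approximate.
* IMV reports maxima over repeated CV rounds and should be read as a
  best-case figure, not an expected accuracy.
* The Lyapunov and Hurst estimators are conventional but parameter-
  sensitive; they are features, not certified dynamical invariants.
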