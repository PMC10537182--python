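# eegstates

Ensemble wavelet decomposition pipeline for detecting mental states —
**focused**, **unfocused** and **drowsy** — from multichannel EEG.

Brain–computer interfaces need a reliable read-out of attention and
drowsiness, but EEG is non-stationary and nonlinear, so no single
time–frequency representation captures all of the discriminative
structure. This package implements a pipeline that attacks the problem
with an *ensemble of three wavelet filter banks*, nonlinear feature
extraction, information-theoretic feature selection and an optimizable
majority-vote ensemble classifier:

1. **Segmentation** — recordings (reference setup: 14 channels at 128 Hz)
   are cut into non-overlapping 30 s windows of 3840 samples.
2. **Decomposition** — each channel of each window is decomposed three
   ways:
   * **MDWT**: multilevel discrete wavelet transform (db2, 4 levels →
     5 subbands aligned with the δ/θ/α/β/γ rhythms);
   * **TQWT**: tunable Q-factor wavelet transform with quality factor
     *q*, oversampling rate *R* and depth *B* (defaults q=2, R=5, B=7 →
     8 subbands), where the channel scalings follow
     β = 2/(q+1) and a = 1 − β/R;
   * **FAWT**: flexible analytic wavelet transform with rational sampling
     rates (p/q = 3/5 low-pass, r/s = 2/3 high-pass, B=6 → 7 subbands)
     and complex analytic high-pass atoms.
   All three are perfect-reconstruction filter banks (verified to
   < 1e−8 / 1e−6 relative error).
3. **Features** — 27 statistical and nonlinear descriptors per subband
   per channel (standard deviation, Hurst exponent, Higuchi fractal
   dimension, largest Lyapunov exponent, Hjorth mobility, energy and
   difference statistics, quartile statistics, …): 14 × 27 = 378 columns
   per subband.
4. **Selection & fusion** — greedy mRMR (mutual-information difference)
   ranks the 27 feature types; the top-k types (default k=4) from each
   transform's best subband are concatenated across transforms. The
   end-to-end pipeline ranks and discovers subbands on a held-out
   stratified selection split (25 % of segments by default) so the
   reported accuracy carries no feature-selection bias.
5. **Classification** — a random search over five ensemble families
   (bagged trees, boosted trees, RUS-boosted trees, random-subspace kNN,
   random-subspace discriminant) picks the best configuration by mean CV
   accuracy; evaluation uses 80:20 holdout (HOCV), 5-fold (FFCV) or
   10-fold (TFCV) stratified cross-validation with one-vs-rest
   recall / specificity / precision / F1, and iterative majority voting
   (IMV) reports the best of repeated TFCV rounds.

A synthetic-data module generates labeled multichannel EEG-like
recordings with state-dependent rhythm power (drowsy = θ/α-dominant,
focused = β-dominant, unfocused = flat), so the entire pipeline is
testable without external data.

## Worked example

```bash
python examples/train_and_evaluate.py
```

builds a compact synthetic dataset (10 segments/class, 6 channels), runs
the fused pipeline and prints:

```
30 segments, 10 per class

best learner: subspace_discriminant (L=29)
TFCV accuracy: 1.0000

per-class metrics (one-vs-rest):
           recall  specificity  precision   f1
drowsy        1.0          1.0        1.0  1.0
focused       1.0          1.0        1.0  1.0
unfocused     1.0          1.0        1.0  1.0

IMV over 3 rounds: best overall 1.0000, best single fold 1.0000
```

With the default well-separated state profiles the three classes are
fully recoverable; shrinking the profile differences moves the accuracy
smoothly down to the chance level of 1/3. The other examples
(`simulate_dataset.py`, `decompose_transforms.py`, `extract_features.py`,
`rank_and_fuse.py`) walk through the individual stages and print what
each number means.

## Command-line interface

The same stages are available as a staged CLI driven by one YAML config:

```bash
eegstates simulate   --config config.yaml   # write labeled recordings
eegstates decompose  --config config.yaml --transform tqwt
eegstates features   --config config.yaml   # segment x feature matrices
eegstates rank       --config config.yaml   # mRMR rankings
eegstates fuse       --config config.yaml --k 4
eegstates train-eval --config config.yaml --cv 10fold --imv-rounds 10
eegstates reproduce  --config config.yaml   # the whole chain + summary
```

`eegstates reproduce` also works on real recordings: point the config's
simulate block at your own EDF or CSV-matrix files loaded via
`eegstates.load_recording` (EDF headers supply the sampling rate; plain
matrices need `fs` explicitly). `--paper-eq11` switches recall and
specificity to a legacy variant with the positive/negative roles swapped.

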