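# pigvoc

Recognition of pig vocalizations for precision livestock monitoring.

Pigs produce acoustically distinct call types — eating, estrus, howling,
humming and panting sounds — whose automatic recognition from pen
microphones supports welfare and health monitoring.  `pigvoc` implements
the full recognition chain as a reusable bioacoustics toolkit:

1. **Kalman denoising** — autoregressive state-space speech enhancement.
   The clean signal in each 20 ms frame is modelled as an order-*p* AR
   process; each noisy sample is filtered with the standard predict/update
   cycle, with the measurement-noise variance *R* taken from a noise
   reference or minimum statistics.
2. **Endpoint detection** — the improved EMD-TEO cepstral-distance method:
   empirical mode decomposition into intrinsic mode functions, Teager
   energy ψ[n] = x²(n) − x(n−1)x(n+1) of the selected IMFs, a double
   threshold on frame energy, and short-time cepstral-distance refinement
   of the boundaries.
3. **MFCC features** — pre-emphasis 0.98, 20 ms frames / 10 ms hop,
   Hamming window, 26 triangular mel filters, DCT; 13 static coefficients
   plus Δ and ΔΔ give the 39-d frame vector.
4. **GMM-HMM acoustic models** — one left-to-right HMM per call type
   (5 states, π = [1, 0, …, 0], self-loop or advance only) with
   diagonal-covariance Gaussian-mixture emissions, trained by
   multi-sequence Baum–Welch EM (40 iterations, tolerance 10⁻⁶) and scored
   by Viterbi.
5. **Hybrid DNN-HMM** — a 3×128 ReLU network with a 25-way softmax maps
   7-frame spliced features (273-d) to class-state posteriors p(q|x_t),
   trained on GMM-HMM forced alignments (Adam, lr 0.003, batch 100, early
   stopping).  Decoding converts posteriors to scaled likelihoods
   p(x_t|q) ∝ p(q|x_t)/p(q) and runs per-class Viterbi:

   p(x|w) ≅ max_q π(q₀) ∏ₜ a_{q_{t−1}q_t} ∏ₜ p(q_t|x_t)/p(q_t)

Because field recordings of this kind are rarely shareable, the package
ships a seeded synthetic vocalization generator (harmonic source + formant
filters + band-limited background noise, with known class labels, clean
references and segment boundaries) so every stage — and the end-to-end
system — is testable with exact ground truth.

## Worked example

```python
from pigvoc import RunConfig, generate_dataset, run_evaluate, run_train

clips, manifest = generate_dataset(n_per_class=12, seed=42)
signals = [c.audio for c in clips]
labels = [e.label for e in manifest.entries]
train = [i for i, e in enumerate(manifest.entries) if e.split == "train"]
test = [i for i, e in enumerate(manifest.entries) if e.split == "test"]

system = run_train([signals[i] for i in train], [labels[i] for i in train],
                   RunConfig(n_components=2, em_max_iter=15, base_hmm=True, seed=42))
reports = run_evaluate(system, [signals[i] for i in test],
                       [labels[i] for i in test])
for name, rep in reports.items():
    print(f"{name:9s} accuracy={rep.accuracy:.2f} "
          f"macro_recall={rep.macro_recall:.2f} "
          f"macro_specificity={rep.macro_specificity:.2f}")
```

prints

```
gmm_hmm   accuracy=1.00 macro_recall=1.00 macro_specificity=1.00
dnn_hmm   accuracy=1.00 macro_recall=1.00 macro_specificity=1.00
base_hmm  accuracy=1.00 macro_recall=1.00 macro_specificity=1.00
```

Accuracy is trace/total of the confusion matrix over held-out clips;
macro recall and specificity are unweighted means of the per-class
one-vs-rest values (recall = TP/(TP+FN), specificity = 1 − FP/(FP+TN)).
At 12 clips per class the five default synthetic call types are cleanly
separated by all three models; `base_hmm` is the single-Gaussian
(K = 1) ablation of the GMM-HMM.

The estimators also compose with scikit-learn:
`GMMHMMClassifier(n_states=5, n_components=4).fit(X, y).predict(X)` where
`X` is a list of T×39 feature matrices, and `MFCCExtractor`,
`KalmanDenoiser` and `EndpointDetector` are transformers.

A command-line interface mirrors the library:

```sh
pigvoc make-fixtures --out data/ --n 50 --seed 7
pigvoc run-all --data data/ --report report.json --seed 7
pigvoc denoise --in noisy.wav --out clean.wav
pigvoc segment --in clean.wav --out segments.csv
```

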