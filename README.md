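# midecode

Continuous decoding of left- vs right-hand **motor imagery (MI)** from
3-channel EEG (C3, Cz, C4 at 250 Hz), built around three ideas:

1. **STFT input images.** Each 8-s trial (cue at 3 s, imagery 3–7 s) is cut
   into eleven sliding 2-s windows (200 ms hop, window end times
   5.0–7.0 s).  Per window and channel a magnitude short-time Fourier
   spectrogram (64-sample Hamming taper, 50-sample overlap, 512 FFT
   points → 257×32) is reduced to the physiologically informative bands:
   the theta–alpha slice (4–13 Hz, 20 rows) is stacked over the beta slice
   (13–32 Hz, 41 rows, cubic-interpolated to 20), and the three channels
   are stacked depthwise into a **40×32×3** image.  Eleven images per trial
   means one decoding — hence one unit of neurofeedback — every 200 ms.
2. **Mega Block CNNs.**  Two small architectures classify the images.
   The intra-subject network is conv16(3×3)→conv32→conv64 with 3×3
   stride-2 max pooling, a final 8×8 average pool and a softmax over
   {left, right}.  The inter-subject network stacks three *Mega Blocks*
   (conv/batch-norm/ReLU blocks of 9, 18, 36 filters, kernels 5×5/3×3/3×3)
   whose repeat counts (1–5 each) adapt network depth to inter-subject
   variability.  Same-padded convolutions and ceil-mode pooling give
   flattened feature sizes 192 (intra) and 108 (inter) regardless of
   repeats.  Training uses SGD-with-momentum
   (v ← μv − η∇ℓ; θ ← θ + v) or Adam
   (m ← β₁m + (1−β₁)g; v ← β₂v + (1−β₂)g²; θ ← θ − η·m̂/(√v̂ + ε))
   on a cross-entropy loss −Σᵢⱼ tᵢⱼ ln yᵢⱼ, implemented from the update
   equations in plain numpy with a gradient-checked backward pass.
3. **GP hyperparameter search.** Repeat counts, learning rate, momentum
   and L2 strength are chosen by Gaussian-process Bayesian optimization
   (Matérn-5/2, expected-improvement EI = E[max(0, μ(x_b) − f(x))] or
   probability-of-improvement PI = Φ((μ(x_b) − m − μ(x))/σ(x))) over
   1–5 layers, lr ∈ [1e-6, 1e-2], momentum ∈ [0.6, 0.98],
   L2 ∈ [1e-10, 1e-2], with a 30-evaluation budget.

Decoding quality is reported as **CA_gross** (percent of all trials×11
window decodings correct), **CA_ST** (percent of trials with ≥6 of 11
windows correct) and **CA_opt** (best single decoding instant), plus
Cohen's κ and paired Wilcoxon comparisons — in both the **intra-subject**
protocol (train sessions 1–3, test sessions 4–5) and the
**inter-subject leave-one-subject-out** protocol (train on all five
sessions of every other subject).

A bundled synthetic EEG generator plants the event-related
desynchronization (ERD) the decoder relies on — contralateral mu/beta
amplitude suppression on a 1/f background — so the full pipeline is
testable end to end without any data download.  Real recordings in GDF
form (e.g. the BCI Competition IV-2b distribution) can be read through
the optional `mne` dependency.

## Worked example

```python
from midecode import (RunConfig, SynthConfig, TrainConfig,
                      generate_dataset, run_intra)
from midecode.metrics import format_report_table

data = generate_dataset(1, 20, 5, SynthConfig(erd_depth=0.7, seed=3))
config = RunConfig(mode="intra", architecture="arch1",
                   train=TrainConfig(optimizer="adam", epochs=5,
                                     batch_size=50, learning_rate=1e-3),
                   seed=3)
reports = run_intra(config, data)
print(format_report_table({f"S{s:02d}": r for s, r in reports.items()}))
```

prints (about a minute on one CPU):

```
subject CA_gross        kappa   CA_ST   kappa   CA_opt  @time(s)
S01     100.00  1.00    100.00  1.00    100.00  5.0
```

CA_gross = 100 means every one of the 40×11 test windows was decoded
correctly (the planted ERD is strong and the synthetic background is
benign — real EEG is far harder); CA_ST = 100 means every test trial had
a correct window majority; CA_opt = 100 at 5.0 s means the first
decoding instant (the 2-s window ending 5 s after trial start) was
already perfect.  κ is the chance-corrected agreement
(0 = chance, 1 = perfect).  With
`erd_depth=0` in the generator the same pipeline drops to the 50 %
chance level of this balanced two-class problem.

The `examples/` scripts walk each capability: synthetic ERD generation,
the image shape chain, intra-subject decoding, and the GP search.  The
same flows are scriptable from the shell via the thin `mi` CLI
(`mi synth`, `mi convert`, `mi images`, `mi run --config run.yaml`,
`mi report`).

## Layout

- `midecode.synth` — ERD/ERS synthetic EEG generator
- `midecode.trials` — trial/session model, fixture + GDF I/O, splits
- `midecode.images` — segmentation, STFT, 40×32×3 image assembly
- `midecode.cnn` — architecture specs, shape tracing, numpy CNN
- `midecode.train` — cross-entropy, SGDM/Adam, training loop
- `midecode.bayesopt` — GP posterior, EI/PI, search loop
- `midecode.metrics` — CA_gross/CA_ST/CA_opt, κ, Wilcoxon
- `midecode.pipeline` — intra/inter orchestration; `midecode.cli` — `mi`

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
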