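# ppgpeakkit

Noise-robust detection of systolic peaks in photoplethysmogram (PPG)
signals. Wrist-worn optical sensors yield a quasi-periodic pulse waveform
whose systolic peaks carry heart rate and heart-rate variability, but
free-living recordings are corrupted by baseline wander and burst-like
motion artifacts whose spectra overlap the pulse band, so classical
threshold- and transform-based peak pickers degrade sharply at low
signal-to-noise ratio (SNR). This package is aimed at researchers and
engineers who need beat-to-beat peak locations from noisy single-channel
PPG and a controlled way to measure how detection quality decays with
noise level.

## What is inside

- **Synthetic signal bank** (`ppgpeakkit.synthetic`) — clean quasi-periodic
  PPG with exactly known peak locations (two-Gaussian cycle morphology,
  lognormal beat-to-beat jitter, heart rates 40–200 bpm), sub-hertz
  baseline wander, and Tukey-tapered band-passed motion-artifact bursts;
  plus linear-interpolation upsampling (e.g. 20 Hz → 100 Hz).
- **Noisy-segment generator** (`ppgpeakkit.generator`) — mixes a clean
  window X with a noise window N as S = w_X·X + w_N·N with w_X = 1 and
  w_N ~ U(0, 5), normalizes S to [−1, 1], computes
  SNR = 10·log₁₀(P_signal/P_noise) from the weighted components, and labels
  each clean-signal systolic peak with five ones (the peak sample ± 2).
  Segments span −2.5 to 47.5 dB in ten 5 dB bins, with optional per-bin
  balancing.
- **Dilated convolutional sequence labeler** (`ppgpeakkit.model`) — seven
  1-D convolution layers, kernel 3, dilation doubling 1 → 64, filters
  (4, 8, 8, 16, 16, 32, 1), ELU hidden activations and a sigmoid output:
  one peak probability per time step at the full 1500-sample resolution,
  with only **3169 trainable parameters** and a final-layer receptive
  field of r_l = 2^(l+2) − 1 = **255 samples**. Forward, backward and the
  Adam optimizer are implemented directly on numpy arrays (with
  numba-fused activations), minimizing per-sample binary cross-entropy.
- **Peak finder** (`ppgpeakkit.peaks`) — probability threshold (default
  0.5), per-run local-maximum extraction (first index on ties), and
  refractory correction: assuming a 200 bpm ceiling, peaks closer than
  300 ms are revisited in descending probability order and kept only if
  they preserve the minimum spacing.
- **Evaluation protocol** (`ppgpeakkit.evaluate`) — one-to-one matching of
  detected vs true peaks within a 50 ms tolerance; precision = TP/(TP+FP),
  recall = TP/(TP+FN), F1 = 2·TP/(2·TP+FP+FN), pooled per 5 dB SNR bin and
  overall.

## Worked example

Train the network on balanced synthetic noisy PPG (batch 64, 20 epochs,
50 steps per epoch) and evaluate on 2000 held-out segments drawn from
unseen virtual subjects:

```python
import ppgpeakkit as pk

seed = 1
clean_tr = pk.build_clean_bank(n_records=24, record_duration_s=60, seed=seed)
noise_tr = pk.build_noise_bank(n_records=24, record_duration_s=60, seed=seed + 1)
clean_te = pk.build_clean_bank(n_records=12, record_duration_s=60, seed=seed + 100)
noise_te = pk.build_noise_bank(n_records=12, record_duration_s=60, seed=seed + 101)

gen_cfg = pk.GeneratorConfig(batch_size=64, seed=seed)
model = pk.build_model(seed=seed)
train_cfg = pk.TrainConfig(batch_size=64, epochs=20, steps_per_epoch=50, seed=seed)
pk.train(model, pk.training_stream(gen_cfg, clean_tr, noise_tr, seed=seed + 10), train_cfg)

segments = pk.generate_batch(pk.GeneratorConfig(batch_size=2000, seed=seed + 200),
                             clean_te, noise_te)
cfg = pk.PeakFinderConfig()
table = pk.evaluate_by_snr(lambda s: pk.detect(s.signal, model, cfg).indices, segments)
print(table.to_frame()[["snr_label_db", "precision", "recall", "f1"]].to_string(index=False))
```

Output of this exact run (training loss fell 0.427 → 0.036 over 1000
steps; ~4 minutes on one CPU core):

```
snr_label_db  precision   recall       f1
           0   0.936924 0.807346 0.867322
           5   0.988470 0.973025 0.980686
          10   0.991145 0.988419 0.989780
          15   0.996701 0.998760 0.997729
          20   0.997248 1.000000 0.998622
          25   0.997452 1.000000 0.998724
          30   0.997207 1.000000 0.998601
          35   0.996626 1.000000 0.998310
          40   0.996068 1.000000 0.998030
          45   0.998089 1.000000 0.999044
     overall   0.989992 0.975539 0.982713
```

Rows are 5 dB SNR bins labeled by their center (45 ≈ noise-free, 0 ≈
noise as strong as the signal). F1 stays near 1 down to ~10 dB and only
the noisiest bin drops below 0.9 — recall suffers first because motion
bursts bury genuine pulses.

A command-line interface mirrors the library:

```bash
ppg-peakkit generate --seed 1 -n 100 --out data/
ppg-peakkit train --seed 1 --out run/
ppg-peakkit detect --input ppg.txt --model run/model.npz --threshold 0.5 \
    --refractory-ms 300 --fs 100 --output peaks.txt
ppg-peakkit evaluate --data data/ --model run/model.npz --out metrics.csv
```

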