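"""From one trial to the CNN's eleven 40x32x3 input images.

Walks the shape chain: 8-s trial -> 11 sliding 2-s windows -> per-channel
257x32 magnitude STFT -> 20-row theta-alpha slice + 41-row beta slice
(cubic-interpolated to 20) -> 40x32 plane -> 40x32x3 image.
"""

import numpy as np

from midecode import (SegmentGrid, StftParams, SynthConfig,
                      compute_spectrogram, generate_trial, trial_images)
from midecode.images import (BETA_BAND_HZ, THETA_ALPHA_BAND_HZ, band_bins,
                             segment_trial)

config = SynthConfig(erd_depth=0.6, seed=1)
trial = generate_trial("left", config, np.random.default_rng(1))

grid = SegmentGrid()
segs = segment_trial(trial, grid)
print(f"trial: {trial.data.shape} samples at {trial.sampling_rate:g} Hz")
print(f"segments: {segs.shape}  (windows end at "
      f"{grid.window_end_times[0]:.1f}..{grid.window_end_times[-1]:.1f} s)")

spec = compute_spectrogram(segs[0][0])
print(f"one-channel spectrogram: {spec.shape}  "
      f"(64-sample Hamming, 50 overlap, 512-point FFT)")

p = StftParams()
ta = band_bins(THETA_ALPHA_BAND_HZ, 250.0, p.n_fft)
be = band_bins(BETA_BAND_HZ, 250.0, p.n_fft)
print(f"theta-alpha rows: bins {ta[0]}..{ta[1]} -> {ta[1]-ta[0]+1} rows")
print(f"beta rows:        bins {be[0]}..{be[1]} -> {be[1]-be[0]+1} rows "
      f"(interpolated to 20)")

imgs = trial_images(trial)
print(f"input images: {imgs.shape}  values in [{imgs.min():.2f}, "
      f"{imgs.max():.2f}]")
# 11 images per trial is the continuous-decoding granularity: one decision
# every 200 ms across the 3-7 s imagery interval.
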