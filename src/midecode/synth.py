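"""Synthetic motor-imagery EEG with ERD structure.

The generator emulates the statistical structure a sensorimotor-rhythm
decoder relies on: three bipolar channels (C3, Cz, C4) carrying mu
(8-13 Hz) and beta (13-32 Hz) oscillations on a 1/f background, with an
event-related desynchronization (ERD) — a band-power *decrease* — at the
channel contralateral to the imagined hand (C4 for left-hand imagery, C3
for right-hand) during the imagery interval.

The oscillations are amplitude-modulated sinusoids at 10 and 22 Hz with
per-trial random phase and narrowband frequency jitter; ERD is applied as
an amplitude gain of sqrt(1 - erd_depth) over the imagery interval with
250 ms cosine on/off ramps so the first and last analysis windows see no
step edge.  The background is Gaussian noise spectrally shaped to
1/f^noise_exponent.

No volume conduction, ocular/muscular artifacts, or feedback-dependent
non-stationarity are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trials import CHANNELS, LABELS, SessionSet, Trial

#: oscillation center frequencies (Hz) for the mu and beta rhythms
MU_CENTER_HZ = 10.0
BETA_CENTER_HZ = 22.0
#: beta amplitude relative to mu (beta rhythms are typically weaker)
BETA_REL_AMPLITUDE = 0.5
#: ERD on/off ramp duration, seconds
ERD_RAMP_S = 0.25
#: half-width of the per-trial center-frequency jitter, Hz
FREQ_JITTER_HZ = 1.0
#: depth of the slow amplitude modulation of each oscillation
AM_DEPTH = 0.3


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults mirror the 2b recording protocol."""

    sampling_rate: float = 250.0
    trial_length: float = 8.0
    mi_interval: tuple[float, float] = (3.0, 7.0)
    channels: tuple[str, ...] = CHANNELS
    erd_depth: float = 0.5
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (13.0, 32.0)
    noise_exponent: float = 1.0
    snr: float = 1.0
    subject_shift_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in [0,1], got {self.erd_depth}")
        lo, hi = self.mi_interval
        if not (0.0 <= lo < hi <= self.trial_length):
            raise ValueError(f"mi_interval {self.mi_interval} must lie within "
                             f"[0, {self.trial_length}]")
        if self.sampling_rate <= 2.0 * max(self.beta_band):
            raise ValueError("sampling_rate must exceed twice the top beta edge")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length * self.sampling_rate))


def _one_over_f_noise(n: int, exponent: float, fs: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.std(x)


def _erd_gain(config: SynthConfig, depth: float) -> np.ndarray:
    """Amplitude gain over the trial: 1 outside MI, sqrt(1-depth) inside,
    with raised-cosine ramps of ERD_RAMP_S at either edge."""
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    lo, hi = config.mi_interval
    ramp = ERD_RAMP_S
    frac = np.zeros(n)
    core = (t >= lo + ramp) & (t < hi - ramp)
    frac[core] = 1.0
    on = (t >= lo) & (t < lo + ramp)
    frac[on] = 0.5 * (1 - np.cos(np.pi * (t[on] - lo) / ramp))
    off = (t >= hi - ramp) & (t < hi)
    frac[off] = 0.5 * (1 + np.cos(np.pi * (t[off] - (hi - ramp)) / ramp))
    return 1.0 - (1.0 - np.sqrt(1.0 - depth)) * frac


def _oscillation(config: SynthConfig, center: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated sinusoid with random phase and frequency jitter."""
    t = np.arange(config.n_samples) / config.sampling_rate
    f = center + rng.uniform(-FREQ_JITTER_HZ, FREQ_JITTER_HZ)
    phase = rng.uniform(0, 2 * np.pi)
    f_env = rng.uniform(0.2, 0.6)
    phase_env = rng.uniform(0, 2 * np.pi)
    env = 1.0 + AM_DEPTH * np.sin(2 * np.pi * f_env * t + phase_env)
    return env * np.sin(2 * np.pi * f * t + phase)


def contralateral_channel(label: str) -> str:
    """The motor-cortex channel showing ERD for the given imagined hand."""
    if label == "left":
        return "C4"
    if label == "right":
        return "C3"
    raise ValueError(f"label must be one of {LABELS}, got {label!r}")


def generate_trial(label: str, config: SynthConfig,
                   rng: np.random.Generator,
                   erd_depth: float | None = None) -> Trial:
    """Generate one labeled trial.

    Every channel carries independent mu+beta oscillations (combined RMS =
    ``snr`` x noise RMS) on 1/f noise; the channel contralateral to the
    imagined hand has its oscillation amplitude scaled by
    sqrt(1 - erd_depth) during the MI interval.
    """
    depth = config.erd_depth if erd_depth is None else float(np.clip(erd_depth, 0, 1))
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    n = config.n_samples
    contra = contralateral_channel(label)
    gain = _erd_gain(config, depth)
    data = np.empty((len(config.channels), n))
    # scale so that combined oscillation RMS / noise RMS = snr (outside MI):
    # osc power = (1 + BETA_REL_AMPLITUDE^2) * a^2 * <env^2> / 2 with unit noise
    env_ms = 1.0 + AM_DEPTH**2 / 2.0
    amp = config.snr / np.sqrt((1.0 + BETA_REL_AMPLITUDE**2) * env_ms / 2.0)
    for ci, ch in enumerate(config.channels):
        noise = _one_over_f_noise(n, config.noise_exponent, config.sampling_rate, rng)
        osc = amp * (_oscillation(config, MU_CENTER_HZ, rng)
                     + BETA_REL_AMPLITUDE * _oscillation(config, BETA_CENTER_HZ, rng))
        if ch == contra:
            osc = osc * gain
        data[ci] = noise + osc
    return Trial(data=data, label=label, sampling_rate=config.sampling_rate)


def _balanced_labels(n: int, rng: np.random.Generator) -> list[str]:
    if n % 2:
        raise ValueError(f"trials per session must be even for exact class "
                         f"balance, got {n}")
    labels = ["left"] * (n // 2) + ["right"] * (n // 2)
    order = rng.permutation(n)
    return [labels[i] for i in order]


def generate_dataset(n_subjects: int,
                     trials_per_session: int | Sequence[int],
                     n_sessions: int,
                     config: SynthConfig) -> list[SessionSet]:
    """Generate a multi-subject, multi-session dataset.

    Each session is exactly class-balanced.  Per-subject ERD depth is drawn
    once, lognormally around ``config.erd_depth`` with log-sd
    ``subject_shift_sd`` (clipped to [0, 1]), emulating between-subject
    variability in sensorimotor responsiveness.

    ``trials_per_session`` may be a single even count or a per-session
    sequence (e.g. ``(140, 140, 140, 160, 160)`` for a competition-shaped
    subject).
    """
    if n_subjects < 1 or n_sessions < 1:
        raise ValueError("n_subjects and n_sessions must be >= 1")
    if isinstance(trials_per_session, (int, np.integer)):
        counts = [int(trials_per_session)] * n_sessions
    else:
        counts = [int(c) for c in trials_per_session]
        if len(counts) != n_sessions:
            raise ValueError("per-session counts must match n_sessions")
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(n_subjects)
    out: list[SessionSet] = []
    for si, sseed in enumerate(subject_seeds, start=1):
        rng = np.random.default_rng(sseed)
        if config.subject_shift_sd > 0:
            depth = float(np.clip(
                config.erd_depth * np.exp(rng.normal(0, config.subject_shift_sd)),
                0.0, 1.0))
        else:
            depth = config.erd_depth
        for sess in range(1, n_sessions + 1):
            labels = _balanced_labels(counts[sess - 1], rng)
            trials = [generate_trial(lab, config, rng, erd_depth=depth)
                      for lab in labels]
            out.append(SessionSet(subject_id=si, session_id=sess, trials=trials,
                                  meta={"erd_depth": depth}))
    return out
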