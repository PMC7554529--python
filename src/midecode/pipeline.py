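"""End-to-end orchestration: trials -> images -> training -> metrics.

Two experimental modes:

* ``run_intra`` — per subject, train on sessions 1-3 and test on sessions
  4-5 (Architecture-1 by default);
* ``run_inter`` — leave-one-subject-out: per held-out subject, train on
  all five sessions of every other subject (Architecture-2 Mega Blocks,
  repeats either given per subject or found by Bayesian optimization) and
  test on the held-out subject's sessions 4-5.

All randomness (weight init, shuffling, validation sampling, acquisition
candidates) derives from one root seed via named substreams, so a run is
reproducible end to end.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import bayesopt, images, metrics, train, trials
from .cnn import ArchitectureSpec, CNNModel, build_architecture
from .trials import LABELS, SessionSet, Trial

LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS)}


def substream_seed(root_seed: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    return (root_seed * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class RunConfig:
    mode: str = "intra"                     # 'intra' or 'inter'
    architecture: str = "arch1"             # 'arch1', 'arch2', or 'bayesopt'
    repeats: tuple[int, int, int] = (1, 1, 1)
    train: train.TrainConfig = field(default_factory=train.TrainConfig)
    bayesopt_budget: int = 30
    acquisition: str = "ei"
    normalize: str = "minmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("intra", "inter"):
            raise ValueError(f"unknown mode {self.mode!r}")


def segment_dataset(trial_list: Sequence[Trial],
                    grid: images.SegmentGrid = images.DEFAULT_GRID,
                    params: images.StftParams = images.DEFAULT_STFT,
                    normalize: str = "minmax") -> tuple[np.ndarray, np.ndarray]:
    """Images and per-segment labels for a list of trials.

    Every window of a trial inherits the trial label, so N trials yield
    N x 11 labeled training instances.
    """
    imgs, labels = [], []
    for t in trial_list:
        ti = images.trial_images(t, grid, params, normalize)
        imgs.append(ti)
        labels.extend([LABEL_INDEX[t.label]] * len(ti))
    return np.concatenate(imgs, axis=0), np.array(labels, dtype=np.int64)


def predict_trials(model: CNNModel, test_trials: Sequence[Trial],
                   grid: images.SegmentGrid = images.DEFAULT_GRID,
                   params: images.StftParams = images.DEFAULT_STFT,
                   normalize: str = "minmax") -> metrics.SegmentPredictions:
    """Decode every window of every test trial."""
    imgs, _ = segment_dataset(test_trials, grid, params, normalize)
    probs = model.predict_proba(imgs)
    n = len(test_trials)
    k = grid.n_segments
    probs = probs.reshape(n, k, -1)
    return metrics.SegmentPredictions(
        predicted=probs.argmax(axis=-1),
        true_labels=np.array([LABEL_INDEX[t.label] for t in test_trials]),
        probabilities=probs,
        window_end_times=grid.window_end_times,
    )


def _audit_no_leakage(train_trials: Sequence[Trial],
                      test_trials: Sequence[Trial]) -> None:
    train_ids = {id(t) for t in train_trials}
    if train_ids & {id(t) for t in test_trials}:
        raise AssertionError("train/test trial leakage detected")


def _fit_and_score(arch: ArchitectureSpec, train_trials, test_trials,
                   tconf: train.TrainConfig, normalize: str):
    _audit_no_leakage(train_trials, test_trials)
    x, y = segment_dataset(train_trials, normalize=normalize)
    model, history = train.fit(arch, x, y, tconf)
    preds = predict_trials(model, test_trials, normalize=normalize)
    report = metrics.MetricsReport.from_predictions(preds)
    return model, history, preds, report


def run_intra(config: RunConfig,
              sessions: Iterable[SessionSet]) -> dict[int, metrics.MetricsReport]:
    """Intra-subject protocol for every subject present."""
    sessions = list(sessions)
    reports: dict[int, metrics.MetricsReport] = {}
    for sid in sorted({s.subject_id for s in sessions}):
        tr, te = trials.split_intra_subject(sessions, sid)
        arch = (build_architecture("arch2", config.repeats)
                if config.architecture == "arch2"
                else build_architecture("arch1"))
        tconf = replace(config.train,
                        seed=substream_seed(config.seed, f"intra.fit.{sid}"))
        _, _, _, report = _fit_and_score(arch, tr, te, tconf, config.normalize)
        reports[sid] = report
    return reports


def _bayesopt_arch(config: RunConfig, train_trials, subject_key: str
                   ) -> tuple[ArchitectureSpec, train.TrainConfig,
                              bayesopt.OptimizationResult]:
    """Search repeats/lr/momentum/l2 by GP optimization of the validation
    error of a short training run on the pooled training trials."""
    x, y = segment_dataset(train_trials, normalize=config.normalize)

    def objective(params: dict) -> float:
        r = int(params["n_conv_layers"])
        arch = build_architecture("arch2", (r, r, r), l2=params["l2"])
        tconf = replace(
            config.train,
            learning_rate=params["learning_rate"],
            momentum=params.get("momentum", config.train.momentum),
            seed=substream_seed(config.seed, f"bayesopt.fit.{subject_key}"),
        )
        _, history = train.fit(arch, x, y, tconf)
        return history["val_error"][-1]

    space = bayesopt.SearchSpace.decoder_default(budget=config.bayesopt_budget)
    result = bayesopt.optimize_hyperparameters(
        objective, space, acquisition=config.acquisition,
        seed=substream_seed(config.seed, f"bayesopt.{subject_key}"))
    best = result.best_config
    r = int(best["n_conv_layers"])
    arch = build_architecture("arch2", (r, r, r), l2=best["l2"])
    tconf = replace(config.train, learning_rate=best["learning_rate"],
                    momentum=best.get("momentum", config.train.momentum))
    return arch, tconf, result


def run_inter(config: RunConfig,
              sessions: Iterable[SessionSet],
              repeats_per_subject: dict[int, tuple[int, int, int]] | None = None,
              ) -> dict[int, metrics.MetricsReport]:
    """Leave-one-subject-out protocol for every subject present.

    ``repeats_per_subject`` supplies published per-subject Mega Block
    repeat counts directly; with ``architecture='bayesopt'`` the repeats
    and training hyperparameters are searched per held-out subject.
    """
    sessions = list(sessions)
    subject_ids = sorted({s.subject_id for s in sessions})
    if len(subject_ids) < 2:
        raise ValueError("inter-subject mode needs >= 2 subjects")
    reports: dict[int, metrics.MetricsReport] = {}
    for sid in subject_ids:
        tr, te = trials.assemble_inter_subject(sessions, sid)
        if config.architecture == "bayesopt":
            arch, tconf, _ = _bayesopt_arch(config, tr, f"s{sid}")
        else:
            reps = (repeats_per_subject or {}).get(sid, config.repeats)
            arch = build_architecture("arch2", reps)
            tconf = config.train
        tconf = replace(tconf, seed=substream_seed(config.seed, f"inter.fit.{sid}"))
        _, _, _, report = _fit_and_score(arch, tr, te, tconf, config.normalize)
        reports[sid] = report
    return reports
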