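"""Continuous-decoding performance metrics.

Each test trial is decoded 11 times — once per sliding 2-s window ending
at 5.0, 5.2, ..., 7.0 s — and three accuracies summarize the grid:

* ``CA_gross``: fraction of all window decodings (trials x 11) that are
  correct — the continuous-feedback view;
* ``CA_ST``: single-trial accuracy — a trial counts as correct when at
  least 6 of its 11 windows agree with the true label;
* ``CA_opt``: the best per-window-instant accuracy across the 11 decoding
  instants (column-wise over trials), with its instant; ties resolve to
  the earliest instant (lowest feedback latency).

All three are reported in percent.  Cohen's kappa gives chance-corrected
agreement; Wilcoxon signed-rank tests compare paired per-subject metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import wilcoxon

#: minimum correct windows (out of 11) for a trial to count as correct
ST_THRESHOLD = 6
N_SEGMENTS = 11


@dataclass
class SegmentPredictions:
    """Per-trial 11-slot prediction grid.

    ``predicted``: (n_trials, 11) integer labels (0 = left, 1 = right);
    ``probabilities``: (n_trials, 11, 2); ``true_labels``: (n_trials,);
    ``window_end_times``: the 11 decoding instants in seconds.
    """

    predicted: np.ndarray
    true_labels: np.ndarray
    probabilities: np.ndarray | None = None
    window_end_times: np.ndarray = field(
        default_factory=lambda: 5.0 + 0.2 * np.arange(N_SEGMENTS))

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=np.int64)
        self.true_labels = np.asarray(self.true_labels, dtype=np.int64)
        if self.predicted.ndim != 2 or self.predicted.shape[1] != len(
                self.window_end_times):
            raise ValueError(
                f"predictions must be trials x {len(self.window_end_times)}, "
                f"got {self.predicted.shape}")
        if len(self.true_labels) != len(self.predicted):
            raise ValueError("one true label per trial required")

    @property
    def n_trials(self) -> int:
        return len(self.predicted)

    @property
    def correct(self) -> np.ndarray:
        """(n_trials, 11) boolean grid of correct decodings."""
        return self.predicted == self.true_labels[:, None]


def ca_gross(preds: SegmentPredictions) -> float:
    """Percent correct over all trials x 11 feedback instances."""
    return 100.0 * float(preds.correct.mean())


def ca_st(preds: SegmentPredictions) -> float:
    """Percent of trials with >= 6 of 11 windows correct."""
    per_trial = preds.correct.sum(axis=1) >= ST_THRESHOLD
    return 100.0 * float(per_trial.mean())


def ca_opt(preds: SegmentPredictions) -> tuple[float, float]:
    """(best per-instant accuracy in percent, its window end time).

    Accuracy is computed column-wise over trials for each of the 11
    decoding instants; ties break toward the earliest instant.
    """
    per_instant = preds.correct.mean(axis=0)
    k = int(np.argmax(per_instant))  # argmax returns the first maximum
    return 100.0 * float(per_instant[k]), float(preds.window_end_times[k])


def per_instant_accuracy(preds: SegmentPredictions) -> np.ndarray:
    """The 11-point accuracy curve over window end times, in percent."""
    return 100.0 * preds.correct.mean(axis=0)


def cohen_kappa(true_labels, predicted_labels) -> float:
    """Two-class Cohen's kappa, (p_o - p_e)/(1 - p_e), with
    marginal-product chance agreement.  Degenerate inputs (either side
    single-class in a way that makes p_e = 1) return 0 with a warning."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(predicted_labels).ravel()
    if len(t) != len(p) or len(t) == 0:
        raise ValueError("label vectors must be equal nonzero length")
    classes = np.unique(np.concatenate([t, p]))
    po = float(np.mean(t == p))
    pe = float(sum(np.mean(t == c) * np.mean(p == c) for c in classes))
    if pe >= 1.0:
        warnings.warn("degenerate single-class labels; kappa defined as 0",
                      stacklevel=2)
        return 0.0
    return (po - pe) / (1.0 - pe)


def compare_methods(metric_a, metric_b) -> float:
    """Two-sided exact Wilcoxon signed-rank p-value for paired per-subject
    metrics.  Zero differences are dropped; all-zero differences give 1."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.allclose(a, b):
        return 1.0
    res = wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                   method="exact")
    return float(res.pvalue)


@dataclass
class MetricsReport:
    """All continuous-decoding measures for one subject/run."""

    ca_gross: float
    ca_st: float
    ca_opt: float
    ca_opt_time: float
    kappa_gross: float
    kappa_st: float
    per_instant: np.ndarray
    n_trials: int

    @classmethod
    def from_predictions(cls, preds: SegmentPredictions) -> "MetricsReport":
        opt, opt_t = ca_opt(preds)
        # per-instance agreement for the gross view; per-trial majority
        # label for the single-trial view
        flat_true = np.repeat(preds.true_labels, preds.predicted.shape[1])
        flat_pred = preds.predicted.ravel()
        majority = (preds.correct.sum(axis=1) >= ST_THRESHOLD)
        st_pred = np.where(majority, preds.true_labels, 1 - preds.true_labels)
        return cls(
            ca_gross=ca_gross(preds),
            ca_st=ca_st(preds),
            ca_opt=opt,
            ca_opt_time=opt_t,
            kappa_gross=cohen_kappa(flat_true, flat_pred),
            kappa_st=cohen_kappa(preds.true_labels, st_pred),
            per_instant=per_instant_accuracy(preds),
            n_trials=preds.n_trials,
        )

    def as_dict(self) -> dict:
        return {
            "ca_gross": self.ca_gross, "ca_st": self.ca_st,
            "ca_opt": self.ca_opt, "ca_opt_time": self.ca_opt_time,
            "kappa_gross": self.kappa_gross, "kappa_st": self.kappa_st,
            "per_instant": [float(v) for v in self.per_instant],
            "n_trials": self.n_trials,
        }


def format_report_table(reports: dict[str, MetricsReport]) -> str:
    """Markdown-ish per-subject table of the three accuracies and kappas."""
    lines = ["subject\tCA_gross\tkappa\tCA_ST\tkappa\tCA_opt\t@time(s)"]
    for key, r in reports.items():
        lines.append(
            f"{key}\t{r.ca_gross:.2f}\t{r.kappa_gross:.2f}\t"
            f"{r.ca_st:.2f}\t{r.kappa_st:.2f}\t{r.ca_opt:.2f}\t{r.ca_opt_time:.1f}")
    if len(reports) > 1:
        g = [r.ca_gross for r in reports.values()]
        s = [r.ca_st for r in reports.values()]
        lines.append(f"mean±std\t{np.mean(g):.2f}±{np.std(g):.2f}\t\t"
                     f"{np.mean(s):.2f}±{np.std(s):.2f}\t\t\t")
    return "\n".join(lines) + "\n"
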