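"""Gaussian-process Bayesian optimization with EI and PI acquisitions.

Minimizes a scalar objective over a small box-bounded space (continuous,
log-scaled continuous, and integer dimensions).  A Matern-5/2 GP is fitted
to the observations on the unit cube (log axes transformed first); the
next evaluation point maximizes an acquisition function over seeded random
candidate points:

* expected improvement  ``EI(x) = E[max(0, mu(x_b) - f(x))]`` where x_b is
  the location of the lowest posterior mean, with the closed-form Gaussian
  expectation  ``EI = s*(z*Phi(z) + phi(z))``, ``z = (mu_b - mu(x))/s``;
* probability of improvement  ``PI(x) = Phi((mu(x_b) - m - mu(x))/s)``
  with a margin ``m`` on the scale of the observation noise.

The hyperparameter search used for the decoder ties the three Mega Block
repeat counts to a single integer (all published per-subject settings use
equal repeats) and searches learning rate, momentum and L2 on the ranges
1..5, [1e-6, 1e-2] (log), [0.6, 0.98] and [1e-10, 1e-2] (log) with a
budget of 30 evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern


@dataclass(frozen=True)
class Dimension:
    """One search axis.  ``log=True`` optimizes in log10 space; integer
    dimensions are rounded half-up after the continuous proposal."""

    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log axis needs positive bounds")

    def to_unit(self, x: float) -> float:
        if self.log:
            return (math.log10(x) - math.log10(self.low)) / (
                math.log10(self.high) - math.log10(self.low))
        return (x - self.low) / (self.high - self.low)

    def from_unit(self, u: float) -> float:
        u = min(max(u, 0.0), 1.0)
        if self.log:
            val = 10 ** (math.log10(self.low)
                         + u * (math.log10(self.high) - math.log10(self.low)))
        else:
            val = self.low + u * (self.high - self.low)
        if self.integer:
            val = math.floor(val + 0.5)  # round half up
            val = int(min(max(val, self.low), self.high))
        return val


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]
    budget: int = 30
    n_initial: int = 5

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")

    @classmethod
    def decoder_default(cls, budget: int = 30) -> "SearchSpace":
        """The hyperparameter space searched for the decoder CNN."""
        return cls(dimensions=(
            Dimension("n_conv_layers", 1, 5, integer=True),
            Dimension("learning_rate", 1e-6, 1e-2, log=True),
            Dimension("momentum", 0.6, 0.98),
            Dimension("l2", 1e-10, 1e-2, log=True),
        ), budget=budget)

    def decode(self, unit_point: Sequence[float]) -> dict:
        return {d.name: d.from_unit(u) for d, u in zip(self.dimensions, unit_point)}


class GPPosterior:
    """GP posterior over the unit cube, fitted to (point, value) pairs."""

    def __init__(self, X: np.ndarray, y: np.ndarray, length_scale: float = 0.3,
                 alpha: float = 1e-10):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("need >= 1 (point, value) observation pairs")
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=length_scale, length_scale_bounds=(1e-2, 1e2), nu=2.5)
        last_err: Exception | None = None
        for jitter in (alpha, 1e-8, 1e-6):
            try:
                gp = GaussianProcessRegressor(kernel=kernel, alpha=jitter,
                                              normalize_y=True,
                                              n_restarts_optimizer=2,
                                              random_state=0)
                gp.fit(X, y)
                break
            except np.linalg.LinAlgError as err:  # jitter-and-retry
                last_err = err
        else:
            raise np.linalg.LinAlgError(
                f"kernel matrix singular even with jitter: {last_err}")
        self.gp = gp
        self.X, self.y = X, y

    def mean_std(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        mu, sd = self.gp.predict(x, return_std=True)
        return mu, sd

    @property
    def incumbent(self) -> tuple[np.ndarray, float]:
        """Location and value of the lowest posterior mean over the
        observed points."""
        mu, _ = self.mean_std(self.X)
        i = int(np.argmin(mu))
        return self.X[i], float(mu[i])

    @property
    def noise_scale(self) -> float:
        """Margin scale: residual std of the posterior mean at the data."""
        mu, _ = self.mean_std(self.X)
        return float(np.std(self.y - mu))


def gp_posterior(observations: Sequence[tuple[Sequence[float], float]],
                 kernel_params: dict | None = None) -> GPPosterior:
    """Fit a GP to (point, value) observations (points in the unit cube)."""
    X = np.array([p for p, _ in observations], dtype=float)
    y = np.array([v for _, v in observations], dtype=float)
    return GPPosterior(X, y, **(kernel_params or {}))


def acquisition_ei(x: np.ndarray, posterior: GPPosterior) -> np.ndarray:
    """Closed-form expected improvement below the incumbent posterior mean.

    With sigma = 0 the deterministic limit max(0, mu_b - mu(x)) is used.
    """
    mu, sd = posterior.mean_std(x)
    _, mu_b = posterior.incumbent
    improve = mu_b - mu
    out = np.where(sd > 0, 0.0, np.maximum(improve, 0.0))
    nz = sd > 0
    if np.any(nz):
        z = improve[nz] / sd[nz]
        out[nz] = sd[nz] * (z * norm.cdf(z) + norm.pdf(z))
    return out


def acquisition_pi(x: np.ndarray, posterior: GPPosterior,
                   margin: float | None = None) -> np.ndarray:
    """Probability of improving on the incumbent mean by at least ``margin``.

    ``margin`` defaults to the posterior's noise scale.  With sigma = 0 the
    probability degenerates to a 0/1 step by the sign of the improvement.
    """
    m = posterior.noise_scale if margin is None else float(margin)
    mu, sd = posterior.mean_std(x)
    _, mu_b = posterior.incumbent
    v = mu_b - m - mu
    out = np.where(v > 0, 1.0, 0.0)  # sigma = 0 step
    nz = sd > 0
    out[nz] = norm.cdf(v[nz] / sd[nz])
    return out


@dataclass
class OptimizationResult:
    best_config: dict
    best_value: float
    history: list[dict] = field(default_factory=list)

    @property
    def best_trace(self) -> np.ndarray:
        """Best observed value after each evaluation (non-increasing)."""
        return np.minimum.accumulate([h["value"] for h in self.history])


def optimize_hyperparameters(objective: Callable[[dict], float],
                             space: SearchSpace,
                             acquisition: str = "ei",
                             seed: int = 0,
                             n_candidates: int = 2000) -> OptimizationResult:
    """Minimize ``objective`` over ``space`` with exactly ``space.budget``
    evaluations.

    The first min(budget, n_initial) points come from a seeded Sobol
    design; each later point maximizes the acquisition over
    ``n_candidates`` seeded uniform candidates.  A failing objective
    evaluation is recorded at the worst value observed so far and the
    search continues.  Returns the argmin of the *observed* values.
    """
    if acquisition not in ("ei", "pi"):
        raise ValueError(f"unknown acquisition {acquisition!r}")
    d = len(space.dimensions)
    rng = np.random.default_rng(seed)
    sobol = qmc.Sobol(d, scramble=True, seed=int(rng.integers(2**31)))
    n_init = min(space.n_initial, space.budget)
    # draw a power-of-two Sobol block and truncate (keeps balance properties)
    m = max(int(np.ceil(np.log2(max(n_init, 1)))), 0)
    unit_points = list(sobol.random_base2(m)[:n_init])
    X: list[np.ndarray] = []
    y: list[float] = []
    history: list[dict] = []

    def evaluate(u: np.ndarray) -> None:
        config = space.decode(u)
        try:
            val = float(objective(config))
            if not np.isfinite(val):
                raise FloatingPointError("objective returned non-finite value")
            failed = False
        except Exception:
            val = max(y) if y else 0.0  # worst observed so far
            failed = True
        X.append(np.asarray(u, dtype=float))
        y.append(val)
        history.append({"point": config, "unit_point": list(map(float, u)),
                        "value": val, "failed": failed})

    for u in unit_points:
        if len(history) >= space.budget:
            break
        evaluate(u)
    while len(history) < space.budget:
        post = GPPosterior(np.array(X), np.array(y))
        cand = rng.random((n_candidates, d))
        if acquisition == "ei":
            scores = acquisition_ei(cand, post)
        else:
            scores = acquisition_pi(cand, post)
        evaluate(cand[int(np.argmax(scores))])

    best = int(np.argmin(y))
    return OptimizationResult(best_config=space.decode(X[best]),
                              best_value=y[best], history=history)


def write_history(result: OptimizationResult, path) -> None:
    """Persist the evaluation history as tab-delimited text."""
    import json
    from pathlib import Path
    lines = ["index\tvalue\tfailed\tconfig"]
    for i, h in enumerate(result.history):
        lines.append(f"{i}\t{h['value']:.10g}\t{int(h['failed'])}\t"
                     f"{json.dumps(h['point'])}")
    Path(path).write_text("\n".join(lines) + "\n")
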