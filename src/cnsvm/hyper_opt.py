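"""Bayesian hyperparameter search with a Tree-structured Parzen Estimator.

TPE models the densities of "good" and "bad" configurations separately:
after a startup phase of prior sampling, trials are split at the gamma
quantile of the objective (larger is better), each dimension's good and bad
observations are turned into densities (Gaussian kernel density with
Silverman bandwidth for continuous/integer dimensions, smoothed counts for
categorical ones), candidates are drawn from the good density and the one
maximising the good/bad density ratio — monotone in expected improvement —
is suggested next.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from cnsvm.errors import ConfigError, OptimizationError

N_STARTUP_TRIALS = 10
GAMMA = 0.25
N_CANDIDATES = 24


# ---------------------------------------------------------------------------
# Search-space dimensions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    pass


@dataclass(frozen=True)
class Uniform(Dimension):
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ConfigError(f"uniform bounds need lo < hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class LogUniform(Dimension):
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ConfigError(f"log-uniform bounds need 0 < lo < hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class Integer(Dimension):
    lo: int
    hi: int

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ConfigError(f"integer bounds need lo < hi, got [{self.lo}, {self.hi}]")


@dataclass(frozen=True)
class Categorical(Dimension):
    options: tuple

    def __post_init__(self):
        if len(self.options) == 0:
            raise ConfigError("categorical dimension needs at least one option")


def uniform(lo: float, hi: float) -> Uniform:
    return Uniform(lo, hi)


def log_uniform(lo: float, hi: float) -> LogUniform:
    return LogUniform(lo, hi)


def integer(lo: int, hi: int) -> Integer:
    return Integer(lo, hi)


def categorical(*options) -> Categorical:
    return Categorical(tuple(options))


SearchSpace = Mapping[str, Dimension]


def _check_space(space: SearchSpace) -> None:
    if not space:
        raise ConfigError("search space must contain at least one dimension")


# ---------------------------------------------------------------------------
# Trial history
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    config: dict
    value: float
    ok: bool = True


@dataclass
class TrialHistory:
    """Evaluated (configuration, objective) pairs; larger objective is
    better.  Failed (non-finite) trials are kept for bookkeeping but are
    excluded from density fitting and from the incumbent."""

    trials: list[Trial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def append(self, config: dict, value: float) -> None:
        ok = np.isfinite(value)
        self.trials.append(Trial(dict(config), float(value) if ok else np.nan, bool(ok)))

    def successes(self) -> list[Trial]:
        return [t for t in self.trials if t.ok]

    def best(self) -> Trial:
        ok = self.successes()
        if not ok:
            raise OptimizationError("no successful trials")
        return max(ok, key=lambda t: t.value)

    def best_so_far(self) -> np.ndarray:
        """Running maximum of the objective (NaN until the first success)."""
        values = np.array([t.value if t.ok else -np.inf for t in self.trials])
        running = np.maximum.accumulate(values)
        return np.where(np.isfinite(running), running, np.nan)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        best = -np.inf
        for i, t in enumerate(self.trials):
            if t.ok:
                best = max(best, t.value)
            rows.append(
                {"trial": i, "value": t.value, "ok": t.ok,
                 "best_so_far": best if np.isfinite(best) else np.nan, **t.config}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Density models
# ---------------------------------------------------------------------------

def _transform(dim: Dimension, v: np.ndarray) -> np.ndarray:
    return np.log(v) if isinstance(dim, LogUniform) else np.asarray(v, dtype=float)


def _bounds(dim: Dimension) -> tuple[float, float]:
    if isinstance(dim, LogUniform):
        return np.log(dim.lo), np.log(dim.hi)
    return float(dim.lo), float(dim.hi)


def _from_transformed(dim: Dimension, v: float):
    if isinstance(dim, LogUniform):
        return float(np.exp(v))
    if isinstance(dim, Integer):
        return int(round(v))
    return float(v)


class _NumericKDE:
    """1-D Gaussian mixture over observations, Silverman bandwidth clipped
    to a fraction of the bound range."""

    def __init__(self, obs: np.ndarray, lo: float, hi: float):
        self.obs = obs
        n = obs.size
        q75, q25 = np.percentile(obs, [75, 25])
        spread = min(np.std(obs), (q75 - q25) / 1.34)
        bw = 0.9 * spread * n ** (-0.2) if spread > 0 else 0.0
        span = hi - lo
        # floor at 1% of the range: a collapsed bandwidth freezes the search
        # on a point cluster before it has drifted onto the optimum
        self.bw = float(np.clip(bw, 1e-2 * span, span))
        self.lo, self.hi = lo, hi

    def sample(self, rng: np.random.Generator) -> float:
        centre = self.obs[rng.integers(self.obs.size)]
        return float(np.clip(rng.normal(centre, self.bw), self.lo, self.hi))

    def log_pdf(self, v: float) -> float:
        z = (v - self.obs) / self.bw
        dens = np.mean(np.exp(-0.5 * z * z)) / (self.bw * np.sqrt(2 * np.pi))
        return float(np.log(max(dens, 1e-300)))


class _CategoricalDensity:
    """Smoothed category frequencies (add-one prior weight per option)."""

    def __init__(self, options: tuple, obs: list):
        counts = np.array([1.0 + sum(o == v for v in obs) for o in options])
        self.options = options
        self.probs = counts / counts.sum()

    def sample(self, rng: np.random.Generator):
        return self.options[rng.choice(len(self.options), p=self.probs)]

    def log_pdf(self, v) -> float:
        return float(np.log(self.probs[self.options.index(v)]))


def _prior_sample(space: SearchSpace, rng: np.random.Generator) -> dict:
    config = {}
    for name, dim in space.items():
        if isinstance(dim, Categorical):
            config[name] = dim.options[rng.integers(len(dim.options))]
        else:
            lo, hi = _bounds(dim)
            config[name] = _from_transformed(dim, rng.uniform(lo, hi))
    return config


def _density(dim: Dimension, observations: list):
    if isinstance(dim, Categorical):
        return _CategoricalDensity(dim.options, observations)
    lo, hi = _bounds(dim)
    obs = _transform(dim, np.array(observations, dtype=float))
    return _NumericKDE(obs, lo, hi)


def tpe_suggest(
    space: SearchSpace,
    history: TrialHistory,
    seed: int | np.random.Generator = 0,
    n_startup: int = N_STARTUP_TRIALS,
    gamma: float = GAMMA,
    n_candidates: int = N_CANDIDATES,
) -> dict:
    """Suggest the next configuration to evaluate.

    During startup (fewer than ``n_startup`` successful trials) this samples
    the prior.  Afterwards, trials are split at the gamma quantile of the
    objective into good/bad sets, per-dimension densities are fitted to
    each, ``n_candidates`` draws from the good density are scored by the
    good/bad log-density ratio, and the argmax is returned.
    """
    _check_space(space)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ok = history.successes() if len(history) else []
    if len(ok) < n_startup:
        return _prior_sample(space, rng)

    values = np.array([t.value for t in ok])
    n_good = max(1, int(np.ceil(gamma * len(ok))))
    order = np.argsort(values)[::-1]
    good = [ok[i] for i in order[:n_good]]
    bad = [ok[i] for i in order[n_good:]]
    if not bad:  # degenerate split; fall back to the prior
        return _prior_sample(space, rng)

    good_density = {
        name: _density(dim, [t.config[name] for t in good]) for name, dim in space.items()
    }
    bad_density = {
        name: _density(dim, [t.config[name] for t in bad]) for name, dim in space.items()
    }

    best_config, best_score = None, -np.inf
    for _ in range(n_candidates):
        candidate = {}
        score = 0.0
        for name, dim in space.items():
            g, b = good_density[name], bad_density[name]
            if isinstance(dim, Categorical):
                value = g.sample(rng)
                score += g.log_pdf(value) - b.log_pdf(value)
                candidate[name] = value
            else:
                raw = g.sample(rng)
                score += g.log_pdf(raw) - b.log_pdf(raw)
                candidate[name] = _from_transformed(dim, raw)
        if score > best_score:
            best_config, best_score = candidate, score
    return best_config


def optimize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    n_iter: int = 100,
    seed: int = 0,
) -> tuple[dict, TrialHistory]:
    """Sequential suggest -> evaluate -> append loop.

    Non-finite objective values are recorded as failed trials and skipped in
    density fitting; if every trial fails an
    :class:`~cnsvm.errors.OptimizationError` is raised.  Returns the best
    configuration and the full history.
    """
    _check_space(space)
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    history = TrialHistory()
    for _ in range(n_iter):
        config = tpe_suggest(space, history, seed=int(rng.integers(2**31)))
        try:
            value = float(objective(config))
        except FloatingPointError:
            value = np.nan
        history.append(config, value)
    return dict(history.best().config), history


# ---------------------------------------------------------------------------
# Default spaces for this package's two tuning problems
# ---------------------------------------------------------------------------

def default_head_space() -> dict[str, Dimension]:
    """SVM-head space: kernel family, soft margin, kernel width, degree."""
    return {
        "kernel": categorical("linear", "polynomial", "radial"),
        "C": log_uniform(1e-2, 1e3),
        "gamma": log_uniform(1e-4, 10.0),
        "degree": categorical(2, 3, 4),
    }


def default_backbone_space() -> dict[str, Dimension]:
    """Backbone space: dropout, l2 strength, dense width and learning-rate
    ceiling, mirroring what the published experiments tuned."""
    return {
        "dropout": uniform(0.05, 0.6),
        "l2_coef": log_uniform(1e-6, 1e-2),
        "dense_width": integer(50, 400),
        "max_lr": log_uniform(1e-3, 3e-2),
    }
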