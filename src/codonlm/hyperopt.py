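"""Bayesian optimization of the model hyperparameters against validation loss.

Sequential model-based optimization: an initial block of random trials, then
a Gaussian-process surrogate (Matern-5/2 over log2-scaled integer dimensions)
with an expected-improvement acquisition proposes subsequent configurations.
Each trial builds and trains a model with a reduced epoch budget and records
its best validation loss; the search returns the argmin configuration and
the full append-only trial log, reproducible from (space, corpus, seed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .corpus import CorpusSplit
from .model import CodonLM, ModelConfig, build_model

logger = logging.getLogger("codonlm")

#: the five searchable architecture hyperparameters, in canonical order
HYPERPARAMETERS = (
    "aa_embedding_dim",
    "codon_embedding_dim",
    "encoder_units",
    "decoder_codon_dense_size",
    "decoder_aa_dense_size",
)

#: default integer bounds bracketing typical small seq2seq models
DEFAULT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "aa_embedding_dim": (8, 128),
    "codon_embedding_dim": (8, 128),
    "encoder_units": (32, 512),
    "decoder_codon_dense_size": (16, 256),
    "decoder_aa_dense_size": (16, 256),
}


@dataclass(frozen=True)
class SearchSpace:
    """Integer bounds per hyperparameter plus trial budget and seed.

    Dimensions are sampled and modelled on a log2 scale (network widths act
    multiplicatively).  Only keys from :data:`HYPERPARAMETERS` are allowed;
    unlisted hyperparameters stay at their base-config values.
    """

    bounds: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    budget: int = 20
    n_initial: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("empty search space")
        for name, (lo, hi) in self.bounds.items():
            if name not in HYPERPARAMETERS:
                raise ValueError(f"not a searchable hyperparameter: {name}")
            if not (1 <= lo < hi):
                raise ValueError(f"{name}: need 1 <= lower < upper, got ({lo}, {hi})")
        if self.budget < 3:
            raise ValueError("budget must be at least 3")
        if self.n_initial < 1 or self.n_initial > self.budget:
            raise ValueError("need 1 <= n_initial <= budget")

    @property
    def dimensions(self) -> List[str]:
        return [d for d in HYPERPARAMETERS if d in self.bounds]


@dataclass
class TrialRecord:
    trial: int
    config: ModelConfig
    val_loss: float
    val_accuracy: float
    n_epochs: int
    status: str = "ok"


def _sample_point(space: SearchSpace, rng: np.random.Generator) -> Dict[str, int]:
    """Log2-uniform integer sample from the box."""
    point = {}
    for name in space.dimensions:
        lo, hi = space.bounds[name]
        u = rng.uniform(np.log2(lo), np.log2(hi))
        point[name] = int(np.clip(round(2.0 ** u), lo, hi))
    return point


def _encode(space: SearchSpace, point: Dict[str, int]) -> np.ndarray:
    return np.array([np.log2(point[d]) for d in space.dimensions])


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * _stats.norm.cdf(z) + sigma * _stats.norm.pdf(z)


def bayesian_search(
    space: SearchSpace,
    split: CorpusSplit,
    base_config: Optional[ModelConfig] = None,
    trial_max_epochs: int = 30,
    n_candidates: int = 512,
    verbose: bool = False,
) -> Tuple[ModelConfig, List[TrialRecord]]:
    """Minimise validation loss over the space; returns (best config, log).

    The first ``space.n_initial`` trials are random; afterwards a GP fitted to
    (log2 point, loss) observations proposes the expected-improvement argmax
    over a random candidate set.  Duplicate proposals fall back to random
    exploration so the budget is always spent on distinct evaluations when
    the space allows it.
    """
    if not split.train or not split.validation:
        raise ValueError("empty train or validation set")
    base = base_config or ModelConfig()
    rng = np.random.default_rng(space.seed)
    records: List[TrialRecord] = []
    X: List[np.ndarray] = []
    y: List[float] = []
    tried: set = set()

    def evaluate(point: Dict[str, int], trial: int) -> None:
        cfg = replace(base, max_epochs=trial_max_epochs, **point)
        try:
            model = build_model(cfg).fit(split.train, split.validation)
            loss = float(np.min(model.history["val_loss"]))
            acc = float(model.history["val_accuracy"][int(np.argmin(model.history["val_loss"]))])
            rec = TrialRecord(trial, cfg, loss, acc, len(model.history["val_loss"]))
        except FloatingPointError as exc:
            logger.warning("trial %d diverged: %s", trial, exc)
            rec = TrialRecord(trial, cfg, float("inf"), 0.0, 0, status="diverged")
        records.append(rec)
        if np.isfinite(rec.val_loss):
            X.append(_encode(space, point))
            y.append(rec.val_loss)
        tried.add(tuple(point[d] for d in space.dimensions))
        if verbose:
            logger.info("trial %d %s -> val_loss=%.4f", trial, point, rec.val_loss)

    for trial in range(space.n_initial):
        evaluate(_sample_point(space, rng), trial)

    for trial in range(space.n_initial, space.budget):
        point = None
        if len(y) >= 2 and np.ptp(y) > 0:
            kernel = (
                ConstantKernel(1.0, (1e-3, 1e3))
                * Matern(length_scale=np.ones(len(space.dimensions)), nu=2.5)
                + WhiteKernel(1e-6, (1e-10, 1e-1))
            )
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=space.seed
            )
            with warnings.catch_warnings():
                # tiny observation sets routinely pin the GP noise bound
                warnings.simplefilter("ignore")
                gp.fit(np.vstack(X), np.asarray(y))
            cands = [_sample_point(space, rng) for _ in range(n_candidates)]
            fresh = [c for c in cands if tuple(c[d] for d in space.dimensions) not in tried]
            if fresh:
                Xc = np.vstack([_encode(space, c) for c in fresh])
                mu, sigma = gp.predict(Xc, return_std=True)
                ei = _expected_improvement(mu, sigma, min(y))
                point = fresh[int(np.argmax(ei))]
        if point is None:
            point = _sample_point(space, rng)
        evaluate(point, trial)

    finite = [r for r in records if np.isfinite(r.val_loss)]
    if not finite:
        raise RuntimeError("all trials failed")
    best = min(finite, key=lambda r: r.val_loss)
    return best.config, records


def trial_log_frame(records: Sequence[TrialRecord]):
    """Trial log as a pandas DataFrame (for the TSV export)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"trial": r.trial, "val_loss": r.val_loss,
               "val_accuracy": r.val_accuracy, "n_epochs": r.n_epochs,
               "status": r.status}
        for name in HYPERPARAMETERS:
            row[name] = getattr(r.config, name)
        rows.append(row)
    return pd.DataFrame(rows)
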