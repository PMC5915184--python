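"""Linear decoders: component separation and noisy figure-ground discrimination.

A decoder for one odorant is a logistic readout of the binary glomerular
pattern, ``Pr(present | z) = 1 / (1 + exp(-(theta . z + b)))``.  A bank of
such classifiers, one per odorant of a known panel ``S``, performs
component separation: every classifier whose output exceeds a shared
detection threshold declares its odorant present.  Sweeping the threshold
trades hit rate (fraction of true components declared) against false
positives (count of declared-but-absent odorants), producing generalized
ROC curves.

Training uses scikit-learn's deterministic lbfgs logistic regression on
balanced present/absent trials of saturating equiproportionate mixtures;
panel responses are cached as weight matrices so the per-classifier work is
a subset-sum, not a resampling of the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from ._rng import as_generator, substream
from .ensemble import EnsembleConfig, sample_odorants

__all__ = [
    "LinearClassifier",
    "PanelTask",
    "panel_patterns",
    "train_classifier",
    "train_panel",
    "component_separation_roc",
    "noisy_figure_ground",
]


@dataclass
class LinearClassifier:
    """Logistic readout over N glomeruli with a detection threshold."""

    theta: np.ndarray
    b: float
    threshold: float = 0.5
    converged: bool = True

    def probability(self, z: np.ndarray) -> np.ndarray:
        """Pr(present | z); accepts a single pattern or a (trials, N) array."""
        return expit(np.asarray(z, float) @ self.theta + self.b)

    def declare(self, z: np.ndarray, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        return self.probability(z) > thr

    def to_dict(self) -> dict:
        return {"theta": self.theta.tolist(), "b": float(self.b),
                "threshold": float(self.threshold)}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearClassifier":
        return cls(theta=np.asarray(d["theta"], float), b=float(d["b"]),
                   threshold=float(d.get("threshold", 0.5)))


@dataclass
class PanelTask:
    """Component separation over a fixed panel S of known odorants.

    ``panel_size`` odorants are sampled once; training backgrounds have
    1..``train_bg_max`` components from S, test mixtures
    1..``test_mix_max`` components, all drawn without replacement.
    """

    config: EnsembleConfig
    panel_size: int = 500
    train_bg_min: int = 1
    train_bg_max: int = 10
    test_mix_min: int = 1
    test_mix_max: int = 20
    seed: int = 0
    noise_level: float = 0.0

    # cached panel parameter matrices, built lazily
    _w: np.ndarray = field(default=None, repr=False)
    _we: np.ndarray = field(default=None, repr=False)

    def _ensure_panel(self):
        if self._w is None:
            rng = substream(self.seed, "panel")
            lk, le = sample_odorants(self.config, self.panel_size, rng)
            self._w = np.exp(lk)            # kappa^-1 weights, (S, N)
            self._we = self._w * np.exp(le)  # eta * kappa^-1

    @property
    def weights(self) -> tuple[np.ndarray, np.ndarray]:
        self._ensure_panel()
        return self._w, self._we


def panel_patterns(task: PanelTask, members: np.ndarray, rng=None,
                   noise_level: float | None = None) -> np.ndarray:
    """Binary patterns of saturating equiproportionate sub-mixtures of S.

    ``members`` is a boolean (trials, S) matrix selecting components.  The
    optional multiplicative efficacy noise ``eta_mix -> (1 + eps) eta_mix``
    with ``eps ~ N(0, noise_level**2)`` truncated at -0.99 models internal
    transduction variability.
    """
    w, we = task.weights
    eps0 = task.noise_level if noise_level is None else noise_level
    members = np.asarray(members, dtype=float)
    s1 = members @ w
    s2 = members @ we
    empty = s1 == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        eta_mix = np.where(empty, 0.0, s2 / np.where(empty, 1.0, s1))
    if eps0 > 0:
        rng = as_generator(rng)
        eps = np.maximum(rng.normal(0.0, eps0, size=eta_mix.shape), -0.99)
        eta_mix = (1.0 + eps) * eta_mix
    eta_star = np.exp(task.config.log_eta_star)
    return eta_mix > eta_star


def _sample_members(rng, trials: int, S: int, k_min: int, k_max: int,
                    exclude: int | None = None) -> np.ndarray:
    """Random without-replacement subsets of S as a boolean matrix."""
    members = np.zeros((trials, S), dtype=bool)
    pool = np.arange(S)
    if exclude is not None:
        pool = pool[pool != exclude]
    k_max = min(k_max, pool.size)  # small panels cap the mixture size
    k_min = min(k_min, k_max)
    sizes = rng.integers(k_min, k_max + 1, size=trials)
    for t in range(trials):
        members[t, rng.choice(pool, size=sizes[t], replace=False)] = True
    return members


def train_classifier(target: int, task: PanelTask, training_trials: int = 5_000,
                     seed: int = 0, l2_C: float = 1.0, max_iter: int = 200,
                     tol: float = 1e-6) -> LinearClassifier:
    """Maximum-likelihood logistic fit detecting ``target`` against S-backgrounds.

    Balanced trials: half contain the target plus 1..train_bg_max panel
    backgrounds, half the backgrounds alone.  Deterministic given the seed.
    Non-convergence produces a warning from the optimizer and is recorded
    on the returned classifier.
    """
    rng = substream(seed, "train", int(target))
    half = training_trials // 2
    S = task.panel_size
    bg = _sample_members(rng, 2 * half, S, task.train_bg_min, task.train_bg_max,
                         exclude=target)
    present = np.zeros(2 * half, dtype=bool)
    present[:half] = True
    members = bg.copy()
    members[:half, target] = True
    Z = panel_patterns(task, members, rng=rng).astype(float)
    clf = LogisticRegression(C=l2_C, solver="lbfgs", max_iter=max_iter, tol=tol)
    clf.fit(Z, present)
    return LinearClassifier(theta=clf.coef_[0].copy(), b=float(clf.intercept_[0]),
                            converged=bool(np.all(clf.n_iter_ < max_iter)))


def train_panel(task: PanelTask, training_trials: int = 5_000, seed: int = 0,
                **kw) -> list[LinearClassifier]:
    """One trained classifier per odorant of the panel."""
    return [train_classifier(i, task, training_trials, seed=seed, **kw)
            for i in range(task.panel_size)]


def component_separation_roc(task: PanelTask, classifiers: Sequence[LinearClassifier],
                             threshold_grid: Sequence[float],
                             test_trials: int = 500, seed: int = 1) -> pd.DataFrame:
    """Generalized ROC: hit rate vs mean false-positive count over the panel.

    Each test trial delivers a saturating mixture of 1..test_mix_max panel
    odorants; an odorant is declared present when its classifier probability
    exceeds the shared threshold.  Returns a tidy frame
    (threshold, hit_rate, false_positives).
    """
    rng = substream(seed, "roc-test")
    S = task.panel_size
    members = _sample_members(rng, test_trials, S, task.test_mix_min,
                              task.test_mix_max)
    Z = panel_patterns(task, members, rng=rng).astype(float)
    theta = np.stack([c.theta for c in classifiers])        # (S, N)
    bias = np.array([c.b for c in classifiers])
    probs = expit(Z @ theta.T + bias)                       # (trials, S)
    rows = []
    for thr in threshold_grid:
        declared = probs > thr
        hits = (declared & members).sum(1) / members.sum(1)
        fps = (declared & ~members).sum(1)
        rows.append({"threshold": float(thr),
                     "hit_rate": float(hits.mean()),
                     "false_positives": float(fps.mean())})
    return pd.DataFrame(rows)


def noisy_figure_ground(config: EnsembleConfig, background_sizes: Sequence[int],
                        noise_level: float = 0.4, panel_size: int = 500,
                        train_trials: int = 4_000, test_trials: int = 2_000,
                        decades: float = 3.0, seed: int = 0) -> pd.DataFrame:
    """Linear-classifier accuracy for figure-ground under efficacy noise.

    The target and the backgrounds are delivered at concentrations drawn
    log-uniformly over ``decades`` orders of magnitude; responses use the
    full finite-concentration mixture formula, with multiplicative efficacy
    noise of level ``noise_level`` (std of eps, truncated at -0.99).
    Returns a frame (n_background, accuracy) of balanced accuracies.
    """
    from .steady_state import response_from_log_params

    rows = []
    for nb in background_sizes:
        rng = substream(seed, "noisy-fg", int(nb))
        tlk, tle = sample_odorants(config, 1, rng)

        def make_set(trials):
            present = np.zeros(trials, dtype=bool)
            present[: trials // 2] = True
            le = rng.normal(0.0, 1.0, size=(trials, nb, config.N))
            om = rng.normal(0.0, 1.0, size=(trials, nb, config.N))
            lk = config.sigma_kappa * (config.rho * le +
                                       np.sqrt(1 - config.rho**2) * om)
            logC = rng.uniform(0.0, decades * np.log(10.0),
                               size=(trials, nb + 1, 1))
            w = np.exp(lk + logC[:, 1:])
            s1 = w.sum(1)
            s2 = (w * np.exp(le)).sum(1)
            wt = np.exp(tlk[0] + logC[:, 0])
            s1 = s1 + np.where(present[:, None], wt, 0.0)
            s2 = s2 + np.where(present[:, None], wt * np.exp(tle[0]), 0.0)
            total = np.exp(logC[:, 1:, 0]).sum(1, keepdims=True) + \
                np.where(present[:, None], np.exp(logC[:, 0, 0, None]), 0.0)
            empty = s1 == 0  # empty stimulus (absent trials with nb = 0)
            s1 = np.where(empty, 1.0, s1)
            eta_mix = s2 / s1
            if noise_level > 0:
                eps = np.maximum(rng.normal(0.0, noise_level, eta_mix.shape),
                                 -0.99)
                eta_mix = (1.0 + eps) * eta_mix
            with np.errstate(divide="ignore"):
                y = response_from_log_params(
                    np.log(np.maximum(total, 1e-300)), np.log(s1 / total),
                    np.log(np.maximum(eta_mix, 1e-300)), n=config.n)
            y = np.where(empty, 0.0, y)
            return (y > config.tau).astype(float), present

        Z_tr, y_tr = make_set(train_trials)
        clf = LogisticRegression(solver="lbfgs", max_iter=200, tol=1e-6)
        clf.fit(Z_tr, y_tr)
        Z_te, y_te = make_set(test_trials)
        pred = clf.predict(Z_te).astype(bool)
        acc = 0.5 * ((pred & y_te).sum() / y_te.sum() +
                     (~pred & ~y_te).sum() / (~y_te).sum())
        rows.append({"n_background": int(nb), "accuracy": float(acc)})
    return pd.DataFrame(rows)
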