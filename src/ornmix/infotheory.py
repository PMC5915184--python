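"""Monte-Carlo mutual information for figure-ground segregation.

The task: a known target odorant is present (T=1) or absent (T=0) with
prior 1/2, on top of ``nb`` unknown background odorants drawn fresh from
the ensemble; the observer sees only the binary glomerular code ``z``.
The mutual information ``I(T; z) = H(T) - H(T|z)`` (at most 1 bit) bounds
any decoder's performance.

Because receptor types are statistically independent and background
odorants are drawn i.i.d., the conditional pattern probability factorizes,

.. math:: \\Pr(z \\mid T, n_b) = \\prod_i q_i(T, n_b)^{z_i}
          \\, (1 - q_i(T, n_b))^{1 - z_i},

so the per-receptor activation probabilities ``q_i(T, nb)`` can be
pre-computed by Monte Carlo once and reused: ``H(T|z)`` is then estimated
by sampling patterns ``z``, forming the Bayes posterior of ``T`` from the
factorized likelihoods (mixed over the background-size distribution
``Pr(nb)``), and averaging the binary entropy of the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from ._rng import as_generator, substream
from .ensemble import (EnsembleConfig, OdorantEnsembleProfile,
                       mixture_params_arrays, sample_odorant)

__all__ = [
    "BackgroundModel",
    "SegregationTask",
    "PROB_CLIP",
    "receptor_activation_prob",
    "activation_prob_tables",
    "mutual_information_from_tables",
    "mutual_information",
    "mi_scan",
    "optimal_rho",
]

#: Clipping bound for activation probabilities (prevents log(0) in Bayes;
#: introduces estimator bias of order PROB_CLIP).
PROB_CLIP = 1e-12

_MAX_NB = 128


class BackgroundModel:
    """Distribution of the number of background odorants ``nb``.

    Either a point mass (``BackgroundModel.fixed(nb)``) or a truncated
    exponential on support 1..``max_nb`` with pmf proportional to
    ``exp(-nb/lam)``, with ``lam`` solved numerically so the mean matches
    the requested value (``BackgroundModel.truncated_exponential(mean)``).
    """

    def __init__(self, pmf: np.ndarray):
        pmf = np.asarray(pmf, dtype=float)
        if pmf.ndim != 1 or np.any(pmf < 0) or not np.isclose(pmf.sum(), 1.0):
            raise ValueError("pmf must be a 1-D probability vector")
        self.pmf = pmf / pmf.sum()

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.pmf.size)

    @property
    def max_nb(self) -> int:
        return self.pmf.size - 1

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    @classmethod
    def fixed(cls, nb: int) -> "BackgroundModel":
        if nb < 0:
            raise ValueError("nb must be >= 0")
        pmf = np.zeros(nb + 1)
        pmf[nb] = 1.0
        return cls(pmf)

    @classmethod
    def truncated_exponential(cls, mean: float = 32.0,
                              max_nb: int = _MAX_NB) -> "BackgroundModel":
        if not 1.0 < mean < max_nb:
            raise ValueError("mean must lie strictly between 1 and max_nb")
        k = np.arange(1, max_nb + 1)

        def mean_given_lam(lam):
            w = np.exp(-(k - 1) / lam)  # shifted for numerical stability
            return float(np.dot(k, w) / w.sum()) - mean

        lam = brentq(mean_given_lam, 1e-3, 1e6)
        pmf = np.zeros(max_nb + 1)
        pmf[1:] = np.exp(-(k - 1) / lam)
        return cls(pmf / pmf.sum())

    def sample(self, size: int, rng) -> np.ndarray:
        rng = as_generator(rng)
        return rng.choice(self.support, size=size, p=self.pmf)


@dataclass
class SegregationTask:
    """Figure-ground segregation: known target vs i.i.d. backgrounds.

    The presence prior is fixed at 1/2, so ``H(T) = 1`` bit.
    """

    config: EnsembleConfig
    background: BackgroundModel
    target: OdorantEnsembleProfile
    mc_background_draws: int = 4_000
    mc_pattern_samples: int = 20_000

    prior_present: float = field(default=0.5, init=False)

    @classmethod
    def sampled_target(cls, config: EnsembleConfig, background: BackgroundModel,
                       seed: int, **kw) -> "SegregationTask":
        rng = substream(seed, "target")
        return cls(config=config, background=background,
                   target=sample_odorant(config, rng), **kw)


def _q_from_draws(task: SegregationTask, T: int, draws: int, rng,
                  chunk: int = 256) -> np.ndarray:
    """q[nb, i] for nb = 0..max_nb, estimated from `draws` background streams.

    Backgrounds are drawn as a sequential stream and cumulatively summed,
    so one stream yields the equiproportionate saturating mixture for every
    nb at once (the per-nb marginals are all that matters).
    """
    cfg = task.config
    max_nb = task.background.max_nb
    N = cfg.N
    counts = np.zeros((max_nb + 1, N))
    wt = np.exp(task.target.log_kappa_inv)        # target weights
    st = wt * np.exp(task.target.log_eta)
    eta_star = np.exp(cfg.log_eta_star)
    if max_nb == 0:
        if T == 1:
            z = task.target.log_eta > cfg.log_eta_star
            return np.clip(np.tile(z.astype(float), (1, 1)).reshape(1, N),
                           PROB_CLIP, 1.0 - PROB_CLIP)
        return np.full((1, N), PROB_CLIP)
    rng = as_generator(rng)
    for start in range(0, draws, chunk):
        m = min(chunk, draws - start)
        le = rng.normal(0.0, 1.0, size=(m, max_nb, N))
        om = rng.normal(0.0, 1.0, size=(m, max_nb, N))
        lk = cfg.sigma_kappa * (cfg.rho * le + np.sqrt(1 - cfg.rho**2) * om)
        w = np.exp(lk)
        s1 = np.cumsum(w, axis=1)                 # sum of kappa^-1, nb = 1..max
        s2 = np.cumsum(w * np.exp(le), axis=1)    # sum of eta * kappa^-1
        if T == 1:
            s1 = s1 + wt
            s2 = s2 + st
        counts[1:] += (s2 > eta_star * s1).sum(axis=0).astype(float)
    q = counts / draws
    # nb = 0: deterministic (target alone, or empty stimulus)
    if T == 1:
        q[0] = (task.target.log_eta > cfg.log_eta_star).astype(float)
    else:
        q[0] = 0.0
    return np.clip(q, PROB_CLIP, 1.0 - PROB_CLIP)


def receptor_activation_prob(task: SegregationTask, T: int, nb: int,
                             mc_draws: int = 4_000, seed: int = 0) -> np.ndarray:
    """Per-receptor activation probability ``q_i(T, nb)`` (clipped)."""
    if nb < 0 or nb > task.background.max_nb:
        raise ValueError("nb outside the background support")
    rng = substream(seed, "qtab", int(T))
    return _q_from_draws(task, T, mc_draws, rng)[nb]


def activation_prob_tables(task: SegregationTask, seed: int = 0) -> np.ndarray:
    """Full table q[T, nb, i] over the background support."""
    draws = task.mc_background_draws
    return np.stack([
        _q_from_draws(task, T, draws, substream(seed, "qtab", T))
        for T in (0, 1)
    ])


def mutual_information_from_tables(q: np.ndarray, pmf: np.ndarray,
                                   n_samples: int, rng) -> tuple[float, float]:
    """MC estimate of I(T; z) in bits given q[T, nb, i] and Pr(nb).

    Samples z from the factorized model (T ~ Bernoulli(1/2), nb ~ pmf,
    z_i ~ Bernoulli(q_i)), computes the exact factorized posterior of T for
    each sampled pattern, and returns (I, standard error).
    """
    rng = as_generator(rng)
    n_T, n_nb, N = q.shape
    log_q = np.log(q).reshape(n_T * n_nb, N)
    log_1q = np.log1p(-q).reshape(n_T * n_nb, N)
    log_pmf = np.full(n_nb, -np.inf)
    pos = pmf > 0
    log_pmf[pos] = np.log(pmf[pos])

    ent = np.empty(n_samples)
    chunk = 8_192
    base = log_1q.sum(axis=1)                       # all-zeros pattern
    for start in range(0, n_samples, chunk):
        m = min(chunk, n_samples - start)
        T = rng.integers(0, 2, size=m)
        nb = rng.choice(n_nb, size=m, p=pmf)
        qz = q[T, nb]                               # (m, N)
        z = (rng.random((m, N)) < qz).astype(float)
        # log Pr(z | T', nb') for all (T', nb') at once
        ll = z @ (log_q - log_1q).T + base          # (m, n_T*n_nb)
        ll = ll.reshape(m, n_T, n_nb) + log_pmf
        ll_T = logsumexp(ll, axis=2)                # (m, 2): log Pr(z|T')
        log_post = ll_T - logsumexp(ll_T, axis=1, keepdims=True)
        post = np.exp(log_post)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(post > 0, post * log_post / np.log(2.0), 0.0)
        ent[start:start + m] = -terms.sum(axis=1)
    I = 1.0 - float(ent.mean())
    se = float(ent.std(ddof=1) / np.sqrt(n_samples)) if n_samples > 1 else 0.0
    return I, se


def mutual_information(task: SegregationTask, seed: int = 0) -> tuple[float, float]:
    """I(T; z) in bits for a segregation task, with its MC standard error."""
    q = activation_prob_tables(task, seed=seed)
    rng = substream(seed, "mi-sampling")
    return mutual_information_from_tables(q, task.background.pmf,
                                          task.mc_pattern_samples, rng)


def mi_scan(config: EnsembleConfig, background: BackgroundModel,
            rho_values: Sequence[float], seed: int = 0,
            n_targets: int = 4, mc_background_draws: int = 4_000,
            mc_pattern_samples: int = 20_000) -> pd.DataFrame:
    """MI vs antagonism factor, averaged over freshly drawn targets.

    Target draws share seeds across rho values (common random numbers), so
    the rho ordering is not confounded by target-to-target variability.
    Returns a tidy frame (rho, target, I, stderr).
    """
    rows = []
    for rho in rho_values:
        cfg = config.with_rho(float(rho))
        for t in range(n_targets):
            # same eta draw across rho; kappa construction follows rho
            trng = substream(seed, "target", t)
            target = sample_odorant(cfg, trng)
            task = SegregationTask(cfg, background, target,
                                   mc_background_draws=mc_background_draws,
                                   mc_pattern_samples=mc_pattern_samples)
            I, se = mutual_information(task, seed=seed * 1000 + t)
            rows.append({"rho": float(rho), "target": t, "I": I, "stderr": se})
    return pd.DataFrame(rows)


def optimal_rho(config: EnsembleConfig, p_values: Sequence[float],
                rho_grid: Sequence[float], background: BackgroundModel,
                seed: int = 0, **scan_kw) -> pd.DataFrame:
    """rho* maximizing mean MI over the grid, per sparsity p (ties: smallest rho).

    Returns a frame with one row per p: (p, rho_star, I_star, I_at_rho1)
    plus the full scan in the ``scan`` attribute of the frame's ``attrs``.
    """
    rows, scans = [], []
    for p in p_values:
        cfg = EnsembleConfig(N=config.N, sigma_kappa=config.sigma_kappa,
                             rho=0.0, p=float(p), n=config.n)
        scan = mi_scan(cfg, background, rho_grid, seed=seed, **scan_kw)
        mean = scan.groupby("rho")["I"].mean()
        rho_star = float(mean.idxmax())  # idxmax returns the first (smallest) max
        scan["p"] = p
        scans.append(scan)
        rows.append({
            "p": float(p),
            "rho_star": rho_star,
            "I_star": float(mean.loc[rho_star]),
            "I_at_rho_max": float(mean.loc[mean.index.max()]),
        })
    out = pd.DataFrame(rows)
    out.attrs["scan"] = pd.concat(scans, ignore_index=True)
    return out
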