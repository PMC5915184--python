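"""Population encoding: receptor ensembles with tunable antagonism.

An odorant is described by two N-vectors over receptor types: log-
sensitivities ``log kappa**-1`` and log-efficacies ``log eta``.  Efficacies
are standard log-normal, ``log eta ~ N(0, 1)``; sensitivities are broad,
``log kappa**-1 = sigma_kappa * (rho * log eta + sqrt(1 - rho**2) * omega)``
with ``omega ~ N(0, 1)``, so that the Pearson correlation between the two
log-parameters equals the antagonism factor ``rho``.  ``rho = 1`` means the
strongest binders are also the strongest activators (no antagonism, the
neuron acts as an OR gate over mixture components); ``rho = 0`` means
binding and activation are statistically independent, which maximizes
competitive antagonism.

At saturating concentration the rescaled glomerular response is
``y = 1/(1 + eta**-n)`` per receptor; thresholding at ``tau`` gives the
binary code ``z``.  Choosing ``tau = 1/(1 + exp(-n * Phi^-1(1 - p)))``
makes the probability that a single odorant activates a glomerulus equal
to the target sparsity ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import as_generator, substream
from .steady_state import (DEFAULT_HILL, mixture_params_arrays,
                           response_from_log_params)

__all__ = [
    "EnsembleConfig",
    "OdorantEnsembleProfile",
    "GlomerularResponse",
    "threshold_for_sparsity",
    "sample_odorant",
    "sample_odorants",
    "saturating_response",
    "finite_concentration_response",
    "fraction_active_vs_complexity",
    "eta_mix_distribution",
]


def threshold_for_sparsity(p: float, n: float = DEFAULT_HILL) -> float:
    """Activation threshold tau with P(y > tau) = p for a single odorant."""
    if not 0.0 < p < 1.0:
        raise ValueError("sparsity p must lie in (0, 1)")
    return float(1.0 / (1.0 + np.exp(-n * norm.ppf(1.0 - p))))


@dataclass(frozen=True)
class EnsembleConfig:
    """Receptor-ensemble parameters.

    ``N`` receptor types; ``sigma_kappa`` is the standard deviation of
    ``log kappa**-1`` in natural-log units (4 spans about six decades of
    sensitivity); ``rho`` is the antagonism factor in [0, 1]; ``p`` the
    target sparsity; ``n`` the Hill coefficient.  The derived threshold
    ``tau`` reproduces ``p`` by construction.
    """

    N: int = 250
    sigma_kappa: float = 4.0
    rho: float = 0.0
    p: float = 0.3
    n: float = DEFAULT_HILL

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if self.sigma_kappa <= 0:
            raise ValueError("sigma_kappa must be positive")

    @property
    def tau(self) -> float:
        return threshold_for_sparsity(self.p, self.n)

    @property
    def log_eta_star(self) -> float:
        """Efficacy cutoff: y > tau iff log eta_mix > this value."""
        return float(norm.ppf(1.0 - self.p))

    def with_rho(self, rho: float) -> "EnsembleConfig":
        return replace(self, rho=rho)


@dataclass(frozen=True)
class OdorantEnsembleProfile:
    """One odorant's (log-sensitivity, log-efficacy) vectors over N receptors."""

    log_kappa_inv: np.ndarray
    log_eta: np.ndarray

    def __post_init__(self):
        lk = np.asarray(self.log_kappa_inv, float)
        le = np.asarray(self.log_eta, float)
        if lk.shape != le.shape or lk.ndim != 1:
            raise ValueError("log_kappa_inv and log_eta must be equal-length 1-D")
        if not (np.all(np.isfinite(lk)) and np.all(np.isfinite(le))):
            raise ValueError("profile entries must be finite")
        object.__setattr__(self, "log_kappa_inv", lk)
        object.__setattr__(self, "log_eta", le)

    @property
    def N(self) -> int:
        return self.log_eta.size


@dataclass(frozen=True)
class GlomerularResponse:
    """Continuous activations y in [0,1]^N and their binarization z = (y > tau)."""

    y: np.ndarray
    z: np.ndarray

    @property
    def fraction_active(self) -> float:
        return float(self.z.mean())


def sample_odorants(config: EnsembleConfig, n_odorants: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw (log_kappa_inv, log_eta) arrays of shape (n_odorants, N)."""
    rng = as_generator(rng)
    le = rng.normal(0.0, 1.0, size=(n_odorants, config.N))
    omega = rng.normal(0.0, 1.0, size=(n_odorants, config.N))
    lk = config.sigma_kappa * (config.rho * le +
                               np.sqrt(1.0 - config.rho**2) * omega)
    return lk, le


def sample_odorant(config: EnsembleConfig, rng) -> OdorantEnsembleProfile:
    """Draw a single odorant profile."""
    lk, le = sample_odorants(config, 1, rng)
    return OdorantEnsembleProfile(lk[0], le[0])


def _as_component_arrays(profiles) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(profiles, OdorantEnsembleProfile):
        profiles = [profiles]
    lk = np.stack([p.log_kappa_inv for p in profiles])
    le = np.stack([p.log_eta for p in profiles])
    return lk, le


def saturating_response(profiles, config: EnsembleConfig,
                        fractions=None) -> GlomerularResponse:
    """Population response to a saturating odorant or mixture.

    ``profiles`` is a profile or list of profiles; ``fractions`` are
    concentration fractions (default equiproportionate).  Per receptor the
    effective ``eta_mix`` follows the exact competitive-mixture formula and
    ``y = 1/(1 + eta_mix**-n)``, thresholded strictly at ``tau``.
    """
    lk, le = _as_component_arrays(profiles)
    log_beta = None if fractions is None else np.log(
        np.asarray(fractions, float) / np.sum(fractions))[:, None]
    _, log_eta_mix = mixture_params_arrays(lk, le, log_beta=log_beta, axis=0)
    y = 1.0 / (1.0 + np.exp(-config.n * log_eta_mix))
    z = log_eta_mix > config.log_eta_star
    return GlomerularResponse(y=y, z=z)


def finite_concentration_response(profiles, config: EnsembleConfig,
                                  concentrations) -> GlomerularResponse:
    """Population response at finite component concentrations (full dose-response).

    ``concentrations`` is one value per component (arbitrary units; the
    median single-receptor kappa is 1 by construction of the ensemble).
    """
    lk, le = _as_component_arrays(profiles)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    total = conc.sum()
    if total == 0:
        y = np.zeros(lk.shape[1])
        return GlomerularResponse(y=y, z=y > config.tau)
    keep = conc > 0
    lk, le, conc = lk[keep], le[keep], conc[keep]
    log_beta = (np.log(conc) - np.log(total))[:, None]
    log_kinv_mix, log_eta_mix = mixture_params_arrays(lk, le, log_beta=log_beta)
    y = response_from_log_params(np.log(total), log_kinv_mix, log_eta_mix,
                                 n=config.n)
    return GlomerularResponse(y=y, z=y > config.tau)


def fraction_active_vs_complexity(config: EnsembleConfig,
                                  nmix_values: Sequence[int],
                                  rho_values: Sequence[float],
                                  trials: int = 100,
                                  seed: int = 0) -> pd.DataFrame:
    """Mean active fraction of saturating equiproportionate mixtures.

    For each (rho, nmix), freshly samples ``nmix`` odorants per trial and
    reports the mean and MC standard error (over trials) of the fraction of
    glomeruli above threshold.  The per-component sparsity is ``config.p``.
    """
    rows = []
    for rho in rho_values:
        cfg = config.with_rho(rho)
        for nmix in nmix_values:
            rng = substream(seed, "frac-active", float(rho), int(nmix))
            lk, le = sample_odorants(cfg, trials * nmix, rng)
            lk = lk.reshape(trials, nmix, cfg.N)
            le = le.reshape(trials, nmix, cfg.N)
            _, log_eta_mix = mixture_params_arrays(lk, le, axis=1)
            frac = (log_eta_mix > cfg.log_eta_star).mean(axis=1)
            rows.append({
                "rho": rho, "nmix": nmix,
                "fraction_active": float(frac.mean()),
                "stderr": float(frac.std(ddof=1) / np.sqrt(trials)),
            })
    return pd.DataFrame(rows)


def eta_mix_distribution(config: EnsembleConfig,
                         nmix_values: Sequence[int],
                         n_samples: int = 10_000,
                         efficacy_dist: str = "log-normal",
                         seed: int = 0,
                         chunk: int = 2_000) -> dict[int, np.ndarray]:
    """Samples of the effective efficacy eta_mix for each mixture size.

    Each sample is one receptor's exact ``eta_mix`` for a fresh saturating
    equiproportionate mixture of ``nmix`` components.  ``efficacy_dist``
    selects the single-component efficacy law: ``"log-normal"``
    (``log eta ~ N(0,1)``) or ``"exponential"`` (``eta ~ Exp(1)``); the
    normalization-by-antagonism effect does not depend on this choice.
    """
    if efficacy_dist not in ("log-normal", "exponential"):
        raise ValueError(f"unknown efficacy_dist: {efficacy_dist!r}")
    out = {}
    for nmix in nmix_values:
        rng = substream(seed, "etamix", efficacy_dist, int(nmix))
        samples = []
        for start in range(0, n_samples, chunk):
            m = min(chunk, n_samples - start)
            if efficacy_dist == "log-normal":
                le = rng.normal(0.0, 1.0, size=(nmix, m))
            else:
                le = np.log(rng.exponential(1.0, size=(nmix, m)))
            omega = rng.normal(0.0, 1.0, size=(nmix, m))
            lk = config.sigma_kappa * (config.rho * le +
                                       np.sqrt(1.0 - config.rho**2) * omega)
            _, log_eta_mix = mixture_params_arrays(lk, le, axis=0)
            samples.append(np.exp(log_eta_mix))
        out[int(nmix)] = np.concatenate(samples)
    return out
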