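"""Closed-form peak-response algebra for single odorants and their mixtures.

An odorant interacting with one receptor type is summarized by two numbers:
the sensitivity scale ``kappa`` (its inverse, :math:`\\kappa^{-1}`, measures
binding affinity) and the activation efficacy ``eta`` (how strongly the
bound complex drives transduction).  The peak firing rate of the neuron to a
single odorant at concentration :math:`C` is the Hill-type response

.. math::

    F(C) = \\frac{F_{max}}{1 + \\left(\\frac{1 + C/\\kappa}
                 {\\eta\\, C/\\kappa}\\right)^n},

which saturates at :math:`F_\\infty = F_{max}/(1+\\eta^{-n})`.

Because all components of a mixture compete for the same finite receptor
pool, a mixture behaves exactly like a single virtual odorant with effective
parameters

.. math::

    \\kappa_{mix}^{-1} = \\sum_i \\beta_i \\kappa_i^{-1}, \\qquad
    \\eta_{mix} = \\kappa_{mix} \\sum_i \\eta_i \\beta_i \\kappa_i^{-1},

where :math:`\\beta_i` is the concentration fraction of component *i*.  When
sensitivities are broadly (log-normally) distributed, a single component
typically dominates both sums, giving the one-component approximation
:math:`\\kappa_{mix}^{-1} \\approx \\beta_M \\kappa_M^{-1}`,
:math:`\\eta_{mix} \\approx \\eta_M` whose error is quantified by
:func:`approximation_error_experiment`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._rng import substream

__all__ = [
    "SteadyStateProfile",
    "MixtureSpec",
    "single_odorant_rate",
    "saturating_rate",
    "effective_mixture_params",
    "mixture_rate",
    "dominant_approximation",
    "mixture_params_arrays",
    "response_from_log_params",
    "approximation_error_experiment",
]

DEFAULT_HILL = 4


@dataclass(frozen=True)
class SteadyStateProfile:
    """Per-receptor (kappa, eta) pair characterizing one odorant's peak response.

    Parameters
    ----------
    kappa : float
        Sensitivity scale in concentration units; the sensitivity itself is
        ``1/kappa``.  Must be strictly positive.
    eta : float
        Dimensionless activation efficacy; sets the saturating response
        ``Fmax / (1 + eta**-n)``.  Must be strictly positive.
    """

    kappa: float
    eta: float

    def __post_init__(self):
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError(f"kappa must be finite and positive, got {self.kappa}")
        if not (np.isfinite(self.eta) and self.eta > 0):
            raise ValueError(f"eta must be finite and positive, got {self.eta}")


class MixtureSpec:
    """A mixture of odorants seen by one receptor type.

    Zero-concentration components are dropped on construction; the remaining
    concentrations define the total ``C`` and fractions ``beta`` (summing to
    one when ``C > 0``).
    """

    def __init__(self, profiles: Sequence[SteadyStateProfile], concentrations):
        conc = np.asarray(concentrations, dtype=float)
        if conc.ndim != 1 or len(profiles) != conc.size:
            raise ValueError("profiles and concentrations must have equal length")
        if np.any(conc < 0) or not np.all(np.isfinite(conc)):
            raise ValueError("concentrations must be finite and >= 0")
        keep = conc > 0
        self.profiles = [p for p, k in zip(profiles, keep) if k]
        self.concentrations = conc[keep]

    @property
    def total_concentration(self) -> float:
        return float(self.concentrations.sum())

    @property
    def fractions(self) -> np.ndarray:
        C = self.total_concentration
        if C == 0:
            raise ValueError("empty mixture: total concentration is zero")
        return self.concentrations / C

    @property
    def kappas(self) -> np.ndarray:
        return np.array([p.kappa for p in self.profiles])

    @property
    def etas(self) -> np.ndarray:
        return np.array([p.eta for p in self.profiles])


def single_odorant_rate(C, profile: SteadyStateProfile, n: float = DEFAULT_HILL,
                        Fmax: float = 1.0):
    """Peak firing rate of one receptor type to a single odorant.

    ``C`` may be a scalar or array; ``C = 0`` maps to 0 and ``C = inf`` to
    the saturating rate ``Fmax / (1 + eta**-n)``.
    """
    C = np.asarray(C, dtype=float)
    out = np.zeros(np.broadcast_shapes(C.shape), dtype=float)
    pos = C > 0
    if np.any(pos):
        x = C[pos] / profile.kappa
        # (1 + x) / (eta x), stable for x -> inf
        with np.errstate(over="ignore", invalid="ignore"):
            ratio = np.where(np.isinf(x), 1.0 / profile.eta,
                             (1.0 + x) / (profile.eta * x))
            out[pos] = Fmax / (1.0 + ratio**n)
    return out if out.ndim else float(out)


def saturating_rate(eta, n: float = DEFAULT_HILL, Fmax: float = 1.0):
    """Saturating-concentration limit ``Fmax / (1 + eta**-n)``."""
    eta = np.asarray(eta, dtype=float)
    out = Fmax / (1.0 + eta ** (-float(n)))
    return out if out.ndim else float(out)


def effective_mixture_params(mix: MixtureSpec) -> SteadyStateProfile:
    """Exact effective (kappa_mix, eta_mix) of a competitive mixture."""
    if mix.total_concentration == 0:
        raise ValueError("empty mixture: total concentration is zero")
    beta = mix.fractions
    kinv = 1.0 / mix.kappas
    kinv_mix = float(np.dot(beta, kinv))
    eta_mix = float(np.dot(mix.etas * beta, kinv) / kinv_mix)
    return SteadyStateProfile(kappa=1.0 / kinv_mix, eta=eta_mix)


def mixture_rate(mix: MixtureSpec, n: float = DEFAULT_HILL, Fmax: float = 1.0,
                 total_concentration: float | None = None) -> float:
    """Peak response of a competitive mixture at its total concentration.

    Equals :func:`single_odorant_rate` evaluated at the total concentration
    with the effective mixture parameters.  ``total_concentration`` overrides
    the mixture's own total (the fractions are kept), which is convenient for
    sweeping a dose-response curve at a fixed composition.
    """
    eff = effective_mixture_params(mix)
    C = mix.total_concentration if total_concentration is None else total_concentration
    return float(single_odorant_rate(C, eff, n=n, Fmax=Fmax))


def dominant_approximation(mix: MixtureSpec) -> SteadyStateProfile:
    """Single-dominant-component approximation of the mixture parameters.

    Keeps only the largest term ``beta_M * kappa_M**-1`` in both effective
    sums: ``kappa_mix**-1 ~= beta_M kappa_M**-1`` and ``eta_mix ~= eta_M``.
    Ties are broken by lowest component index.
    """
    if mix.total_concentration == 0:
        raise ValueError("empty mixture: total concentration is zero")
    beta = mix.fractions
    terms = beta / mix.kappas
    M = int(np.argmax(terms))  # argmax returns the first maximal index
    return SteadyStateProfile(kappa=1.0 / terms[M], eta=mix.etas[M])


# ----------------------------------------------------------------------
# Vectorized log-domain versions used by the ensemble-level modules.
# ----------------------------------------------------------------------

def mixture_params_arrays(log_kinv: np.ndarray, log_eta: np.ndarray,
                          log_beta: np.ndarray | None = None, axis: int = 0):
    """Log-domain effective mixture parameters for arrays of components.

    Parameters
    ----------
    log_kinv, log_eta : ndarray
        ``log kappa**-1`` and ``log eta`` with components along ``axis``
        (any other axes are broadcast, e.g. receptors or Monte Carlo trials).
    log_beta : ndarray or None
        Log concentration fractions; ``None`` means equiproportionate
        (fractions cancel out of ``eta_mix`` and shift ``log kappa_mix**-1``
        by ``-log K``).

    Returns
    -------
    (log_kinv_mix, log_eta_mix) : tuple of ndarray
    """
    w = log_kinv if log_beta is None else log_kinv + log_beta
    lse_w = logsumexp(w, axis=axis)
    log_eta_mix = logsumexp(w + log_eta, axis=axis) - lse_w
    if log_beta is None:
        K = log_kinv.shape[axis]
        log_kinv_mix = lse_w - np.log(K)
    else:
        log_kinv_mix = lse_w
    return log_kinv_mix, log_eta_mix


def response_from_log_params(log_C, log_kinv_mix, log_eta_mix,
                             n: float = DEFAULT_HILL, Fmax: float = 1.0):
    """Hill response at finite total concentration, in the log domain.

    Computes ``Fmax / (1 + ((1 + x)/(eta x))**n)`` with
    ``x = C * kappa_mix**-1``; ``log_C = inf`` gives the saturating limit.
    """
    log_x = np.asarray(log_C, dtype=float) + log_kinv_mix
    # log((1+x)/x) = log1p(exp(-log_x)) computed stably
    log_ratio = np.logaddexp(0.0, -log_x) - log_eta_mix
    with np.errstate(over="ignore"):
        return Fmax / (1.0 + np.exp(float(n) * log_ratio))


# ----------------------------------------------------------------------
# Approximation-error experiment
# ----------------------------------------------------------------------

def approximation_error_experiment(nmix_values: Sequence[int],
                                   n_receptors: int = 250,
                                   sigma_kappa: float = 4.0,
                                   concentration_mode: str = "equiproportionate",
                                   trials: int = 100,
                                   seed: int = 0,
                                   decades: float = 6.0) -> pd.DataFrame:
    """Relative error of the dominant-component approximation vs mixture size.

    For each mixture size ``nmix``, each trial draws ``nmix`` odorants with
    independent per-receptor ``log kappa**-1 ~ N(0, sigma_kappa)`` and
    ``log eta ~ N(0, 1)``, computes the exact and approximate
    ``(kappa_mix**-1, eta_mix)`` for every receptor, and records the mean
    (and median) relative error ``|approx - exact| / exact`` over receptors.

    ``concentration_mode`` is ``"equiproportionate"`` (all fractions equal)
    or ``"log-uniform"`` (component concentrations drawn uniformly in log
    scale over ``decades`` orders of magnitude).

    Returns a tidy frame with columns
    ``nmix, trial, err_kappa, err_eta, err_kappa_median, err_eta_median``.
    """
    if concentration_mode not in ("equiproportionate", "log-uniform"):
        raise ValueError(f"unknown concentration_mode: {concentration_mode!r}")
    rows = []
    for nmix in nmix_values:
        if nmix < 1:
            raise ValueError("nmix must be >= 1")
        rng = substream(seed, "approx-error", concentration_mode, int(nmix))
        for trial in range(trials):
            lk = rng.normal(0.0, sigma_kappa, size=(nmix, n_receptors))
            le = rng.normal(0.0, 1.0, size=(nmix, n_receptors))
            if concentration_mode == "equiproportionate":
                lb = np.full((nmix, 1), -np.log(nmix))
            else:
                logC = rng.uniform(0.0, decades * np.log(10.0), size=(nmix, 1))
                lb = logC - logsumexp(logC, axis=0)
            w = lk + lb
            lkinv_exact, leta_exact = mixture_params_arrays(lk, le, log_beta=lb)
            M = np.argmax(w, axis=0)
            cols = np.arange(n_receptors)
            lkinv_appr = w[M, cols]
            leta_appr = le[M, cols]
            rel_k = np.abs(np.expm1(lkinv_appr - lkinv_exact))
            rel_e = np.abs(np.expm1(leta_appr - leta_exact))
            rows.append({
                "nmix": nmix, "trial": trial,
                "err_kappa": float(rel_k.mean()),
                "err_eta": float(rel_e.mean()),
                "err_kappa_median": float(np.median(rel_k)),
                "err_eta_median": float(np.median(rel_e)),
            })
    return pd.DataFrame(rows)
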