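"""Non-competitive masking: suppression of CNG-channel gating by bilayer-bound agents.

Masking agents bind sites on the ciliary lipid bilayer near the
cyclic-nucleotide-gated (CNG) channels and lower the effective affinity of
cAMP for the channel.  With several agents competing for a limited pool of
sites, agent *i* at concentration :math:`M_i` with site affinity
:math:`K_{M,i}` occupies the fraction

.. math:: \\tilde M_i = \\frac{K_{M,i} M_i}{1 + \\sum_j K_{M,j} M_j},

and the channel opening rate is scaled by the suppression factor

.. math:: \\chi_M = \\Big(1 - \\sum_i \\mu_i \\tilde M_i\\Big)^m,

where the masking coefficient :math:`\\mu_i \\in [0, 1]` lumps the site
density, disruption radius and binding-energy shift of agent *i*, and the
exponent ``m = j/n`` counts the fraction of channel subunits affected.
Because the activation efficacy ``eta`` is proportional to the channel
opening rate, masking acts on a mixture simply as
:math:`\\eta_{mix} \\to \\chi_M\\, \\eta_{mix}`; it therefore lowers the
saturating firing rate to :math:`F_{max}/(1 + (\\chi_M \\eta)^{-n})` while
leaving receptor competition untouched.  A masking agent may itself also be
an excitatory odorant (it then carries both a receptor profile and a masking
profile), which is what makes mixture synergy possible: a weakly-masking
strong excitant can displace a strongly-masking companion from the masking
sites and "unmask" its own response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .steady_state import (DEFAULT_HILL, MixtureSpec, SteadyStateProfile,
                           effective_mixture_params, saturating_rate,
                           single_odorant_rate)

__all__ = [
    "MaskingProfile",
    "MaskedOdorant",
    "masking_occupancy",
    "suppression_factor",
    "masked_saturating_rate",
    "mixture_rate_with_masking",
    "mixture_dose_response",
    "masking_dose_response",
    "fit_masking_curve",
]


@dataclass(frozen=True)
class MaskingProfile:
    """Masking parameters of one agent.

    ``KM`` is the affinity for the masking sites (inverse concentration;
    0 means the agent never occupies them), ``mu`` the masking coefficient
    in [0, 1], and ``m`` the subunit exponent (``j/n`` for ``j`` affected
    CNG subunits; default 1).
    """

    KM: float = 0.0
    mu: float = 0.0
    m: float = 1.0

    def __post_init__(self):
        if self.KM < 0:
            raise ValueError("KM must be >= 0")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.m <= 0:
            raise ValueError("m must be positive")


# a pure masker carries a receptor profile it effectively never uses
_INERT = SteadyStateProfile(kappa=1.0, eta=1.0)


@dataclass(frozen=True)
class MaskedOdorant:
    """An odorant with both a receptor profile and a masking profile.

    ``binds_receptor=False`` marks a pure masking agent: it occupies masking
    sites but takes no part in receptor competition (the attached receptor
    profile is ignored).
    """

    receptor: SteadyStateProfile = _INERT
    masking: MaskingProfile = field(default_factory=MaskingProfile)
    binds_receptor: bool = True


def masking_occupancy(concentrations, affinities) -> np.ndarray:
    """Steady-state occupancy fractions of competing masking agents.

    ``Mtilde_i = KM_i M_i / (1 + sum_j KM_j M_j)``; the fractions sum to
    strictly less than one.
    """
    M = np.asarray(concentrations, dtype=float)
    KM = np.asarray(affinities, dtype=float)
    if np.any(M < 0) or np.any(KM < 0):
        raise ValueError("concentrations and affinities must be >= 0")
    load = KM * M
    return load / (1.0 + load.sum())


def suppression_factor(occupancies, mus, m: float = 1.0) -> float:
    """Suppression factor ``chi_M = (1 - sum_i mu_i Mtilde_i)**m``.

    The base cannot go negative when the occupancy and coefficient
    invariants hold, but is clipped at zero defensively.
    """
    occ = np.asarray(occupancies, dtype=float)
    mu = np.asarray(mus, dtype=float)
    base = 1.0 - float(np.dot(mu, occ))
    return float(max(base, 0.0) ** m)


def masked_saturating_rate(eta: float, chi: float, n: float = DEFAULT_HILL,
                           Fmax: float = 1.0) -> float:
    """Saturating rate under masking, ``Fmax / (1 + (chi*eta)**-n)``."""
    if not 0.0 <= chi <= 1.0:
        raise ValueError("chi must lie in [0, 1]")
    if chi == 0.0:
        return 0.0
    return float(saturating_rate(chi * eta, n=n, Fmax=Fmax))


def _chi_of_components(components, concentrations, m_default=None) -> float:
    """chi_M from the masking occupancies of all mixture components."""
    M = np.asarray(concentrations, dtype=float)
    KM = np.array([c.masking.KM for c in components])
    mu = np.array([c.masking.mu for c in components])
    ms = [c.masking.m for c in components]
    # the subunit exponent is a channel-level property; require consistency
    m = m_default if m_default is not None else (ms[0] if ms else 1.0)
    occ = masking_occupancy(M, KM)
    return suppression_factor(occ, mu, m=m)


def mixture_rate_with_masking(components, concentrations,
                              n: float = DEFAULT_HILL, Fmax: float = 1.0,
                              total_concentration: float | None = None) -> float:
    """Peak response of a mixture with both competition and masking.

    Receptor competition among the receptor-binding components gives
    ``(kappa_mix, eta_mix)``; all components (including pure maskers)
    compete for the masking sites and produce ``chi_M``; the response is the
    Hill form with effective efficacy ``chi_M * eta_mix``.  With all
    ``mu = 0`` this reduces exactly to the competitive mixture rate.
    """
    conc = np.asarray(concentrations, dtype=float)
    if len(components) != conc.size:
        raise ValueError("components and concentrations must have equal length")
    chi = _chi_of_components(components, conc)
    binds = np.array([c.binds_receptor for c in components])
    profiles = [c.receptor for c, b in zip(components, binds) if b]
    mix = MixtureSpec(profiles, conc[binds])
    if mix.total_concentration == 0:
        return 0.0
    eff = effective_mixture_params(mix)
    if chi == 0.0:
        return 0.0
    masked = SteadyStateProfile(kappa=eff.kappa, eta=chi * eff.eta)
    C = mix.total_concentration if total_concentration is None else total_concentration
    return float(single_odorant_rate(C, masked, n=n, Fmax=Fmax))


def mixture_dose_response(components, fractions, concentration_grid,
                          n: float = DEFAULT_HILL, Fmax: float = 1.0) -> np.ndarray:
    """Dose-response helper: sweep total concentration at fixed composition."""
    frac = np.asarray(fractions, dtype=float)
    frac = frac / frac.sum()
    return np.array([
        mixture_rate_with_masking(components, frac * C, n=n, Fmax=Fmax)
        for C in np.asarray(concentration_grid, dtype=float)
    ])


def masking_dose_response(excitant: MaskedOdorant, masker: MaskingProfile,
                          masker_concentrations, n: float = DEFAULT_HILL) -> np.ndarray:
    """Suppression ratio ``1 - F_M(inf)/F(inf)`` vs masker concentration.

    The excitant is held at saturating concentration; the pure masking agent
    is swept over ``masker_concentrations`` (positive, sorted).  The ratio
    lies in [0, 1] and is non-decreasing in the masker concentration.
    """
    grid = np.asarray(masker_concentrations, dtype=float)
    if np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("masker concentration grid must be >= 0 and sorted")
    eta = excitant.receptor.eta
    F0 = saturating_rate(eta, n=n)
    out = np.empty(grid.size)
    for i, M in enumerate(grid):
        occ = masking_occupancy([M], [masker.KM])
        chi = suppression_factor(occ, [masker.mu], m=masker.m)
        out[i] = 1.0 - masked_saturating_rate(eta, chi, n=n) / F0
    return out


def fit_masking_curve(concentrations, ratios, eta: float,
                      n: float = DEFAULT_HILL, fit_m: bool = False):
    """Least-squares fit of (KM, mu[, m]) to a measured suppression curve.

    ``ratios`` are observed values of ``1 - F_M(inf)/F(inf)`` at the given
    masker ``concentrations`` for an excitant of known efficacy ``eta``.
    Returns a fitted :class:`MaskingProfile`.
    """
    from scipy.optimize import least_squares

    conc = np.asarray(concentrations, dtype=float)
    obs = np.asarray(ratios, dtype=float)

    def resid(x):
        KM, mu = np.exp(x[0]), 1.0 / (1.0 + np.exp(-x[1]))
        m = np.exp(x[2]) if fit_m else 1.0
        prof = MaskingProfile(KM=KM, mu=mu, m=m)
        pred = masking_dose_response(
            MaskedOdorant(receptor=SteadyStateProfile(1.0, eta)), prof, conc, n=n)
        return pred - obs

    x0 = [0.0, 0.0] + ([0.0] if fit_m else [])
    sol = least_squares(resid, x0)
    KM, mu = float(np.exp(sol.x[0])), float(1.0 / (1.0 + np.exp(-sol.x[1])))
    m = float(np.exp(sol.x[2])) if fit_m else 1.0
    return MaskingProfile(KM=KM, mu=mu, m=m)
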