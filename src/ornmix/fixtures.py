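"""Canonical small, deterministic instances used by tests and examples."""

from __future__ import annotations

from dataclasses import dataclass

from ._rng import substream
from .ensemble import EnsembleConfig, OdorantEnsembleProfile, sample_odorant
from .masking import MaskedOdorant, MaskingProfile
from .steady_state import SteadyStateProfile

__all__ = ["Fixtures", "generate_fixtures", "synergy_pair", "inhibition_pair"]


def synergy_pair() -> list[MaskedOdorant]:
    """Binary mixture whose response curve can exceed both components.

    kappa_A = kappa_B = 1, eta_A = 1, eta_B = 5.  B is the strong activator
    and the strong suppressor (mu_B = 0.7) but binds the masking sites only
    weakly (KM_B = 1e-5); A does not suppress (mu_A = 0) yet binds the
    sites strongly (KM_A = 1e-1).  In the mixture A displaces B from the
    masking sites, unmasking B's strong activation: at high concentration
    the mixture curve rises above both component curves.
    """
    return [
        MaskedOdorant(SteadyStateProfile(1.0, 1.0), MaskingProfile(KM=1e-1, mu=0.0)),
        MaskedOdorant(SteadyStateProfile(1.0, 5.0), MaskingProfile(KM=1e-5, mu=0.7)),
    ]


def inhibition_pair() -> list[MaskedOdorant]:
    """Same receptors as :func:`synergy_pair`, but now B binds the masking
    sites strongly (KM_B = 1, KM_A = 1e-5): B self-masks and A's receptor
    competition drags the mixture below both component curves."""
    return [
        MaskedOdorant(SteadyStateProfile(1.0, 1.0), MaskingProfile(KM=1e-5, mu=0.0)),
        MaskedOdorant(SteadyStateProfile(1.0, 5.0), MaskingProfile(KM=1.0, mu=0.7)),
    ]


@dataclass
class Fixtures:
    """Small deterministic instances: an N=8 ensemble with a 4-odorant pool
    (small enough for exhaustive 2^8 pattern enumeration) and the canonical
    synergy/inhibition masking pairs."""

    small_config: EnsembleConfig
    pool: list[OdorantEnsembleProfile]
    target: OdorantEnsembleProfile
    synergy: list[MaskedOdorant]
    inhibition: list[MaskedOdorant]


def generate_fixtures(seed: int = 12345) -> Fixtures:
    """Deterministic fixture set for the given seed (platform-independent)."""
    config = EnsembleConfig(N=8, sigma_kappa=4.0, rho=0.0, p=0.3)
    pool = [sample_odorant(config, substream(seed, "pool", i)) for i in range(4)]
    target = sample_odorant(config, substream(seed, "fixture-target"))
    return Fixtures(small_config=config, pool=pool, target=target,
                    synergy=synergy_pair(), inhibition=inhibition_pair())
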