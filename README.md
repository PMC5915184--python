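# ornmix

Modeling odor-mixture responses of mammalian olfactory receptor neurons
(ORNs): receptor-level antagonism, masking, and their consequences for
population coding and perception.

Natural odors are mixtures of many molecules that compete for a finite pool
of receptors on each ORN type. `ornmix` implements a biophysical model of
this competition and everything downstream of it: the transduction cascade
that converts binding into firing, the closed-form mixture algebra it
induces, a population-encoding model in which the degree of antagonism is a
single tunable correlation, and the decoding/psychophysics experiments that
quantify what antagonism buys (normalization of population activity,
better figure-ground segregation and component separation) and what it
costs (suppression and overshadowing of individual components).

The package is aimed at computational neuroscientists studying olfactory
encoding and at modelers who need a tested reference implementation of
competitive receptor algebra and non-competitive masking.

## The model in brief

Each odorant–receptor pair is reduced to two numbers: a sensitivity scale
κ (binding) and an activation efficacy η (transduction drive). The peak
firing rate of one ORN type to a single odorant at concentration *C* is

    F(C) = Fmax / (1 + ((1 + C/κ) / (η C/κ))^n),

a Hill response (n = 4 from CNG-channel cooperativity) that saturates at
`Fmax / (1 + η^-n)`. Because mixture components compete for the same
receptors, a K-component mixture behaves exactly like one virtual odorant
with effective parameters

    κ_mix⁻¹ = Σᵢ βᵢ κᵢ⁻¹,    η_mix = κ_mix Σᵢ ηᵢ βᵢ κᵢ⁻¹,

where βᵢ are concentration fractions. A strongly-binding, weakly-activating
component therefore *antagonizes* stronger activators. At the population
level, an odorant is a pair of N-vectors (log κ⁻¹, log η) across N receptor
types; the Pearson correlation ρ between them is the antagonism dial
(ρ = 1: best binders are best activators, no antagonism; ρ = 0: maximal
statistical antagonism). Non-competitive *masking* agents bind sites near
the CNG channels and scale η by a factor χ_M ≤ 1, which is what makes
mixture synergy and suppression below the component envelope possible.

Modules: `kinetics` (full ODE transduction model), `steady_state` (mixture
algebra), `masking`, `ensemble` (population encoding), `infotheory`
(Monte-Carlo mutual information for figure-ground segregation), `decoders`
(logistic classifier banks, generalized ROC), `psychophysics` (perceived
intensity, suppression, overshadowing), plus an `ornmix` CLI for
reproducible figure-level experiments. See `docs/methods.md` for the
science and the numerical choices.

## Worked example

```python
import numpy as np
from ornmix import EnsembleConfig, SteadyStateProfile, MixtureSpec
from ornmix.steady_state import (single_odorant_rate,
                                 effective_mixture_params, mixture_rate)
from ornmix.infotheory import BackgroundModel, SegregationTask, mutual_information

# competitive antagonism in a binary mixture (one receptor type)
A = SteadyStateProfile(kappa=1.0, eta=5.0)   # strong activator
B = SteadyStateProfile(kappa=0.01, eta=0.2)  # sensitive but weak: an antagonist
mix = MixtureSpec([A, B], [1.0, 1.0])
eff = effective_mixture_params(mix)
print(f"F_A(2) = {single_odorant_rate(2.0, A):.3f}")
print(f"F_B(2) = {single_odorant_rate(2.0, B):.3f}")
print(f"kappa_mix = {eff.kappa:.4f}, eta_mix = {eff.eta:.3f}")
print(f"F_mix(2) = {mixture_rate(mix):.3f}")

# what antagonism buys: detecting a known target on a 64-odorant background
for rho in (0.0, 1.0):
    task = SegregationTask.sampled_target(
        EnsembleConfig(N=250, rho=rho, p=0.5),
        BackgroundModel.fixed(64), seed=1,
        mc_background_draws=1500, mc_pattern_samples=10000)
    I, se = mutual_information(task, seed=1)
    print(f"rho = {rho:.0f}: I(T; z) = {I:.3f} +- {se:.3f} bits")
```

prints

```
F_A(2) = 0.992
F_B(2) = 0.002
kappa_mix = 0.0198, eta_mix = 0.248
F_mix(2) = 0.004
rho = 0: I(T; z) = 0.649 +- 0.003 bits
rho = 1: I(T; z) = 0.000 +- 0.000 bits
```

The first block shows competitive antagonism at work: odorant B barely
responds on its own (0.002) yet drags the mixture response down to 0.004,
because it out-competes A for receptors (κ_mix is set by B) while
activating almost nothing (η_mix ≈ 0.25). The second block shows the
population-level payoff: with a 64-odorant background and sparsity 0.5, an
antagonistic code (ρ = 0) retains 0.65 of the 1 bit of target-presence
information, while the non-antagonistic code (ρ = 1) saturates and retains
essentially none.

Figure-level experiments run from the shell, e.g.

```sh
ornmix normalize-scan --out results/norm --seed 1
ornmix optimal-rho --out results/rho --seed 1
```

Each run writes tidy CSVs plus a `manifest.json` with the resolved
configuration and seeds; rerunning with the same seed reproduces the
outputs byte for byte.

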