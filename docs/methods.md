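# Methods

This note documents the models implemented in `ornmix`, their assumptions,
the parameters that matter, and the numerical and design choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Transduction kinetics (`ornmix.kinetics`)

**Reaction scheme.** Odorant X binds a receptor R and the complex activates
in a second step, `R + X <-> RX <-> RX*`, with forward/backward rates
(k1, k-1) and (k2, k-2); κ1 = k-1/k1 and κ2 = k-2/k2 are the step
equilibrium ratios. Activated receptors drive cAMP production (rate kC per
activated receptor, degradation dC); cAMP opens CNG channels cooperatively;
Ca²⁺ flows through open channels (influx kCa per open channel, extrusion
dCa); Ca²⁺–calmodulin (Ca-CaM) accumulates (forward rate kCaCaM, first-order
dissociation kCaCaM_back) and blocks CNG gating, producing adaptation.
Firing rate is proportional to the Ca²⁺-gated Cl⁻ current, taken linear in
Ca²⁺ with the constant lumped into Fmax.

**ODEs.** Per odorant i in the stimulus:

    dBᵢ/dt = k1ᵢ Cᵢ(t) R − (k-1ᵢ + k2ᵢ) Bᵢ + k-2ᵢ Aᵢ
    dAᵢ/dt = k2ᵢ Bᵢ − k-2ᵢ Aᵢ,      R = Rtot − Σ(Bᵢ + Aᵢ)
    dC/dt  = kC ΣAᵢ − dC·C
    open   = 1 / (1 + (kG_eff·C)⁻ⁿ),  kG_eff = kG / (1 + (CaCaM/CaCaM0)²)
    dCa/dt = kCa·CNGtot·open − dCa·Ca
    dCaCaM/dt = kCaCaM·Ca − kCaCaM_back·CaCaM

CNG gating is quasi-steady (the strong-cooperativity limit of the allosteric
scheme collapses to a Hill form of coefficient n); odorant concentration is
in excess of receptors; stimuli are ideal square pulses. The firing rate is
`F = Fmax · Ca·dCa/(kCa·CNGtot)`, the unique linear readout for which the
no-feedback steady state of a saturating stimulus equals the closed-form
`Fmax/(1+η⁻ⁿ)` — this ties the ODE model and the steady-state algebra
together, and is verified to 1% on random rate constants in the tests.

**Parameters** (defaults; rates in s⁻¹, counts rescaled to 1): kC=2, dC=1,
kG=10 (the lumped CNG half-activation constant k′G), CNGtot=1, n=4, kCa=20,
dCa=0.5, kCaCaM=1, CaCaM0=0.05, Rtot=1, Fmax=1. The reference
odorant-receptor pairs used in examples are (k1,k-1,k2,k-2) = (100,100,2,2)
and (80,100,0.4,2), giving (κ, η) = (0.5, 10) and (25/24, 10/3) through
κ = κ1κ2/(1+κ2) and η = kC·kG·Rtot/((1+κ2)·dC).

**The Ca-CaM dissociation rate is a free parameter** (only the forward rate
and the feedback half-point are constrained above). We set
kCaCaM_back = 0.5 s⁻¹. The trade-off: a very slow dissociation (e.g.
0.05 s⁻¹) lets Ca-CaM keep integrating the post-pulse Ca²⁺ tail, which (a)
drives the feedback so deep that second-pulse responses are identically
zero for tens of seconds (no graded recovery) and (b) places the Ca-CaM
peak seconds *after* the pulse, making two-pulse recovery non-monotone in
the inter-pulse interval. At 0.5 s⁻¹ recovery is monotone, complete within
a few tens of seconds, and the two-pulse suppression at a 10 s
onset-to-onset spacing is graded by the conditioning-pulse duration. The
feedback Hill coefficient (2) only needs to be steeply sigmoidal; its exact
value does not change the qualitative results.

**Operational definitions.** Latency is the first crossing of
`latency_fraction · Fmax` after stimulus onset (default fraction 0.05;
concentration–latency scans use 0.002 because adaptation terminates
responses well below Fmax). Two-pulse intervals are onset-to-onset, and the
second-pulse peak is measured above the residual rate at its onset so a
first-pulse tail cannot masquerade as recovery.

**Numerics.** LSODA with rtol 1e-6 / atol 1e-9, restarted at each
concentration breakpoint, output on a fixed grid (1 ms default; 5 ms for
multi-minute protocols). Mass conservation holds to 1e-8·Rtot.

## 2. Steady-state mixture algebra (`ornmix.steady_state`)

The peak response to a single odorant is `F(C) = Fmax/(1+((1+C/κ)/(ηC/κ))ⁿ)`
with F(0) = 0. Competition makes a K-component mixture equivalent to a
single odorant with `κ_mix⁻¹ = Σβᵢκᵢ⁻¹` and `η_mix = κ_mix Σηᵢβᵢκᵢ⁻¹`;
consequently the mixture dose-response always lies inside the envelope of
the component curves at equal total concentration (betweenness; property-
tested on random pairs). Zero-concentration components are dropped before
fractions are computed.

Because sensitivities are log-normally distributed with σ = 4 (natural
log), one term typically dominates both sums, giving the
single-dominant-component approximation `κ_mix⁻¹ ≈ β_M κ_M⁻¹`,
`η_mix ≈ η_M` with M = argmax βᵢκᵢ⁻¹ (ties broken by lowest index). Its
error is measured by `approximation_error_experiment`: the arithmetic mean
over receptors of `|approx−exact|/exact` per parameter (medians also
emitted), for equiproportionate or log-uniform (six-decade) concentrations.
At 128 components the mean error is ≈40% (the acceptance script recomputes
this), and variable concentrations make the approximation better, not
worse, by broadening the β·κ⁻¹ distribution.

All ensemble-scale computations run in the log domain (logsumexp over
components) so that σ = 4 log-normal weights never overflow.

## 3. Masking (`ornmix.masking`)

Masking agents compete for a limited pool of bilayer sites near the CNG
channels: agent i at concentration Mᵢ with site affinity K_{M,i} occupies
`M̃ᵢ = K_{M,i}Mᵢ / (1 + Σⱼ K_{M,j}Mⱼ)`. Occupied sites raise the energy of
the cAMP-bound channel state; in the dilute-site, additive-energy limit the
channel opening rate is scaled by `χ_M = (1 − Σ μᵢM̃ᵢ)^m`, where the
masking coefficient μᵢ ∈ [0,1] lumps the site density, disruption radius
and binding-energy shift of agent i (these microscopic parameters are not
separate model inputs), and m = j/n counts the fraction of affected channel
subunits (default 1). Since η is proportional to the channel opening rate,
masking acts on the whole mixture as η_mix → χ_M·η_mix — a channel-level
effect downstream of receptor identity, deliberately not applied
per-component. The base (1 − ΣμM̃) cannot go negative under the invariants
but is clipped at zero defensively.

The saturating masked rate is `Fmax/(1+(χ_M η)⁻ⁿ)`, and the measurable
suppression ratio `1 − F_M(∞)/F(∞)` is monotone in the masker
concentration. A least-squares fitter for (K_M, μ[, m]) against measured
suppression curves is provided as a utility.

**Synergy and inhibition.** Pure competition cannot push a mixture outside
the component envelope; masking can, in both directions. The package's
canonical binary pair has κ_A = κ_B = 1, η_A = 1, η_B = 5, μ_A = 0,
μ_B = 0.7, m = 1, with the masking-site affinities selecting the regime:

* *Synergy* (K_{M,A} = 10⁻¹, K_{M,B} = 10⁻⁵): B is the strong activator
  and the strong suppressor but binds the masking sites weakly; A binds
  them strongly without suppressing. In the mixture A displaces B from the
  sites and unmasks B's activation, lifting the mixture curve above both
  component curves at high concentration.
* *Inhibition* (K_{M,A} = 10⁻⁵, K_{M,B} = 1): B self-masks efficiently and
  A's receptor competition drags η_mix down, pushing the mixture below both
  component curves.

This assignment is the one consistent with the displacement mechanism; an
exhaustive scan over affinity pairings confirms no other assignment of
these values produces synergy.

## 4. Population encoding (`ornmix.ensemble`)

An odorant is a pair of N-vectors over receptor types (N = 250 default):
`log η ~ N(0,1)` i.i.d., and `log κ⁻¹ = σ_κ(ρ·log η + √(1−ρ²)·ω)` with
`ω ~ N(0,1)`, σ_κ = 4 — so ρ is exactly the Pearson correlation between
log-sensitivity and log-efficacy (natural logs throughout). ρ = 1 removes
antagonism (the best binder is the best activator; mixtures behave like OR
gates); ρ = 0 maximizes it.

At saturating concentration the rescaled glomerular response is
`y = 1/(1+η_mix⁻ⁿ)` per receptor (exact effective-parameter formula, not
the dominant approximation), binarized by the strict threshold
`τ = 1/(1+e^{−n·Φ⁻¹(1−p)})`, which makes the single-odorant activation
probability exactly the sparsity p. Finite-concentration responses use the
full Hill form with (κ_mix, η_mix); both code paths are exposed and
saturating mixtures default to the analytic limit.

**Normalization.** With ρ = 0 the active fraction of saturating mixtures
stays near p as the number of components grows into the hundreds, while at
ρ = 1 it climbs toward the OR-gate bound 1−(1−p)^K; intermediate ρ
interpolates monotonically. Two caveats the exact algebra imposes on the
idealized (dominant-approximation) picture, both visible in the acceptance
suite: the ρ = 1 active fraction sits systematically *below* 1−(1−p)^K
(η_mix is a weighted mean, strictly below the component maximum), and the
ρ = 0 η_mix distribution is not literally invariant in mixture size — the
weighted mean shrinks it (two-sample KS ≈ 0.2 between 1 and 100 components)
even though the active fraction moves by less than 0.1 and the drift is far
smaller than at ρ = 1. The distribution-independence of normalization is
checked with exponential efficacies as well as log-normal.

## 5. Figure-ground information (`ornmix.infotheory`)

Task: a known target is present (T=1) or absent (T=0) with prior 1/2 on
top of nb background odorants drawn i.i.d. from the ensemble; the observer
sees the binary pattern z. Receptor types are independent and backgrounds
i.i.d., so `Pr(z|T,nb)` factorizes into per-receptor Bernoulli terms whose
probabilities q_i(T,nb) are precomputed by Monte Carlo: background streams
of 128 odorants are drawn once and cumulatively summed so a single stream
yields the saturating equiproportionate mixture for *every* nb at once.
`H(T|z)` is then estimated by sampling z from the factorized model,
computing the exact Bayes posterior (log-domain, background sizes mixed
over Pr(nb)), and averaging the binary entropy; `I = 1 − H(T|z)` with the
MC standard error from the entropy samples. Probabilities are clipped to
[1e-12, 1−1e-12], an estimator bias of that order. The background-size law
is either a point mass or a discrete truncated exponential
(pmf ∝ e^{−nb/λ} on 1..128, λ solved by root-finding so the mean is 32).

The MC estimator is validated against exhaustive enumeration of all 2⁸
patterns on an 8-receptor, 4-odorant-pool fixture (agreement within 0.02
bits). MI scans over ρ average a few freshly drawn targets with common
random numbers across ρ so target-to-target variability does not confound
the ordering; ρ* is the grid argmax (ties to smallest ρ). Default problem
sizes (10³–10⁴ background draws per table, 8×10³–2×10⁴ pattern samples,
3–4 targets) hold the per-curve standard error near 0.003 bits.

## 6. Decoders (`ornmix.decoders`)

A decoder is a logistic readout `Pr(present|z) = 1/(1+e^{−(θ·z+b)})`,
fitted by scikit-learn's deterministic lbfgs (L2 penalty C=1, tol 1e-6,
fixed iteration budget, seeded balanced training sets). For component
separation, one classifier per odorant of a fixed panel S (500 default) is
trained against backgrounds of 1–10 panel odorants; test mixtures have
1–20. Sweeping a shared detection threshold yields generalized ROC curves:
hit rate (declared ∩ present / present) versus mean false-positive count
out of the panel. Panel responses are cached as weight matrices (Σκ⁻¹ and
Σηκ⁻¹ are subset sums), so the 500 classifiers reuse one pattern bank.

The noisy figure-ground variant delivers target and backgrounds at
concentrations log-uniform over 3 decades, perturbs each receptor's
effective efficacy as η_mix → (1+ε)η_mix with ε ~ N(0, ε₀²) truncated at
−0.99 (the truncation keeps η_mix positive; the distribution is a modeling
choice, the level ε₀ = 0.4 the reference condition), and reports balanced
accuracy of a single trained classifier.

## 7. Psychophysics (`ornmix.psychophysics`)

**Recruitment and perceived intensity.** For one odorant, each glomerulus
crosses τ at some concentration; the recruitment table records, per
glomerulus, the smallest concentration on a 121-point, six-decade log grid
where the full single-odorant response exceeds τ (expected table size
≈ p·N). The inferred log-concentration of an odorant given an active set is
the sum of the per-glomerulus log-increments of its active table members,
with concentrations read in units of the grid floor so every increment is
non-negative: the first glomerulus contributes log(c₁/c_min), glomerulus
i>1 contributes log(cᵢ/cᵢ₋₁). A contiguous active prefix telescopes to
log c_k; a suppressed middle glomerulus does not void later contributions
(each carries its own increment); an empty active set returns a "below
first recruitment" sentinel. The floor-based convention matters: with
absolute log c₁ as the first increment, masking off the most sensitive
glomerulus while higher-efficacy ones survive would *raise* the estimate
by decades; with floor-based increments a shrinking active set can only
lower it, so masking curves are monotone by construction.

The readout rounds down to the last recruited glomerulus, so its bias is
−½ of the local recruitment-event spacing (the Weber step,
≈ log(c_max/c₁)/(pN)); at p = 0.5, N = 250 this averages −0.025 decades
over the central four decades — exactly half a 0.05-decade grid step, a
resolution limit of the estimator rather than a removable error.

**Experiments** (all at p = 0.5 by default, averaged over freshly sampled
odorant pairs): inferred-vs-true curves for an odorant alone (identity
within resolution), with an equal-concentration companion (inhibition at
high concentration, mild synergy near threshold — cooperative
hyper-additivity pushes extra glomeruli over τ), and with a pure,
non-receptor-binding masker (monotone decrease, faster for larger μ).
Suppression: A fixed at saturating concentration (10⁶ in units of the
median κ), B varied; a glomerulus is suppressed for A if it is active under
A alone, inactive under B alone, yet inactive in the mixture. The reported
fraction is conditional on that set (the per-N unconditional fraction is
also emitted; per-trial fractions are averaged, trials with empty
conditioning sets are skipped and counted). When B masks, its solo
response includes its own self-masking — the channel-level effect applies
to whatever is delivered — which is precisely what makes suppression
asymmetric (A's glomeruli are masked away; B's were never counted as
active). Overshadowing: logistic detectors for A and B are trained on
single-odorant patterns at log-uniform concentrations (negatives: blanks
and the other odorant), then read out on mixtures at varying concentration
ratios; B is overshadowed where its mean detector output falls below 0.5.

## 8. Synthetic data, problem sizes, and what the tests show

All inputs are synthetic by design: the generator *is* the study
condition. Reference conditions are N = 250 receptor types, σ_κ = 4,
log-normal (or exponential, for robustness checks) efficacies, Hill n = 4,
equiproportionate saturating mixtures unless stated, truncated-exponential
background complexity (mean 32, max 128), panel size 500, noise ε₀ = 0.4.
The test suite and acceptance script run scaled versions chosen to hold
Monte-Carlo standard errors well below the effect sizes they check
(e.g. 60–200 trials per fraction estimate, 8–20×10³ MI pattern samples,
panels of 40 for decoder unit tests); these sizes are package defaults for
testing, and every stochastic routine takes explicit seeds through named
substreams of one master seed (no global RNG state).

What passing tests do *not* show: the generator's receptors are
statistically exchangeable and independent — real receptor repertoires
have correlated tuning, gain control and temporal structure; stimuli are
square pulses at equilibrium, not sniff-modulated plumes; "perception" is
a fixed algorithmic readout of a binary code, not behavior. Conclusions
transfer to real data only insofar as those idealizations hold.

## 9. Known limitations

* The Ca-CaM closure (first-order dissociation, no CaM-pool depletion) is
  one admissible reading of the feedback; other closures change two-pulse
  quantitative detail but not the steady-state algebra.
* PI3K-dependent non-competitive inhibition is out of scope; masking is
  the only non-competitive mechanism modeled.
* The OR-gate closed form 1−(1−p)^K and exact η_mix-distribution
  invariance at ρ = 0 hold only under the single-dominant-component
  approximation; the package computes the exact algebra and quantifies the
  gap (see §4).
* Binary glomerular codes: graded multi-level readouts would change
  absolute information values, though not the ρ comparisons the binary
  code is used for.
* Decoders are linear; recurrent or nonlinear readouts could exploit
  structure the logistic bank cannot.
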