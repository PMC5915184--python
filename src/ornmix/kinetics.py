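"""Time-resolved ORN signal-transduction dynamics.

The model follows the canonical mammalian transduction cascade: odorant
binding and two-step activation of the receptor, cAMP production by
adenylyl-cyclase coupled to activated receptors, cooperative opening of
cyclic-nucleotide-gated (CNG) channels by cAMP, Ca2+ influx through open
channels, and Ca2+-calmodulin (Ca-CaM) feedback that blocks CNG gating and
produces adaptation.  Firing rate is taken proportional to the Ca2+-gated
Cl- current, itself linear in Ca2+ here, with the constant lumped into
``Fmax``.

State variables (per odorant *i* in the stimulus, plus globals)::

    dB_i/dt     = k1_i C_i(t) R - (k-1_i + k2_i) B_i + k-2_i A_i
    dA_i/dt     = k2_i B_i - k-2_i A_i
    R           = Rtot - sum_i (B_i + A_i)          (conservation)
    dC/dt       = kC sum_i A_i - dC C               (cAMP)
    open        = 1 / (1 + (kG_eff C)^-n)           (quasi-steady CNG)
    kG_eff      = kG / (1 + (CaCaM/CaCaM0)^2)       (feedback block)
    dCa/dt      = kCa CNGtot open - dCa Ca
    dCaCaM/dt   = kCaCaM Ca - kCaCaM_back CaCaM

CNG gating is treated as instantaneous (quasi-steady Hill form, the strong
cooperativity limit), and the firing rate is
``F = Fmax * Ca * dCa / (kCa * CNGtot)``, normalized so that with feedback
off the steady state of a saturating stimulus is ``Fmax / (1 + eta^-n)``,
matching the closed-form peak-response algebra in
:mod:`ornmix.steady_state`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .steady_state import SteadyStateProfile

__all__ = [
    "OdorantReceptorKinetics",
    "TransductionParams",
    "StimulusEvent",
    "StimulusProtocol",
    "ResponseTimeSeries",
    "simulate",
    "response_summary",
    "two_pulse_peaks",
    "adaptation_protocol",
    "NO_RESPONSE",
]

#: Sentinel latency for a trace that never crosses the latency criterion.
NO_RESPONSE = float("nan")


@dataclass(frozen=True)
class OdorantReceptorKinetics:
    """Full rate constants of the two-step binding/activation scheme.

    ``k1`` / ``k_neg1`` are the forward/backward binding rates and ``k2`` /
    ``k_neg2`` the forward/backward activation rates for one
    odorant-receptor pair.  The derived ratios ``kappa1 = k_neg1/k1`` and
    ``kappa2 = k_neg2/k2`` give the sensitivity scale
    ``kappa = kappa1*kappa2/(1+kappa2)``.
    """

    k1: float
    k_neg1: float
    k2: float
    k_neg2: float

    def __post_init__(self):
        for name in ("k1", "k_neg1", "k2", "k_neg2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"rate {name} must be finite and positive, got {v}")

    @property
    def kappa1(self) -> float:
        return self.k_neg1 / self.k1

    @property
    def kappa2(self) -> float:
        return self.k_neg2 / self.k2

    @property
    def kappa(self) -> float:
        return self.kappa1 * self.kappa2 / (1.0 + self.kappa2)


@dataclass(frozen=True)
class TransductionParams:
    """Parameters of the transduction cascade downstream of the receptor.

    Defaults are the reference values used throughout the package:
    ``kC=2, dC=1, kG=10, CNGtot=1, n=4, kCa=20, dCa=0.5, kCaCaM=1,
    CaCaM0=0.05`` (rates in 1/s; receptor and channel counts rescaled to 1).
    The Ca-CaM dissociation rate ``kCaCaM_back`` closes the feedback loop
    with first-order kinetics; its default (0.5/s) makes recovery from
    adaptation complete within a few tens of seconds while keeping the
    two-pulse suppression graded by stimulation history (see the methods
    note for the trade-off behind this choice).  Set ``CaCaM0 = inf`` to
    disable feedback.
    """

    kC: float = 2.0
    dC: float = 1.0
    kG: float = 10.0
    CNGtot: float = 1.0
    n: float = 4.0
    kCa: float = 20.0
    dCa: float = 0.5
    kCaCaM: float = 1.0
    kCaCaM_back: float = 0.5
    CaCaM0: float = 0.05
    Rtot: float = 1.0
    Fmax: float = 1.0

    def __post_init__(self):
        for name in ("kC", "dC", "kG", "CNGtot", "kCa", "dCa", "kCaCaM",
                     "kCaCaM_back", "Rtot", "Fmax"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.CaCaM0 > 0:
            raise ValueError("CaCaM0 must be positive (inf disables feedback)")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")

    def efficacy(self, kin: OdorantReceptorKinetics) -> float:
        """Activation efficacy eta = kC * kG * alpha / dC, alpha = Rtot/(1+kappa2)."""
        alpha = self.Rtot / (1.0 + kin.kappa2)
        return self.kC * self.kG * alpha / self.dC

    def steady_state_profile(self, kin: OdorantReceptorKinetics) -> SteadyStateProfile:
        """The (kappa, eta) pair implied by full rate constants and cascade."""
        return SteadyStateProfile(kappa=kin.kappa, eta=self.efficacy(kin))


@dataclass(frozen=True)
class StimulusEvent:
    odorant: int        # index into the kinetics list
    concentration: float
    onset: float
    offset: float

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not self.offset > self.onset:
            raise ValueError("offset must exceed onset")


@dataclass
class StimulusProtocol:
    """Square-pulse stimulus protocol; overlapping events form mixtures."""

    events: Sequence[StimulusEvent]
    duration: float
    dt: float = 1e-3

    def __post_init__(self):
        self.events = [e if isinstance(e, StimulusEvent) else StimulusEvent(*e)
                       for e in self.events]
        if any(e.offset > self.duration for e in self.events):
            raise ValueError("protocol duration must cover all events")

    def breakpoints(self) -> np.ndarray:
        pts = {0.0, self.duration}
        for e in self.events:
            pts.add(e.onset)
            pts.add(e.offset)
        return np.array(sorted(p for p in pts if 0.0 <= p <= self.duration))

    def concentrations(self, t: float, n_odorants: int) -> np.ndarray:
        c = np.zeros(n_odorants)
        for e in self.events:
            if e.onset <= t < e.offset:
                c[e.odorant] += e.concentration
        return c


@dataclass
class ResponseTimeSeries:
    """Integrated trajectory: time grid, firing rate and all state variables."""

    time: np.ndarray
    rate: np.ndarray               # F(t), fraction of Fmax times Fmax
    bound: np.ndarray              # B_i(t), shape (n_odorants, T)
    active: np.ndarray             # A_i(t)
    camp: np.ndarray               # C(t)
    ca: np.ndarray                 # Ca(t)
    cacam: np.ndarray              # CaCaM(t)
    params: TransductionParams = field(repr=False, default=None)

    def free_receptors(self) -> np.ndarray:
        return self.params.Rtot - self.bound.sum(0) - self.active.sum(0)


_STATE_NAMES = ("bound B", "active A", "cAMP C", "Ca", "CaCaM")


def _open_fraction(C, kG_eff, n):
    # Hill form 1/(1+(kG C)^-n) written as a logistic in log concentration
    with np.errstate(divide="ignore"):
        return expit(n * (np.log(np.maximum(C, 0.0)) + np.log(kG_eff)))


def simulate(kinetics_set: Sequence[OdorantReceptorKinetics],
             params: TransductionParams,
             protocol: StimulusProtocol,
             rtol: float = 1e-6, atol: float = 1e-9) -> ResponseTimeSeries:
    """Integrate the transduction ODEs for an arbitrary pulse protocol.

    The stimulus is piecewise constant, so integration restarts at each
    concentration breakpoint with a stiff-capable solver (LSODA) and the
    solution is evaluated on a fixed grid of step ``protocol.dt``.
    """
    if len(kinetics_set) == 0:
        raise ValueError("at least one odorant is required")
    K = len(kinetics_set)
    k1 = np.array([k.k1 for k in kinetics_set])
    kn1 = np.array([k.k_neg1 for k in kinetics_set])
    k2 = np.array([k.k2 for k in kinetics_set])
    kn2 = np.array([k.k_neg2 for k in kinetics_set])
    p = params
    inv_cacam0_sq = 0.0 if np.isinf(p.CaCaM0) else 1.0 / p.CaCaM0**2

    def rhs(t, y, conc):
        B = y[:K]
        A = y[K:2 * K]
        C, Ca, CaCaM = y[2 * K], y[2 * K + 1], y[2 * K + 2]
        R = p.Rtot - B.sum() - A.sum()
        dB = k1 * conc * R - (kn1 + k2) * B + kn2 * A
        dA = k2 * B - kn2 * A
        dC = p.kC * A.sum() - p.dC * C
        kG_eff = p.kG / (1.0 + CaCaM**2 * inv_cacam0_sq)
        opn = _open_fraction(C, kG_eff, p.n)
        dCa = p.kCa * p.CNGtot * opn - p.dCa * Ca
        dCaCaM = p.kCaCaM * Ca - p.kCaCaM_back * CaCaM
        return np.concatenate([dB, dA, [dC, dCa, dCaCaM]])

    grid = np.arange(0.0, protocol.duration + 0.5 * protocol.dt, protocol.dt)
    grid[-1] = min(grid[-1], protocol.duration)
    y = np.zeros(2 * K + 3)
    states = np.empty((y.size, grid.size))
    states[:, 0] = y
    filled = 1
    bps = protocol.breakpoints()
    for t0, t1 in zip(bps[:-1], bps[1:]):
        conc = protocol.concentrations(t0, K)
        seg = grid[(grid > t0) & (grid <= t1)]
        t_eval = seg if seg.size else None
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, args=(conc,))
        if not sol.success:
            y_last = sol.y[:, -1] if sol.y.size else y
            bad = _first_bad_state(y_last, K)
            raise RuntimeError(
                f"integrator failed in [{t0}, {t1}]: {sol.message} "
                f"(first offending state variable: {bad})")
        if seg.size:
            states[:, filled:filled + seg.size] = sol.y
            filled += seg.size
        y = sol.y[:, -1] if sol.y.size else y
        bad = _first_bad_state(y, K)
        if bad is not None:
            raise RuntimeError(f"non-finite state after t={t1}: {bad}")

    B = states[:K]
    A = states[K:2 * K]
    C = states[2 * K]
    Ca = states[2 * K + 1]
    CaCaM = states[2 * K + 2]
    F = p.Fmax * np.clip(Ca * p.dCa / (p.kCa * p.CNGtot), 0.0, 1.0)
    return ResponseTimeSeries(time=grid, rate=F, bound=B, active=A,
                              camp=C, ca=Ca, cacam=CaCaM, params=p)


def _first_bad_state(y: np.ndarray, K: int):
    if np.all(np.isfinite(y)):
        return None
    idx = int(np.flatnonzero(~np.isfinite(y))[0])
    if idx < K:
        return f"{_STATE_NAMES[0]}[{idx}]"
    if idx < 2 * K:
        return f"{_STATE_NAMES[1]}[{idx - K}]"
    return _STATE_NAMES[2 + idx - 2 * K]


def response_summary(ts: ResponseTimeSeries, latency_fraction: float = 0.05,
                     onset: float | None = None):
    """Peak rate and response latency of a simulated trace.

    Latency is the first time after stimulus ``onset`` (default: start of
    the trace) at which F crosses ``latency_fraction * Fmax``; if the trace
    never crosses, the latency is the ``NO_RESPONSE`` sentinel (NaN).
    """
    if ts.time.size == 0:
        raise ValueError("empty time series")
    if not 0.0 < latency_fraction < 1.0:
        raise ValueError("latency_fraction must lie in (0, 1)")
    t0 = 0.0 if onset is None else onset
    sel = ts.time >= t0
    rate = ts.rate[sel]
    time = ts.time[sel]
    peak = float(rate.max())
    thr = latency_fraction * ts.params.Fmax
    above = np.flatnonzero(rate >= thr)
    latency = float(time[above[0]] - t0) if above.size else NO_RESPONSE
    return peak, latency


def two_pulse_peaks(kinetics: OdorantReceptorKinetics,
                    params: TransductionParams,
                    interval: float,
                    pulse_duration: float = 1.0,
                    concentration: float = 1.0,
                    dt: float = 5e-3) -> tuple[float, float]:
    """Peaks of two identical pulses with onset-to-onset ``interval``.

    The second-pulse peak is measured above the residual rate at its onset
    (baseline-subtracted and clipped at zero), so a tail of the first
    response does not masquerade as recovery.
    """
    if interval < pulse_duration:
        raise ValueError("interval must be >= pulse_duration (no overlap)")
    proto = StimulusProtocol(
        events=[StimulusEvent(0, concentration, 0.0, pulse_duration),
                StimulusEvent(0, concentration, interval, interval + pulse_duration)],
        duration=interval + pulse_duration + 3.0, dt=dt)
    ts = simulate([kinetics], params, proto)
    i2 = int(np.searchsorted(ts.time, interval))
    first = float(ts.rate[:i2].max())
    second = float(max(ts.rate[i2:].max() - ts.rate[i2 - 1], 0.0))
    return first, second


def adaptation_protocol(kinetics: OdorantReceptorKinetics,
                        params: TransductionParams,
                        interpulse_intervals: Sequence[float],
                        pulse_duration: float = 1.0,
                        concentration: float = 1.0,
                        dt: float = 5e-3) -> np.ndarray:
    """Two-pulse adaptation assay: recovery fraction vs inter-pulse interval.

    Intervals are onset-to-onset.  Returns the ratio of the (baseline-
    subtracted) second-pulse peak to the first-pulse peak, one value per
    interval, each in [0, 1] up to solver tolerance.
    """
    intervals = np.asarray(interpulse_intervals, dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    out = np.empty(intervals.size)
    for j, gap in enumerate(intervals):
        first, second = two_pulse_peaks(kinetics, params, gap, pulse_duration,
                                        concentration, dt)
        out[j] = second / first if first > 0 else np.nan
    return out
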