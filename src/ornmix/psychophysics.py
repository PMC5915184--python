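"""Simulated psychophysics: perceived intensity, suppression, overshadowing.

Perceived intensity of an odorant is modeled as the concentration read out
from its own glomerular recruitment sequence: as concentration rises,
glomeruli cross the activation threshold one by one at concentrations
``c_1 <= c_2 <= ...``; each active glomerulus ``g_i`` contributes the
log-increment ``log c_i - log c_{i-1}`` (the first contributes
``log c_1``), so a contiguous active prefix telescopes to ``log c_k`` —
an unbiased concentration estimate with a concentration-invariant Weber
ratio of about ``log(c_max/c_1) / (p N)``.

Delivering a companion odorant (or masking agent) alongside changes which
of the odorant's glomeruli are active in the mixture, moving the inferred
concentration: competitive antagonism produces inhibition at high
concentrations and mild synergy near threshold; masking lowers the
inferred concentration monotonically; two equal-intensity odorants under
full antagonism (rho = 0) suppress each other reciprocally, and a strong
odorant overshadows a weak one in a trained logistic detector's output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._rng import substream
from .ensemble import (EnsembleConfig, OdorantEnsembleProfile,
                       finite_concentration_response, sample_odorant,
                       sample_odorants)
from .masking import MaskingProfile, masking_occupancy, suppression_factor
from .steady_state import response_from_log_params

__all__ = [
    "RecruitmentTable",
    "BELOW_FIRST",
    "default_grid",
    "recruitment_table",
    "infer_concentration",
    "mixture_intensity_experiment",
    "masking_intensity_experiment",
    "suppression_fraction",
    "overshadowing_curve",
]

#: Sentinel inferred log-concentration when no table glomerulus is active.
BELOW_FIRST = -np.inf


def default_grid(decades: float = 6.0, points: int = 121,
                 center: float = 1.0) -> np.ndarray:
    """Log-spaced concentration grid centered on ``center`` (121 pts, 6 decades)."""
    half = decades / 2.0
    return center * np.logspace(-half, half, points)


@dataclass(frozen=True)
class RecruitmentTable:
    """Per-odorant recruitment concentrations of its glomeruli.

    ``concentrations`` are sorted ascending; ``glomeruli`` are the receptor
    indices recruited at those concentrations (glomeruli never recruited
    below ``cmax`` are excluded).  Expected size is about ``p * N``.
    """

    glomeruli: np.ndarray       # receptor indices, sorted by recruitment conc
    concentrations: np.ndarray  # recruitment concentration per glomerulus
    cmin: float                 # bottom of the recruitment grid (unit of c)
    cmax: float

    def __len__(self) -> int:
        return self.glomeruli.size

    @property
    def log_increments(self) -> np.ndarray:
        """Per-glomerulus log-concentration increments, all non-negative.

        Concentrations are read in units of the grid floor ``cmin``, so the
        first glomerulus contributes ``log(c_1/cmin)`` and glomerulus i > 1
        contributes ``log(c_i/c_{i-1})``; a sum of any subset is therefore
        monotone in the subset, and a contiguous prefix telescopes to
        ``log(c_k/cmin)``.
        """
        logc = np.log(self.concentrations)
        inc = np.diff(logc, prepend=np.log(self.cmin))
        return inc


def recruitment_table(odorant: OdorantEnsembleProfile, config: EnsembleConfig,
                      grid: np.ndarray | None = None) -> RecruitmentTable:
    """Smallest grid concentration at which each glomerulus crosses tau.

    Uses the full single-odorant dose-response per receptor; glomeruli
    whose response never exceeds the threshold on the grid are excluded.
    An empty table (no glomerulus recruited) is returned explicitly.
    """
    grid = default_grid() if grid is None else np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0) or np.any(grid <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    logc = np.log(grid)
    # y(c) per receptor: response of the single odorant at each grid point
    y = response_from_log_params(logc[:, None], odorant.log_kappa_inv[None, :],
                                 odorant.log_eta[None, :], n=config.n)
    above = y > config.tau
    ever = above.any(axis=0)
    first = np.argmax(above, axis=0)
    glomeruli = np.flatnonzero(ever)
    conc = grid[first[glomeruli]]
    order = np.argsort(conc, kind="stable")
    return RecruitmentTable(glomeruli=glomeruli[order], concentrations=conc[order],
                            cmin=float(grid[0]), cmax=float(grid[-1]))


def infer_concentration(active: np.ndarray, table: RecruitmentTable) -> float:
    """Inferred log-concentration from an active-glomerulus set.

    Each active table glomerulus contributes its own log-increment
    independently (a suppressed glomerulus earlier in the sequence does not
    void later contributions); active glomeruli not in the table are
    ignored.  Increments are accumulated on top of the grid floor
    ``log cmin``, so shrinking the active set can only lower the estimate.
    Returns ``BELOW_FIRST`` (-inf) when none are active.
    """
    if len(table) == 0:
        raise ValueError("empty recruitment table")
    active = np.asarray(active)
    if active.dtype == bool:
        mask = active[table.glomeruli]
    else:
        mask = np.isin(table.glomeruli, active)
    if not mask.any():
        return BELOW_FIRST
    return float(np.log(table.cmin) + table.log_increments[mask].sum())


def _infer_from_response(resp, table: RecruitmentTable) -> float:
    return infer_concentration(resp.z, table)


def mixture_intensity_experiment(config: EnsembleConfig,
                                 concentration_grid: np.ndarray | None = None,
                                 trials: int = 40, seed: int = 0,
                                 companion: str = "equal") -> pd.DataFrame:
    """Inferred vs true concentration of odorant A, alone and with odorant B.

    ``companion="equal"`` delivers B at the same concentration as A at each
    grid point; ``companion="none"`` measures A alone (the identity-check
    control).  Returns a tidy frame (trial, concentration, inferred_alone,
    inferred_mixture) of log10 values.
    """
    grid = default_grid() if concentration_grid is None else np.asarray(concentration_grid)
    rows = []
    for t in range(trials):
        rng = substream(seed, "intensity", t)
        A = sample_odorant(config, rng)
        B = sample_odorant(config, rng)
        table = recruitment_table(A, config, grid)
        if len(table) == 0:
            continue
        for c in grid:
            alone = finite_concentration_response([A], config, [c])
            la = _infer_from_response(alone, table)
            if companion == "equal":
                mix = finite_concentration_response([A, B], config, [c, c])
                lm = _infer_from_response(mix, table)
            else:
                lm = la
            rows.append({"trial": t, "log10_true": np.log10(c),
                         "log10_alone": la / np.log(10.0),
                         "log10_mixture": lm / np.log(10.0)})
    return pd.DataFrame(rows)


def masking_intensity_experiment(config: EnsembleConfig,
                                 mu_values: Sequence[float] = (0.4, 0.7, 1.0),
                                 masker_KM: float = 1.0,
                                 masker_concentrations: np.ndarray | None = None,
                                 concentration_A: float = 100.0,
                                 trials: int = 40, seed: int = 0) -> pd.DataFrame:
    """Inferred concentration of A as a pure masking agent's concentration rises.

    The masker binds no receptors; it scales every receptor's efficacy by
    ``chi_M = 1 - mu * Mtilde``.  Returns (mu, masker_concentration,
    inferred mean log10-concentration of A over trials).
    """
    mgrid = (np.logspace(-3, 3, 25) if masker_concentrations is None
             else np.asarray(masker_concentrations, float))
    rows = []
    for t in range(trials):
        rng = substream(seed, "masking-intensity", t)
        A = sample_odorant(config, rng)
        table = recruitment_table(A, config)
        if len(table) == 0:
            continue
        for mu in mu_values:
            for M in mgrid:
                occ = masking_occupancy([M], [masker_KM])
                chi = suppression_factor(occ, [mu])
                masked = OdorantEnsembleProfile(
                    A.log_kappa_inv,
                    A.log_eta + np.log(max(chi, 1e-300)))
                resp = finite_concentration_response([masked], config,
                                                     [concentration_A])
                rows.append({"trial": t, "mu": mu, "masker_concentration": M,
                             "log10_inferred": _infer_from_response(resp, table)
                             / np.log(10.0)})
    return pd.DataFrame(rows)


def suppression_fraction(config: EnsembleConfig,
                         concentration_ratios: Sequence[float] = (1.0,),
                         concentration_A: float = 1e6,
                         trials: int = 200, seed: int = 0,
                         masking_B: MaskingProfile | None = None) -> pd.DataFrame:
    """Fraction of each odorant's glomeruli suppressed in the binary mixture.

    A is fixed at a saturating concentration; B's concentration is
    ``concentration_A / ratio``.  A glomerulus counts as suppressed for A
    when it is active under A alone and inactive under B alone, yet
    inactive in the mixture (and symmetrically for B).  The conditional
    fraction normalizes by the size of that conditioning set; the
    unconditional per-N fraction is also reported.  Trials with an empty
    conditioning set are skipped and counted.

    ``masking_B`` optionally gives B a masking capacity (its occupancy is
    computed from B's own concentration), producing asymmetric suppression.
    """
    rows = []
    for ratio in concentration_ratios:
        cB = concentration_A / ratio
        stats = {k: [] for k in ("cond_A", "cond_B", "uncond_A", "uncond_B")}
        skipped = 0
        for t in range(trials):
            rng = substream(seed, "suppression", float(ratio), t)
            A = sample_odorant(config, rng)
            B = sample_odorant(config, rng)
            zA = finite_concentration_response([A], config, [concentration_A]).z
            if masking_B is None:
                zB = finite_concentration_response([B], config, [cB]).z
                zmix = finite_concentration_response(
                    [A, B], config, [concentration_A, cB]).z
            else:
                # B's masking acts at the channel level, so it suppresses B's
                # own solo response exactly as it suppresses the mixture
                occ = masking_occupancy([cB], [masking_B.KM])
                chi = suppression_factor(occ, [masking_B.mu], m=masking_B.m)
                log_chi = np.log(max(chi, 1e-300))
                Achi = OdorantEnsembleProfile(A.log_kappa_inv, A.log_eta + log_chi)
                Bchi = OdorantEnsembleProfile(B.log_kappa_inv, B.log_eta + log_chi)
                zB = finite_concentration_response([Bchi], config, [cB]).z
                zmix = finite_concentration_response(
                    [Achi, Bchi], config, [concentration_A, cB]).z
            condA = zA & ~zB
            condB = zB & ~zA
            if condA.sum() == 0 or condB.sum() == 0:
                skipped += 1
                continue
            stats["cond_A"].append((condA & ~zmix).sum() / condA.sum())
            stats["cond_B"].append((condB & ~zmix).sum() / condB.sum())
            stats["uncond_A"].append((condA & ~zmix).sum() / config.N)
            stats["uncond_B"].append((condB & ~zmix).sum() / config.N)
        rows.append({
            "ratio": float(ratio),
            "suppressed_A": float(np.mean(stats["cond_A"])),
            "suppressed_B": float(np.mean(stats["cond_B"])),
            "suppressed_A_perN": float(np.mean(stats["uncond_A"])),
            "suppressed_B_perN": float(np.mean(stats["uncond_B"])),
            "stderr_A": float(np.std(stats["cond_A"], ddof=1)
                              / np.sqrt(len(stats["cond_A"]))),
            "stderr_B": float(np.std(stats["cond_B"], ddof=1)
                              / np.sqrt(len(stats["cond_B"]))),
            "skipped_trials": skipped,
        })
    return pd.DataFrame(rows)


def _train_single_odorant_detector(odorant, others, config, rng,
                                   trials=2_000, decades: float = 6.0,
                                   center: float = 1.0):
    """Logistic detector of one odorant delivered alone at varying concentration.

    Positives: the odorant alone at log-uniform concentrations; negatives:
    an equal split of blanks and the other odorants delivered alone.
    """
    half = trials // 2
    lo = np.log(center) - 0.5 * decades * np.log(10.0)
    Z = np.zeros((trials, config.N))
    ypos = np.zeros(trials, dtype=bool)
    for i in range(half):
        c = np.exp(lo + rng.uniform(0, decades * np.log(10.0)))
        Z[i] = finite_concentration_response([odorant], config, [c]).z
        ypos[i] = True
    for i in range(half, trials):
        if others and rng.random() < 0.5:
            o = others[rng.integers(len(others))]
            c = np.exp(lo + rng.uniform(0, decades * np.log(10.0)))
            Z[i] = finite_concentration_response([o], config, [c]).z
    clf = LogisticRegression(solver="lbfgs", max_iter=200, tol=1e-6)
    clf.fit(Z, ypos)
    return clf


def overshadowing_curve(config: EnsembleConfig,
                        concentration_ratios: Sequence[float],
                        concentration_B: float = 1.0,
                        trials: int = 30, train_trials: int = 1_000,
                        detection_threshold: float = 0.5,
                        seed: int = 0) -> pd.DataFrame:
    """Detector output for a weak odorant B as a strong companion A grows.

    B stays at ``concentration_B`` while A is delivered at ratio * C_B.
    Logistic detectors for A and B are trained on single-odorant patterns
    at varying concentrations; the mean detector probabilities on the
    mixture are reported per ratio (B is 'overshadowed' where its
    probability falls below the detection threshold).
    """
    rows = []
    for t in range(trials):
        rng = substream(seed, "overshadow", t)
        A = sample_odorant(config, rng)
        B = sample_odorant(config, rng)
        detB = _train_single_odorant_detector(B, [A], config, rng, train_trials)
        detA = _train_single_odorant_detector(A, [B], config, rng, train_trials)
        for ratio in concentration_ratios:
            cA = concentration_B * ratio
            z = finite_concentration_response([A, B], config,
                                              [cA, concentration_B]).z
            pB = float(detB.predict_proba(z[None].astype(float))[0, 1])
            pA = float(detA.predict_proba(z[None].astype(float))[0, 1])
            rows.append({"trial": t, "ratio": float(ratio),
                         "prob_B": pB, "prob_A": pA,
                         "detected_B": pB > detection_threshold})
    return pd.DataFrame(rows)
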