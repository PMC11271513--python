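"""Pharmacology kinetics: decay/PK/4PL fitting, insurmountable-antagonism
ODE model, and residence-time PK-PD occupancy.

Fitting conventions
-------------------
* One-phase decay: y(t) = plateau − span·exp(−k·t); complex half-life
  t½ = ln2/k.  Initial values come from a deterministic log-linear
  pre-fit so repeated fits are reproducible.
* Terminal-phase PK: linear regression of log C vs t; t½ = ln2/kel.
* 4PL: y = bottom + (top − bottom)/(1 + (c/ic50)^hill).

Two-step induced-fit antagonism
-------------------------------
Receptor species (fractions of total, conserved at 1):

    R + A ⇌ R·A                 (agonist_kon·[A], agonist_koff)
    R + I ⇌ R·I                 (k1·[I], k_1)        encounter complex
    R·I  ⇌ R·I*                 (k2, k_2)            tight (isomerized)

Free ligand concentrations are held constant within a phase (ligand
excess), so each phase is a linear ODE dx/dt = M·x solved exactly with
the matrix exponential.  The functional-reversibility protocol is:
pretreat with inhibitor, wash (free [I] → 0), add agonist, read out the
agonist-occupied fraction relative to an inhibitor-free control.  A
slow-isomerizing inhibitor leaves a reservoir of tight complex R·I* that
the agonist cannot displace on the assay timescale — insurmountable
antagonism (Emax < 100%); with k2 = 0 the antagonism is surmountable.

Units: hours and nM throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit

from .assays import LN2, four_pl


class KineticsError(ValueError):
    pass


class DegenerateDataError(KineticsError):
    """Raised when the data carry no signal for the requested fit."""


# ---------------------------------------------------------------------------
# fitters
# ---------------------------------------------------------------------------

@dataclass
class OnePhaseDecayFit:
    k: float                 # 1/h
    t_half: Optional[float]  # h
    plateau: float
    span: float
    residual_sse: float
    converged: bool


@dataclass
class PKFit:
    kel: float
    t_half: Optional[float]
    c0: float
    residual_sse: float
    converged: bool


@dataclass
class FourPLFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    residual_sse: float
    converged: bool


def _decay_model(t, plateau, span, k):
    return plateau - span * np.exp(-k * t)


def fit_one_phase_decay(
    times: Sequence[float],
    responses: Sequence[float],
    constrain_plateau: Optional[float] = None,
) -> OnePhaseDecayFit:
    """Nonlinear least-squares fit of a one-phase exponential decay.

    ``constrain_plateau`` pins the long-time plateau (e.g. to 100% of
    control) instead of fitting it.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(t).size < 3:
        raise KineticsError("need at least 3 distinct time points")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        raise DegenerateDataError("responses are constant; no decay to fit")

    plateau0 = constrain_plateau if constrain_plateau is not None else y[np.argmax(t)]
    span0 = plateau0 - y[np.argmin(t)]
    if span0 == 0:
        span0 = np.ptp(y)
    # log-linear pre-fit for the rate
    resid = (plateau0 - y) / span0
    mask = resid > 0.02
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = LN2 / max(np.median(t[t > 0]), 1e-6)

    try:
        if constrain_plateau is not None:
            popt, _ = curve_fit(
                lambda tt, span, k: _decay_model(tt, constrain_plateau, span, k),
                t, y, p0=[span0, k0], maxfev=20000,
            )
            plateau, (span, k) = constrain_plateau, popt
        else:
            popt, _ = curve_fit(_decay_model, t, y, p0=[plateau0, span0, k0], maxfev=20000)
            plateau, span, k = popt
    except RuntimeError:
        return OnePhaseDecayFit(math.nan, None, math.nan, math.nan, math.inf, False)

    sse = float(np.sum((_decay_model(t, plateau, span, k) - y) ** 2))
    if k <= 0:
        return OnePhaseDecayFit(float(k), None, float(plateau), float(span), sse, False)
    return OnePhaseDecayFit(float(k), LN2 / float(k), float(plateau), float(span), sse, True)


def fit_log_linear_pk(
    times: Sequence[float],
    concentrations: Sequence[float],
    terminal_points: Optional[int] = None,
) -> PKFit:
    """Terminal-phase half-life by log-linear regression.

    ``terminal_points`` restricts the regression to the last n samples
    (default: all samples, appropriate for mono-exponential decay).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if terminal_points is not None:
        t, c = t[-terminal_points:], c[-terminal_points:]
    if t.size < 3:
        raise KineticsError("need at least 3 samples in the terminal window")
    if np.any(c <= 0):
        raise KineticsError("non-positive concentration in the terminal window")
    slope, intercept = np.polyfit(t, np.log(c), 1)
    logc_hat = slope * t + intercept
    sse = float(np.sum((logc_hat - np.log(c)) ** 2))
    kel = -float(slope)
    if kel <= 0:
        return PKFit(kel, None, float(np.exp(intercept)), sse, False)
    return PKFit(kel, LN2 / kel, float(np.exp(intercept)), sse, True)


def fit_4pl(concentrations: Sequence[float], responses: Sequence[float]) -> FourPLFit:
    """4-parameter-logistic concentration–response fit."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size < 4:
        raise KineticsError("need at least 4 concentrations")
    if np.any(c <= 0):
        raise KineticsError("concentrations must be positive")
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        raise DegenerateDataError("responses are constant; no sigmoid to fit")

    order = np.argsort(c)
    c_s, y_s = c[order], y[order]
    top0, bottom0 = y_s[0], y_s[-1]
    mid = 0.5 * (top0 + bottom0)
    ic50_0 = float(c_s[int(np.argmin(np.abs(y_s - mid)))])
    hill0 = 1.0 if top0 >= bottom0 else -1.0
    try:
        popt, _ = curve_fit(
            four_pl, c, y, p0=[ic50_0, hill0, top0, bottom0], maxfev=20000
        )
    except RuntimeError:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.inf, False)
    ic50, hill, top, bottom = (float(v) for v in popt)
    sse = float(np.sum((four_pl(c, *popt) - y) ** 2))
    if ic50 <= 0:
        return FourPLFit(ic50, hill, top, bottom, sse, False)
    return FourPLFit(ic50, hill, top, bottom, sse, True)


# ---------------------------------------------------------------------------
# two-step induced-fit antagonism
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStepModelParams:
    k1: float            # encounter association, 1/(nM·h)
    k_1: float           # encounter dissociation, 1/h
    k2: float            # isomerization to tight state, 1/h
    k_2: float           # reverse isomerization, 1/h
    agonist_kon: float = 1.0   # 1/(nM·h)
    agonist_koff: float = 1.0  # 1/h
    receptor_total: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_1", "k2", "k_2", "agonist_kon", "agonist_koff"):
            if getattr(self, name) < 0:
                raise KineticsError(f"{name} must be non-negative")

    @property
    def apparent_koff(self) -> float:
        """Slow off-rate of the complex pool under rapid RI⇌RI* pre-equilibrium."""
        if self.k2 == 0:
            return self.k_1
        return self.k_1 / (1.0 + self.k2 / self.k_2)

    @property
    def apparent_dissociation_half_life(self) -> float:
        return LN2 / self.apparent_koff


def _preset(t_half_h: float, encounter_kd_nm: float, k2: float, k_2: float,
            **kw) -> TwoStepModelParams:
    iso = 1.0 + (k2 / k_2 if k2 > 0 else 0.0)
    k_1 = (LN2 / t_half_h) * iso
    return TwoStepModelParams(k1=k_1 / encounter_kd_nm, k_1=k_1, k2=k2, k_2=k_2, **kw)


# Pseudoirreversible preset: encounter Kd 30 nM, isomerization constant
# k2/k_2 = 4 (hence apparent Kd 6 nM) and tight-pool dissociation
# half-life 9.41 h.  Surmountable presets have no tight state (k2 = 0)
# and complex half-lives 0.20 h and 0.98 h.
KSI_LIKE = _preset(9.41, 30.0, k2=2.0, k_2=0.5)
W146_LIKE = _preset(0.20, 30.0, k2=0.0, k_2=0.0)
COMPOUND4_LIKE = _preset(0.98, 30.0, k2=0.0, k_2=0.0)


def _rate_matrix(p: TwoStepModelParams, agonist_nm: float, inhibitor_nm: float) -> np.ndarray:
    """Generator matrix over species order (R, RA, RI, RI*)."""
    ka = p.agonist_kon * agonist_nm
    ki = p.k1 * inhibitor_nm
    return np.array(
        [
            [-(ka + ki), p.agonist_koff, p.k_1, 0.0],
            [ka, -p.agonist_koff, 0.0, 0.0],
            [ki, 0.0, -(p.k_1 + p.k2), p.k_2],
            [0.0, 0.0, p.k2, -p.k_2],
        ]
    )


def _propagate(p: TwoStepModelParams, x0: np.ndarray, agonist: float,
               inhibitor: float, duration: float) -> np.ndarray:
    if duration == 0:
        return x0
    return expm(_rate_matrix(p, agonist, inhibitor) * duration) @ x0


def _emax_model(c, emax, ec50, hill):
    c = np.asarray(c, dtype=float)
    return emax * c**hill / (ec50**hill + c**hill)


def fit_emax(agonist_concs, responses) -> dict:
    """Saturating-logistic fit of an ascending agonist curve; Emax = plateau."""
    c = np.asarray(agonist_concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    order = np.argsort(c)
    top_level = float(np.mean(y[order][-3:])) if y.size >= 3 else float(y.mean())
    # near-flat curves (e.g. a frozen tight-state reservoir suppresses all
    # agonist concentrations equally): the plateau is the high-dose level
    if np.ptp(y) < max(0.5, 5e-3 * np.abs(y).max()):
        return {"emax": top_level, "ec50": math.nan, "hill": math.nan,
                "converged": True}
    try:
        # EC50 confined to within a decade of the data so the fit cannot
        # drift to a degenerate flat-asymptote solution
        popt, _ = curve_fit(
            _emax_model, c, y,
            p0=[top_level, float(np.sqrt(c.min() * c.max())), 1.0],
            bounds=([0.0, c.min() / 10.0, 0.3], [1e4, c.max() * 10.0, 6.0]),
            maxfev=20000,
        )
        return {"emax": float(popt[0]), "ec50": float(popt[1]),
                "hill": float(popt[2]), "converged": True}
    except RuntimeError:
        return {"emax": top_level, "ec50": math.nan, "hill": math.nan,
                "converged": False}


def simulate_two_step_competition(
    params: TwoStepModelParams,
    pretreat_conc: float,
    pretreat_time: float = 1.0,
    agonist_concs: Sequence[float] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
    readout_time: float = 2.0,
) -> dict:
    """Functional-reversibility protocol in silico.

    Pretreat naive receptor with inhibitor for ``pretreat_time`` h, wash
    (free inhibitor → 0), add agonist, and read out the agonist-occupied
    fraction at ``readout_time`` h as % of the inhibitor-free control at
    the same agonist concentration.  Returns per-concentration responses
    and the fitted Emax.
    """
    if pretreat_time < 0 or readout_time <= 0:
        raise KineticsError("phase durations must be positive")
    if pretreat_conc < 0:
        raise KineticsError("pretreat_conc must be non-negative")
    x0 = np.array([params.receptor_total, 0.0, 0.0, 0.0])
    x_pre = _propagate(params, x0, agonist=0.0, inhibitor=pretreat_conc,
                       duration=pretreat_time)
    responses = []
    for a in agonist_concs:
        x_t = _propagate(params, x_pre, agonist=a, inhibitor=0.0,
                         duration=readout_time)
        x_c = _propagate(params, x0, agonist=a, inhibitor=0.0,
                         duration=readout_time)
        if abs(x_t.sum() - params.receptor_total) > 1e-8:
            raise KineticsError("receptor conservation violated")
        responses.append(100.0 * x_t[1] / x_c[1])
    responses = np.asarray(responses)
    emax = fit_emax(agonist_concs, responses)
    return {
        "agonist_concs": np.asarray(agonist_concs, dtype=float),
        "responses": responses,
        "emax": emax["emax"],
        "emax_fit": emax,
        "species_after_pretreat": {
            "R": x_pre[0], "RA": x_pre[1], "RI": x_pre[2], "RI_tight": x_pre[3],
        },
    }


def emax_vs_pretreatment(
    params: TwoStepModelParams,
    pretreat_grid: Sequence[float],
    pretreat_time: float = 1.0,
    agonist_concs: Sequence[float] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0),
    readout_time: float = 2.0,
) -> list[dict]:
    """Emax as a function of antagonist pretreatment concentration."""
    grid = np.asarray(pretreat_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or not np.all(np.diff(grid) > 0):
        raise KineticsError("pretreat_grid must be positive and increasing")
    out = []
    for conc in grid:
        res = simulate_two_step_competition(
            params, float(conc), pretreat_time, agonist_concs, readout_time
        )
        out.append({"pretreat_conc": float(conc), "emax": res["emax"]})
    return out


# ---------------------------------------------------------------------------
# residence-time PK-PD occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancyTimecourse:
    times: np.ndarray        # h
    occupancy: np.ndarray    # bound fraction in [0, 1]
    plasma_conc: np.ndarray  # nM


def simulate_receptor_occupancy_pk(
    pk: dict,
    kon: float,
    koff: float,
    duration: float = 48.0,
    n_grid: int = 2001,
    occ0: float = 0.0,
) -> OccupancyTimecourse:
    """Receptor occupancy driven by decaying plasma exposure.

    Solves dOcc/dt = kon·C(t)·(1 − Occ) − koff·Occ with C(t) =
    c0·exp(−kel·t) by an exponential integrator: within each grid step
    the exposure is frozen at its midpoint value, for which the linear
    ODE has an exact unconditionally stable update.  The solution is
    exact for constant exposure and for C ≡ 0.
    """
    if kon < 0 or koff < 0:
        raise KineticsError("rates must be non-negative")
    c0, kel = float(pk["c0"]), float(pk["kel"])
    t = np.linspace(0.0, duration, n_grid)
    conc = c0 * np.exp(-kel * t)
    t_mid = 0.5 * (t[:-1] + t[1:])
    c_mid = c0 * np.exp(-kel * t_mid)
    occ = np.empty(n_grid)
    occ[0] = occ0
    for i in range(n_grid - 1):
        rate = kon * c_mid[i] + koff
        dt = t[i + 1] - t[i]
        if rate == 0.0:
            occ[i + 1] = occ[i]
            continue
        ss = kon * c_mid[i] / rate
        occ[i + 1] = ss + (occ[i] - ss) * math.exp(-rate * dt)
    occ = np.clip(occ, 0.0, 1.0)
    return OccupancyTimecourse(times=t, occupancy=occ, plasma_conc=conc)


def persistence_metric(tc: OccupancyTimecourse, threshold: float) -> float:
    """Total time (h) with occupancy ≥ threshold, linear between samples."""
    if not 0.0 < threshold < 1.0:
        raise KineticsError("threshold must lie in (0, 1)")
    t, y = tc.times, tc.occupancy
    total = 0.0
    for i in range(len(t) - 1):
        a, b = y[i] - threshold, y[i + 1] - threshold
        dt = t[i + 1] - t[i]
        if a >= 0 and b >= 0:
            total += dt
        elif a >= 0 or b >= 0:
            frac = abs(a) / (abs(a) + abs(b)) if (a - b) != 0 else 0.5
            total += dt * (frac if a >= 0 else 1.0 - frac)
    return total


def half_persistence_time(tc: OccupancyTimecourse) -> float:
    """Last time at which occupancy is at least half its peak value."""
    peak = tc.occupancy.max()
    if peak == 0:
        return 0.0
    above = np.where(tc.occupancy >= 0.5 * peak)[0]
    return float(tc.times[above[-1]]) if above.size else 0.0


def occupancy_terminal_half_life(tc: OccupancyTimecourse, tail_fraction: float = 0.25) -> float:
    """Terminal half-life of the occupancy decay (log-linear tail fit).

    Once exposure has decayed, occupancy falls at rate koff if dissociation
    is slower than elimination, and tracks the plasma half-life otherwise —
    the operational signature of residence-time-driven persistence.
    """
    n = len(tc.times)
    i0 = int((1.0 - tail_fraction) * n)
    t, y = tc.times[i0:], tc.occupancy[i0:]
    mask = y > 0
    if mask.sum() < 3:
        return math.inf
    slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
    return math.inf if slope >= 0 else LN2 / -float(slope)
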