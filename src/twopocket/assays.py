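"""Synthetic pharmacology assay datasets.

Three generators emulate the bench readouts used downstream: washout
recovery of the agonist response (one-phase exponential decay toward a
plateau), one-compartment IV-bolus plasma decay, and 4-parameter-logistic
concentration–response curves.  Each dataset records its generating
parameters and seed so fitters can be validated against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

LN2 = math.log(2.0)


class AssayError(ValueError):
    """Raised for invalid assay-generator parameters."""


@dataclass
class AssayDataset:
    kind: Literal["washout", "pk", "dose_response"]
    x: np.ndarray          # hours (time-courses) or nM (dose-response)
    y: np.ndarray          # % of control, or plasma concentration (arb. units)
    noise_sd: float
    seed: int
    true_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(self.x < 0):
            raise AssayError("x values must be non-negative")
        if self.kind in ("washout", "pk") and not np.all(np.diff(self.x) > 0):
            raise AssayError("time-course x must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise AssayError("y must be finite")


def one_phase_decay(t, t_half: float, initial: float, plateau: float):
    """y(t) = plateau + (initial − plateau)·exp(−ln2·t/t_half)."""
    t = np.asarray(t, dtype=float)
    return plateau + (initial - plateau) * np.exp(-LN2 * t / t_half)


def generate_washout_dataset(
    t_half: float,
    times: Sequence[float],
    plateau: float = 100.0,
    initial: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AssayDataset:
    """Washout time-course: response recovers from `initial` to `plateau`
    as the antagonist–receptor complex decays with half-life ``t_half``."""
    if t_half <= 0:
        raise AssayError("t_half must be positive")
    times = np.asarray(times, dtype=float)
    y = one_phase_decay(times, t_half, initial, plateau)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=times.shape)
    return AssayDataset(
        kind="washout",
        x=times,
        y=y,
        noise_sd=noise_sd,
        seed=seed,
        true_params={"t_half": t_half, "plateau": plateau, "initial": initial},
    )


def generate_pk_dataset(
    c0: float,
    t_half: float,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    multiplicative_noise: bool = False,
) -> AssayDataset:
    """One-compartment IV-bolus decay C(t) = c0·exp(−ln2·t/t_half)."""
    if t_half <= 0:
        raise AssayError("t_half must be positive")
    if c0 <= 0:
        raise AssayError("c0 must be positive")
    times = np.asarray(times, dtype=float)
    y = c0 * np.exp(-LN2 * times / t_half)
    if noise_sd > 0:
        eps = np.random.default_rng(seed).normal(0.0, noise_sd, size=times.shape)
        y = y * np.exp(eps) if multiplicative_noise else y + eps
    return AssayDataset(
        kind="pk",
        x=times,
        y=y,
        noise_sd=noise_sd,
        seed=seed,
        true_params={"c0": c0, "t_half": t_half, "multiplicative": multiplicative_noise},
    )


def four_pl(c, ic50: float, hill: float, top: float, bottom: float):
    """Descending 4PL: y = bottom + (top − bottom)/(1 + (c/ic50)^hill)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def generate_dose_response(
    ic50: float,
    hill: float,
    top: float,
    bottom: float,
    concs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AssayDataset:
    """Sigmoidal concentration–response dataset on a 4PL curve."""
    if ic50 <= 0:
        raise AssayError("ic50 must be positive")
    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0):
        raise AssayError("concentrations must be positive")
    y = four_pl(concs, ic50, hill, top, bottom)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=concs.shape)
    return AssayDataset(
        kind="dose_response",
        x=concs,
        y=y,
        noise_sd=noise_sd,
        seed=seed,
        true_params={"ic50": ic50, "hill": hill, "top": top, "bottom": bottom},
    )
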