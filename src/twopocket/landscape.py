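"""Coarse-grained two-pocket receptor landscape.

The receptor is reduced to a fixed 2-D frame containing two attractive
pockets: a *deep pocket* holding the docking-like pose (gate A) and a
shallower metastable *Met pocket* (gate B) next to a gatekeeper-residue
anchor on the dissociation path.  The ligand is a rigid pair of probe
beads — a CF3-like probe and a carboxylate-oxygen-like probe (O1) — so
that pocket-specific pose geometry (which probe end faces the gatekeeper
residue) is resolvable, as it is in the all-atom picture this toy
emulates.

Energies are in units of kBT and lengths in Å-like reduced units, so the
30-unit dissociation threshold used downstream mirrors a 30 Å cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator


class LandscapeError(ValueError):
    """Raised for invalid landscape specifications."""


def _rot(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _triangle_angle(a: float, b: float, opposite: float) -> float:
    """Angle (rad) between sides a and b in a triangle with the given opposite side."""
    cosg = (a * a + b * b - opposite * opposite) / (2.0 * a * b)
    if not -1.0 < cosg < 1.0:
        raise LandscapeError(
            f"no pose triangle with probe distances ({a}, {b}) and bond {opposite}"
        )
    return math.acos(cosg)


class LandscapeSpec(BaseModel):
    """Parameters of the two-pocket landscape.

    Pose-site distances default to values typical of the deep-pocket and
    Met-pocket binding modes (CF3-probe/gatekeeper ~9.4 vs ~6.3 units; O1
    probe ~10 vs ~13 units) so that simulated pose ensembles exercise the
    default gate-classification windows.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    dimensionality: int = 2
    deep_pocket_center: tuple[float, float] = (0.0, 0.0)
    deep_pocket_depth: float = Field(6.0, gt=0)   # kBT
    deep_pocket_width: float = Field(2.0, gt=0)
    met_anchor: tuple[float, float] = (7.0, 0.0)  # gatekeeper-residue site
    met_pocket_depth: float = Field(6.0, gt=0)    # WT value; scaled for mutant
    met_pocket_width: float = Field(3.0, gt=0)
    genotype: Literal["WT", "M124V"] = "WT"
    mutant_met_scale: float = Field(0.1, ge=0.0, le=0.3)
    bulk_radius: float = Field(30.0, gt=0)
    confinement_radius: float = Field(42.0, gt=0)
    wall_stiffness: float = Field(4.0, gt=0)      # kBT / unit^2
    bond_length: float = Field(7.0, ge=0)
    orientation_width: float = Field(6.0, gt=0)   # softness of the O1 half of each well
    # exit funnel: dissociation is confined to a corridor along the exit
    # axis (the toy analogue of the helix I/VII egress channel), bounded
    # by soft side walls at |perp| > funnel_half_width and a back wall
    # behind the deep pocket
    funnel_half_width: float = Field(4.5, gt=0)
    back_wall: float = -2.5                       # along-axis coordinate of the cavity floor
    # pocket pose geometry: probe-to-gatekeeper distances in each bound pose
    pose_a_cf3_dist: float = Field(9.42, gt=0)
    pose_a_o1_dist: float = Field(9.97, gt=0)
    pose_b_cf3_dist: float = Field(6.27, gt=0)
    pose_b_o1_dist: float = Field(12.95, gt=0)
    pose_b_angle_deg: float = 10.0  # tilt of the Met-pocket site off the exit axis

    @model_validator(mode="after")
    def _check(self) -> "LandscapeSpec":
        if self.dimensionality != 2:
            raise LandscapeError("only 2-D landscapes are supported")
        d = math.dist(self.deep_pocket_center, self.met_anchor)
        if self.bulk_radius <= d:
            raise LandscapeError("bulk_radius must exceed the pocket separation")
        if self.confinement_radius <= self.bulk_radius:
            raise LandscapeError("confinement_radius must exceed bulk_radius")
        return self

    @property
    def effective_met_depth(self) -> float:
        """Met-pocket depth after the genotype scaling (kBT)."""
        if self.genotype == "M124V":
            return self.met_pocket_depth * self.mutant_met_scale
        return self.met_pocket_depth


@dataclass(frozen=True)
class Ligand:
    """Rigid two-probe ligand state.

    ``probe_cf3`` is the hydrophobic-end probe (CF3-carbon analogue) and
    ``probe_o1`` the polar-end probe (carboxylic-acid O1 analogue).  A
    ``bond_length`` of 0 collapses both probes into a single point
    particle (used for 1-D/point-potential studies).
    """

    probe_cf3: np.ndarray
    probe_o1: np.ndarray
    bond_length: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_cf3", np.asarray(self.probe_cf3, dtype=float))
        object.__setattr__(self, "probe_o1", np.asarray(self.probe_o1, dtype=float))
        if self.probe_cf3.shape != self.probe_o1.shape:
            raise LandscapeError("probe coordinate shapes differ")
        sep = float(np.linalg.norm(self.probe_cf3 - self.probe_o1))
        if abs(sep - self.bond_length) > 1e-6 * max(1.0, self.bond_length):
            raise LandscapeError(
                f"probe separation {sep:.8f} violates bond length {self.bond_length}"
            )

    @property
    def com(self) -> np.ndarray:
        return 0.5 * (self.probe_cf3 + self.probe_o1)


def _pose_sites(spec: LandscapeSpec) -> dict[str, np.ndarray]:
    """Probe-bead anchor sites of the two bound poses.

    Pose A (deep pocket) sits on the buried side of the gatekeeper anchor;
    pose B (Met pocket) on the exit side, tilted off the exit axis so that
    the metastable pocket is a detour rather than a point on the straight
    dissociation line.  All four sites are placed exactly at the specified
    probe-to-gatekeeper distances, consistent with the rigid bond.
    """
    m = np.asarray(spec.met_anchor, dtype=float)
    d = np.asarray(spec.deep_pocket_center, dtype=float)
    axis = m - d
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise LandscapeError("met_anchor coincides with deep_pocket_center")
    e = axis / norm  # exit axis, pointing from deep pocket past the gatekeeper

    b = spec.bond_length
    ga = _triangle_angle(spec.pose_a_cf3_dist, spec.pose_a_o1_dist, b)
    cf3_a = m + spec.pose_a_cf3_dist * _rot(-e, +0.5 * ga)
    o1_a = m + spec.pose_a_o1_dist * _rot(-e, -0.5 * ga)

    gb = _triangle_angle(spec.pose_b_cf3_dist, spec.pose_b_o1_dist, b)
    th = math.radians(spec.pose_b_angle_deg)
    cf3_b = m + spec.pose_b_cf3_dist * _rot(e, th)
    o1_b = m + spec.pose_b_o1_dist * _rot(e, th - gb)
    return {"cf3_a": cf3_a, "o1_a": o1_a, "cf3_b": cf3_b, "o1_b": o1_b}


@dataclass
class TwoPocketPotential:
    """Potential energy of the two-pocket landscape.

    Two views are exposed.  Calling the object with a single position
    evaluates the *point* potential (Gaussian wells at the deep-pocket
    center and at the CF3-probe Met-pocket site, flat bulk, soft
    confinement wall) — this is the view used for 1-D cuts, Boltzmann
    checks and collective-variable-level reasoning.  ``ligand_energy`` /
    ``ligand_gradient`` evaluate the pose-anchored two-bead potential that
    drives the rigid-ligand dynamics: each pocket is a Gaussian well in
    the joint (CF3, O1) coordinates centred on that pocket's bound pose.
    """

    spec: LandscapeSpec
    sites: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.sites = _pose_sites(self.spec)
        s = self.spec
        self._dd = s.deep_pocket_depth
        self._dm = s.effective_met_depth
        self._wd2 = s.deep_pocket_width**2
        self._wm2 = s.met_pocket_width**2
        self._wo2 = s.orientation_width**2
        self._deep_center = np.asarray(s.deep_pocket_center, dtype=float)
        self._met_site = self.sites["cf3_b"]
        axis = np.asarray(s.met_anchor, dtype=float) - self._deep_center
        self._exit_axis = axis / np.linalg.norm(axis)
        self._exit_perp = np.array([-self._exit_axis[1], self._exit_axis[0]])

    # -- point view ---------------------------------------------------------
    def __call__(self, x) -> float:
        x = np.asarray(x, dtype=float)
        r2d = float(np.sum((x - self._deep_center) ** 2))
        r2m = float(np.sum((x - self._met_site) ** 2))
        u = -self._dd * math.exp(-r2d / (2 * self._wd2))
        if self._dm > 0:
            u -= self._dm * math.exp(-r2m / (2 * self._wm2))
        return u + self._wall(x)

    def point_gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        dd_vec = x - self._deep_center
        dm_vec = x - self._met_site
        g = (self._dd / self._wd2) * math.exp(
            -float(dd_vec @ dd_vec) / (2 * self._wd2)
        ) * dd_vec
        if self._dm > 0:
            g = g + (self._dm / self._wm2) * math.exp(
                -float(dm_vec @ dm_vec) / (2 * self._wm2)
            ) * dm_vec
        return g + self._wall_gradient(x)

    # -- two-bead view ------------------------------------------------------
    def ligand_energy(self, cf3, o1) -> float:
        cf3 = np.asarray(cf3, dtype=float)
        o1 = np.asarray(o1, dtype=float)
        ea = math.exp(
            -float(np.sum((cf3 - self.sites["cf3_a"]) ** 2)) / (2 * self._wd2)
            - float(np.sum((o1 - self.sites["o1_a"]) ** 2)) / (2 * self._wo2)
        )
        eb = math.exp(
            -float(np.sum((cf3 - self.sites["cf3_b"]) ** 2)) / (2 * self._wm2)
            - float(np.sum((o1 - self.sites["o1_b"]) ** 2)) / (2 * self._wo2)
        )
        return (
            -self._dd * ea - self._dm * eb + self._wall(cf3) + self._wall(o1)
        )

    def ligand_gradient(self, cf3, o1) -> tuple[np.ndarray, np.ndarray]:
        cf3 = np.asarray(cf3, dtype=float)
        o1 = np.asarray(o1, dtype=float)
        dca = cf3 - self.sites["cf3_a"]
        doa = o1 - self.sites["o1_a"]
        dcb = cf3 - self.sites["cf3_b"]
        dob = o1 - self.sites["o1_b"]
        ea = math.exp(
            -float(dca @ dca) / (2 * self._wd2) - float(doa @ doa) / (2 * self._wo2)
        )
        eb = math.exp(
            -float(dcb @ dcb) / (2 * self._wm2) - float(dob @ dob) / (2 * self._wo2)
        )
        g_c = (self._dd * ea / self._wd2) * dca + (self._dm * eb / self._wm2) * dcb
        g_o = (self._dd * ea / self._wo2) * doa + (self._dm * eb / self._wo2) * dob
        return g_c + self._wall_gradient(cf3), g_o + self._wall_gradient(o1)

    # -- confinement --------------------------------------------------------
    # Three soft harmonic walls act on every bead: a radial cap at
    # confinement_radius, funnel side walls at |perp| > funnel_half_width,
    # and a cavity back wall at along-axis coordinate < back_wall.  The
    # funnel confines dissociation to the exit corridor past the
    # gatekeeper anchor, mimicking the egress channel of the receptor.
    def _wall(self, x: np.ndarray) -> float:
        k = self.spec.wall_stiffness
        u = 0.0
        r = float(np.linalg.norm(x))
        exc = r - self.spec.confinement_radius
        if exc > 0:
            u += 0.5 * k * exc * exc
        rel = x - self._deep_center
        along = float(rel @ self._exit_axis)
        perp = float(rel @ self._exit_perp)
        exc_p = abs(perp) - self.spec.funnel_half_width
        if exc_p > 0:
            u += 0.5 * k * exc_p * exc_p
        exc_b = self.spec.back_wall - along
        if exc_b > 0:
            u += 0.5 * k * exc_b * exc_b
        return u

    def _wall_gradient(self, x: np.ndarray) -> np.ndarray:
        k = self.spec.wall_stiffness
        g = np.zeros_like(x)
        r = float(np.linalg.norm(x))
        exc = r - self.spec.confinement_radius
        if exc > 0 and r > 0:
            g = g + (k * exc / r) * x
        rel = x - self._deep_center
        along = float(rel @ self._exit_axis)
        perp = float(rel @ self._exit_perp)
        exc_p = abs(perp) - self.spec.funnel_half_width
        if exc_p > 0:
            g = g + (k * exc_p * math.copysign(1.0, perp)) * self._exit_perp
        exc_b = self.spec.back_wall - along
        if exc_b > 0:
            g = g - (k * exc_b) * self._exit_axis
        return g

    # -- convenience --------------------------------------------------------
    def bound_pose(self, pocket: Literal["deep", "met"] = "deep") -> Ligand:
        """The ligand state at the bottom of the requested pocket."""
        if pocket == "deep":
            c, o = self.sites["cf3_a"], self.sites["o1_a"]
        else:
            c, o = self.sites["cf3_b"], self.sites["o1_b"]
        sep = float(np.linalg.norm(c - o))
        return Ligand(probe_cf3=c, probe_o1=o, bond_length=sep)

    @property
    def binding_site_anchors(self) -> list[np.ndarray]:
        """Binding-site anchor points (deep-pocket center and gatekeeper
        residue), whose centroid defines the distance CV.  Placing the
        centroid on the exit axis inside the cavity keeps the CV close to
        monotone along the dissociation corridor."""
        return [self._deep_center.copy(), np.asarray(self.spec.met_anchor, dtype=float)]


def build_landscape(spec: LandscapeSpec) -> TwoPocketPotential:
    """Construct the two-pocket potential from a validated spec."""
    if not isinstance(spec, LandscapeSpec):
        raise LandscapeError("spec must be a LandscapeSpec")
    return TwoPocketPotential(spec=spec)


class PointField:
    """Adapter giving an arbitrary scalar potential the two-bead interface.

    The ligand energy is the sum of the point potential over the probes
    (evaluated once for a point-particle ligand with bond length 0).
    Gradients default to centred finite differences unless an analytic
    gradient is supplied; used mainly for reference potentials in tests
    and for 1-D free-energy studies.
    """

    def __init__(self, u, grad=None, fd_step: float = 1e-6):
        self._u = u
        self._grad = grad
        self._h = fd_step

    def __call__(self, x) -> float:
        return float(self._u(np.asarray(x, dtype=float)))

    def point_gradient(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self._grad is not None:
            return np.asarray(self._grad(x), dtype=float)
        g = np.empty_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += self._h
            xm[i] -= self._h
            g[i] = (self._u(xp) - self._u(xm)) / (2 * self._h)
        return g

    def ligand_energy(self, cf3, o1) -> float:
        return self(cf3) + self(o1)

    def ligand_gradient(self, cf3, o1) -> tuple[np.ndarray, np.ndarray]:
        return self.point_gradient(cf3), self.point_gradient(o1)


def as_two_bead_potential(u):
    """Coerce a potential to the two-bead interface expected by the integrator."""
    if hasattr(u, "ligand_gradient") and hasattr(u, "ligand_energy"):
        return u
    if callable(u):
        return PointField(u)
    raise LandscapeError("potential must be callable or expose ligand_gradient")
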