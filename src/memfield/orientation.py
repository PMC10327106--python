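"""Rigid-body orientation search: depth, tilt and spin of a helix in the slab.

The peptide is treated as rigid; an orientation state is (z, tilt, spin):
depth of the helix-axis midpoint along the membrane normal, tilt of the
helix axis away from the normal (folded into [0, 90] by axis symmetry), and
spin about the helix axis.  The search is an exhaustive grid scan followed
by a deterministic pattern-search polish, with ties broken by (|z|, tilt,
spin).

For the membrane composite score a vectorized evaluator exploits rigidity:
intra-structure pair distances are orientation-independent, so only
per-atom depths (hence hydration fractions and the lipid potential) change
between states.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .calibration import WeightSet, F23_WEIGHTS
from .constants import EV_TO_KCAL
from .electrostatics import bonded_exclusions
from .membrane import MembraneFrame
from .scoring import MembraneSystem

__all__ = ["OrientationState", "helix_axis", "place", "tilt_of",
           "find_min_orientation", "OrientationScorer"]


@dataclass
class OrientationState:
    z: float = 0.0          # Å, helix-axis midpoint depth
    tilt: float = 0.0       # degrees in [0, 90]
    spin: float = 0.0       # degrees in [0, 360)

    def __post_init__(self):
        if not 0.0 <= self.tilt <= 90.0:
            raise ValueError("tilt must lie in [0, 90] degrees")
        self.spin = float(self.spin) % 360.0


class GeometryError(ValueError):
    pass


def helix_axis(structure) -> np.ndarray:
    """Principal axis of the CA trace, oriented N- to C-terminus (unit)."""
    ca = structure.ca_coords()
    if len(ca) < 4:
        raise GeometryError("need at least 4 CA atoms to define a helix axis")
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _membrane_basis(frame: MembraneFrame):
    """Orthonormal (u, v, n) with n the membrane normal."""
    n = frame.normal
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, n)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v, n


def _rot(axis, angle_deg):
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.deg2rad(angle_deg) * np.asarray(axis)).as_matrix()


def canonical_coords(structure) -> np.ndarray:
    """Coordinates with the CA centroid at the origin and helix axis on +z."""
    from scipy.spatial.transform import Rotation

    axis = helix_axis(structure)
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    ca = structure.ca_coords()
    return (structure.coord - ca.mean(axis=0)) @ rot.as_matrix().T


def place(structure, state: OrientationState, frame: MembraneFrame):
    """Rigid placement of the structure at an orientation state.

    The structure is first moved to its canonical frame (axis along +z, CA
    centroid at origin), spun about its axis, tilted away from the membrane
    normal, and translated to depth ``state.z`` along the normal.  Internal
    geometry is untouched.
    """
    xyz = canonical_coords(structure)
    u, v, n = _membrane_basis(frame)
    basis = np.stack([u, v, n], axis=1)       # maps local z -> normal
    R = basis @ _rot([0.0, 1.0, 0.0], state.tilt) @ _rot([0.0, 0.0, 1.0], state.spin)
    out = structure.copy()
    out.coord = xyz @ R.T + frame.center + state.z * n
    return out


def tilt_of(structure, frame: MembraneFrame) -> float:
    """Tilt angle in degrees: arccos |helix axis . membrane normal|."""
    axis = helix_axis(structure)
    c = abs(float(np.dot(axis, frame.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ------------------------------------------------------------ fast evaluator
class OrientationScorer:
    """Vectorized composite-score evaluator over orientation states.

    Precomputes everything orientation-independent: canonical coordinates,
    per-atom transfer energies and charges, the non-bonded pair list within
    the dielectric cutoff with per-pair solution/membrane dielectrics at
    the (fixed) pair distances.
    """

    def __init__(self, structure, system: MembraneSystem,
                 weights: WeightSet = F23_WEIGHTS):
        self.system = system
        self.weights = weights
        self.xyz = canonical_coords(structure)
        self.dg = structure.dg_wl.astype(float)
        self.q = structure.charge.astype(float)
        diel = system.dielectric
        tree = cKDTree(structure.coord)
        pairs = tree.query_pairs(diel.r_max, output_type="ndarray")
        if len(pairs):
            excl = bonded_exclusions(structure)
            keep = np.array([(min(i, j), max(i, j)) not in excl
                             for i, j in pairs], dtype=bool)
            pairs = pairs[keep]
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            r = np.linalg.norm(structure.coord[i] - structure.coord[j], axis=1)
            self.pair_i, self.pair_j = i, j
            self.pair_k = diel.c0 * self.q[i] * self.q[j] * (1.0 / r - 1.0 / diel.r_max)
            self.pair_eps_s = diel.eps_sol(r)
            self.pair_eps_m = diel.eps_memb(r)
        else:
            self.pair_i = self.pair_j = np.zeros(0, dtype=int)
            self.pair_k = self.pair_eps_s = self.pair_eps_m = np.zeros(0)
        # dense lookup of the lipid potential for fast interpolation
        self._psi_z = np.linspace(-60.0, 60.0, 2401)
        self._psi_v = system.profile.evaluate(self._psi_z)

    def _axis_depth_coeff(self, tilt, spin):
        """Per-atom depth offsets at z=0 for a given (tilt, spin)."""
        R = _rot([0.0, 1.0, 0.0], tilt) @ _rot([0.0, 0.0, 1.0], spin)
        return (self.xyz @ R.T)[:, 2]

    def component_energies(self, z_values, tilt, spin):
        """Arrays of (transfer, lipid, excess-elec) energies over depths."""
        z_values = np.atleast_1d(np.asarray(z_values, dtype=float))
        c = self._axis_depth_coeff(tilt, spin)
        depths = z_values[:, None] + c[None, :]
        frame = self.system.frame
        t2, s = frame.half_thickness, frame.steepness
        f = 1.0 / (1.0 + np.exp(-(np.abs(depths) - t2) / s))
        e_tr = (1.0 - f) @ self.dg
        e_lip = (np.interp(depths, self._psi_z, self._psi_v) * self.q
                 ).sum(axis=1) * EV_TO_KCAL
        if len(self.pair_k):
            fp = np.sqrt(f[:, self.pair_i] * f[:, self.pair_j])
            eps_mix = fp * self.pair_eps_s + (1.0 - fp) * self.pair_eps_m
            e_exc = (self.pair_k * (1.0 / eps_mix - 1.0 / self.pair_eps_s)
                     ).sum(axis=1)
        else:
            e_exc = np.zeros_like(e_tr)
        return e_tr, e_lip, e_exc

    def energies(self, z_values, tilt, spin):
        e_tr, e_lip, e_exc = self.component_energies(z_values, tilt, spin)
        w = self.weights
        return w.w_wl * e_tr + w.w_lipid * e_lip + w.w_dielec * e_exc

    def __call__(self, state: OrientationState) -> float:
        return float(self.energies([state.z], state.tilt, state.spin)[0])


# -------------------------------------------------------------------- search
def find_min_orientation(structure=None, score: Callable = None,
                         system: MembraneSystem = None,
                         weights: WeightSet = F23_WEIGHTS,
                         z_range=(-40.0, 40.0), z_step: float = 1.0,
                         tilt_step: float = 2.0, spin_step: float = 10.0,
                         refine: bool = True, refine_z: float = 0.25,
                         refine_angle: float = 0.5,
                         return_landscape: bool = False):
    """Exhaustive grid scan plus local polish of the orientation energy.

    Either pass ``score`` (any deterministic callable of an
    :class:`OrientationState`; an :class:`OrientationScorer` is used
    vectorized) or pass ``structure`` + ``system`` to build the composite
    scorer.  Ties are broken by lower |z|, then tilt, then spin.  Returns
    (OrientationState, energy) or (state, energy, landscape DataFrame).
    """
    if score is None:
        if structure is None or system is None:
            raise ValueError("pass either a score callable or structure+system")
        score = OrientationScorer(structure, system, weights)

    zs = np.arange(z_range[0], z_range[1] + 1e-9, z_step)
    tilts = np.arange(0.0, 90.0 + 1e-9, tilt_step)
    spins = np.arange(0.0, 360.0, spin_step)

    rows = []
    best = None     # (energy, (|z|, tilt, spin) tie key, z)
    for tilt in tilts:
        for spin in spins:
            if isinstance(score, OrientationScorer):
                e = score.energies(zs, tilt, spin)
            else:
                e = np.array([score(OrientationState(z, tilt, spin)) for z in zs])
            if return_landscape:
                rows.append(pd.DataFrame({"z": zs, "tilt": tilt, "spin": spin,
                                          "energy": e}))
            for t in np.flatnonzero(e <= e.min() + 1e-12):
                cand = (float(e[t]), (abs(float(zs[t])), tilt, spin),
                        float(zs[t]))
                if (best is None or cand[0] < best[0] - 1e-12
                        or (cand[0] <= best[0] + 1e-12 and cand[1] < best[1])):
                    best = cand
    e_best = best[0]
    state = OrientationState(best[2], best[1][1], best[1][2])

    if refine:
        state, e_best = _pattern_polish(score, state, e_best,
                                        refine_z, refine_angle)
    state = OrientationState(state.z, state.tilt, state.spin)
    if return_landscape:
        return state, e_best, pd.concat(rows, ignore_index=True)
    return state, e_best


def _pattern_polish(score, state, energy, dz, dang, max_iter=60):
    """Coordinate pattern search; never accepts a worse energy."""
    z, tilt, spin = state.z, state.tilt, state.spin
    step_z, step_t, step_s = dz * 4, dang * 4, dang * 8
    for _ in range(max_iter):
        improved = False
        for (az, at, asp) in ((step_z, 0, 0), (-step_z, 0, 0),
                              (0, step_t, 0), (0, -step_t, 0),
                              (0, 0, step_s), (0, 0, -step_s)):
            t_new = min(90.0, max(0.0, tilt + at))
            cand = OrientationState(z + az, t_new, (spin + asp) % 360.0)
            e = score(cand) if not isinstance(score, OrientationScorer) \
                else float(score.energies([cand.z], cand.tilt, cand.spin)[0])
            if e < energy - 1e-15:
                z, tilt, spin, energy = cand.z, cand.tilt, cand.spin, e
                improved = True
        if not improved:
            if step_z <= dz and step_t <= dang and step_s <= dang:
                break
            step_z = max(dz, step_z / 2)
            step_t = max(dang, step_t / 2)
            step_s = max(dang, step_s / 2)
    return OrientationState(z, tilt, spin), energy
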