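"""Membrane electrostatic energy terms.

Two terms beyond the transfer energy:

* the lipid-potential energy: sum over charged atoms of the mean-field
  bilayer potential difference at the atom's depth times its charge;
* the excess dielectric Coulomb energy: a truncated-Coulomb pair term with a
  hydration-mixed, distance-dependent sigmoidal dielectric, minus the same
  term evaluated with the aqueous dielectric, isolating what the membrane
  environment adds.

Both pair energies vanish identically beyond the cutoff ``r_max``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import C0, R_MAX, EV_TO_KCAL
from .membrane import HydrationModel, MembraneFrame, depth, hydration_fraction, pair_hydration

__all__ = [
    "DielectricModel", "sigmoid_dielectric", "mixed_dielectric",
    "pair_energy_membrane", "excess_pair_energy", "structure_excess_elec",
    "lipid_potential_energy", "infer_bonds", "bonded_exclusions",
]


class SingularPairError(ValueError):
    pass


@dataclass
class DielectricModel:
    """Distance/hydration-dependent dielectric parameters.

    Solution sigmoid runs from the protein core (6) to the aqueous surface
    (80); the membrane sigmoid from 3 to 10.  ``r_mid``/``steepness`` shape
    the common sigmoidal distance dependence (chosen so the solution
    dielectric is mid-range near the cutoff); both are configurable.
    """

    eps_core_sol: float = 6.0
    eps_surf_sol: float = 80.0
    eps_core_memb: float = 3.0
    eps_surf_memb: float = 10.0
    r_mid: float = 5.5
    steepness: float = 0.6
    r_max: float = R_MAX
    c0: float = C0

    def __post_init__(self):
        if min(self.eps_core_sol, self.eps_surf_sol,
               self.eps_core_memb, self.eps_surf_memb) <= 0:
            raise ValueError("dielectric constants must be positive")
        if (self.eps_core_sol >= self.eps_surf_sol
                or self.eps_core_memb >= self.eps_surf_memb):
            raise ValueError("core dielectric must be below surface dielectric")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    def eps_sol(self, r):
        return sigmoid_dielectric(r, self.eps_core_sol, self.eps_surf_sol,
                                  self.r_mid, self.steepness)

    def eps_memb(self, r):
        return sigmoid_dielectric(r, self.eps_core_memb, self.eps_surf_memb,
                                  self.r_mid, self.steepness)


def sigmoid_dielectric(r, eps_core, eps_surf, r_mid=5.5, steepness=0.6):
    """Smooth monotone dielectric: eps_core at contact -> eps_surf at range."""
    r = np.asarray(r, dtype=float)
    arg = np.clip(-(r - r_mid) / steepness, -60.0, 60.0)
    out = eps_core + (eps_surf - eps_core) / (1.0 + np.exp(arg))
    return out if out.ndim else float(out)


def mixed_dielectric(r, f_pair, model: DielectricModel | None = None):
    """Linear hydration mixture: f*eps_sol(r) + (1-f)*eps_memb(r)."""
    model = model or DielectricModel()
    f = np.asarray(f_pair, dtype=float)
    out = f * model.eps_sol(r) + (1.0 - f) * model.eps_memb(r)
    return out if out.ndim else float(out)


def _truncated_coulomb(qi, qj, r, model):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise SingularPairError("pair distance must be positive")
    geom = np.where(r < model.r_max, 1.0 / r - 1.0 / model.r_max, 0.0)
    return model.c0 * np.asarray(qi) * np.asarray(qj) * geom


def pair_energy_membrane(qi, qj, r, f_pair, model: DielectricModel | None = None):
    """Truncated Coulomb energy with the mixed dielectric, kcal/mol.

    Exactly zero for r >= r_max (5.5 Å by default).
    """
    model = model or DielectricModel()
    base = _truncated_coulomb(qi, qj, r, model)
    out = base / mixed_dielectric(r, f_pair, model)
    return out if np.ndim(out) else float(out)


def excess_pair_energy(qi, qj, r, f_pair, model: DielectricModel | None = None):
    """Membrane excess: mixed-dielectric energy minus the aqueous-dielectric one.

    Zero when the pair is fully hydrated (f_pair = 1) and for r >= r_max.
    """
    model = model or DielectricModel()
    base = _truncated_coulomb(qi, qj, r, model)
    r_arr = np.asarray(r, dtype=float)
    out = base * (1.0 / mixed_dielectric(r_arr, f_pair, model)
                  - 1.0 / model.eps_sol(r_arr))
    return out if np.ndim(out) else float(out)


# ----------------------------------------------------------------- structure
_BOND_CUTOFF = 1.95         # Å, heavy-atom covalent bond detection
_BOND_CUTOFF_S = 2.25       # Å, bonds involving sulfur


def infer_bonds(structure) -> list[tuple[int, int]]:
    """Distance-based covalent bond list over heavy atoms (same chain only)."""
    coord = structure.coord
    elements = structure.element
    tree = cKDTree(coord)
    pairs = tree.query_pairs(_BOND_CUTOFF_S, output_type="ndarray")
    bonds = []
    for i, j in pairs:
        if structure.chain_id[i] != structure.chain_id[j]:
            continue
        cut = _BOND_CUTOFF_S if "S" in (elements[i], elements[j]) else _BOND_CUTOFF
        if np.linalg.norm(coord[i] - coord[j]) <= cut:
            bonds.append((int(i), int(j)))
    return bonds


def bonded_exclusions(structure, max_bond_separation: int = 2) -> set:
    """Atom pairs within ``max_bond_separation`` covalent bonds (1-2 and 1-3)."""
    adj: dict[int, set] = {}
    for i, j in infer_bonds(structure):
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excluded = set()
    for i in adj:
        frontier = {i}
        seen = {i}
        for _ in range(max_bond_separation):
            frontier = {k for f in frontier for k in adj.get(f, ())} - seen
            seen |= frontier
        for j in seen - {i}:
            excluded.add((min(i, j), max(i, j)))
    return excluded


def _per_residue(structure, atom_values) -> pd.Series:
    ordinal = structure.residue_ordinal
    s = pd.Series(atom_values).groupby(ordinal).sum()
    s.index.name = "residue"
    return s


def structure_excess_elec(structure, model: HydrationModel,
                          diel: DielectricModel | None = None,
                          exclude_bonded: bool = True):
    """Excess dielectric Coulomb energy summed over intra-structure pairs.

    Pairs within r_max are enumerated (KD-tree), 1-2 and 1-3 bonded pairs
    excluded, pair hydration taken as the geometric mean of the two atomic
    hydration fractions.  Returns (per-residue Series, total); each pair's
    energy is split evenly between its two residues.
    """
    diel = diel or DielectricModel()
    n = structure.n_atoms
    per_atom = np.zeros(n)
    if n >= 2 and np.any(structure.charge != 0):
        tree = cKDTree(structure.coord)
        pairs = tree.query_pairs(diel.r_max, output_type="ndarray")
        if len(pairs):
            if exclude_bonded:
                excl = bonded_exclusions(structure)
                keep = np.array([(min(i, j), max(i, j)) not in excl
                                 for i, j in pairs])
                pairs = pairs[keep]
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            r = np.linalg.norm(structure.coord[i] - structure.coord[j], axis=1)
            f = hydration_fraction(model, structure.coord)
            fp = pair_hydration(f[i], f[j])
            e = excess_pair_energy(structure.charge[i], structure.charge[j],
                                   r, fp, diel)
            np.add.at(per_atom, i, 0.5 * e)
            np.add.at(per_atom, j, 0.5 * e)
    series = _per_residue(structure, per_atom)
    return series, float(series.sum())


def lipid_potential_energy(structure, lp, frame: MembraneFrame):
    """Mean-field lipid-potential energy: sum q * dPsi(z) * 23.0609 kcal/(mol e V).

    Returns (per-residue Series, total).
    """
    z = depth(frame, structure.coord)
    e = structure.charge * lp.evaluate(z) * EV_TO_KCAL
    series = _per_residue(structure, e)
    return series, float(series.sum())
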