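"""Membrane frame, per-atom depth, hydration/pore fractions and region labels.

The membrane is a rigid slab: a center point, a unit normal and a
hydrophobic half-thickness t/2.  Hydration ``f_hyd`` is a logistic function
of |depth| with midpoint t/2 and steepness ``s`` (0 at the bilayer center,
0.5 at the hydrophobic boundary, 1 in bulk water).  An optional water-filled
pore (axis + radius) raises hydration inside the slab; the pore and depth
contributions combine by maximum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Nominal hydrophobic half-thicknesses (Å) per lipid type; user-overridable.
HALF_THICKNESS = {
    "DLPC": 10.8, "DLPE": 11.2, "DLPG": 10.8,
    "DPPC": 14.4, "DOPC": 13.6, "POPC": 13.7,
}


@dataclass
class MembraneFrame:
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    half_thickness: float = 10.8
    steepness: float = 2.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(self.normal)
        if norm == 0:
            raise ValueError("membrane normal must be non-zero")
        self.normal = self.normal / norm
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")

    @classmethod
    def for_lipid(cls, lipid_name: str, **kw) -> "MembraneFrame":
        return cls(half_thickness=HALF_THICKNESS[lipid_name], **kw)


def depth(frame: MembraneFrame, position: np.ndarray) -> np.ndarray:
    """Signed projection of position(s) onto the membrane normal, Å."""
    rel = np.asarray(position, dtype=float) - frame.center
    return rel @ frame.normal


@dataclass
class HydrationModel:
    """Maps positions to hydration fraction f_hyd and pore fraction f_pore."""

    frame: MembraneFrame
    pore_axis_point: Optional[np.ndarray] = None   # a point on the pore axis
    pore_radius: float = 0.0
    pore_steepness: float = 2.0

    def __post_init__(self):
        if self.pore_axis_point is not None:
            self.pore_axis_point = np.asarray(self.pore_axis_point, dtype=float)

    @property
    def has_pore(self) -> bool:
        return self.pore_axis_point is not None and self.pore_radius > 0

    def _depth_sigmoid(self, z):
        t2, s = self.frame.half_thickness, self.frame.steepness
        return 1.0 / (1.0 + np.exp(-(np.abs(z) - t2) / s))

    def _radial_distance(self, position):
        rel = np.asarray(position, dtype=float) - self.pore_axis_point
        n = self.frame.normal
        rel_perp = rel - np.outer(rel @ n, n).reshape(rel.shape)
        return np.linalg.norm(rel_perp, axis=-1)


def hydration_fraction(model: HydrationModel, position: np.ndarray) -> np.ndarray:
    """f_hyd in [0, 1]: ~0 lipid-exposed at the core, ~1 in bulk water.

    Logistic in |depth| with midpoint at the hydrophobic half-thickness;
    inside the slab a water-filled pore raises the value (max-combination).
    """
    z = depth(model.frame, position)
    f = model._depth_sigmoid(z)
    if model.has_pore:
        f = np.maximum(f, _pore_sigmoid(model, position))
    return f


def _pore_sigmoid(model: HydrationModel, position) -> np.ndarray:
    d = model._radial_distance(position)
    return 1.0 / (1.0 + np.exp(-(model.pore_radius - d) / model.pore_steepness))


def pair_hydration(fi, fj):
    """Geometric mean of two hydration fractions."""
    return np.sqrt(np.asarray(fi, dtype=float) * np.asarray(fj, dtype=float))


def pore_fraction(model: HydrationModel, position: np.ndarray) -> np.ndarray:
    """f_pore in [0, 1]: exposure to a water-filled pore.

    Outside the slab (|depth| > half-thickness) the atom sees bulk water and
    f_pore = 1.  Inside, it is a sigmoid of (pore radius - radial distance to
    the pore axis), or 0 when no pore is defined.
    """
    z = depth(model.frame, position)
    outside = np.abs(z) > model.frame.half_thickness
    if model.has_pore:
        inner = _pore_sigmoid(model, position)
    else:
        inner = np.zeros_like(np.asarray(z, dtype=float))
    return np.where(outside, 1.0, inner)


def classify_region(f_hyd, f_pore):
    """Label positions as 'lipid' / 'interface' / 'aqueous'.

    Thresholds: lipid f_hyd < 0.25, interface f_hyd in [0.25, 0.75], aqueous
    f_hyd > 0.75 -- all conditioned on f_pore <= 0.5; any position with
    f_pore > 0.5 sits in a water-filled pore and is aqueous.  Total on
    [0,1]^2.
    """
    f_hyd = np.asarray(f_hyd, dtype=float)
    f_pore = np.asarray(f_pore, dtype=float)
    out = np.where(f_hyd < 0.25, "lipid",
                   np.where(f_hyd > 0.75, "aqueous", "interface")).astype(object)
    out = np.where(f_pore > 0.5, "aqueous", out)
    if out.ndim == 0:
        return str(out)
    return out


def hydration_table(structure, model: HydrationModel):
    """Per-atom audit table: depth, f_hyd, f_pore, region (pandas DataFrame)."""
    import pandas as pd

    z = depth(model.frame, structure.coord)
    fh = hydration_fraction(model, structure.coord)
    fp = pore_fraction(model, structure.coord)
    return pd.DataFrame({
        "chain": structure.chain_id, "res_id": structure.res_id,
        "res_name": structure.res_name, "atom_name": structure.atom_name,
        "depth": z, "f_hyd": fh, "f_pore": fp,
        "region": classify_region(fh, fp),
    })
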