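"""The reduced composite membrane score and its per-residue breakdown.

The composite combines three membrane terms by non-negative weights:

    E = w_wl * dG_transfer + w_lipid * dG_lipid + w_dielec * dE_excess_elec

(+ an optional user-supplied base-score callback for the soluble-protein
part, which this package deliberately does not reimplement).  The transfer
term is hydration-complement weighted: each atom contributes
(1 - f_hyd) * dG_wl_atom, which vanishes in bulk water and is the full
transfer energy at the bilayer core.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .calibration import WeightSet, F23_WEIGHTS, F19_WEIGHTS
from .electrostatics import (DielectricModel, lipid_potential_energy,
                             structure_excess_elec)
from .lipid_potential import LipidPotentialProfile, load_profile_library
from .membrane import HydrationModel, MembraneFrame, HALF_THICKNESS

__all__ = ["EnergyBreakdown", "MembraneSystem", "transfer_energy", "score"]


@dataclass
class MembraneSystem:
    """Bundle of membrane frame, hydration model, lipid profile and dielectric."""

    frame: MembraneFrame
    hydration: HydrationModel
    profile: LipidPotentialProfile
    dielectric: DielectricModel = field(default_factory=DielectricModel)

    @classmethod
    def for_lipid(cls, lipid_name: str, profile_library=None,
                  pore_axis_point=None, pore_radius: float = 0.0,
                  **frame_kw) -> "MembraneSystem":
        """Build a system for a named lipid from the packaged profile library."""
        library = profile_library if profile_library is not None \
            else load_profile_library()
        if lipid_name not in library:
            raise KeyError(f"no lipid potential profile for {lipid_name!r}; "
                           f"available: {sorted(library)}")
        frame = MembraneFrame(half_thickness=HALF_THICKNESS[lipid_name],
                              **frame_kw)
        hydration = HydrationModel(frame, pore_axis_point=pore_axis_point,
                                   pore_radius=pore_radius)
        return cls(frame, hydration, library[lipid_name])


@dataclass
class EnergyBreakdown:
    """Per-residue, per-term energies plus the weighted total (kcal/mol)."""

    table: pd.DataFrame            # columns: E_transfer, E_lipid, E_excess_elec, weighted_total
    weights: WeightSet
    metadata: dict = field(default_factory=dict)

    ENERGY_COLUMNS = ("E_transfer", "E_lipid", "E_excess_elec", "weighted_total")

    @property
    def totals(self) -> pd.Series:
        return self.table[list(self.ENERGY_COLUMNS)].sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.table["weighted_total"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6f")


def transfer_energy(structure, model: HydrationModel):
    """Water-to-bilayer transfer energy, hydration-complement weighted.

    Returns (per-residue Series, total).
    """
    from .membrane import hydration_fraction

    f = hydration_fraction(model, structure.coord)
    per_atom = (1.0 - f) * structure.dg_wl
    s = pd.Series(per_atom).groupby(structure.residue_ordinal).sum()
    s.index.name = "residue"
    return s, float(s.sum())


def score(structure, system: MembraneSystem,
          weights: WeightSet = F23_WEIGHTS,
          base_score: Optional[Callable] = None) -> EnergyBreakdown:
    """Evaluate the composite membrane score of a placed structure.

    ``base_score``, if given, is called with the structure and must return a
    scalar added to the reported total (the soluble-protein score hook); it
    does not enter the per-residue membrane table.
    """
    e_tr, _ = transfer_energy(structure, system.hydration)
    e_lip, _ = lipid_potential_energy(structure, system.profile, system.frame)
    e_exc, _ = structure_excess_elec(structure, system.hydration,
                                     system.dielectric)
    table = pd.DataFrame({"E_transfer": e_tr, "E_lipid": e_lip,
                          "E_excess_elec": e_exc})
    # annotate rows with chain / residue id for export
    ordinal = structure.residue_ordinal
    first = np.searchsorted(ordinal, np.arange(structure.n_residues))
    table.insert(0, "chain", [structure.chain_id[i] for i in first])
    table.insert(1, "res_id", [int(structure.res_id[i]) for i in first])
    table["weighted_total"] = (weights.w_wl * table["E_transfer"]
                               + weights.w_lipid * table["E_lipid"]
                               + weights.w_dielec * table["E_excess_elec"])
    meta = {"structure": structure.source,
            "lipid_name": system.profile.lipid_name}
    breakdown = EnergyBreakdown(table, weights, meta)
    if base_score is not None:
        breakdown.metadata["base_score"] = float(base_score(structure))
    return breakdown


def total_score(structure, system, weights=F23_WEIGHTS, base_score=None) -> float:
    b = score(structure, system, weights, base_score)
    return b.total + b.metadata.get("base_score", 0.0)
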