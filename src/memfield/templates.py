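"""Idealized residue templates for side-chain grafting.

Templates carry fixed Cartesian heavy-atom geometry for each residue type at
its default conformation, taken from the Chemical Component Dictionary
entries bundled with biotite.  Grafting onto a backbone is done by
superimposing the template (N, CA, C) frame; side-chain torsions are the CCD
defaults (no repacking).
"""
from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

#: Atoms considered backbone for the fixed-backbone contract.
BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

#: Variants sharing parent heavy-atom geometry.
_GEOMETRY_PARENT = {"ASH": "ASP", "GLH": "GLU"}


@dataclass(frozen=True)
class ResidueTemplate:
    residue_name: str
    backbone_coord: np.ndarray   # (3, 3): N, CA, C
    side_names: tuple            # side-chain heavy atoms (incl. CB)
    side_coord: np.ndarray       # (n_side, 3)

    def min_interatomic_distance(self) -> float:
        xyz = np.vstack([self.backbone_coord, self.side_coord])
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        return float(d[np.triu_indices(len(xyz), 1)].min()) if len(xyz) > 1 else np.inf


@functools.lru_cache(maxsize=None)
def residue_template(res3: str) -> ResidueTemplate:
    """Idealized template for a 3-letter residue code (incl. ASH/GLH variants)."""
    from biotite.structure.info import residue as ccd_residue

    parent = _GEOMETRY_PARENT.get(res3, res3)
    try:
        arr = ccd_residue(parent)
    except Exception as exc:  # noqa: BLE001 - normalized error type
        raise KeyError(f"no idealized template for residue {res3!r}") from exc
    heavy = arr[arr.element != "H"]
    names = [str(n) for n in heavy.atom_name]
    coord = np.asarray(heavy.coord, dtype=float)
    pos = {n: coord[i] for i, n in enumerate(names)}
    for nm in ("N", "CA", "C"):
        if nm not in pos:
            raise KeyError(f"template {res3!r} lacks backbone atom {nm}")
    side = [(n, pos[n]) for n in names if n not in BACKBONE_ATOMS]
    side_names = tuple(n for n, _ in side)
    side_coord = (np.array([xyz for _, xyz in side])
                  if side else np.zeros((0, 3)))
    return ResidueTemplate(res3, np.array([pos["N"], pos["CA"], pos["C"]]),
                           side_names, side_coord)
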