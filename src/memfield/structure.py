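"""Atom-level peptide/protein representation.

A :class:`PeptideStructure` is a flat, array-backed container (one entry per
atom) carrying coordinates, united heavy-atom partial charges, atom-type
tokens and per-atom water-to-bilayer transfer energies.  Structures come from
PDB files (:func:`read_pdb`) or from the ideal-helix builder
(:func:`build_ideal_helix`), which places backbones by internal-coordinate
chaining at requested (phi, psi) and grafts side chains from idealized
residue templates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple

import numpy as np

from . import params as _params
from .templates import residue_template, BACKBONE_ATOMS

__all__ = [
    "AtomRecord", "PeptideStructure", "read_pdb", "write_pdb",
    "build_ideal_helix", "sequence_generators", "mutate_residue",
    "backbone_dihedrals",
]


class AtomRecord(NamedTuple):
    atom_name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    partial_charge: float
    atom_type: str
    dG_wl_atom: float


@dataclass
class PeptideStructure:
    """Ordered atom arrays plus provenance; the object every energy term scores."""

    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    coord: np.ndarray
    charge: np.ndarray = None
    atom_type: np.ndarray = None
    dg_wl: np.ndarray = None
    source: str = "unknown"

    def __post_init__(self):
        n = len(self.atom_name)
        self.coord = np.asarray(self.coord, dtype=float).reshape(n, 3)
        if self.charge is None:
            self.charge = np.zeros(n)
        if self.atom_type is None:
            self.atom_type = np.array(["UNK"] * n, dtype=object)
        if self.dg_wl is None:
            self.dg_wl = np.zeros(n)
        for name in ("atom_name", "res_name", "chain_id", "atom_type"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.charge = np.asarray(self.charge, dtype=float)
        self.dg_wl = np.asarray(self.dg_wl, dtype=float)

    # ------------------------------------------------------------------ views
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def element(self) -> np.ndarray:
        return np.array([next(c for c in n if c.isalpha()) for n in self.atom_name],
                        dtype=object)

    @property
    def residue_ordinal(self) -> np.ndarray:
        """Atom -> 0-based residue ordinal (new residue on (chain, res_id) change)."""
        keys = list(zip(self.chain_id, self.res_id))
        ordinal = np.zeros(self.n_atoms, dtype=int)
        for i in range(1, self.n_atoms):
            ordinal[i] = ordinal[i - 1] + (keys[i] != keys[i - 1])
        return ordinal

    @property
    def n_residues(self) -> int:
        return 0 if self.n_atoms == 0 else int(self.residue_ordinal[-1]) + 1

    @property
    def residue_names(self) -> list[str]:
        ordinal = self.residue_ordinal
        first = np.searchsorted(ordinal, np.arange(self.n_residues))
        return [str(self.res_name[i]) for i in first]

    @property
    def sequence(self) -> str:
        return "".join(_params.THREE_TO_ONE.get(r, "X") for r in self.residue_names)

    @property
    def net_charge(self) -> float:
        return float(self.charge.sum())

    def atoms(self) -> Iterator[AtomRecord]:
        el = self.element
        for i in range(self.n_atoms):
            yield AtomRecord(self.atom_name[i], el[i], self.res_name[i],
                             int(self.res_id[i]), self.chain_id[i],
                             self.coord[i], float(self.charge[i]),
                             self.atom_type[i], float(self.dg_wl[i]))

    def copy(self) -> "PeptideStructure":
        return PeptideStructure(self.atom_name.copy(), self.res_name.copy(),
                                self.res_id.copy(), self.chain_id.copy(),
                                self.coord.copy(), self.charge.copy(),
                                self.atom_type.copy(), self.dg_wl.copy(),
                                self.source)

    def transformed(self, rotation: np.ndarray = None,
                    translation: np.ndarray = None) -> "PeptideStructure":
        out = self.copy()
        if rotation is not None:
            out.coord = out.coord @ np.asarray(rotation).T
        if translation is not None:
            out.coord = out.coord + np.asarray(translation)
        return out

    def select(self, mask: np.ndarray) -> "PeptideStructure":
        return PeptideStructure(self.atom_name[mask], self.res_name[mask],
                                self.res_id[mask], self.chain_id[mask],
                                self.coord[mask], self.charge[mask],
                                self.atom_type[mask], self.dg_wl[mask],
                                self.source)

    def ca_coords(self) -> np.ndarray:
        return self.coord[self.atom_name == "CA"]


class EmptyStructureError(ValueError):
    pass


# --------------------------------------------------------------------- params
def apply_parameters(structure: PeptideStructure, table=None,
                     charged_termini: bool = True) -> PeptideStructure:
    """Attach charges, atom types and transfer energies from the parameter table.

    Atoms of residues absent from the table are flagged with a warning and get
    zero charge/transfer energy (atom type ``UNK``) rather than being dropped.
    Terminal patches: the first residue of each chain receives the ammonium
    N-terminus patch when ``charged_termini`` is set, and any residue carrying
    an OXT atom receives the carboxylate C-terminus patch.
    """
    table = table if table is not None else _params.load_atom_params()
    out = structure.copy()
    ordinal = out.residue_ordinal
    unknown: set[str] = set()

    # residues that take the C-terminal patch: those owning an OXT atom
    cter_res = set(ordinal[out.atom_name == "OXT"])
    nter_res = set()
    if charged_termini:
        for chain in dict.fromkeys(out.chain_id):
            nter_res.add(int(ordinal[out.chain_id == chain][0]))

    for i in range(out.n_atoms):
        res, name = str(out.res_name[i]), str(out.atom_name[i])
        key = (res, name)
        if ordinal[i] in cter_res and name in ("C", "O", "OXT"):
            key = ("CTER", name)
        elif ordinal[i] in nter_res and name == "N":
            key = ("NTER", name)
        try:
            row = table.loc[key]
        except KeyError:
            if res not in {r for r, _ in table.index}:
                unknown.add(res)
            out.atom_type[i], out.charge[i], out.dg_wl[i] = "UNK", 0.0, 0.0
            continue
        out.atom_type[i] = row["atom_type"]
        out.charge[i] = float(row["charge_e"])
        out.dg_wl[i] = float(row["dG_wl_atom"])
    for res in sorted(unknown):
        warnings.warn(f"residue {res!r} not in parameter table; its atoms get "
                      "zero charge and transfer energy", stacklevel=2)
    return out


# --------------------------------------------------------------------- PDB IO
def read_pdb(path, attach_params: bool = True,
             charged_termini: bool = True) -> PeptideStructure:
    """Read a PDB file into a :class:`PeptideStructure` (one entry per ATOM/HETATM).

    Raises ``EmptyStructureError`` if the file contains no atom records.
    Coordinates are preserved at PDB precision (3 decimals).
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        arr = pdb.get_structure(model=1)
    except ValueError as exc:
        raise EmptyStructureError(f"no ATOM records in {path}") from exc
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no ATOM records in {path}")
    st = PeptideStructure(
        atom_name=arr.atom_name.astype(object),
        res_name=arr.res_name.astype(object),
        res_id=arr.res_id.astype(int),
        chain_id=arr.chain_id.astype(object),
        coord=np.asarray(arr.coord, dtype=float),
        source="pdb-file",
    )
    if attach_params:
        st = apply_parameters(st, charged_termini=charged_termini)
    return st


def write_pdb(structure: PeptideStructure, path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = struc.AtomArray(structure.n_atoms)
    arr.atom_name = structure.atom_name.astype("U6")
    arr.res_name = structure.res_name.astype("U5")
    arr.res_id = structure.res_id
    arr.chain_id = structure.chain_id.astype("U4")
    arr.element = structure.element.astype("U2")
    arr.coord = structure.coord
    arr.hetero = np.zeros(structure.n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ------------------------------------------------------------- helix building
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8}


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF: position of atom d given chain a-b-c, |cd|, angle(b,c,d), torsion(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(angle),
                               np.sin(angle) * np.cos(torsion),
                               np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _kabsch(mobile: np.ndarray, fixed: np.ndarray):
    """Rotation R and translation t minimizing ||R@mobile + t - fixed||."""
    mc, fc = mobile.mean(axis=0), fixed.mean(axis=0)
    H = (mobile - mc).T @ (fixed - fc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, fc - R @ mc


_VARIANT_THREE = {"D-1": "ASP", "E-1": "GLU", "D0": "ASH", "E0": "GLH"}


def _tokenize_sequence(sequence) -> list[str]:
    """One-letter string or iterable of tokens (incl. D-1/E-1/D0/E0) -> 3-letter codes."""
    tokens = list(sequence) if not isinstance(sequence, str) else list(sequence)
    out = []
    for t in tokens:
        if t in _VARIANT_THREE:
            out.append(_VARIANT_THREE[t])
        elif t in _params.ONE_TO_THREE:
            out.append(_params.ONE_TO_THREE[t])
        else:
            raise ValueError(f"invalid residue token {t!r}")
    return out


def build_ideal_helix(sequence, phi: float = -57.0, psi: float = -47.0,
                      charged_ends: bool = True, omega: float = 180.0,
                      protonated_de: bool = False,
                      chain_id: str = "A") -> PeptideStructure:
    """Build an ideal alpha-helical peptide with the requested backbone dihedrals.

    The backbone is chained by internal coordinates (trans peptide bond);
    side chains are grafted from idealized residue templates by superimposing
    template (N, CA, C) frames.  The finished helix is centered at the origin
    with its principal axis along +z, N- to C-terminus.

    ``sequence`` is a one-letter string or a list of tokens which may include
    the protonation variants ``D-1``/``E-1``/``D0``/``E0``.  With
    ``protonated_de`` the plain letters D/E select the neutral species.
    ``charged_ends`` terminates the peptide with NH3+ / COO- groups (an OXT
    atom is added and terminal charge patches applied).
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    res3 = _tokenize_sequence(sequence)
    if protonated_de:
        res3 = [{"ASP": "ASH", "GLU": "GLH"}.get(r, r) for r in res3]
    nres = len(res3)

    N = np.zeros((nres, 3))
    CA = np.zeros((nres, 3))
    C = np.zeros((nres, 3))
    # first residue in a local frame
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND["N-CA"], 0.0, 0.0)
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    C[0] = CA[0] + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(nres - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], _BOND["C-N"],
                               _ANGLE["CA-C-N"], psi)
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], _BOND["N-CA"],
                                _ANGLE["C-N-CA"], omega)
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], _BOND["CA-C"],
                               _ANGLE["N-CA-C"], phi)

    names, resnames, resids, coords = [], [], [], []

    def add(name, res_i, xyz):
        names.append(name)
        resnames.append(res3[res_i])
        resids.append(res_i + 1)
        coords.append(np.asarray(xyz, dtype=float))

    for i in range(nres):
        add("N", i, N[i])
        add("CA", i, CA[i])
        add("C", i, C[i])
        if i < nres - 1:
            add("O", i, _place_atom(N[i + 1], CA[i], C[i], _BOND["C-O"],
                                    _ANGLE["CA-C-O"], 180.0))
        else:
            # carboxy terminus: O anti to the virtual next N, OXT in its place
            n_virt = _place_atom(N[i], CA[i], C[i], _BOND["C-N"],
                                 _ANGLE["CA-C-N"], psi)
            add("O", i, _place_atom(n_virt, CA[i], C[i], _BOND["C-O"],
                                    _ANGLE["CA-C-O"], 180.0))
            if charged_ends:
                add("OXT", i, _place_atom(n_virt, CA[i], C[i], _BOND["C-O"],
                                          _ANGLE["CA-C-O"], 0.0))
        # side chain from idealized template
        tmpl = residue_template(res3[i])
        if tmpl.side_names:
            R, t = _kabsch(tmpl.backbone_coord, np.array([N[i], CA[i], C[i]]))
            for name, xyz in zip(tmpl.side_names, tmpl.side_coord @ R.T + t):
                add(name, i, xyz)

    st = PeptideStructure(np.array(names, dtype=object),
                          np.array(resnames, dtype=object),
                          np.array(resids, dtype=int),
                          np.array([chain_id] * len(names), dtype=object),
                          np.array(coords), source="built-helix")

    # canonical placement: CA centroid at origin, principal axis along +z
    ca = st.ca_coords()
    center = ca.mean(axis=0)
    if nres >= 4:
        axis = _principal_axis(ca)
        rot = _rotation_onto_z(axis)
        st.coord = (st.coord - center) @ rot.T
    else:
        st.coord = st.coord - center
    return apply_parameters(st, charged_termini=charged_ends)


def _principal_axis(ca: np.ndarray) -> np.ndarray:
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:   # orient N -> C
        axis = -axis
    return axis / np.linalg.norm(axis)


def _rotation_onto_z(axis: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    return rot.as_matrix()


# --------------------------------------------------------- sequence templates
def sequence_generators(kind: str, n: int) -> str:
    """Benchmark peptide sequences.

    ``polyalanine``: "A"*n for n in 20..40.  ``walp``: GWW(LA)_k LWWA of total
    odd length ``n`` = 7 + 2k (19..39).  ``glrlg``: the poly-Leu motif
    G L^X R L^X G for X = ``n`` in 5..8.
    """
    if kind == "polyalanine":
        if not 20 <= n <= 40:
            raise ValueError("polyalanine length must be in 20..40")
        return "A" * n
    if kind == "walp":
        if not (19 <= n <= 39) or (n - 7) % 2:
            raise ValueError("WALP length must be odd, 19..39 (n = 7 + 2k)")
        k = (n - 7) // 2
        return "GWW" + "LA" * k + "LWWA"
    if kind == "glrlg":
        if not 5 <= n <= 8:
            raise ValueError("GLxRLxG repeat count must be in 5..8")
        return "G" + "L" * n + "R" + "L" * n + "G"
    raise ValueError(f"unknown sequence kind {kind!r}")


# ------------------------------------------------------------------- mutation
def mutate_residue(structure: PeptideStructure, position: int,
                   new_residue: str) -> PeptideStructure:
    """Fixed-backbone point mutation at 0-based residue ``position``.

    Backbone atoms (N, CA, C, O, OXT) are untouched; side-chain atoms are
    replaced by the idealized template of ``new_residue`` (one-letter code or
    a protonation variant token D-1/E-1/D0/E0) grafted onto the existing
    backbone frame.  Parameters are re-attached afterwards.
    """
    ordinal = structure.residue_ordinal
    if not 0 <= position < structure.n_residues:
        raise IndexError(f"residue position {position} out of range")
    res3 = _tokenize_sequence([new_residue])[0]
    tmpl = residue_template(res3)

    in_res = ordinal == position
    is_bb = np.isin(structure.atom_name.astype(str), list(BACKBONE_ATOMS))
    keep = ~in_res | is_bb
    kept = structure.select(keep)

    bb = {}
    for nm in ("N", "CA", "C"):
        sel = in_res & (structure.atom_name == nm)
        if not sel.any():
            raise ValueError(f"residue {position} lacks backbone atom {nm}")
        bb[nm] = structure.coord[sel][0]
    R, t = _kabsch(tmpl.backbone_coord, np.array([bb["N"], bb["CA"], bb["C"]]))
    side_xyz = tmpl.side_coord @ R.T + t

    # rebuild atom arrays, inserting the new side chain after the residue's
    # backbone atoms to keep residue contiguity
    kept_ord = kept.residue_ordinal
    insert_at = int(np.searchsorted(kept_ord, position, side="right"))
    res_id = int(structure.res_id[in_res][0])
    chain = structure.chain_id[in_res][0]

    def splice(arr, new_vals):
        return np.concatenate([arr[:insert_at], np.asarray(new_vals, dtype=arr.dtype),
                               arr[insert_at:]])

    nside = len(tmpl.side_names)
    out = PeptideStructure(
        splice(kept.atom_name, np.array(tmpl.side_names, dtype=object)),
        splice(kept.res_name, np.array([res3] * nside, dtype=object)),
        splice(kept.res_id, np.full(nside, res_id)),
        splice(kept.chain_id, np.array([chain] * nside, dtype=object)),
        np.concatenate([kept.coord[:insert_at], side_xyz, kept.coord[insert_at:]]),
        source=structure.source,
    )
    out.res_name[out.residue_ordinal == position] = res3
    charged = "OXT" in set(structure.atom_name.astype(str))
    return apply_parameters(out, charged_termini=charged)


# ---------------------------------------------------------------- measurement
def backbone_dihedrals(structure: PeptideStructure):
    """(phi, psi) in degrees per residue; NaN where undefined (termini)."""
    ordinal = structure.residue_ordinal
    nres = structure.n_residues
    pos = {}
    for i in range(structure.n_atoms):
        pos[(int(ordinal[i]), str(structure.atom_name[i]))] = structure.coord[i]

    def dihedral(p0, p1, p2, p3):
        b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
        b1 = b1 / np.linalg.norm(b1)
        v = b0 - np.dot(b0, b1) * b1
        w = b2 - np.dot(b2, b1) * b1
        return np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))

    phi = np.full(nres, np.nan)
    psi = np.full(nres, np.nan)
    for r in range(nres):
        try:
            if r > 0:
                phi[r] = dihedral(pos[(r - 1, "C")], pos[(r, "N")],
                                  pos[(r, "CA")], pos[(r, "C")])
            if r < nres - 1:
                psi[r] = dihedral(pos[(r, "N")], pos[(r, "CA")],
                                  pos[(r, "C")], pos[(r + 1, "N")])
        except KeyError:
            pass
    return phi, psi
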