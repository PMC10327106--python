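"""Loading of parameter tables: per-atom charges/types and hydrophobicity scales.

The package ships a single united-heavy-atom parameter file
(``data/atom_params.tsv``) with one row per (residue, atom): partial charge in
elementary charges, an atom-type token, and the water-to-bilayer transfer
energy of that atom type in kcal/mol.  The format is plain TSV so users can
substitute their own (e.g. force-field derived) charge sets.
"""
from __future__ import annotations

import functools
from importlib import resources

import pandas as pd

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "ASH": "D", "GLH": "E",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k not in ("ASH", "GLH")}

#: Canonical one-letter amino-acid alphabet, alphabetical.
AA20 = tuple(sorted(ONE_TO_THREE))

#: Residue formal charges implied by the shipped parameter set.
FORMAL_CHARGE = {r: 0.0 for r in THREE_TO_ONE}
FORMAL_CHARGE.update({"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0})


def _data_path(name: str):
    return resources.files("memfield.data").joinpath(name)


@functools.lru_cache(maxsize=None)
def load_atom_params(path: str | None = None) -> pd.DataFrame:
    """Load the per-atom parameter table.

    Returns a DataFrame indexed by (residue, atom_name) with columns
    ``atom_type``, ``charge_e`` and ``dG_wl_atom``.  Rows for the pseudo
    residues ``NTER``/``CTER`` are terminal patches applied on top of the
    base residue entries.
    """
    src = path if path is not None else _data_path("atom_params.tsv")
    df = pd.read_csv(src, sep="\t", comment="#")
    return df.set_index(["residue", "atom_name"])


@functools.lru_cache(maxsize=None)
def load_scale(name: str = "mf") -> dict[str, float]:
    """Load a hydrophobicity scale as ``{one-letter code: kcal/mol}``.

    ``name`` is ``"mf"`` (bilayer-context scale; the shipped table is a
    synthetic stand-in, see file header) or ``"ww"`` (water-to-octanol).
    Charged/neutral Asp and Glu variants appear as ``D-1``/``E-1`` and
    ``D0``/``E0`` where available.
    """
    fname = {"mf": "mf_scale_synthetic.tsv", "ww": "ww_scale.tsv"}[name]
    df = pd.read_csv(_data_path(fname), sep="\t", comment="#")
    return dict(zip(df["residue"], df["dG_wl"].astype(float)))
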