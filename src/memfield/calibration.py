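"""Hydrophobicity-scale calibration and composite-weight fitting.

Machinery for (1) the linear relation between the bilayer-context and
octanol hydrophobicity scales and the extrapolation of charged Asp/Glu
transfer energies, (2) the least-squares decomposition of per-residue
transfer energies into per-atom-type contributions via a stoichiometry
matrix, and (3) fitting the three composite weights by maximizing the
Pearson correlation with experimental mutation ddG values under
non-negativity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import params as _params

__all__ = [
    "HydrophobicityScale", "WeightSet", "linear_fit", "extrapolate_charged_de",
    "build_stoichiometry", "solve_atom_transfer", "fit_weights",
    "F23_WEIGHTS", "F19_WEIGHTS",
]


@dataclass
class HydrophobicityScale:
    """Per-amino-acid water-to-bilayer transfer energies, kcal/mol."""

    values: dict
    scale_name: str = "derived"

    @classmethod
    def load(cls, name: str) -> "HydrophobicityScale":
        return cls(_params.load_scale(name), {"mf": "MF", "ww": "WW"}[name])

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values


@dataclass
class WeightSet:
    """Non-negative weights of the three membrane terms in the composite score."""

    w_wl: float = 1.0
    w_lipid: float = 0.128
    w_dielec: float = 0.01

    def __post_init__(self):
        if min(self.w_wl, self.w_lipid, self.w_dielec) < 0:
            raise ValueError("weights must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_wl, self.w_lipid, self.w_dielec])


#: Calibrated composite weights of the full model.
F23_WEIGHTS = WeightSet(1.0, 0.128, 0.01)
#: Transfer-only preset reproducing the predecessor composite.
F19_WEIGHTS = WeightSet(0.5, 0.0, 0.0)


class DegenerateFitError(ValueError):
    pass


def linear_fit(x, y):
    """Ordinary least squares y = slope*x + intercept; returns (slope, intercept, r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise DegenerateFitError("need at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateFitError("x is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def extrapolate_charged_de(mf: HydrophobicityScale, ww: HydrophobicityScale,
                           exclude=("D", "E")):
    """Transfer energies of charged Asp/Glu on the bilayer-context scale.

    Fits the bilayer scale against the octanol scale over the residues shared
    by both (excluding Asp/Glu, whose bilayer values were measured near their
    side-chain pKa and are protonation mixtures) and evaluates the line at
    the octanol values of the charged species D-1 and E-1.

    Returns ``{"D-1": value, "E-1": value}`` plus a fit record.
    """
    for key in ("D-1", "E-1"):
        if key not in ww:
            raise KeyError(f"octanol scale lacks charged entry {key!r}")
    shared = [a for a in _params.AA20 if a in mf and a in ww and a not in exclude]
    if len(shared) < 3:
        raise DegenerateFitError("too few shared residues for the scale fit")
    slope, intercept, r = linear_fit([ww[a] for a in shared],
                                     [mf[a] for a in shared])
    out = {k: slope * ww[k] + intercept for k in ("D-1", "E-1")}
    record = {"slope": slope, "intercept": intercept, "r": r,
              "excluded": tuple(exclude), "n": len(shared)}
    return out, record


# ------------------------------------------------------------- atom transfer
def build_stoichiometry(param_table=None, residues=None) -> pd.DataFrame:
    """Atom-type stoichiometry matrix: rows residue codes, columns atom types."""
    table = param_table if param_table is not None else _params.load_atom_params()
    df = table.reset_index()
    df = df[~df["residue"].isin(["NTER", "CTER"])]
    if residues is not None:
        df = df[df["residue"].isin(residues)]
    mat = df.groupby(["residue", "atom_type"]).size().unstack(fill_value=0)
    return mat


def solve_atom_transfer(A, dg_aa, regularization: float | None = None):
    """Least-squares per-atom-type transfer energies from per-residue values.

    Solves ``A @ dg_atom = dg_aa`` (A the stoichiometry matrix).  Appending
    extra rows for charged-residue variants simply means passing an A /
    dg_aa with those rows included.  Without ``regularization`` a
    rank-deficient matrix raises, reporting a null-space basis (atom types
    that always co-occur -- e.g. one-per-residue backbone types -- are not
    individually identifiable from residue sums); with a ridge penalty the
    minimum-norm-biased solution is returned instead.

    Returns (atom values as Series/array, per-residue residuals).
    """
    A_arr = np.asarray(A, dtype=float)
    b = np.asarray(dg_aa, dtype=float)
    if A_arr.shape[0] != len(b):
        raise ValueError("row count of A must match dG vector length")
    rank = np.linalg.matrix_rank(A_arr)
    if regularization is None:
        if rank < A_arr.shape[1]:
            _, _, vt = np.linalg.svd(A_arr)
            null = vt[rank:]
            raise np.linalg.LinAlgError(
                f"stoichiometry matrix is rank-deficient (rank {rank} < "
                f"{A_arr.shape[1]} atom types); null-space basis:\n{null}")
        x, *_ = np.linalg.lstsq(A_arr, b, rcond=None)
    else:
        if regularization <= 0:
            raise ValueError("regularization must be positive")
        n = A_arr.shape[1]
        x = np.linalg.solve(A_arr.T @ A_arr + regularization * np.eye(n),
                            A_arr.T @ b)
    resid = A_arr @ x - b
    if isinstance(A, pd.DataFrame):
        x = pd.Series(x, index=A.columns, name="dG_wl_atom")
        resid = pd.Series(resid, index=A.index, name="residual")
    return x, resid


# -------------------------------------------------------------- weight fitting
def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return 0.0 if denom == 0 else float((a * b).sum() / denom)


def fit_weights(term_matrix, ddg_exp, exclude_mask=None) -> tuple:
    """Fit non-negative composite weights maximizing Pearson correlation.

    ``term_matrix`` is (n, 3): per-mutation transfer, lipid-potential and
    excess-dielectric term energies; ``ddg_exp`` the experimental values;
    ``exclude_mask`` marks rows left out of the objective (e.g. residues
    prone to overfitting).  Correlation is invariant to positive rescaling,
    so the maximizing direction is found in closed form by non-negative
    least squares on centered data, then polished with a deterministic
    Nelder-Mead pass; weights are reported normalized to w_wl = 1 when
    possible.

    Returns (WeightSet, achieved correlation).
    """
    X = np.asarray(term_matrix, dtype=float)
    y = np.asarray(ddg_exp, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("term_matrix must be (n, 3)")
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, dtype=bool)
        X, y = X[keep], y[keep]
    if len(y) < 5:
        raise ValueError("need at least 5 non-excluded rows")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < 3:
        import warnings
        warnings.warn("term matrix is rank-deficient on the fitted rows; "
                      "weight direction only partially identified")
    yc = y - y.mean()
    w, _ = optimize.nnls(Xc, yc)

    def neg_corr(v):
        vv = np.where(v < 0, 0.0, v)
        if not vv.any():
            return 1.0
        return -_pearson(Xc @ vv, yc)

    res = optimize.minimize(neg_corr, w, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14,
                                     "maxiter": 4000})
    w_ref = np.where(res.x < 0, 0.0, res.x)
    if -res.fun < _pearson(Xc @ w, yc):
        w_ref = w
    if w_ref[0] > 0:
        w_ref = w_ref / w_ref[0]
    elif w_ref.max() > 0:
        w_ref = w_ref / w_ref.max()
    corr = _pearson(Xc @ w_ref, yc) if w_ref.any() else 0.0
    return WeightSet(*w_ref), corr
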