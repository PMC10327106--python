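"""Mean-field bilayer electrostatic potentials.

Workflow: a periodic 3D charge-density grid (e/Å^3) -> spectral solution of
Poisson's equation in vacuum permittivity -> plane average to a depth profile
Psi(z) in volts -> non-linear fit of a piecewise sigmoid/quartic form ->
a per-lipid-type profile object that the lipid-potential energy term
evaluates.  A synthetic density generator emulates head-group dipole sheets
for PC/PE/PG patterns so the whole chain is testable without MD input.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .constants import COULOMB_V_ANG, WATER_REFERENCE_Z

__all__ = [
    "ChargeDensityGrid", "PotentialGrid", "PotentialProfile",
    "LipidPotentialProfile", "solve_poisson_periodic", "plane_average",
    "fit_piecewise_potential", "evaluate_profile", "synthetic_bilayer_density",
    "load_profile_library", "save_profile_library",
]

NET_CHARGE_TOL = 1e-6


class ChargedBoxError(ValueError):
    pass


@dataclass
class ChargeDensityGrid:
    """Periodic charge density on a regular 3D grid, e/Å^3."""

    values: np.ndarray
    spacing: tuple          # Å per axis (dx, dy, dz)
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    periodic: bool = True
    provenance: str = "synthetic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 8:
            raise ValueError("density grid must be 3D with all dimensions >= 8")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def box_lengths(self) -> np.ndarray:
        return np.array(self.values.shape) * np.array(self.spacing)

    def net_charge(self) -> float:
        return float(self.values.sum() * self.voxel_volume)

    def neutralized(self) -> "ChargeDensityGrid":
        """Subtract a uniform background so the box is exactly neutral."""
        out = ChargeDensityGrid(self.values - self.values.mean(), self.spacing,
                                self.origin, self.periodic, self.provenance)
        return out

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass
class PotentialGrid:
    """Electrostatic potential on the source grid geometry, volts (mean-free)."""

    values: np.ndarray
    spacing: tuple
    origin: np.ndarray

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass
class PotentialProfile:
    """Plane-averaged potential vs depth, volts."""

    z: np.ndarray
    psi: np.ndarray
    reference_z: float = WATER_REFERENCE_Z

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("profile z must be strictly ascending")


def solve_poisson_periodic(grid: ChargeDensityGrid,
                           neutralize: bool = False) -> PotentialGrid:
    """Spectral solution of nabla^2 Psi = -rho/eps0 on a periodic box.

    The k = 0 Fourier mode is set to zero (mean-free gauge).  Output is in
    volts via the conversion 1/(4 pi eps0) = 14.3996 V·Å/e.  A box with
    |net charge| > 1e-6 e raises ``ChargedBoxError`` unless ``neutralize``
    subtracts a uniform background first.
    """
    if not grid.periodic:
        raise ValueError("spectral solver requires a periodic grid")
    if abs(grid.net_charge()) > NET_CHARGE_TOL:
        if not neutralize:
            raise ChargedBoxError(
                f"box carries net charge {grid.net_charge():.3e} e; "
                "pass neutralize=True to add a uniform background")
        grid = grid.neutralized()

    rho_k = np.fft.fftn(grid.values)
    kx, ky, kz = (2.0 * np.pi * np.fft.fftfreq(n, d=s)
                  for n, s in zip(grid.values.shape, grid.spacing))
    k2 = (kx[:, None, None] ** 2 + ky[None, :, None] ** 2
          + kz[None, None, :] ** 2)
    k2[0, 0, 0] = np.inf          # zero the k=0 mode (gauge)
    psi_k = 4.0 * np.pi * COULOMB_V_ANG * rho_k / k2
    psi = np.fft.ifftn(psi_k).real
    return PotentialGrid(psi, grid.spacing, grid.origin.copy())


def plane_average(pot: PotentialGrid, axis: str = "z") -> PotentialProfile:
    """Average the potential over the two axes orthogonal to ``axis``."""
    iax = {"x": 0, "y": 1, "z": 2}[axis]
    other = tuple(i for i in range(3) if i != iax)
    return PotentialProfile(pot.axis_coords(iax), pot.values.mean(axis=other))


# ------------------------------------------------------------------ profiles
@dataclass
class LipidPotentialProfile:
    """Piecewise-fitted depth profile of the bilayer potential.

    Sigmoid branch for z >= zc:  A1 + (A1 - A2) / (1 + exp((z - A3)/A4));
    quartic branch for z < zc:   C1 z^4 + C2 z^3 + C3 z^2 + C4 z + C5,
    evaluated on |z| (symmetric leaflets), value-continuous at zc by
    construction, and referenced so the potential vanishes at the water
    reference depth (exactly zero beyond it).
    """

    lipid_name: str
    A: np.ndarray               # A1, A2 (V); A3, A4 (Å)
    C: np.ndarray               # C1..C5 (V/Å^n)
    zc: float
    reference_z: float = WATER_REFERENCE_Z
    salt_molar: float = 0.0
    fit_rms: float = 0.0

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.C = np.asarray(self.C, dtype=float)

    def _raw(self, a: np.ndarray) -> np.ndarray:
        A1, A2, A3, A4 = self.A
        arg = np.clip((a - A3) / A4 if A4 != 0 else np.full_like(a, 60.0), -60, 60)
        sig = A1 + (A1 - A2) / (1.0 + np.exp(arg))
        poly = np.polyval(self.C, a)
        return np.where(a >= self.zc, sig, poly)

    def evaluate(self, z) -> np.ndarray:
        """Potential difference vs water at depth z (volts), symmetric in z."""
        a = np.abs(np.asarray(z, dtype=float))
        ref = self._raw(np.array([self.reference_z]))[0]
        out = np.where(a >= self.reference_z, 0.0, self._raw(a) - ref)
        return out if out.ndim else float(out)

    @property
    def delta_psi(self) -> float:
        """Potential at the bilayer center relative to water, volts."""
        return float(self.evaluate(0.0))

    def to_dict(self) -> dict:
        return {"lipid_name": self.lipid_name,
                "A": [float(v) for v in self.A],
                "C": [float(v) for v in self.C],
                "zc": float(self.zc), "reference_z": float(self.reference_z),
                "salt_molar": float(self.salt_molar),
                "fit_rms": float(self.fit_rms)}

    @classmethod
    def from_dict(cls, d: dict) -> "LipidPotentialProfile":
        return cls(d["lipid_name"], np.array(d["A"]), np.array(d["C"]),
                   d["zc"], d.get("reference_z", WATER_REFERENCE_Z),
                   d.get("salt_molar", 0.0), d.get("fit_rms", 0.0))


def evaluate_profile(lp: LipidPotentialProfile, z) -> np.ndarray:
    return lp.evaluate(z)


class FitError(RuntimeError):
    pass


def _fold_symmetric(profile: PotentialProfile, n: int | None = None):
    """Fold the profile onto |z| in [0, reference_z], averaging leaflets.

    By default the fold grid is the profile's own (absolute) sample grid, so
    no interpolation error enters; pass ``n`` to resample onto a uniform grid.
    """
    zmax = min(profile.reference_z, float(np.abs(profile.z).max()))
    if n is None:
        a = np.unique(np.round(np.abs(profile.z), 9))
        a = a[a <= zmax + 1e-9]
    else:
        a = np.linspace(0.0, zmax, n)
    pos = np.interp(a, profile.z, profile.psi)
    if profile.z.min() < -1.0:   # a second leaflet exists
        neg = np.interp(-a[::-1], profile.z, profile.psi)[::-1]
        folded = 0.5 * (pos + neg)
    else:
        folded = pos
    return a, folded - folded[-1]


def _sigmoid(z, p):
    A1, A2, A3, A4 = p
    arg = np.clip((z - A3) / (A4 if A4 != 0 else 1e-9), -60, 60)
    return A1 + (A1 - A2) / (1.0 + np.exp(arg))


def _fit_at_zc(a, y, zc, warm=None):
    """Best piecewise fit for a fixed split depth; returns (rms, A, C).

    ``warm`` is an optional sigmoid-parameter start (used during the 1-D zc
    refinement to avoid re-running the full multi-start).
    """
    hi = a >= zc
    lo = ~hi
    if hi.sum() < 5:
        return np.inf, None, None
    zh, yh = a[hi], y[hi]

    # deterministic (multi-)start for the 4-parameter sigmoid branch
    if warm is not None:
        starts = [np.asarray(warm, dtype=float)]
    else:
        A1_0 = yh[-1]
        v_c = yh[0]
        slopes = np.gradient(yh, zh)
        z_steep = zh[np.argmax(np.abs(slopes))]
        starts = [np.array([A1_0, 2.0 * A1_0 - v_c, A3_0, A4_0])
                  for A4_0 in (0.5, 1.0, 2.0, 4.0)
                  for A3_0 in (z_steep, 0.5 * (zc + zh[-1]))]
    best = (np.inf, None)
    for p0 in starts:
        try:
            res = least_squares(lambda p: _sigmoid(zh, p) - yh, p0,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=300)
        except Exception:
            continue
        if res.cost < best[0]:
            best = (res.cost, res.x)
    if best[1] is None:
        return np.inf, None, None
    A = best[1]
    s_zc = _sigmoid(np.array([zc]), A)[0]

    # quartic branch with C5 constrained for value continuity at zc
    if lo.sum() == 0:
        C = np.array([0.0, 0.0, 0.0, 0.0, s_zc])
        resid = _sigmoid(zh, A) - yh
    else:
        zl, yl = a[lo], y[lo]
        basis = np.stack([zl ** 4 - zc ** 4, zl ** 3 - zc ** 3,
                          zl ** 2 - zc ** 2, zl - zc], axis=1)
        coef, *_ = np.linalg.lstsq(basis, yl - s_zc, rcond=None)
        C5 = s_zc - np.polyval(np.append(coef, 0.0), zc)
        C = np.append(coef, C5)
        resid = np.concatenate([np.polyval(C, zl) - yl, _sigmoid(zh, A) - yh])
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return rms, A, C


def fit_piecewise_potential(profile: PotentialProfile,
                            lipid_name: str = "custom",
                            salt_molar: float = 0.0,
                            n_fold: int | None = None) -> LipidPotentialProfile:
    """Fit the sigmoid/quartic piecewise form to a depth profile.

    The profile is folded onto |z| (symmetric-bilayer assumption) and
    referenced to the water depth.  The split depth zc is initialized at the
    largest-z stationary point of a smoothed copy of the profile, then
    refined by a bounded 1-D search minimizing the total residual; value
    continuity at zc is enforced by constraining C5.  All starts are
    deterministic.
    """
    a, y = _fold_symmetric(profile, n=n_fold)
    if np.ptp(y) < 1e-12:       # flat (e.g. zero) profile: nothing to fit
        return LipidPotentialProfile(lipid_name, np.zeros(4), np.zeros(5),
                                     zc=15.0, reference_z=float(a[-1]),
                                     salt_molar=salt_molar, fit_rms=0.0)

    # stationary points of the smoothed profile -> zc candidates
    kernel = np.ones(5) / 5.0
    ys = np.convolve(y, kernel, mode="same")
    dy = np.gradient(ys, a)
    sign_change = np.where(np.diff(np.sign(dy)) != 0)[0]
    cand = [float(a[i]) for i in sign_change if 2.0 < a[i] < a[-1] - 5.0]
    cand = sorted(cand)[-3:] if cand else []
    cand += [10.0, 15.0, 20.0]

    best = (np.inf, None, None, None)
    for zc0 in dict.fromkeys(round(c, 6) for c in cand):
        rms, A, C = _fit_at_zc(a, y, zc0)
        if rms < best[0]:
            best = (rms, A, C, zc0)
    if best[1] is None:
        raise FitError("piecewise potential fit failed for every zc candidate")

    zc0 = best[3]
    warm_A = best[1]
    lo_b = max(2.0, zc0 - 4.0)
    hi_b = min(a[-1] - 5.0, zc0 + 4.0)
    res = minimize_scalar(lambda zc: _fit_at_zc(a, y, zc, warm=warm_A)[0],
                          bounds=(lo_b, hi_b), method="bounded",
                          options={"xatol": 1e-3})
    zc = float(res.x) if res.fun < best[0] else zc0
    rms, A, C = _fit_at_zc(a, y, zc, warm=warm_A)
    if not np.isfinite(rms):
        raise FitError("piecewise potential fit did not converge")

    # joint polish of all branch parameters together with zc (C5 stays
    # constrained for continuity)
    def model(p):
        A_, C4_, zc_ = p[:4], p[4:8], p[8]
        s_zc = _sigmoid(np.array([zc_]), A_)[0]
        C5_ = s_zc - np.polyval(np.append(C4_, 0.0), zc_)
        full = np.append(C4_, C5_)
        return np.where(a >= zc_, _sigmoid(a, A_), np.polyval(full, a))

    p0 = np.concatenate([A, C[:4], [zc]])
    try:
        polish = least_squares(lambda p: model(p) - y, p0,
                               xtol=1e-15, ftol=1e-15, gtol=1e-15,
                               max_nfev=5000)
        prms = float(np.sqrt(np.mean(polish.fun ** 2)))
        if prms < rms:
            A, zc, rms = polish.x[:4], float(polish.x[8]), prms
            s_zc = _sigmoid(np.array([zc]), A)[0]
            C5 = s_zc - np.polyval(np.append(polish.x[4:8], 0.0), zc)
            C = np.append(polish.x[4:8], C5)
    except Exception:
        pass
    return LipidPotentialProfile(lipid_name, A, C, zc,
                                 reference_z=float(a[-1]),
                                 salt_molar=salt_molar, fit_rms=rms)


# -------------------------------------------------------- synthetic densities
def synthetic_bilayer_density(head_charge_pattern: str = "PC",
                              tail_halfwidth: float = 10.8,
                              salt_molar: float = 0.0,
                              seed: int = 0,
                              shape: tuple = (24, 24, 96),
                              spacing: float = 1.0,
                              noise: float = 0.0) -> ChargeDensityGrid:
    """Synthetic charge density emulating head-group dipole sheets.

    Two mirrored Gaussian dipole sheets (positive layer inward, negative
    outward, so the bilayer core sits at positive potential like a dipole
    potential) are placed just outside ``tail_halfwidth``.  PE packs a higher
    local head-group charge density into narrower sheets (higher potential
    than PC); PG adds a net-negative head layer neutralized by an adsorbed
    counterion layer just outside it (screening the potential); salt adds an
    opposing screening double layer in the water region.  The box is neutral
    by construction.
    """
    if tail_halfwidth <= 0 or spacing <= 0:
        raise ValueError("geometry parameters must be positive")
    if head_charge_pattern not in ("PC", "PE", "PG"):
        raise ValueError("head_charge_pattern must be PC, PE or PG")
    nx, ny, nz = shape
    lz = nz * spacing
    z = (np.arange(nz) - nz / 2) * spacing    # box centered on the bilayer

    def sheet_pair(center, width, amplitude):
        """Mirrored Gaussian sheets at +-center, each of total charge `amplitude` e."""
        per_area = amplitude / (nx * ny * spacing ** 2)
        g = (np.exp(-0.5 * ((z - center) / width) ** 2)
             + np.exp(-0.5 * ((z + center) / width) ** 2))
        g *= per_area / (g.sum() * spacing)
        return 2.0 * g   # both leaflets carry `amplitude`

    width = {"PC": 2.2, "PE": 1.3, "PG": 2.2}[head_charge_pattern]
    h_in = tail_halfwidth + 2.0     # positive layer (choline/amine)
    h_out = tail_halfwidth + 5.0    # negative layer (phosphate)
    # effective (water-screened) head charge per area, e/Å^2 x box area;
    # PE packs more charge into a smaller head-group footprint
    per_100A2 = {"PC": 0.10, "PE": 0.13, "PG": 0.10}[head_charge_pattern]
    sigma_e = per_100A2 * (nx * ny * spacing ** 2) / 100.0

    rho_z = sheet_pair(h_in, width, sigma_e) - sheet_pair(h_out, width, sigma_e)

    if head_charge_pattern == "PG":
        # anionic head charge plus adsorbed counterions just outside it:
        # an opposing dipole that screens the net potential
        q_pg = 0.5 * sigma_e
        rho_z += -sheet_pair(h_out, width, q_pg) + sheet_pair(h_out + 1.5, 1.5, q_pg)

    if salt_molar > 0.0:
        # screening double layer in the water region, Debye-like decay
        kappa = np.sqrt(salt_molar) / 3.04 * 10.0      # 1/Å from c in mol/L
        amp = sigma_e * (1.0 - np.exp(-kappa * 4.0))
        rho_z += -sheet_pair(h_out + 3.0, 2.0, amp) + sheet_pair(h_out + 3.0 + 1.0 / max(kappa, 0.05), 2.5, amp)

    vals = np.broadcast_to(rho_z, (nx, ny, nz)).copy()
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        vals = vals + noise * rng.standard_normal(vals.shape)
    vals -= vals.mean()             # exact neutrality after discretization
    origin = np.array([0.0, 0.0, -lz / 2.0])
    return ChargeDensityGrid(vals, (spacing, spacing, spacing), origin,
                             periodic=True, provenance="synthetic")


# ----------------------------------------------------------------- grid + IO
def write_profile_tsv(profile: PotentialProfile, path) -> None:
    np.savetxt(path, np.column_stack([profile.z, profile.psi]),
               header="z_angstrom\tpsi_volt", delimiter="\t")


def read_profile_tsv(path, reference_z: float = WATER_REFERENCE_Z) -> PotentialProfile:
    data = np.loadtxt(path)
    return PotentialProfile(data[:, 0], data[:, 1], reference_z)


def save_profile_library(profiles: dict, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({name: lp.to_dict() for name, lp in profiles.items()}, fh)


def load_profile_library(path=None) -> dict:
    """Load fitted profiles keyed by lipid name (default: packaged library)."""
    import yaml
    from importlib import resources

    if path is None:
        path = resources.files("memfield.data").joinpath("lipid_profiles_synthetic.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: LipidPotentialProfile.from_dict(v) for k, v in raw.items()}


def write_dx(grid, path) -> None:
    """OpenDX scalar export for visualization."""
    vals = grid.values
    nx, ny, nz = vals.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing[0]:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing[1]:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing[2]:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {vals.size} data follows\n")
        flat = vals.ravel()
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
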