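"""Deterministic synthetic-data generators.

Every generator is a pure function of its parameters and an explicit seed,
so fixtures for tests and demonstrations are reproducible bit-for-bit and
no external downloads are needed.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .benchmarks import SequencePairSet, REGIONS
from .calibration import WeightSet
from .params import AA20
from .structure import build_ideal_helix, sequence_generators

__all__ = [
    "FixtureSpec", "make_sequence_set", "make_ddg_set", "make_helix",
    "make_density_grid", "walp_series", "glrlg_series", "RESIDUE_FREQUENCIES",
]

#: Stated background amino-acid frequencies used by the sequence generator
#: (membrane-protein-like: enriched in Leu/Ala/Val/Ile/Gly/Phe).
RESIDUE_FREQUENCIES = {
    "A": 0.085, "C": 0.015, "D": 0.040, "E": 0.050, "F": 0.055, "G": 0.070,
    "H": 0.020, "I": 0.065, "K": 0.040, "L": 0.110, "M": 0.025, "N": 0.035,
    "P": 0.040, "Q": 0.030, "R": 0.045, "S": 0.060, "T": 0.055, "V": 0.075,
    "W": 0.025, "Y": 0.030,
}


@dataclass
class FixtureSpec:
    kind: str                          # helix | density_grid | sequence_set | ddg_set
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def build(self):
        fn = {"helix": make_helix, "density_grid": make_density_grid,
              "sequence_set": make_sequence_set, "ddg_set": make_ddg_set}[self.kind]
        return fn(seed=self.seed, **self.parameters)


def artifact_hash(obj) -> str:
    """Stable content hash of a generated fixture (round-trip checks)."""
    h = hashlib.sha256()
    if isinstance(obj, SequencePairSet):
        for part in (obj.native, obj.designed, obj.regions, obj.burial or []):
            for entry in part:
                entry = "".join(entry) if not isinstance(entry, str) else entry
                h.update(entry.encode())
                h.update(b"|")
    elif isinstance(obj, tuple):
        for el in obj:
            h.update(np.ascontiguousarray(np.asarray(el, dtype=float)).tobytes())
    elif hasattr(obj, "values"):
        h.update(np.ascontiguousarray(np.asarray(obj.values, dtype=float)).tobytes())
    elif hasattr(obj, "coord"):
        h.update(np.ascontiguousarray(obj.coord).tobytes())
        h.update("".join(map(str, obj.atom_name)).encode())
    else:
        raise TypeError(f"cannot hash fixture of type {type(obj)!r}")
    return h.hexdigest()


def make_sequence_set(n_proteins: int = 50, length: int = 200,
                      recovery_target: float = 0.3,
                      region_mix=(0.35, 0.25, 0.40),
                      buried_fraction: float = 0.3,
                      seed: int = 0) -> SequencePairSet:
    """Native/designed sequence pairs with a controlled recovery rate.

    Native sequences are drawn from :data:`RESIDUE_FREQUENCIES`; each
    designed position copies its native residue with probability
    ``recovery_target`` and otherwise resamples from the background
    distribution *excluding* the native residue (so measured recovery is
    exactly binomial around the target).  Region labels are drawn from
    ``region_mix`` over (lipid, interface, aqueous); burial labels are
    buried with probability ``buried_fraction``.
    """
    if not 0.0 <= recovery_target <= 1.0:
        raise ValueError("recovery_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aas = np.array(list(RESIDUE_FREQUENCIES))
    p = np.array(list(RESIDUE_FREQUENCIES.values()))
    p = p / p.sum()
    native, designed, regions, burial = [], [], [], []
    for _ in range(n_proteins):
        nat = rng.choice(aas, size=length, p=p)
        keep = rng.random(length) < recovery_target
        des = nat.copy()
        for j in np.flatnonzero(~keep):
            mask = aas != nat[j]
            pj = p[mask] / p[mask].sum()
            des[j] = rng.choice(aas[mask], p=pj)
        native.append("".join(nat))
        designed.append("".join(des))
        regions.append(list(rng.choice(REGIONS, size=length, p=region_mix)))
        burial.append(list(rng.choice(["buried", "surface"], size=length,
                                      p=[buried_fraction, 1 - buried_fraction])))
    return SequencePairSet(native, designed, regions, burial)


def make_ddg_set(weights_true: WeightSet = None, n: int = 100,
                 noise_sd: float = 0.0, seed: int = 0):
    """Synthetic mutation set exercising the weight fit.

    Term energies are drawn uniformly from ranges chosen so each weighted
    term contributes visibly to the response (transfer +-5, lipid-potential
    +-30, excess-dielectric +-100 kcal/mol); the response is the true
    weighted sum plus Gaussian noise.  Rows carry cycling residue labels so
    exclusion lists can be exercised.

    Returns a DataFrame with columns residue, T_transfer, T_lipid,
    T_dielec, ddg_exp.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    weights_true = weights_true or WeightSet(1.0, 0.128, 0.01)
    rng = np.random.default_rng(seed)
    T = np.column_stack([rng.uniform(-5, 5, n), rng.uniform(-30, 30, n),
                         rng.uniform(-100, 100, n)])
    y = T @ weights_true.as_array() + noise_sd * rng.standard_normal(n)
    residues = [AA20[i % len(AA20)] for i in range(n)]
    return pd.DataFrame({"residue": residues, "T_transfer": T[:, 0],
                         "T_lipid": T[:, 1], "T_dielec": T[:, 2],
                         "ddg_exp": y})


def make_helix(sequence=None, kind: str = None, n: int = None,
               seed: int = 0, **kw):
    """Built helix fixture; either an explicit sequence or a (kind, n) spec."""
    if sequence is None:
        sequence = sequence_generators(kind, n)
    return build_ideal_helix(sequence, **kw)


def make_density_grid(head_charge_pattern: str = "PC",
                      tail_halfwidth: float = 10.8,
                      salt_molar: float = 0.0, seed: int = 0, **kw):
    from .lipid_potential import synthetic_bilayer_density

    return synthetic_bilayer_density(head_charge_pattern, tail_halfwidth,
                                     salt_molar, seed, **kw)


def walp_series(lengths=range(19, 40, 2)):
    """All WALP sequences GWW(LA)_k LWWA for the requested odd lengths."""
    return {n: sequence_generators("walp", n) for n in lengths}


def glrlg_series(repeats=range(5, 9)):
    """Poly-Leu G L^X R L^X G sequences for X in ``repeats``."""
    return {x: sequence_generators("glrlg", x) for x in repeats}
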