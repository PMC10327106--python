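"""Evaluation protocols: mutation ddG, insertion ddG, and sequence-design metrics.

Stability protocols
-------------------
``ddg_mutation`` scores a fixed-backbone, fixed-orientation point mutant and
native in the bilayer and in water and returns the double difference.  In
the reduced composite (no soluble-protein base score) the water state
carries zero membrane energy by construction, so the double difference
reduces to the bilayer-score difference.

``ddg_insertion`` is the energy difference between the lowest-energy
membrane orientation and the aqueous state; the aqueous state (zero) is a
member of the candidate set, so the result is never positive.

Design metrics
--------------
Sequence recovery, KL divergence of pooled designed vs native amino-acid
distributions (with per-type log-likelihood differences), the design
confusion matrix p(designed=s | native=r), and its per-native-residue
perplexity 2^H2.  All metrics support region ({lipid, interface, aqueous})
and burial ({buried, surface}) stratification.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import WeightSet, F23_WEIGHTS
from .params import AA20
from .scoring import MembraneSystem, score
from .structure import mutate_residue

__all__ = [
    "MutationSpec", "SequencePairSet", "DesignMetrics",
    "ddg_mutation", "ddg_insertion", "sequence_recovery",
    "divergence", "confusion_matrix", "perplexity", "compute_design_metrics",
]

REGIONS = ("lipid", "interface", "aqueous")


# ------------------------------------------------------------------ stability
@dataclass
class MutationSpec:
    position: int               # 0-based residue position
    native: str                 # one-letter code, sanity-checked
    mutant: str                 # one-letter code or D-1/E-1/D0/E0 token
    structure_id: str = ""
    fixed_depth: bool = True


def ddg_mutation(native_structure, spec: MutationSpec,
                 system: MembraneSystem,
                 weights: WeightSet = F23_WEIGHTS) -> float:
    """Mutational ddG at fixed backbone and fixed membrane orientation.

    The native structure must already be placed in the membrane frame; the
    orientation is never re-searched.  Returns kcal/mol (REU-equivalent).
    """
    seq = native_structure.sequence
    if seq[spec.position] != spec.native[0]:
        raise ValueError(f"native residue mismatch at position {spec.position}: "
                         f"structure has {seq[spec.position]}, spec says {spec.native}")
    mutant = mutate_residue(native_structure, spec.position, spec.mutant)
    g_bil_nat = score(native_structure, system, weights).total
    g_bil_mut = score(mutant, system, weights).total
    # aqueous-state membrane energies vanish by construction in the reduced
    # composite (transfer and excess terms are zero at f_hyd = 1, the lipid
    # potential is zero beyond the water reference depth)
    g_wat_nat = 0.0
    g_wat_mut = 0.0
    return (g_bil_mut - g_wat_mut) - (g_bil_nat - g_wat_nat)


def ddg_insertion(structure, system: MembraneSystem,
                  weights: WeightSet = F23_WEIGHTS,
                  **search_kw):
    """Insertion ddG: lowest membrane-orientation energy vs the aqueous state.

    The unfolded-reference term cancels between the two phases in the
    reduced model.  The aqueous state (all membrane terms zero) is included
    in the candidate set, so the returned value is <= 0; a peptide whose
    best membrane placement is unfavorable is reported as expelled (0).

    Returns (ddG, OrientationState or None if expelled).
    """
    from .orientation import find_min_orientation

    state, e_min = find_min_orientation(structure, system=system,
                                        weights=weights, **search_kw)
    if e_min >= 0.0:
        return 0.0, None
    return float(e_min), state


# ------------------------------------------------------------------- pair set
@dataclass
class SequencePairSet:
    """Aligned native/designed sequences with per-position labels."""

    native: list
    designed: list
    regions: list                      # per-position region labels
    burial: Optional[list] = None      # per-position {buried|surface}

    def __post_init__(self):
        if len(self.native) != len(self.designed):
            raise ValueError("native/designed entry counts differ")
        for i, (n, d) in enumerate(zip(self.native, self.designed)):
            if len(n) != len(d):
                raise ValueError(f"entry {i}: sequence lengths differ")
            if len(self.regions[i]) != len(n):
                raise ValueError(f"entry {i}: region labels do not cover sequence")

    def positions(self, region: str = None, burial: str = None):
        """Flattened (native, designed) position arrays after filtering."""
        nat, des = [], []
        for i, (n, d) in enumerate(zip(self.native, self.designed)):
            for j in range(len(n)):
                if region is not None and self.regions[i][j] != region:
                    continue
                if burial is not None:
                    if self.burial is None or self.burial[i][j] != burial:
                        continue
                nat.append(n[j])
                des.append(d[j])
        return np.array(nat), np.array(des)


class UndefinedMetricError(ValueError):
    pass


def sequence_recovery(pairs: SequencePairSet, region: str = None,
                      burial: str = None):
    """Fraction of native residues recovered, plus per-residue-type rates.

    Returns (recovery fraction, Series of per-native-type recovery).
    """
    nat, des = pairs.positions(region, burial)
    if len(nat) == 0:
        raise UndefinedMetricError("no positions after filtering")
    match = nat == des
    per_type = pd.Series(
        {aa: float(match[nat == aa].mean()) for aa in AA20 if (nat == aa).any()},
        name="recovery")
    return float(match.mean()), per_type


def _distribution(seq_array, pseudocount: float):
    counts = pd.Series(0.0, index=list(AA20))
    vals, cnt = np.unique(seq_array, return_counts=True)
    for v, c in zip(vals, cnt):
        if v in counts.index:
            counts[v] += c
    raw = counts / counts.sum() if counts.sum() else counts
    counts += pseudocount
    p = counts / counts.sum()
    if pseudocount > 0 and counts.sum() and np.max(np.abs(p - raw)) > 1e-3:
        warnings.warn("pseudocount shifts a probability by more than 1e-3",
                      stacklevel=3)
    return p


def divergence(pairs: SequencePairSet, region: str = None,
               burial: str = None, pseudocount: float = 0.5,
               base: str = "nats"):
    """KL divergence of designed vs native amino-acid distributions.

    Distributions are pooled over all entries.  Returns a dict with
    ``D_KL`` (>= 0), the per-type log-likelihood differences ``D_s``
    (Series), their sum ``D``, and the two distributions.  ``base`` selects
    natural log (default) or ``"bits"``.
    """
    nat, des = pairs.positions(region, burial)
    if len(nat) == 0:
        raise UndefinedMetricError("no positions after filtering")
    q_nat = _distribution(nat, pseudocount)
    p_des = _distribution(des, pseudocount)
    log = np.log2 if base == "bits" else np.log
    ratio = log(p_des / q_nat)
    d_kl = float((p_des * ratio).sum())
    return {"D_KL": d_kl, "D_s": pd.Series(ratio, name="D_s"),
            "D": float(ratio.sum()), "p_des": p_des, "q_nat": q_nat,
            "base": base}


def confusion_matrix(pairs: SequencePairSet, region: str = None,
                     burial: str = None, pseudocount: float = 0.0) -> pd.DataFrame:
    """p(designed = s | native = r): rows native types, columns designed types.

    Rows for native types with zero occurrences are omitted (not
    zero-filled); remaining rows sum to 1.  ``pseudocount`` is added to all
    counts of a row before normalizing when non-zero.
    """
    nat, des = pairs.positions(region, burial)
    rows = {}
    for r in AA20:
        sel = nat == r
        if not sel.any():
            continue
        counts = pd.Series(pseudocount, index=list(AA20), dtype=float)
        vals, cnt = np.unique(des[sel], return_counts=True)
        for v, c in zip(vals, cnt):
            if v in counts.index:
                counts[v] += c
        rows[r] = counts / counts.sum()
    return pd.DataFrame(rows).T


def perplexity(row) -> float:
    """2 to the base-2 Shannon entropy of a designed-residue probability row.

    1 for a deterministic design choice; 20 for uniform confusion over the
    canonical alphabet.
    """
    p = np.asarray(row, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("row must be a probability vector")
    nz = p[p > 0]
    return float(2.0 ** (-(nz * np.log2(nz)).sum()))


@dataclass
class DesignMetrics:
    recovery: float
    per_type_recovery: pd.Series
    D_KL: float
    D_s: pd.Series
    D: float
    confusion: pd.DataFrame
    perplexity: pd.Series
    region: Optional[str] = None


def compute_design_metrics(pairs: SequencePairSet, region: str = None,
                           burial: str = None,
                           pseudocount: float = 0.5) -> DesignMetrics:
    rec, per_type = sequence_recovery(pairs, region, burial)
    div = divergence(pairs, region, burial, pseudocount)
    conf = confusion_matrix(pairs, region, burial)
    pp = pd.Series({r: perplexity(conf.loc[r]) for r in conf.index},
                   name="perplexity")
    return DesignMetrics(rec, per_type, div["D_KL"], div["D_s"], div["D"],
                         conf, pp, region)
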