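"""Probabilistic interface-connectivity model.

Treats the formation/breakage of each interface hydrogen bond as an
independent Bernoulli event whose success probability is the bond's
occupancy ω.  From the per-bond occupancies it derives

* ``p_ij`` — probability that ligand residue *i* is bound to receptor
  residue *j*:  p_ij = 1 − Π_l (1 − ω_ij,l);
* residue binding profiles P_{j,L}, P_{j,R} (row/column marginals);
* the complex dissociation probability
  P_D = Π_j (1 − P_{j,L}) = Π_j (1 − P_{j,R}) = Π_bonds (1 − ω);
* the mechano-regulation factor f_D = P_D|_{f=f0} / P_D|_{f=0}, the
  force-normalised dissociation: f_D < 1 marks the catch (force-enhanced
  binding) regime, f_D > 1 the slip regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContactProbabilityMatrix",
    "ResidueBindingProfile",
    "ConnectivityResult",
    "pair_probability",
    "residue_profiles",
    "dissociation_probability",
    "mechano_regulation_factor",
]


def _check_unit_interval(values: np.ndarray, what: str) -> None:
    arr = np.asarray(values, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError(f"{what} must lie in [0, 1]")


def pair_probability(omegas: Iterable[float]) -> float:
    """Residue-pair binding probability from its bond occupancies.

    p = 1 − Π_l (1 − ω_l); the empty bond list yields 0.
    """
    arr = np.asarray(list(omegas), dtype=float)
    _check_unit_interval(arr, "occupancies")
    if arr.size == 0:
        return 0.0
    return float(1.0 - np.prod(1.0 - arr))


@dataclass
class ContactProbabilityMatrix:
    """M_L × M_R matrix of residue-pair binding probabilities p_ij."""

    p: np.ndarray
    ligand_residues: list[str]
    receptor_residues: list[str]
    bond_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        _check_unit_interval(self.p, "p_ij")
        ml, mr = self.p.shape
        if len(self.ligand_residues) != ml or len(self.receptor_residues) != mr:
            raise ValueError("residue label lengths must match matrix shape")
        if self.bond_counts is None:
            self.bond_counts = (self.p > 0).astype(int)
        else:
            self.bond_counts = np.atleast_2d(np.asarray(self.bond_counts, dtype=int))
            if self.bond_counts.shape != self.p.shape:
                raise ValueError("bond_counts shape must match p")
            if np.any((self.bond_counts == 0) & (self.p != 0)):
                raise ValueError("p_ij must be 0 wherever no bond exists")

    @classmethod
    def from_occupancies(
        cls, table: pd.DataFrame | Sequence[tuple[int, int, float]]
    ) -> "ContactProbabilityMatrix":
        """Build the matrix from per-bond rows (i, j, ω).

        Accepts the occupancy DataFrame produced by
        :func:`mechbond.interactions.occupancy` or any iterable of
        ``(i, j, omega)`` triples.  Each bond instance contributes its own
        ω (a pair with two bonds enters the product twice).
        """
        if isinstance(table, pd.DataFrame):
            triples = list(
                zip(table["i"].astype(int), table["j"].astype(int), table["occupancy"])
            )
            lig_labels = {}
            rec_labels = {}
            if "ligand_residue" in table:
                for i, lab in zip(table["i"].astype(int), table["ligand_residue"]):
                    lig_labels[i] = str(lab)
                for j, lab in zip(table["j"].astype(int), table["receptor_residue"]):
                    rec_labels[j] = str(lab)
        else:
            triples = [(int(i), int(j), float(w)) for i, j, w in table]
            lig_labels, rec_labels = {}, {}
        if not triples:
            raise ValueError("no bonds supplied")
        ml = max(i for i, _, _ in triples) + 1
        mr = max(j for _, j, _ in triples) + 1
        comp = np.ones((ml, mr))
        counts = np.zeros((ml, mr), dtype=int)
        for i, j, w in triples:
            _check_unit_interval(np.array([w]), "occupancy")
            comp[i, j] *= 1.0 - w
            counts[i, j] += 1
        return cls(
            p=1.0 - comp,
            ligand_residues=[lig_labels.get(i, f"L{i}") for i in range(ml)],
            receptor_residues=[rec_labels.get(j, f"R{j}") for j in range(mr)],
            bond_counts=counts,
        )


@dataclass
class ResidueBindingProfile:
    """Per-residue binding probabilities for the ligand and receptor sides."""

    P_L: np.ndarray
    P_R: np.ndarray


@dataclass
class ConnectivityResult:
    """Complex dissociation probability, optionally tagged with the clamp force."""

    P_D: float
    force_pN: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.P_D <= 1.0):
            raise ValueError("P_D must lie in [0, 1]")


def residue_profiles(cpm: ContactProbabilityMatrix) -> ResidueBindingProfile:
    """Row-wise (ligand) and column-wise (receptor) binding probabilities."""
    comp = 1.0 - cpm.p
    return ResidueBindingProfile(
        P_L=1.0 - comp.prod(axis=1),
        P_R=1.0 - comp.prod(axis=0),
    )


def dissociation_probability(
    cpm: ContactProbabilityMatrix, force_pN: float = float("nan")
) -> ConnectivityResult:
    """Complex dissociation probability under the independent-bond model.

    Computed from the ligand side; the receptor side is algebraically equal
    (both reduce to the product of (1 − p_ij) over all cells) and is checked
    here to floating tolerance.  The per-residue survival probabilities
    1 − P_j are evaluated as complement products directly, never as
    1 − (1 − Π(1 − p)), which would round P_j near one and destroy the
    small products this model is used for.
    """
    comp = 1.0 - cpm.p
    pd_l = float(np.prod(comp.prod(axis=1)))
    pd_r = float(np.prod(comp.prod(axis=0)))
    if not np.isclose(pd_l, pd_r, rtol=1e-12, atol=1e-300):
        raise AssertionError("ligand/receptor-side products disagree")
    return ConnectivityResult(P_D=min(max(pd_l, 0.0), 1.0), force_pN=force_pN)


def dissociation_from_omegas(
    omegas: Iterable[float], force_pN: float = float("nan")
) -> ConnectivityResult:
    """P_D straight from bond occupancies: Π (1 − ω)."""
    arr = np.asarray(list(omegas), dtype=float)
    _check_unit_interval(arr, "occupancies")
    return ConnectivityResult(P_D=float(np.prod(1.0 - arr)), force_pN=force_pN)


def mechano_regulation_factor(
    result_at_f0: ConnectivityResult, result_at_zero: ConnectivityResult
) -> float:
    """f_D = P_D at clamp force / P_D at zero force.

    Raises when P_D at zero force is 0 (the normalisation is undefined).
    """
    if result_at_zero.P_D == 0.0:
        raise ZeroDivisionError(
            "P_D at zero force is 0; the mechano-regulation factor is undefined"
        )
    return result_at_f0.P_D / result_at_zero.P_D
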