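"""Per-frame hydrogen-bond and salt-bridge detection, survival rasters,
occupancies and interface bond counts.

The geometric hydrogen-bond criterion is the standard one used in MD
post-processing: donor–acceptor distance below a cutoff (default 3.5 Å)
together with an angular cutoff (default 30°).  Two angle conventions are
supported — donor-vertex (angle between the D→H and D→A vectors, the
convention of common visualization tools) and hydrogen-vertex
(180° − ∠D–H–A) — selectable via :class:`HBondCriteria`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .structio import Atom, Frame, StructureError, Trajectory

__all__ = [
    "HBondCriteria",
    "BondInstance",
    "BondRaster",
    "MissingHydrogensError",
    "detect_hbonds",
    "detect_salt_bridges",
    "build_raster",
    "occupancy",
    "nhb_series",
]


class MissingHydrogensError(ValueError):
    """Hydrogens required by the criteria but absent from the structure."""


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion.

    d_cut_A:
        Donor–acceptor distance cutoff, Å.
    angle_cut_deg:
        Angular cutoff, degrees.
    angle_convention:
        'donor-vertex' (∠(D→H, D→A) ≤ cutoff) or 'hydrogen-vertex'
        (180° − ∠D–H–A ≤ cutoff).
    require_hydrogens:
        If True, a structure without hydrogens is an error; otherwise
        detection falls back to distance-only with a warning flag.
    """

    d_cut_A: float = 3.5
    angle_cut_deg: float = 30.0
    angle_convention: Literal["donor-vertex", "hydrogen-vertex"] = "donor-vertex"
    require_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.d_cut_A <= 0:
            raise ValueError("d_cut_A must be positive")
        if not (0 < self.angle_cut_deg <= 90):
            raise ValueError("angle_cut_deg must be in (0, 90]")


@dataclass(frozen=True)
class BondInstance:
    """One interface hydrogen bond, identified by its heavy atoms.

    ``i``/``j`` are indices of the ligand/receptor residues among the
    residues involved in binding; ``l`` numbers the bonds within a residue
    pair.  They are assigned when a raster is built.
    """

    donor: tuple[str, int, str]
    acceptor: tuple[str, int, str]
    donor_resname: str = ""
    acceptor_resname: str = ""
    hydrogen: str | None = None
    i: int = -1
    j: int = -1
    l: int = 0

    @property
    def key(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        """Heavy-atom identity; hydrogen relabelling never splits a bond."""
        return (self.donor, self.acceptor)

    @property
    def ligand_residue(self) -> tuple[str, int]:
        return self.donor[:2]

    @property
    def receptor_residue(self) -> tuple[str, int]:
        return self.acceptor[:2]


@dataclass
class BondRaster:
    """Bond-instance × frame boolean survival matrix.

    Column sums are the per-frame interface hydrogen-bond count N_HB;
    row means are the per-bond occupancies ω.
    """

    bonds: list[BondInstance]
    states: np.ndarray
    dt_ns: float = 1.0
    distance_only: bool = False
    ligand_chains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.shape[0] != len(self.bonds):
            raise ValueError("states row count must equal number of bonds")
        if len(self.bonds) and not self.states.any(axis=1).all():
            raise ValueError("every bond must be present in at least one frame")

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.states.astype(int),
            index=[_bond_id(b) for b in self.bonds],
            columns=[f"frame_{k}" for k in range(self.n_frames)],
        )
        df.index.name = "bond"
        df.to_csv(path)


def _bond_id(b: BondInstance) -> str:
    d, a = b.donor, b.acceptor
    return f"{d[0]}:{b.donor_resname}{d[1]}:{d[2]}--{a[0]}:{b.acceptor_resname}{a[1]}:{a[2]}"


# --------------------------------------------------------------------------
# Donor/acceptor chemistry (heavy atoms; hydrogens found geometrically)

_BACKBONE_DONOR = {"N"}
_BACKBONE_ACCEPTOR = {"O", "OXT"}

_SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"}, "HIS": {"ND1", "NE2"},
    "HSD": {"ND1", "NE2"}, "HSE": {"ND1", "NE2"}, "HSP": {"ND1", "NE2"},
}

_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "HSD": {"ND1", "NE2"}, "HSE": {"ND1", "NE2"},
    "MET": set(),
}

_ACIDIC_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
_BASIC_N = {"LYS": {"NZ"}, "ARG": {"NH1", "NH2", "NE"}}

# covalent D–H bond length ceiling used for geometric H attachment
_H_ATTACH_CUTOFF_A = 1.25


def _is_donor(a: Atom) -> bool:
    if a.name in _BACKBONE_DONOR and a.element == "N":
        return True
    return a.name in _SIDECHAIN_DONORS.get(a.resname.upper(), set())


def _is_acceptor(a: Atom) -> bool:
    if a.name in _BACKBONE_ACCEPTOR and a.element == "O":
        return True
    return a.name in _SIDECHAIN_ACCEPTORS.get(a.resname.upper(), set())


def _attached_hydrogens(frame: Frame, heavy_idx: int) -> list[int]:
    """Hydrogens covalently attached to a heavy atom (same residue, < 1.25 Å)."""
    heavy = frame.atoms[heavy_idx]
    out = []
    for k, a in enumerate(frame.atoms):
        if a.element != "H" or a.residue_key != heavy.residue_key:
            continue
        if np.linalg.norm(frame.coords[k] - frame.coords[heavy_idx]) < _H_ATTACH_CUTOFF_A:
            out.append(k)
    return out


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(
    frame: Frame,
    group_a: Sequence[int],
    group_b: Sequence[int],
    crit: HBondCriteria = HBondCriteria(),
) -> tuple[set[BondInstance], bool]:
    """Detect interface hydrogen bonds between two disjoint atom groups.

    Donors are searched in both groups (the result is symmetric in group
    order).  Returns ``(bonds, distance_only)`` where the flag records a
    hydrogen-free fallback to the distance criterion alone.
    """
    ga, gb = set(map(int, group_a)), set(map(int, group_b))
    if ga & gb:
        raise ValueError("groups must be disjoint")
    any_h = any(frame.atoms[k].element == "H" for k in (ga | gb))
    if not any_h and crit.require_hydrogens:
        raise MissingHydrogensError(
            "hydrogens required by criteria but none present in either group"
        )
    distance_only = not any_h

    bonds: set[BondInstance] = set()
    for donors, acceptors in ((ga, gb), (gb, ga)):
        d_idx = [k for k in donors if _is_donor(frame.atoms[k])]
        a_idx = [k for k in acceptors if _is_acceptor(frame.atoms[k])]
        if not d_idx or not a_idx:
            continue
        a_pos = frame.coords[a_idx]
        for d in d_idx:
            d_pos = frame.coords[d]
            dist = np.linalg.norm(a_pos - d_pos, axis=1)
            near = np.flatnonzero(dist <= crit.d_cut_A)
            if near.size == 0:
                continue
            h_list = [] if distance_only else _attached_hydrogens(frame, d)
            for ai in near:
                acc = a_idx[ai]
                hit, h_name = False, None
                if distance_only or not h_list:
                    # donors with no attached hydrogen cannot satisfy the
                    # angular criterion; in distance-only mode every donor
                    # within the cutoff counts
                    hit = distance_only
                else:
                    for h in h_list:
                        if crit.angle_convention == "donor-vertex":
                            ang = _angle_deg(
                                frame.coords[h] - d_pos, frame.coords[acc] - d_pos
                            )
                        else:
                            ang = 180.0 - _angle_deg(
                                d_pos - frame.coords[h],
                                frame.coords[acc] - frame.coords[h],
                            )
                        if ang <= crit.angle_cut_deg:
                            hit, h_name = True, frame.atoms[h].name
                            break
                if hit:
                    da, aa = frame.atoms[d], frame.atoms[acc]
                    bonds.add(
                        BondInstance(
                            donor=da.atom_key,
                            acceptor=aa.atom_key,
                            donor_resname=da.resname,
                            acceptor_resname=aa.resname,
                            hydrogen=h_name,
                        )
                    )
    return bonds, distance_only


def detect_salt_bridges(
    frame: Frame,
    group_a: Sequence[int],
    group_b: Sequence[int],
    cutoff_A: float = 4.0,
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Salt bridges: side-chain O of Asp/Glu within ``cutoff_A`` of a
    side-chain N of Lys/Arg, collapsed to one bridge per residue pair."""
    ga, gb = set(map(int, group_a)), set(map(int, group_b))
    bridges: set[tuple[tuple[str, int], tuple[str, int]]] = set()
    for side1, side2 in ((ga, gb), (gb, ga)):
        o_idx = [
            k for k in side1
            if frame.atoms[k].name in _ACIDIC_O.get(frame.atoms[k].resname.upper(), set())
        ]
        n_idx = [
            k for k in side2
            if frame.atoms[k].name in _BASIC_N.get(frame.atoms[k].resname.upper(), set())
        ]
        for o in o_idx:
            for n in n_idx:
                if np.linalg.norm(frame.coords[o] - frame.coords[n]) <= cutoff_A:
                    bridges.add(
                        (frame.atoms[o].residue_key, frame.atoms[n].residue_key)
                    )
    return bridges


# --------------------------------------------------------------------------
# Rasters and occupancy


def build_raster(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    crit: HBondCriteria = HBondCriteria(),
) -> BondRaster:
    """Scan a trajectory and build the bond × frame survival raster.

    Rows are the union of bonds observed in any frame, keyed by heavy atoms;
    the ligand side (the ``i`` index) is the set of chains in ``group_a``.
    """
    if traj.n_frames == 0:
        raise StructureError("empty trajectory")
    per_frame: list[set] = []
    seen: dict = {}
    order: list[BondInstance] = []
    distance_only = False
    for fr in traj.frames:
        bonds, fallback = detect_hbonds(fr, group_a, group_b, crit)
        distance_only = distance_only or fallback
        keys = set()
        for b in sorted(bonds, key=lambda b: b.key):  # deterministic row order
            if b.key not in seen:
                seen[b.key] = b
                order.append(b)
            keys.add(b.key)
        per_frame.append(keys)
    if distance_only:
        warnings.warn(
            "no hydrogens present: hydrogen bonds detected by distance only",
            stacklevel=2,
        )
    ligand_chains = frozenset(traj.atoms[int(k)].chain for k in group_a)
    states = np.zeros((len(order), traj.n_frames), dtype=bool)
    for t, keys in enumerate(per_frame):
        for r, b in enumerate(order):
            if b.key in keys:
                states[r, t] = True
    # assign (i, j, l) indices in order of first appearance
    lig_res: list[tuple[str, int]] = []
    rec_res: list[tuple[str, int]] = []
    pair_count: dict[tuple[int, int], int] = {}
    final: list[BondInstance] = []
    for b in order:
        if b.donor[0] in ligand_chains:
            lres, rres = b.donor[:2], b.acceptor[:2]
        else:
            lres, rres = b.acceptor[:2], b.donor[:2]
        if lres not in lig_res:
            lig_res.append(lres)
        if rres not in rec_res:
            rec_res.append(rres)
        i, j = lig_res.index(lres), rec_res.index(rres)
        l = pair_count.get((i, j), 0)
        pair_count[(i, j)] = l + 1
        final.append(
            BondInstance(
                donor=b.donor, acceptor=b.acceptor,
                donor_resname=b.donor_resname, acceptor_resname=b.acceptor_resname,
                hydrogen=b.hydrogen, i=i, j=j, l=l,
            )
        )
    return BondRaster(
        final, states, dt_ns=traj.dt_ns,
        distance_only=distance_only, ligand_chains=ligand_chains,
    )


def occupancy(raster: BondRaster) -> pd.DataFrame:
    """Per-bond occupancies ω = (frames present)/(total frames).

    Returns a DataFrame with one row per bond instance: (i, j, l, ligand
    residue, receptor residue, donor, acceptor, occupancy) plus the
    residue-pair occupancy (fraction of frames in which any bond of that
    pair is present).
    """
    if raster.n_frames < 1:
        raise ValueError("raster must contain at least one frame")
    rows = []
    for b, row in zip(raster.bonds, raster.states):
        lig = b.donor if b.donor[0] in raster.ligand_chains else b.acceptor
        rec = b.acceptor if lig is b.donor else b.donor
        lig_name = b.donor_resname if lig is b.donor else b.acceptor_resname
        rec_name = b.acceptor_resname if rec is b.acceptor else b.donor_resname
        rows.append(
            {
                "i": b.i, "j": b.j, "l": b.l,
                "ligand_residue": f"{lig_name}{lig[1]}",
                "receptor_residue": f"{rec_name}{rec[1]}",
                "donor": ":".join(map(str, b.donor)),
                "acceptor": ":".join(map(str, b.acceptor)),
                "occupancy": row.mean(),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["i", "j", "l", "ligand_residue", "receptor_residue",
                 "donor", "acceptor", "occupancy"],
    )
    if len(df):
        pair_occ = {}
        for (i, j), grp in df.groupby(["i", "j"]):
            rows_idx = [
                k for k, b in enumerate(raster.bonds) if (b.i, b.j) == (i, j)
            ]
            pair_occ[(i, j)] = raster.states[rows_idx].any(axis=0).mean()
        df["pair_occupancy"] = [pair_occ[(i, j)] for i, j in zip(df["i"], df["j"])]
    else:
        df["pair_occupancy"] = pd.Series(dtype=float)
    return df


def nhb_series(raster: BondRaster) -> np.ndarray:
    """Per-frame interface hydrogen-bond count N_HB(t) (column sums)."""
    return raster.states.sum(axis=0).astype(int)
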