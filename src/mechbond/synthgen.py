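"""Synthetic fixture generation.

Everything the analysis modules consume can be generated here with known
ground truth: two-chain toy trajectories in which prescribed donor–H–
acceptor triplets satisfy the hydrogen-bond criteria in a scheduled
fraction of frames; rigid-motion-plus-jitter trajectories with closed-form
RMSD/RMSF; virtual-spring force-ramp traces with a designed rupture peak
(spring constant 13.9 pN/Å, pulling velocity 3 Å/ns by default); sphere
clusters with analytic SASA; and full multi-force replica sweeps whose
dissociation-probability curve is known in closed form.

All randomness is seed-controlled; identical seeds give bit-identical
fixtures.  Bond schedules use a deterministic block pattern by default, so
realised occupancies equal their targets up to 1/n_frames quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .structio import Atom, Frame, Trajectory

__all__ = [
    "BondSchedule",
    "SweepDesign",
    "SweepResult",
    "make_bond_states",
    "make_hbond_trajectory",
    "make_rigid_jitter_trajectory",
    "make_force_trace",
    "make_sweep",
    "make_ca_chain",
    "make_sphere_cluster",
    "catch_slip_profile",
    "RUN2_OCCUPANCIES",
]

#: equilibrium per-bond occupancies of the six dominant interface bonds
#: (most stable replica); used as the default base profile for sweeps
RUN2_OCCUPANCIES: tuple[float, ...] = (0.971, 0.719, 0.722, 0.539, 0.131, 0.179)

# on/off donor–acceptor distances of the toy geometry, Å
_D_ON = 2.9
_D_OFF = 5.0
_PAIR_SPACING = 20.0  # Å between scheduled residue pairs along x


@dataclass(frozen=True)
class BondSchedule:
    """Occupancy schedule for one interface bond of the toy system."""

    target_occupancy: float
    ligand_resid: int = 0
    receptor_resid: int = 0
    ligand_resname: str = "GLY"
    receptor_resname: str = "GLY"
    pattern: str = "block"  # 'block' | 'periodic' | 'bernoulli'
    phase_frames: int = 0  # start offset of the block pattern (wraps)

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_occupancy <= 1.0):
            raise ValueError("target occupancy must be in [0, 1]")
        if self.pattern not in ("block", "periodic", "bernoulli"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


def make_bond_states(
    schedules: Sequence[BondSchedule],
    n_frames: int,
    seed: int = 0,
) -> np.ndarray:
    """Boolean (bond × frame) on/off matrix realising the schedules.

    Block and periodic patterns are deterministic with realised on-fraction
    within 1/n_frames of the target; the Bernoulli pattern draws i.i.d.
    frames from the target probability.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    states = np.zeros((len(schedules), n_frames), dtype=bool)
    for r, sch in enumerate(schedules):
        w = sch.target_occupancy
        if sch.pattern == "block":
            m = int(round(w * n_frames))
            idx = (sch.phase_frames + np.arange(m)) % n_frames
            states[r, idx] = True
        elif sch.pattern == "periodic":
            t = np.arange(n_frames)
            states[r] = np.floor((t + 1) * w) > np.floor(t * w)
        else:
            states[r] = rng.random(n_frames) < w
    return states


def _residue_atoms(
    chain: str, resid: int, resname: str, serial0: int, base: np.ndarray, side: str
) -> tuple[list[Atom], np.ndarray]:
    """A glycine-like 5-atom residue (N, H on N, CA, C, O) near ``base``.

    The ligand residue points its N–H donor toward +y; the receptor residue
    presents its carbonyl O toward −y.  Spectator atoms are kept > 3.5 Å
    from the partner chain in every frame.
    """
    if side == "ligand":
        offsets = {
            "N": (0.0, 0.0, 0.0),
            "H": (0.0, 1.0, 0.0),
            "CA": (1.5, -1.0, 0.0),
            "C": (3.0, -1.5, 0.0),
            "O": (3.0, -3.0, 0.0),
        }
    else:
        offsets = {
            "O": (0.0, 0.0, 0.0),
            "C": (1.2, 1.0, 0.0),
            "CA": (2.5, 2.0, 0.0),
            "N": (4.0, 3.0, 0.0),
            "H": (4.0, 4.0, 0.0),
        }
    atoms, xyz = [], []
    for k, (name, off) in enumerate(offsets.items()):
        atoms.append(
            Atom(
                serial=serial0 + k,
                name=name,
                element="H" if name == "H" else name[0],
                resname=resname,
                resid=resid,
                chain=chain,
            )
        )
        xyz.append(base + np.asarray(off))
    return atoms, np.asarray(xyz)


def make_hbond_trajectory(
    schedules: Sequence[BondSchedule],
    n_frames: int,
    seed: int = 0,
    dt_ns: float = 0.04,
    label: str = "",
) -> Trajectory:
    """Two-chain toy trajectory realising the bond schedules.

    Chain ``L`` (ligand) and chain ``R`` (receptor) carry one glycine-like
    residue per scheduled bond.  In "on" frames the donor–H–acceptor triplet
    is collinear at d(D, A) = 2.9 Å; in "off" frames the receptor residue is
    displaced so d = 5.0 Å, violating the distance criterion under either
    angle convention.
    """
    schedules = list(schedules)
    if not schedules:
        raise ValueError("need at least one schedule")
    # assign default residue numbers and check for conflicts
    resolved: list[BondSchedule] = []
    for k, sch in enumerate(schedules):
        resolved.append(
            replace(
                sch,
                ligand_resid=sch.ligand_resid or 740 + k,
                receptor_resid=sch.receptor_resid or 354 + k,
            )
        )
    pairs = [(s.ligand_resid, s.receptor_resid) for s in resolved]
    if len(set(pairs)) != len(pairs):
        raise ValueError("conflicting schedules: duplicate residue pair")
    if len({p[0] for p in pairs}) != len(pairs) or len({p[1] for p in pairs}) != len(pairs):
        raise ValueError("conflicting schedules on the same residue's atoms")

    states = make_bond_states(resolved, n_frames, seed=seed)

    lig_atoms: list[Atom] = []
    lig_xyz: list[np.ndarray] = []
    rec_atoms: list[Atom] = []
    rec_xyz_on: list[np.ndarray] = []
    serial = 1
    rec_slices: list[slice] = []
    for k, sch in enumerate(resolved):
        base = np.array([k * _PAIR_SPACING, 0.0, 0.0])
        a, x = _residue_atoms("L", sch.ligand_resid, sch.ligand_resname, serial, base, "ligand")
        serial += len(a)
        lig_atoms.extend(a)
        lig_xyz.extend(x)
        a, x = _residue_atoms(
            "R", sch.receptor_resid, sch.receptor_resname, serial,
            base + np.array([0.0, _D_ON, 0.0]), "receptor",
        )
        serial += len(a)
        start = len(rec_atoms)
        rec_atoms.extend(a)
        rec_xyz_on.extend(x)
        rec_slices.append(slice(start, start + len(a)))

    atoms = lig_atoms + rec_atoms
    lig_block = np.asarray(lig_xyz)
    rec_block_on = np.asarray(rec_xyz_on)
    off_shift = np.array([0.0, _D_OFF - _D_ON, 0.0])

    frames: list[Frame] = []
    for t in range(n_frames):
        rec_block = rec_block_on.copy()
        for k, sl in enumerate(rec_slices):
            if not states[k, t]:
                rec_block[sl] += off_shift
        frames.append(Frame(list(atoms), np.vstack([lig_block, rec_block])))
    return Trajectory(frames, dt_ns=dt_ns, label=label)


def make_ca_chain(
    n_res: int = 10,
    chain: str = "A",
    spacing: float = 3.8,
    resname: str = "GLY",
    start_resid: int = 1,
) -> Frame:
    """A non-collinear Cα-only chain, one atom per residue."""
    atoms, xyz = [], []
    for k in range(n_res):
        atoms.append(
            Atom(
                serial=k + 1, name="CA", element="C", resname=resname,
                resid=start_resid + k, chain=chain,
            )
        )
        xyz.append((k * spacing, 1.5 * (k % 2), 0.7 * (k % 3)))
    return Frame(atoms, np.asarray(xyz, dtype=float))


def make_rigid_jitter_trajectory(
    base: Frame,
    n_frames: int,
    rotations: Sequence[np.ndarray] | None = None,
    translations: Sequence[np.ndarray] | None = None,
    jitter_sigma_A: float = 0.0,
    seed: int = 0,
    dt_ns: float = 1.0,
    label: str = "",
) -> Trajectory:
    """Frames = per-frame rigid motion of ``base`` plus isotropic Gaussian jitter."""
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_frames):
        xyz = base.coords.copy()
        if rotations is not None:
            xyz = xyz @ np.asarray(rotations[t]).T
        if translations is not None:
            xyz = xyz + np.asarray(translations[t])
        if jitter_sigma_A > 0:
            xyz = xyz + rng.normal(0.0, jitter_sigma_A, size=xyz.shape)
        frames.append(Frame(list(base.atoms), xyz))
    return Trajectory(frames, dt_ns=dt_ns, label=label)


def make_force_trace(
    peak_pN: float,
    peak_time_ns: float,
    k_pN_per_A: float = 13.9,
    v_A_per_ns: float = 3.0,
    dt_ns: float = 0.01,
    total_ns: float | None = None,
    decay_ns: float = 1.5,
    noise_sigma_pN: float = 0.0,
    seed: int = 0,
):
    """Spring-ramp force trace with a designed rupture peak.

    The force rises linearly (a compliant attachment under the virtual
    spring) to exactly ``peak_pN`` at ``peak_time_ns``, then decays
    exponentially toward zero after rupture.  The designed peak cannot
    exceed the stiff-spring bound k·v·t_peak (the attachment would need
    negative extension), which is rejected as an inconsistent design.
    At zero noise the global maximum is exactly (peak, peak time).
    """
    from .structio import ForceTrace

    if peak_pN <= 0 or peak_time_ns <= 0:
        raise ValueError("peak force and time must be positive")
    if peak_pN > k_pN_per_A * v_A_per_ns * peak_time_ns + 1e-9:
        raise ValueError(
            "inconsistent design: peak exceeds the stiff-spring ramp "
            f"k*v*t = {k_pN_per_A * v_A_per_ns * peak_time_ns:.1f} pN"
        )
    steps = round(peak_time_ns / dt_ns)
    if abs(steps * dt_ns - peak_time_ns) > 1e-9:
        raise ValueError("peak_time_ns must be a multiple of dt_ns")
    total = total_ns if total_ns is not None else peak_time_ns + 5.0 * decay_ns
    n = int(round(total / dt_ns)) + 1
    t = np.arange(n) * dt_ns
    f = np.where(
        t <= peak_time_ns,
        peak_pN * t / peak_time_ns,
        peak_pN * np.exp(-(t - peak_time_ns) / decay_ns),
    )
    # the sample after the peak must not tie it
    f[t > peak_time_ns] *= 1.0 - 1e-9
    if noise_sigma_pN > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sigma_pN, size=f.shape)
    return ForceTrace(t, f)


def make_sphere_cluster(
    positions: Sequence[Sequence[float]],
    elements: Sequence[str] | str = "O",
    chain: str = "A",
    resname: str = "SPH",
) -> Frame:
    """A frame of bare atoms at given positions (analytic SASA fixtures)."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if isinstance(elements, str):
        elements = [elements] * len(pos)
    atoms = [
        Atom(
            serial=k + 1, name=e, element=e, resname=resname,
            resid=k + 1, chain=chain,
        )
        for k, e in enumerate(elements)
    ]
    return Frame(atoms, pos)


# --------------------------------------------------------------------------
# Multi-force sweeps


def catch_slip_profile(
    force_pN: float,
    base: Sequence[float] = RUN2_OCCUPANCIES,
    strengthening: Mapping[float, float] | None = None,
) -> np.ndarray:
    """Default per-bond occupancy profile ω(f) with a catch–slip turn at 60 pN.

    Each bond's breakage probability (1 − ω) is scaled by a force-dependent
    factor s(f) that dips at 60 pN, so the closed-form mechano-regulation
    factor is f_D(f) = s(f)^n_bonds: below one, minimal at 60 pN, rising
    again at 80 pN — the biphasic catch–slip signature.
    """
    s = strengthening or {0.0: 1.0, 20.0: 0.8, 40.0: 0.6, 60.0: 0.4, 80.0: 0.7}
    if float(force_pN) not in s:
        raise KeyError(f"no strengthening factor defined for {force_pN} pN")
    w0 = np.asarray(base, dtype=float)
    return 1.0 - (1.0 - w0) * s[float(force_pN)]


@dataclass
class SweepDesign:
    """Design of a multi-force replica set.

    ``occupancy_profile`` maps a clamp force (pN) to the per-bond ω vector;
    the default emulates equilibrium occupancies strengthened toward a
    60 pN catch–slip turn point.
    """

    forces_pN: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0)
    occupancy_profile: Callable[[float], np.ndarray] = catch_slip_profile
    replicas: int = 3
    n_frames: int = 1000
    pattern: str = "bernoulli"
    seed: int = 0


@dataclass
class SweepResult:
    design: SweepDesign
    #: force → list of replica trajectories
    trajectories: dict[float, list[Trajectory]]
    #: force → designed per-bond occupancies
    design_omegas: dict[float, np.ndarray]
    #: force → closed-form P_D from the design (Π(1 − ω))
    design_P_D: dict[float, float]
    ligand_selection: str = "chain L"
    receptor_selection: str = "chain R"


def make_sweep(design: SweepDesign) -> SweepResult:
    """Generate per-force replica trajectories with closed-form ground truth."""
    rng = np.random.default_rng(design.seed)
    trajectories: dict[float, list[Trajectory]] = {}
    design_omegas: dict[float, np.ndarray] = {}
    design_P_D: dict[float, float] = {}
    for f in design.forces_pN:
        omegas = np.asarray(design.occupancy_profile(f), dtype=float)
        design_omegas[f] = omegas
        design_P_D[f] = float(np.prod(1.0 - omegas))
        reps = []
        for r in range(design.replicas):
            schedules = [
                BondSchedule(target_occupancy=w, pattern=design.pattern)
                for w in omegas
            ]
            sub_seed = int(rng.integers(0, 2**31 - 1))
            reps.append(
                make_hbond_trajectory(
                    schedules, design.n_frames, seed=sub_seed,
                    label=f"f{f:g}_rep{r + 1}",
                )
            )
        trajectories[f] = reps
    return SweepResult(
        design=design,
        trajectories=trajectories,
        design_omegas=design_omegas,
        design_P_D=design_P_D,
    )
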