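"""Superposition-based and vector-based structural descriptors.

Covers the standard trajectory descriptors: Kabsch least-squares
superposition, Cα-RMSD time series, per-residue RMSF about the iteratively
fitted mean structure, inter-atom distance series (e.g. the Cα–Cα distance
L_F between a β-strand and a helix anchor), principal-axis angles between
secondary-structure segments (θ), and the cross angle of two Cα–Cα lines
(the turn angle γ).  All angles are reported on [0°, 90°], the cross angle
of undirected lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import Trajectory

__all__ = [
    "SuperpositionResult",
    "DescriptorSeries",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "atom_distance_series",
    "segment_axis",
    "interaxis_angle_series",
    "turn_angle_series",
]


class DegenerateGeometryError(ValueError):
    """Fit/axis geometry too degenerate (collinear or coincident points)."""


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd_A: float


@dataclass
class DescriptorSeries:
    """A named per-frame scalar descriptor (time in ns)."""

    t_ns: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.t_ns = np.asarray(self.t_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_ns.shape != self.values.shape:
            raise ValueError("t_ns and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite descriptor values")


def _check_fit_set(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] < 1e-9 or s[1] / s[0] < 1e-9:
        raise DegenerateGeometryError("fit atoms are coincident or collinear")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Sequence[int] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections corrected), translation and the
    RMSD over the fit set after the transform.  The transform maps mobile
    coordinates as ``x @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal shapes")
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices)
    mob, ref = mobile[idx], reference[idx]
    _check_fit_set(mob)
    _check_fit_set(ref)
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd_A=rmsd)


def _apply(sup: SuperpositionResult, coords: np.ndarray) -> np.ndarray:
    return coords @ sup.rotation.T + sup.translation


def rmsd_series(
    traj: Trajectory,
    fit_selection: Sequence[int],
    measure_selection: Sequence[int] | None = None,
    reference_frame: int = 0,
) -> DescriptorSeries:
    """Per-frame RMSD over ``measure_selection`` after fitting on ``fit_selection``."""
    fit = np.asarray(fit_selection, dtype=int)
    meas = fit if measure_selection is None else np.asarray(measure_selection, dtype=int)
    if fit.size == 0 or meas.size == 0:
        raise ValueError("selections must be non-empty")
    ref = traj.frames[reference_frame].coords
    out = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        sup = kabsch_superpose(fr.coords[fit], ref[fit])
        moved = _apply(sup, fr.coords[meas])
        out[k] = np.sqrt(np.mean(np.sum((moved - ref[meas]) ** 2, axis=1)))
    return DescriptorSeries(traj.times_ns, out, name="rmsd_A")


def rmsf(
    traj: Trajectory,
    selection: Sequence[int],
    n_iter: int = 2,
    reference: str = "mean",
) -> np.ndarray:
    """Per-atom RMS fluctuation about the mean structure, Å.

    Frames are superposed (over ``selection``) onto an iteratively refined
    mean structure (``n_iter`` passes; ``reference='first'`` fits to the
    first frame instead).  Returns one value per selected atom; a rigid
    motion applied to every frame leaves the result unchanged.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.asarray(selection, dtype=int)
    coords = traj.coords_array()[:, sel, :]
    ref = coords[0]
    iters = 1 if reference == "first" else max(1, n_iter)
    fitted = coords
    for _ in range(iters):
        fitted = np.empty_like(coords)
        for k in range(coords.shape[0]):
            sup = kabsch_superpose(coords[k], ref)
            fitted[k] = _apply(sup, coords[k])
        if reference == "first":
            break
        ref = fitted.mean(axis=0)
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def atom_distance_series(
    traj: Trajectory, atom_a: int, atom_b: int, name: str = "L_F_A"
) -> DescriptorSeries:
    """Euclidean distance between two atoms, per frame (Å)."""
    n = traj.n_atoms
    for idx in (atom_a, atom_b):
        if not (0 <= idx < n):
            raise IndexError(f"atom index {idx} outside trajectory ({n} atoms)")
    xyz = traj.coords_array()
    d = np.linalg.norm(xyz[:, atom_a, :] - xyz[:, atom_b, :], axis=1)
    return DescriptorSeries(traj.times_ns, d, name=name)


def segment_axis(coords: np.ndarray) -> np.ndarray:
    """Principal axis of a run of Cα coordinates (unit vector).

    The sign is fixed toward increasing residue order (first → last point).
    Raises :class:`DegenerateGeometryError` when the leading principal
    direction is not clearly dominant (e.g. planar isotropic scatter).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("segment needs at least 3 points")
    centered = coords - coords.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9 or (s[0] - s[1]) / s[0] < 0.05:
        raise DegenerateGeometryError("segment axis ill-conditioned")
    axis = vt[0]
    chain_dir = coords[-1] - coords[0]
    if np.dot(axis, chain_dir) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _cross_angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("zero-length direction vector")
    c = abs(float(np.dot(v1, v2) / (n1 * n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def interaxis_angle_series(
    traj: Trajectory,
    segment_a: Sequence[int],
    segment_b: Sequence[int],
    name: str = "theta_deg",
) -> DescriptorSeries:
    """Angle between the principal axes of two segments, per frame, [0°, 90°]."""
    sa = np.asarray(segment_a, dtype=int)
    sb = np.asarray(segment_b, dtype=int)
    out = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        out[k] = _cross_angle_deg(
            segment_axis(fr.coords[sa]), segment_axis(fr.coords[sb])
        )
    return DescriptorSeries(traj.times_ns, out, name=name)


def turn_angle_series(
    traj: Trajectory,
    line1: tuple[int, int],
    line2: tuple[int, int],
    name: str = "gamma_deg",
) -> DescriptorSeries:
    """Cross angle of two Cα–Cα lines, per frame, [0°, 90°].

    ``line1``/``line2`` are (atom index, atom index) endpoint pairs, e.g.
    the Cα atoms flanking a β-strand turn.
    """
    (a1, a2), (b1, b2) = line1, line2
    out = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        v1 = fr.coords[a2] - fr.coords[a1]
        v2 = fr.coords[b2] - fr.coords[b1]
        out[k] = _cross_angle_deg(v1, v2)
    return DescriptorSeries(traj.times_ns, out, name=name)
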