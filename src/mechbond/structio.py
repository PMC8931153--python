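"""Structure/trajectory I/O, atom selections, and force-trace parsing.

Trajectories are multi-model PDB files (wwPDB v3.3 fixed columns); every
model must present the same atoms in the same order, which is what all
downstream per-frame analyses rely on.  Force traces are two-column
plain-text (time, force) files as written by pulling-simulation tools.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "ForceTrace",
    "ParseError",
    "StructureError",
    "SelectionSyntaxError",
    "TraceValidationError",
    "read_pdb_models",
    "write_pdb_models",
    "select",
    "read_force_trace",
    "write_force_trace",
]


class ParseError(ValueError):
    """Unparseable field in an input file; message carries the line number."""


class StructureError(ValueError):
    """Structurally inconsistent trajectory (atom count/order mismatch)."""


class SelectionSyntaxError(ValueError):
    """Malformed selection expression; message carries the character position."""


class TraceValidationError(ValueError):
    """Force trace violating the (strictly increasing time, finite) contract."""


@dataclass(frozen=True)
class Atom:
    """A single atom record; residue numbers are kept verbatim from the file."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.resid)

    @property
    def atom_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.name)


@dataclass
class Frame:
    """Ordered atoms plus an (n_atoms, 3) coordinate array in Å."""

    atoms: list[Atom]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class Trajectory:
    """An ordered list of frames sharing one atom ordering.

    Parameters
    ----------
    frames:
        Frames with identical atom sequences (serial/name/resid/chain).
    dt_ns:
        Frame spacing in nanoseconds (metadata only).
    label:
        Free-text run identifier.
    """

    frames: list[Frame]
    dt_ns: float = 1.0
    label: str = ""
    hydrogens_missing: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        ref = [a.atom_key for a in self.frames[0].atoms]
        for m, fr in enumerate(self.frames[1:], start=2):
            keys = [a.atom_key for a in fr.atoms]
            if keys != ref:
                if len(keys) != len(ref):
                    raise StructureError(
                        f"model {m} has {len(keys)} atoms, expected {len(ref)}"
                    )
                raise StructureError(f"model {m} atom ordering differs from model 1")
        self.hydrogens_missing = not any(
            a.element == "H" for a in self.frames[0].atoms
        )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def atoms(self) -> list[Atom]:
        return self.frames[0].atoms

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ns

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coords for fr in self.frames])


@dataclass
class ForceTrace:
    """A (time, force) series from a pulling simulation, pN vs ns."""

    t_ns: np.ndarray
    f_pN: np.ndarray

    def __post_init__(self) -> None:
        self.t_ns = np.asarray(self.t_ns, dtype=float)
        self.f_pN = np.asarray(self.f_pN, dtype=float)
        if self.t_ns.shape != self.f_pN.shape or self.t_ns.ndim != 1:
            raise TraceValidationError("time and force arrays must be equal-length 1-D")
        if self.t_ns.size < 2:
            raise TraceValidationError("force trace needs at least 2 samples")
        if not (np.all(np.isfinite(self.t_ns)) and np.all(np.isfinite(self.f_pN))):
            raise TraceValidationError("non-finite values in force trace")
        if not np.all(np.diff(self.t_ns) > 0):
            raise TraceValidationError("time axis must be strictly increasing")

    @property
    def n(self) -> int:
        return self.t_ns.size

    @property
    def dt_ns(self) -> float:
        return float(np.median(np.diff(self.t_ns)))


# --------------------------------------------------------------------------
# PDB reading/writing

_TWO_LETTER_ELEMENTS = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "CU", "SE", "K",
}


def _infer_element(name: str, resname: str) -> str:
    """Infer the element from an atom name (MD-written PDBs often omit it)."""
    stripped = name.strip()
    # names like "1HB" put the digit first
    alpha = re.sub(r"^[0-9]+", "", stripped)
    if not alpha:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if alpha[:2].upper() in _TWO_LETTER_ELEMENTS and resname.strip().upper() == alpha[:2].upper():
        # monatomic ions name the atom after the residue (e.g. NA/NA)
        return alpha[:2].upper().capitalize()
    return alpha[0].upper()


def _coerce_stream(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    text = str(source)
    if "\n" not in text and Path(text).exists():
        return open(text)
    return io.StringIO(text)


def read_pdb_models(source, dt_ns: float = 1.0, label: str = "") -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    ``source`` may be a path, PDB text, or an open text stream.  MODEL/ENDMDL
    cards delimit frames; a file without MODEL cards is a single frame.
    ATOM and HETATM records are parsed by fixed columns.
    """
    stream = _coerce_stream(source)
    frames: list[Frame] = []
    atoms: list[Atom] = []
    xyz: list[tuple[float, float, float]] = []
    in_model = False
    saw_model_card = False

    def flush(model_no: int, require_atoms: bool = False) -> None:
        if atoms:
            frames.append(Frame(list(atoms), np.array(xyz)))
            atoms.clear()
            xyz.clear()
        elif require_atoms:
            raise StructureError(f"model {model_no} contains no atoms")

    model_no = 0
    for lineno, raw in enumerate(stream, start=1):
        rec = raw[:6].strip().upper()
        if rec == "MODEL":
            if in_model:
                raise StructureError(f"nested MODEL card at line {lineno}")
            in_model = True
            saw_model_card = True
            model_no += 1
        elif rec == "ENDMDL":
            in_model = False
            flush(model_no, require_atoms=True)
        elif rec in ("ATOM", "HETATM"):
            line = raw.rstrip("\n")
            if len(line) < 54:
                raise ParseError(f"line {lineno}: ATOM record shorter than 54 columns")
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip()
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: unparseable field ({exc})") from None
            occ_s = line[54:60].strip()
            bfac_s = line[60:66].strip()
            elem = line[76:78].strip() if len(line) >= 78 else ""
            if not elem:
                elem = _infer_element(name, resname)
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=elem.capitalize() if len(elem) > 1 else elem.upper(),
                    resname=resname,
                    resid=resid,
                    chain=chain,
                    occupancy=float(occ_s) if occ_s else 1.0,
                    bfactor=float(bfac_s) if bfac_s else 0.0,
                )
            )
            xyz.append((x, y, z))
    # trailing atoms (file without MODEL cards, or unterminated final model)
    flush(model_no if saw_model_card else 1)
    if not frames:
        raise StructureError("no ATOM records found")
    try:
        return Trajectory(frames, dt_ns=dt_ns, label=label)
    finally:
        if stream is not source:
            stream.close()


def write_pdb_models(traj: Trajectory, stream=None) -> str | None:
    """Write a trajectory as multi-model PDB text (coordinates to 3 decimals).

    Returns the text when ``stream`` is None, otherwise writes to the stream
    (or path) and returns None.
    """
    out = io.StringIO()
    multi = traj.n_frames > 1
    for m, fr in enumerate(traj.frames, start=1):
        if multi:
            out.write(f"MODEL     {m:4d}\n")
        for a, (x, y, z) in zip(fr.atoms, fr.coords):
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            out.write(
                f"ATOM  {a.serial:5d} {name:<4s} {a.resname:<3s} {a.chain:1s}"
                f"{a.resid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}\n"
            )
        if multi:
            out.write("ENDMDL\n")
    out.write("END\n")
    text = out.getvalue()
    if stream is None:
        return text
    if hasattr(stream, "write"):
        stream.write(text)
    else:
        Path(stream).write_text(text)
    return None


# --------------------------------------------------------------------------
# Atom selections
#
# Grammar:  expr := term ("or" term)* ; term := factor ("and" factor)*
#           factor := "(" expr ")" | "not" factor | primitive
#           primitive := name A [B ...] | resname A [...] | chain A [...]
#                        | resid N | resid A-B | resid A to B | resid N1 N2 ...

_KEYWORDS = {"and", "or", "not", "name", "resname", "chain", "resid", "to", "(", ")"}


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        m = re.match(r"[^\s()]+", expr[i:])
        tokens.append((m.group(0), i))
        i += len(m.group(0))
    return tokens


class _SelParser:
    def __init__(self, expr: str, atoms: Sequence[Atom]):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.atoms = atoms

    def fail(self, msg: str) -> None:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expr)
        raise SelectionSyntaxError(f"{msg} at position {at} in {self.expr!r}")

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            self.fail("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr_()
        if self.pos != len(self.tokens):
            self.fail("unexpected token")
        return mask

    def expr_(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "(":
            self.take()
            mask = self.expr_()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.take()
            return mask
        if tok == "not":
            self.take()
            return ~self.factor()
        return self.primitive()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            self.fail("expected at least one value")
        return vals

    def primitive(self) -> np.ndarray:
        key = self.take()
        if key == "name":
            wanted = set(self._values())
            return np.array([a.name in wanted for a in self.atoms])
        if key == "resname":
            wanted = {v.upper() for v in self._values()}
            return np.array([a.resname.upper() in wanted for a in self.atoms])
        if key == "chain":
            wanted = set(self._values())
            return np.array([a.chain in wanted for a in self.atoms])
        if key == "resid":
            return self._resid()
        self.fail(f"unknown keyword {key!r}")

    def _resid(self) -> np.ndarray:
        vals = self._values()
        # "resid A to B" spelled as separate tokens
        if len(vals) == 3 and vals[1] == "to":
            vals = [f"{vals[0]}-{vals[2]}"]
        wanted: set[int] = set()
        for v in vals:
            m = re.fullmatch(r"(-?\d+)[-:](-?\d+)", v)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if lo > hi:
                    self.fail(f"empty resid range {v!r}")
                wanted.update(range(lo, hi + 1))
            else:
                try:
                    wanted.add(int(v))
                except ValueError:
                    self.fail(f"bad resid token {v!r}")
        return np.array([a.resid in wanted for a in self.atoms])


def select(traj: Trajectory | Frame, expr: str) -> np.ndarray:
    """Resolve a selection expression to a sorted array of 0-based atom indices.

    Supports ``name``, ``resname``, ``chain`` and ``resid`` primitives (the
    latter with single values, ``A-B`` / ``A to B`` ranges and lists),
    combined with ``and`` / ``or`` / ``not`` and parentheses.  Deterministic
    and idempotent; an empty selection is allowed.
    """
    atoms = traj.atoms if isinstance(traj, Trajectory) else traj.atoms
    mask = _SelParser(expr, atoms).parse()
    return np.flatnonzero(mask)


def resolve_atom(traj: Trajectory, chain: str, resid: int, name: str) -> int:
    """Return the index of a single named atom, or raise naming the residue."""
    for i, a in enumerate(traj.atoms):
        if a.chain == chain and a.resid == resid and a.name == name:
            return i
    raise KeyError(f"atom {name} of residue {chain}:{resid} not found")


# --------------------------------------------------------------------------
# Force traces


def read_force_trace(
    source,
    time_col: int = 0,
    force_col: int = 1,
) -> ForceTrace:
    """Parse a plain-text force trace (whitespace- or comma-delimited).

    Lines starting with ``#`` are comments.  Column roles are configurable
    through ``time_col``/``force_col``.
    """
    stream = _coerce_stream(source)
    rows: list[tuple[float, float]] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) <= max(time_col, force_col):
                raise ParseError(f"line {lineno}: expected at least "
                                 f"{max(time_col, force_col) + 1} columns")
            try:
                rows.append((float(parts[time_col]), float(parts[force_col])))
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric field") from None
    finally:
        if stream is not source:
            stream.close()
    if len(rows) < 2:
        raise TraceValidationError("force trace needs at least 2 rows")
    arr = np.array(rows)
    return ForceTrace(arr[:, 0], arr[:, 1])


def write_force_trace(trace: ForceTrace, stream=None, header: str = "t_ns f_pN") -> str | None:
    out = io.StringIO()
    if header:
        out.write(f"# {header}\n")
    for t, f in zip(trace.t_ns, trace.f_pN):
        out.write(f"{t:.6g} {f:.6g}\n")
    text = out.getvalue()
    if stream is None:
        return text
    if hasattr(stream, "write"):
        stream.write(text)
    else:
        Path(stream).write_text(text)
    return None
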