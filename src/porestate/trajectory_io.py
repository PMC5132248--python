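"""Trajectory reading/writing and atom selection.

Two on-disk dialects are supported: GROMACS TRR (through MDAnalysis, which
converts nm → Å and reports times in ps) and a plain-text dialect used for
fixtures and synthetic data::

    #frames N atoms M
    t <time_ps>
    x y z          (M lines, Å, fixed atom order)
    t <time_ps>
    ...

Frames are streamed lazily; multiple files are concatenated in the given
order with a globally increasing frame index.  No periodic-boundary
unwrapping is performed: the pore region is assumed whole in every frame.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Selections",
    "TrajectoryError",
    "SelectionError",
    "read_trajectory",
    "read_plaintext",
    "write_plaintext",
    "read_trr",
    "write_trr",
    "resolve_selection",
    "make_topology",
]


class TrajectoryError(RuntimeError):
    """Unreadable, truncated or empty trajectory input."""


class SelectionError(ValueError):
    """Malformed selection expression or a selection matching nothing."""


@dataclass
class Frame:
    """One trajectory snapshot: positions in Å, time in ps."""

    index: int
    time: float
    positions: np.ndarray  # (n_atoms, 3) float64, Å
    box: np.ndarray | None = None  # (3, 3) lattice vectors, Å

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"non-finite coordinates in frame {self.index}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Selections:
    """Resolved atom-index sets for the pore-axis bases and the ions."""

    basis_from: list[int]
    basis_to: list[int]
    ions: list[int]
    species_label: str = "K"

    def __post_init__(self) -> None:
        for name in ("basis_from", "basis_to", "ions"):
            idx = getattr(self, name)
            if len(idx) != len(set(idx)):
                raise ValueError(f"duplicate atom indices in {name}")
        if not self.basis_from or not self.basis_to:
            raise ValueError("axis basis sets must be non-empty")
        ions = set(self.ions)
        if ions & set(self.basis_from) or ions & set(self.basis_to):
            raise ValueError("ion selection overlaps an axis basis set")


# ---------------------------------------------------------------------------
# plain-text dialect
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^#frames\s+(\d+)\s+atoms\s+(\d+)\s*$")


def write_plaintext(frames: Iterable[Frame], path: str | Path) -> int:
    """Write frames to the plain-text dialect; returns the frame count.

    Coordinates are written with repr-level precision (%.17g) so the
    read-back is bit-identical.
    """
    frames = list(frames)
    if not frames:
        raise TrajectoryError("refusing to write an empty trajectory")
    n_atoms = frames[0].n_atoms
    with open(path, "w") as fh:
        fh.write(f"#frames {len(frames)} atoms {n_atoms}\n")
        for fr in frames:
            if fr.n_atoms != n_atoms:
                raise TrajectoryError(
                    f"frame {fr.index} has {fr.n_atoms} atoms, expected {n_atoms}"
                )
            fh.write(f"t {fr.time:.17g}\n")
            for x, y, z in fr.positions:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
    return len(frames)


def read_plaintext(path: str | Path, start_index: int = 0) -> Iterator[Frame]:
    """Lazily yield frames from a plain-text trajectory file.

    Errors carry the 1-based line number of the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if header == "":
            raise TrajectoryError(f"{path}: empty trajectory file")
        m = _HEADER_RE.match(header)
        if m is None:
            raise TrajectoryError(f"{path}:1: malformed header {header.strip()!r}")
        n_frames, n_atoms = int(m.group(1)), int(m.group(2))
        lineno = 1
        for k in range(n_frames):
            tline = fh.readline()
            lineno += 1
            if tline == "":
                raise TrajectoryError(
                    f"{path}: truncated at frame {start_index + k} "
                    f"(expected {n_frames} frames)"
                )
            if not tline.startswith("t "):
                raise TrajectoryError(f"{path}:{lineno}: expected time line, got {tline.strip()!r}")
            try:
                time = float(tline[2:])
            except ValueError as exc:
                raise TrajectoryError(f"{path}:{lineno}: bad time value") from exc
            pos = np.empty((n_atoms, 3), dtype=float)
            for a in range(n_atoms):
                row = fh.readline()
                lineno += 1
                if row == "" or row.startswith("t "):
                    raise TrajectoryError(
                        f"{path}:{lineno}: frame {start_index + k} missing atom row "
                        f"{a} of {n_atoms}"
                    )
                parts = row.split()
                if len(parts) != 3:
                    raise TrajectoryError(f"{path}:{lineno}: expected 3 coordinates")
                try:
                    pos[a] = [float(p) for p in parts]
                except ValueError as exc:
                    raise TrajectoryError(f"{path}:{lineno}: bad coordinate") from exc
            yield Frame(index=start_index + k, time=time, positions=pos)


# ---------------------------------------------------------------------------
# TRR via MDAnalysis
# ---------------------------------------------------------------------------


def read_trr(path: str | Path, start_index: int = 0) -> Iterator[Frame]:
    """Lazily yield frames from a GROMACS TRR file (positions Å, time ps)."""
    from MDAnalysis.coordinates.TRR import TRRReader

    path = Path(path)
    try:
        reader = TRRReader(str(path))
    except Exception as exc:  # pragma: no cover - reader-specific
        raise TrajectoryError(f"{path}: unreadable TRR file ({exc})") from exc
    with reader:
        for k, ts in enumerate(reader):
            yield Frame(
                index=start_index + k,
                time=float(ts.time),
                positions=np.asarray(ts.positions, dtype=float),
            )


def write_trr(frames: Iterable[Frame], path: str | Path) -> int:
    """Write frames to TRR (single precision on disk, ~1e-3 Å round trip)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.TRR import TRRWriter

    frames = list(frames)
    if not frames:
        raise TrajectoryError("refusing to write an empty trajectory")
    n_atoms = frames[0].n_atoms
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with TRRWriter(str(path), n_atoms=n_atoms) as w:
        for fr in frames:
            u.atoms.positions = fr.positions
            u.trajectory.ts.time = fr.time
            u.trajectory.ts.frame = fr.index
            w.write(u.atoms)
    return len(frames)


def read_trajectory(
    paths: Sequence[str | Path] | str | Path,
    format: str = "plaintext",
) -> Iterator[Frame]:
    """Stream frames from one or more trajectory files, concatenated in order.

    Frame indices increase globally across files; duplicate boundary frames
    between segments are not detected (user's responsibility, as with
    GROMACS segment outputs).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise TrajectoryError("no trajectory files given")
    readers = {"plaintext": read_plaintext, "trr": read_trr}
    try:
        reader = readers[format]
    except KeyError:
        raise TrajectoryError(
            f"unknown trajectory format {format!r}; expected one of {sorted(readers)}"
        ) from None
    index = 0
    yielded = False
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise TrajectoryError(f"trajectory file not found: {p}")
        for fr in reader(p, start_index=index):
            yielded = True
            index = fr.index + 1
            yield fr
    if not yielded:
        raise TrajectoryError("trajectory stream is empty")


# ---------------------------------------------------------------------------
# atom selection over a topology table
# ---------------------------------------------------------------------------


def make_topology(
    names: Sequence[str],
    resids: Sequence[int],
    resnames: Sequence[str],
) -> pd.DataFrame:
    """Build the atom-metadata table consumed by :func:`resolve_selection`."""
    return pd.DataFrame({"name": list(names), "resid": list(resids), "resname": list(resnames)})


_FIELDS = ("name", "resid", "resname")
_KEYWORDS = {"and", "or", "not", "(", ")"}


def _tokenize(expr: str) -> list[str]:
    return expr.replace("(", " ( ").replace(")", " ) ").split()


class _SelParser:
    """Recursive-descent parser for ``name K``, ``resid 374 377``, and/or/not."""

    def __init__(self, tokens: list[str], top: pd.DataFrame):
        self.toks = tokens
        self.i = 0
        self.top = top

    def peek(self) -> str | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.predicate()

    def predicate(self) -> np.ndarray:
        fld = self.next()
        if fld not in _FIELDS:
            raise SelectionError(
                f"unknown selection field {fld!r}; expected one of {_FIELDS}"
            )
        values: list[str] = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            values.append(self.next())
        if not values:
            raise SelectionError(f"field {fld!r} given without values")
        col = self.top[fld]
        if fld == "resid":
            try:
                vals = {int(v) for v in values}
            except ValueError as exc:
                raise SelectionError(f"non-integer resid in {values}") from exc
            return col.isin(vals).to_numpy()
        return col.isin(set(values)).to_numpy()


def resolve_selection(spec: str, topology: pd.DataFrame) -> list[int]:
    """Resolve a selection expression to an order-preserving atom index list.

    Grammar: ``predicate := (name|resid|resname) value [value ...]``,
    combined with ``and``, ``or``, ``not`` and parentheses.  Zero matches is
    an error (an empty basis or ion set is never meaningful downstream).
    """
    missing = [f for f in _FIELDS if f not in topology.columns]
    if missing:
        raise SelectionError(f"topology table lacks columns {missing}")
    tokens = _tokenize(spec)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, topology).parse()
    idx = list(np.flatnonzero(mask))
    if not idx:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return [int(i) for i in idx]
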