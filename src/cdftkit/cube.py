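"""Gaussian-cube scalar fields: container, reader and writer.

The cube format stores a scalar field (here: electron density or fields
derived from it) on a regular, possibly non-orthogonal voxel grid together
with the molecular geometry.  Layout: two comment lines; one line with the
atom count and grid origin; three lines with the voxel count and step vector
of each grid axis; one line per atom (atomic number, nuclear charge,
position); then the values, up to six per line, with the *last* grid axis
varying fastest.  All lengths are in bohr.  A negative atom count (the
convention some codes use to flag an extra orbital-index line after the
atoms) is accepted on read; the extra line is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Union

import numpy as np

from .exceptions import ParseError, ValidationError

__all__ = ["Atom", "ScalarField", "read_cube", "write_cube"]

_VALUES_PER_LINE = 6
_VALUE_FMT = "%16.8E"


@dataclass(frozen=True)
class Atom:
    """One cube-file atom line: atomic number, nuclear charge, position (bohr)."""

    number: int
    charge: float
    position: tuple[float, float, float]


@dataclass(frozen=True)
class ScalarField:
    """A scalar field sampled on a regular voxel grid.

    Attributes
    ----------
    origin : ndarray, shape (3,)
        Position of the first voxel, bohr.
    axes : ndarray, shape (3, 3)
        Voxel step vectors, one per row, bohr.  Their determinant (the voxel
        volume) must be positive.
    counts : tuple of 3 ints
        Voxels along each axis, all >= 1.
    atoms : tuple of Atom
        Molecular geometry carried in the header.
    values : ndarray, shape ``counts``
        Field values; the last axis is the fastest-varying one on disk.
    """

    origin: np.ndarray
    axes: np.ndarray
    counts: tuple[int, int, int]
    atoms: tuple[Atom, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )
        if self.origin.shape != (3,):
            raise ValidationError("origin must be a 3-vector")
        if self.axes.shape != (3, 3):
            raise ValidationError("axes must be three 3-vectors")
        if len(self.counts) != 3 or any(c < 1 for c in self.counts):
            raise ValidationError(f"counts must be 3 positive ints, got {self.counts}")
        if self.values.shape != self.counts:
            raise ValidationError(
                f"values shape {self.values.shape} != counts {self.counts}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("field values must be finite")
        if self.voxel_volume <= 0:
            raise ValidationError("voxel volume (det of axes) must be > 0")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, bohr^3 (determinant of the axes matrix)."""
        return float(np.linalg.det(self.axes))

    def with_values(self, values: np.ndarray) -> "ScalarField":
        """Same grid and atoms, new values (geometry-preserving)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def same_geometry(self, other: "ScalarField") -> bool:
        return (
            self.counts == other.counts
            and np.array_equal(self.origin, other.origin)
            and np.array_equal(self.axes, other.axes)
            and self.atoms == other.atoms
        )


def _tokens(source: Union[str, Path, IO[str]]) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    return Path(source).read_text().splitlines()


def read_cube(source: Union[str, Path, IO[str]]) -> ScalarField:
    """Read a Gaussian cube file into a :class:`ScalarField`.

    Raises :class:`~cdftkit.exceptions.ParseError` (with a line number) on
    malformed numeric tokens and when the number of stored values does not
    match the voxel counts.
    """
    lines = _tokens(source)
    if len(lines) < 6:
        raise ParseError("cube file truncated: fewer than 6 lines")

    def floats(lineno: int) -> list[float]:
        try:
            return [float(tok) for tok in lines[lineno].split()]
        except ValueError as exc:
            raise ParseError(f"line {lineno + 1}: non-numeric token") from exc

    header = floats(2)
    if len(header) < 4:
        raise ParseError("line 3: expected atom count and origin")
    natoms_signed = int(header[0])
    natoms = abs(natoms_signed)
    origin = np.array(header[1:4])

    counts = []
    axes = []
    for i in range(3):
        row = floats(3 + i)
        if len(row) < 4:
            raise ParseError(f"line {4 + i}: expected count and axis vector")
        counts.append(int(row[0]))
        axes.append(row[1:4])
    counts = tuple(counts)

    atoms = []
    for i in range(natoms):
        row = floats(6 + i)
        if len(row) < 5:
            raise ParseError(f"line {7 + i}: expected atom line with 5 fields")
        atoms.append(Atom(int(row[0]), row[1], tuple(row[2:5])))

    first_value_line = 6 + natoms
    if natoms_signed < 0:
        first_value_line += 1  # orbital-index line, skipped

    values: list[float] = []
    for lineno in range(first_value_line, len(lines)):
        if lines[lineno].strip():
            values.extend(floats(lineno))
    expected = counts[0] * counts[1] * counts[2]
    if len(values) != expected:
        raise ParseError(
            f"value count {len(values)} does not match grid size {expected}"
        )
    grid = np.array(values).reshape(counts)  # C order: last axis fastest
    return ScalarField(origin=origin, axes=np.array(axes), counts=counts,
                       atoms=atoms, values=grid)


def write_cube(
    fieldobj: ScalarField,
    sink: Union[str, Path, IO[str]],
    comment: str = "cdftkit scalar field",
    comment2: str = "",
) -> None:
    """Write a :class:`ScalarField` as a Gaussian cube file.

    Values are emitted six per line in fixed scientific notation at a
    precision that re-reads within 1e-6 relative.  At least one atom is
    required (an atomless cube header is rejected by common viewers); pass a
    dummy atom for purely synthetic fields.  Output is byte-deterministic
    for identical fields and comments.
    """
    if not isinstance(fieldobj, ScalarField):
        raise ValidationError("write_cube expects a ScalarField")
    if len(fieldobj.atoms) == 0:
        raise ValidationError("cube output requires at least one atom")

    out = []
    out.append(comment)
    out.append(comment2)
    ox, oy, oz = fieldobj.origin
    out.append(f"{len(fieldobj.atoms):5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}")
    for count, axis in zip(fieldobj.counts, fieldobj.axes):
        out.append(f"{count:5d}{axis[0]:12.6f}{axis[1]:12.6f}{axis[2]:12.6f}")
    for atom in fieldobj.atoms:
        x, y, z = atom.position
        out.append(
            f"{atom.number:5d}{atom.charge:12.6f}{x:12.6f}{y:12.6f}{z:12.6f}"
        )
    flat = fieldobj.values.reshape(-1)
    for start in range(0, flat.size, _VALUES_PER_LINE):
        chunk = flat[start:start + _VALUES_PER_LINE]
        out.append("".join(_VALUE_FMT % v for v in chunk))
    text = "\n".join(out) + "\n"

    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)
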