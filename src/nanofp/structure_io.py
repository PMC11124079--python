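"""Readers and writers for the structure formats the toolset touches.

Three plain-text formats are supported:

* **XYZ** — line 1: atom count, line 2: free comment, then one
  ``Symbol x y z`` line per atom. Extra per-line columns (e.g. a
  core/shell label) are ignored on read.
* **labelled XYZ** — standard XYZ with a trailing ``core``/``shell``
  column per atom line.
* **GRF** — a minimal labelled-graph dialect for query patterns:
  line 1 ``N M``; then ``N`` lines ``index element``; then ``M`` lines
  ``i j`` with 0-based, unordered node indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np

from .elements import atomic_number, known_elements

if TYPE_CHECKING:  # pragma: no cover
    from .graph_build import ShellAssignment

__all__ = [
    "Atom",
    "Structure",
    "LocalPatternGraph",
    "ParseError",
    "read_xyz",
    "write_xyz",
    "write_labeled_xyz",
    "read_grf",
    "write_grf",
]


class ParseError(ValueError):
    """Malformed structure file; the message names the offending line."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, atomic number and Cartesian position (A)."""

    element: str
    atomic_number: int
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite coordinates: {pos}")
        object.__setattr__(self, "position", pos)
        if atomic_number(self.element) != self.atomic_number:
            raise ValueError(
                f"atomic number {self.atomic_number} does not match element "
                f"{self.element!r}"
            )

    @classmethod
    def of(cls, element: str, x: float, y: float, z: float) -> "Atom":
        return cls(element, atomic_number(element), np.array([x, y, z], float))


@dataclass
class Structure:
    """An ordered list of atoms parsed from an XYZ file or built in memory."""

    atoms: list[Atom]
    comment: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a Structure must contain at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of coordinates in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def element_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return counts

    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.element)
        return tuple(seen)


@dataclass
class LocalPatternGraph:
    """A small element-labelled query graph (nodes + undirected edges)."""

    nodes: list[str]
    edges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.nodes)
        seen: set[tuple[int, int]] = set()
        canon: list[tuple[int, int]] = []
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references node out of range 0..{n - 1}")
            e = (min(i, j), max(i, j))
            if e in seen:
                raise ValueError(f"duplicate edge ({i},{j})")
            seen.add(e)
            canon.append(e)
        self.edges = canon
        for label in self.nodes:
            if label not in known_elements():
                raise ValueError(f"unknown element label {label!r}")

    def __len__(self) -> int:
        return len(self.nodes)


def _tokenize(text: str) -> list[tuple[int, str]]:
    """Non-blank lines with their 1-based line numbers (trailing blanks dropped)."""
    lines = [(no, line.rstrip()) for no, line in enumerate(text.splitlines(), start=1)]
    while lines and not lines[-1][1].strip():
        lines.pop()
    return lines


def read_xyz(path: str | Path) -> Structure:
    """Parse an XYZ file into a :class:`Structure`.

    Tolerates trailing whitespace, blank trailing lines and extra columns
    after z (such as the core/shell label written by
    :func:`write_labeled_xyz`). Raises :class:`ParseError` naming the line
    on a count mismatch, unknown element or malformed coordinate.
    """
    path = Path(path)
    lines = _tokenize(path.read_text(encoding="utf-8"))
    if not lines:
        raise ParseError(f"{path}: empty file")
    no, first = lines[0]
    try:
        declared = int(first.strip())
    except ValueError:
        raise ParseError(f"{path}:{no}: expected atom count, got {first!r}") from None
    comment = lines[1][1] if len(lines) > 1 else ""
    atom_lines = lines[2:]
    if len(atom_lines) != declared:
        raise ParseError(
            f"{path}: declared {declared} atoms but found {len(atom_lines)} atom lines"
        )
    atoms: list[Atom] = []
    for no, line in atom_lines:
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{no}: expected 'Symbol x y z', got {line!r}")
        symbol = parts[0]
        if symbol not in known_elements():
            raise ParseError(f"{path}:{no}: unknown element symbol {symbol!r}")
        try:
            x, y, z = (float(v) for v in parts[1:4])
        except ValueError:
            raise ParseError(f"{path}:{no}: malformed coordinate in {line!r}") from None
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise ParseError(f"{path}:{no}: non-finite coordinate in {line!r}")
        atoms.append(Atom.of(symbol, x, y, z))
    return Structure(atoms, comment=comment, source=str(path))


def write_xyz(structure: Structure, path: str | Path, precision: int = 6) -> Path:
    """Write a standard XYZ file; coordinates at ``precision`` decimals."""
    path = Path(path)
    lines = [str(len(structure)), structure.comment]
    for a in structure.atoms:
        x, y, z = a.position
        lines.append(f"{a.element} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_labeled_xyz(
    structure: Structure,
    shell: "ShellAssignment",
    path: str | Path,
    precision: int = 6,
) -> Path:
    """Write XYZ with a trailing per-atom ``core``/``shell`` label column."""
    if len(shell.is_shell) != len(structure):
        raise ValueError(
            f"shell assignment covers {len(shell.is_shell)} atoms, "
            f"structure has {len(structure)}"
        )
    path = Path(path)
    lines = [str(len(structure)), structure.comment]
    for a, in_shell in zip(structure.atoms, shell.is_shell):
        x, y, z = a.position
        label = "shell" if in_shell else "core"
        lines.append(
            f"{a.element} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f} {label}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_grf(path: str | Path) -> LocalPatternGraph:
    """Parse the GRF query-graph dialect (see module docstring)."""
    path = Path(path)
    lines = _tokenize(path.read_text(encoding="utf-8"))
    if not lines:
        raise ParseError(f"{path}: empty file")
    no, header = lines[0]
    parts = header.split()
    if len(parts) != 2:
        raise ParseError(f"{path}:{no}: expected 'N M' header, got {header!r}")
    try:
        n_nodes, n_edges = int(parts[0]), int(parts[1])
    except ValueError:
        raise ParseError(f"{path}:{no}: non-integer header {header!r}") from None
    body = lines[1:]
    if len(body) != n_nodes + n_edges:
        raise ParseError(
            f"{path}: header declares {n_nodes} nodes + {n_edges} edges, "
            f"found {len(body)} body lines"
        )
    labels: dict[int, str] = {}
    for no, line in body[:n_nodes]:
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{no}: expected 'index element', got {line!r}")
        try:
            idx = int(parts[0])
        except ValueError:
            raise ParseError(f"{path}:{no}: non-integer node index in {line!r}") from None
        if not 0 <= idx < n_nodes or idx in labels:
            raise ParseError(f"{path}:{no}: bad or repeated node index {idx}")
        if parts[1] not in known_elements():
            raise ParseError(f"{path}:{no}: unknown element symbol {parts[1]!r}")
        labels[idx] = parts[1]
    edges: list[tuple[int, int]] = []
    for no, line in body[n_nodes:]:
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{no}: expected 'i j' edge, got {line!r}")
        try:
            i, j = int(parts[0]), int(parts[1])
        except ValueError:
            raise ParseError(f"{path}:{no}: non-integer edge endpoint in {line!r}") from None
        edges.append((i, j))
    try:
        return LocalPatternGraph([labels[i] for i in range(n_nodes)], edges)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_grf(graph: LocalPatternGraph, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{len(graph.nodes)} {len(graph.edges)}"]
    lines += [f"{i} {label}" for i, label in enumerate(graph.nodes)]
    lines += [f"{i} {j}" for i, j in graph.edges]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
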