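"""The four-section shell fingerprint: layout, construction, differencing.

The fingerprint is a fixed-layout count vector over local coordination
structures found in the shell of a binary metal-oxide nanoparticle:

* **Section 1** (6 slots): shell thickness (A), MAX, particle size (A),
  atomic number of the metal, number of shell O atoms, number of shell
  metal atoms.
* **Section 2** (2*MAX slots): O(c) / M(c) — shell atoms with total
  coordination c, for c in 1..MAX.
* **Section 3** (2*(MAX+1)^2 slots): O(x,y) / M(x,y) — shell atoms with x
  oxygen and y metal neighbours, x,y in 0..MAX.
* **Section 4** (3*(MAX+1)^4 slots): bonded pairs of typed environments
  O(x,y)-O(x',y'), M(x,y)-M(x',y') and O(x,y)-M(x',y'); each shell-shell
  bond contributes exactly one count.

With W = MAX+1 the canonical vector length is 6 + 2*MAX + 2*W^2 + 3*W^4.
A second "positive-only" length convention (6 + 2*MAX + 2*MAX^2 + 3*MAX^4)
is exposed for arithmetic compatibility only; the stored vector always
follows the canonical layout.

Counting conventions (documented choices where the layout alone does not
pin them down):

* Only bonds with BOTH endpoints in the shell enter the counts; degrees in
  sections 2-4 are degrees of the shell-restricted graph.
* Shell atoms with degree > MAX are counted in section-1 slots 5/6 but
  excluded from sections 2-4, as are any bonds touching them.
* The symmetric pair blocks (O-O, M-M) count each bond once at the
  lexicographically canonicalised slot (p1 <= p2); the O-M block needs no
  canonicalisation because the O endpoint always comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from .elements import atomic_number, is_metal
from .graph_build import (
    DEFAULT_TOLERANCE,
    assign_shell,
    compute_size,
    infer_bonds,
    BondGraph,
    ShellAssignment,
)
from .structure_io import Structure

__all__ = [
    "PatternLabel",
    "NanoFingerprint",
    "fingerprint_length",
    "index_of",
    "iter_labels",
    "build_fingerprint",
    "diff_fingerprints",
]

LengthConvention = Literal["inclusive-zero", "positive-only"]

SECTION1_NAMES = (
    "shell_thickness",
    "max_bonds",
    "size",
    "metal_atomic_number",
    "n_O_shell",
    "n_M_shell",
)


@dataclass(frozen=True)
class PatternLabel:
    """Label of one counted local structure.

    kind: "O" / "M" with a single coordination index c (section 2);
    "O()" / "M()" with an (x, y) pair (section 3); "O-O" / "M-M" / "O-M"
    with two (x, y) pairs (section 4).
    """

    kind: str
    indices: tuple

    def __str__(self) -> str:  # e.g. O(3), M(2,0), O(0,1)-M(2,0)
        if self.kind in ("O", "M"):
            return f"{self.kind}({self.indices[0]})"
        if self.kind in ("O()", "M()"):
            x, y = self.indices
            return f"{self.kind[0]}({x},{y})"
        (x, y), (u, v) = self.indices
        a, b = self.kind.split("-")
        return f"{a}({x},{y})-{b}({u},{v})"

    @staticmethod
    def atom(element_kind: str, c: int) -> "PatternLabel":
        return PatternLabel(element_kind, (c,))

    @staticmethod
    def env(element_kind: str, x: int, y: int) -> "PatternLabel":
        return PatternLabel(element_kind + "()", (x, y))

    @staticmethod
    def pair(kind: str, xy1: tuple[int, int], xy2: tuple[int, int]) -> "PatternLabel":
        return PatternLabel(kind, (tuple(xy1), tuple(xy2)))


def fingerprint_length(
    max_bonds: int, convention: LengthConvention = "inclusive-zero"
) -> int:
    """Total fingerprint length for a given MAX.

    "inclusive-zero" (canonical, matches the stored vector):
        6 + 2*MAX + 2*(MAX+1)^2 + 3*(MAX+1)^4
    "positive-only" (compatibility arithmetic, e.g. 30,226 at MAX=10):
        6 + 2*MAX + 2*MAX^2 + 3*MAX^4
    """
    if max_bonds < 1:
        raise ValueError(f"max_bonds must be >= 1, got {max_bonds}")
    m = int(max_bonds)
    if convention == "inclusive-zero":
        w = m + 1
        return 6 + 2 * m + 2 * w**2 + 3 * w**4
    if convention == "positive-only":
        return 6 + 2 * m + 2 * m**2 + 3 * m**4
    raise ValueError(f"unknown length convention {convention!r}")


def _check_range(value: int, lo: int, hi: int, what: str) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"{what}={value} out of range [{lo}, {hi}]")


def index_of(label: PatternLabel, max_bonds: int) -> int:
    """Position of a pattern label in the canonical vector layout."""
    m = int(max_bonds)
    if m < 1:
        raise ValueError(f"max_bonds must be >= 1, got {m}")
    w = m + 1
    b3 = 6 + 2 * m          # section-3 base
    b4 = b3 + 2 * w * w     # section-4 base
    block = w * w           # per-environment stride in section 4

    def pos(x: int, y: int) -> int:
        _check_range(x, 0, m, "x")
        _check_range(y, 0, m, "y")
        return x * w + y

    kind = label.kind
    if kind in ("O", "M"):
        (c,) = label.indices
        _check_range(c, 1, m, "c")
        return 6 + (0 if kind == "O" else m) + (c - 1)
    if kind in ("O()", "M()"):
        x, y = label.indices
        return b3 + (0 if kind == "O()" else w * w) + pos(x, y)
    if kind in ("O-O", "M-M", "O-M"):
        (x, y), (u, v) = label.indices
        p1, p2 = pos(x, y), pos(u, v)
        if kind == "O-O":
            p1, p2 = min(p1, p2), max(p1, p2)
            return b4 + p1 * block + p2
        if kind == "M-M":
            p1, p2 = min(p1, p2), max(p1, p2)
            return b4 + block * block + p1 * block + p2
        return b4 + 2 * block * block + p1 * block + p2
    raise ValueError(f"unknown pattern kind {kind!r}")


def iter_labels(max_bonds: int) -> Iterator[PatternLabel]:
    """All pattern labels of sections 2-4, canonicalised (O-O/M-M: p1 <= p2)."""
    m = int(max_bonds)
    w = m + 1
    for kind in ("O", "M"):
        for c in range(1, m + 1):
            yield PatternLabel.atom(kind, c)
    for kind in ("O", "M"):
        for x in range(w):
            for y in range(w):
                yield PatternLabel.env(kind, x, y)
    grid = [(x, y) for x in range(w) for y in range(w)]
    for kind in ("O-O", "M-M"):
        for i, xy1 in enumerate(grid):
            for xy2 in grid[i:]:
                yield PatternLabel.pair(kind, xy1, xy2)
    for xy1 in grid:
        for xy2 in grid:
            yield PatternLabel.pair("O-M", xy1, xy2)


@dataclass
class NanoFingerprint:
    """The packed four-section vector plus the parameters that produced it."""

    thickness: float
    max_bonds: int
    size: float
    metal_atomic_number: int
    n_O_shell: int
    n_M_shell: int
    vector: np.ndarray

    def __post_init__(self) -> None:
        expected = fingerprint_length(self.max_bonds)
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (expected,):
            raise ValueError(
                f"vector length {self.vector.shape} != canonical length {expected} "
                f"for MAX={self.max_bonds}"
            )

    # -- access ---------------------------------------------------------

    @property
    def section1(self) -> tuple:
        return (
            self.thickness,
            self.max_bonds,
            self.size,
            self.metal_atomic_number,
            self.n_O_shell,
            self.n_M_shell,
        )

    def get(self, label: PatternLabel) -> int:
        return int(self.vector[index_of(label, self.max_bonds)])

    @property
    def index_map(self) -> dict[str, int]:
        return {str(lab): index_of(lab, self.max_bonds) for lab in iter_labels(self.max_bonds)}

    def section_slice(self, section: int) -> slice:
        m = self.max_bonds
        w = m + 1
        bounds = [0, 6, 6 + 2 * m, 6 + 2 * m + 2 * w**2, fingerprint_length(m)]
        if not 1 <= section <= 4:
            raise ValueError(f"section must be 1..4, got {section}")
        return slice(bounds[section - 1], bounds[section])

    # -- serialisation --------------------------------------------------

    def to_text(self, path: str | Path) -> Path:
        """Sparse plain-text form: section-1 header, then 'position value' lines."""
        path = Path(path)
        lines = [
            f"# shell fingerprint, MAX={self.max_bonds}, "
            f"length={len(self.vector)}",
        ]
        for name, value in zip(SECTION1_NAMES, self.section1):
            lines.append(f"# {name} {value}")
        lines += [f"{i} {value:g}" for i, value in enumerate(self.vector) if value != 0]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_text(cls, path: str | Path) -> "NanoFingerprint":
        path = Path(path)
        header: dict[str, float] = {}
        entries: dict[int, float] = {}
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] in SECTION1_NAMES:
                    header[parts[0]] = float(parts[1])
                continue
            pos, value = line.split()
            entries[int(pos)] = float(value)
        missing = [n for n in SECTION1_NAMES if n not in header]
        if missing:
            raise ValueError(f"{path}: missing header fields {missing}")
        max_bonds = int(header["max_bonds"])
        vector = np.zeros(fingerprint_length(max_bonds))
        for pos, value in entries.items():
            vector[pos] = value
        return cls(
            thickness=header["shell_thickness"],
            max_bonds=max_bonds,
            size=header["size"],
            metal_atomic_number=int(header["metal_atomic_number"]),
            n_O_shell=int(header["n_O_shell"]),
            n_M_shell=int(header["n_M_shell"]),
            vector=vector,
        )

    def to_dense_csv(self, path: str | Path) -> Path:
        import csv as _csv

        path = Path(path)
        labels = [""] * len(self.vector)
        for name, i in zip(SECTION1_NAMES, range(6)):
            labels[i] = name
        for lab in iter_labels(self.max_bonds):
            labels[index_of(lab, self.max_bonds)] = str(lab)
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh)
            writer.writerow(["position", "label", "value"])
            for i, (label, value) in enumerate(zip(labels, self.vector)):
                writer.writerow([i, label, f"{value:g}"])
        return path


def _validate_binary_oxide(structure: Structure) -> str:
    """Return the metal symbol; raise if not a single-metal binary oxide."""
    species = set(structure.species())
    metals = sorted(s for s in species if s != "O")
    if "O" not in species:
        raise ValueError("structure contains no oxygen; not a metal oxide")
    if not metals:
        raise ValueError("structure contains no metal species")
    if len(metals) > 1:
        raise ValueError(f"more than one metal species: {metals}")
    if not is_metal(metals[0]):
        raise ValueError(f"element {metals[0]!r} is not a metal")
    return metals[0]


def _count_into_vector(
    elements: list[str],
    graph: BondGraph,
    shell: ShellAssignment,
    max_bonds: int,
) -> np.ndarray:
    """Fill sections 2-4 from the shell-restricted graph."""
    m = max_bonds
    vector = np.zeros(fingerprint_length(m))
    sub = graph.subgraph(shell.is_shell, elements)
    deg = sub.degrees

    def env(i: int) -> tuple[int, int]:
        return int(sub.coord_O[i]), int(sub.coord_M[i])

    for i, el in enumerate(elements):
        if not shell.is_shell[i] or deg[i] > m:
            continue
        kind = "O" if el == "O" else "M"
        if deg[i] >= 1:
            vector[index_of(PatternLabel.atom(kind, int(deg[i])), m)] += 1
        vector[index_of(PatternLabel.env(kind, *env(i)), m)] += 1
    for i, j in sub.edges:
        if deg[i] > m or deg[j] > m:
            continue
        ei, ej = elements[i], elements[j]
        if ei == "O" and ej == "O":
            vector[index_of(PatternLabel.pair("O-O", env(i), env(j)), m)] += 1
        elif ei != "O" and ej != "O":
            vector[index_of(PatternLabel.pair("M-M", env(i), env(j)), m)] += 1
        else:
            o, metal = (i, j) if ei == "O" else (j, i)
            vector[index_of(PatternLabel.pair("O-M", env(o), env(metal)), m)] += 1
    return vector


def build_fingerprint(
    structure: Structure,
    thickness: float,
    max_bonds: int,
    tolerance: float = DEFAULT_TOLERANCE,
    shell: ShellAssignment | None = None,
) -> NanoFingerprint:
    """Build the fingerprint of a structure.

    Pipeline: infer bonds -> classify core/shell (unless a frozen ``shell``
    assignment is supplied) -> restrict the graph to shell-shell bonds ->
    count the local structures of sections 2-4. Section-1 slot 3 (size) is
    measured on the whole particle.
    """
    if max_bonds < 1:
        raise ValueError(f"max_bonds must be >= 1, got {max_bonds}")
    metal = _validate_binary_oxide(structure)
    graph = infer_bonds(structure, tolerance=tolerance)
    if shell is None:
        shell = assign_shell(structure, thickness)
    elif len(shell.is_shell) != len(structure):
        raise ValueError("frozen shell assignment does not match structure length")
    elements = structure.elements
    size = compute_size(structure)
    n_o = sum(1 for i, e in enumerate(elements) if shell.is_shell[i] and e == "O")
    n_m = sum(1 for i, e in enumerate(elements) if shell.is_shell[i] and e != "O")
    vector = _count_into_vector(elements, graph, shell, max_bonds)
    vector[0] = shell.thickness
    vector[1] = max_bonds
    vector[2] = size
    vector[3] = atomic_number(metal)
    vector[4] = n_o
    vector[5] = n_m
    return NanoFingerprint(
        thickness=shell.thickness,
        max_bonds=max_bonds,
        size=size,
        metal_atomic_number=atomic_number(metal),
        n_O_shell=n_o,
        n_M_shell=n_m,
        vector=vector,
    )


def diff_fingerprints(a: NanoFingerprint, b: NanoFingerprint) -> np.ndarray:
    """Signed element-wise difference a - b over sections 2-4.

    The returned vector has the full canonical length; the six section-1
    slots are zeroed (they are parameters and global descriptors, reported
    side by side rather than subtracted).
    """
    if a.max_bonds != b.max_bonds:
        raise ValueError(
            f"MAX mismatch: {a.max_bonds} vs {b.max_bonds}"
        )
    if len(a.vector) != len(b.vector):
        raise ValueError("fingerprint length mismatch")
    out = a.vector - b.vector
    out[:6] = 0.0
    return out
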