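"""Bond inference, particle size and core/shell classification.

XYZ files carry no bond information, so bonds are deduced geometrically:
atoms i and j are bonded iff

    distance(i, j) <= tolerance * (r_cov(i) + r_cov(j))

with covalent radii from the packaged table and a dimensionless tolerance
(default 1.15). The shell is the radial band of a given thickness below
the particle's outer radius, measured from the centroid of all atoms; the
boundary is closed, so an atom exactly at ``outer_radius - thickness`` is
a shell atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .elements import covalent_radius
from .structure_io import Structure

__all__ = [
    "BondGraph",
    "ShellAssignment",
    "DEFAULT_TOLERANCE",
    "infer_bonds",
    "compute_size",
    "assign_shell",
    "freeze_shell",
]

DEFAULT_TOLERANCE = 1.15


@dataclass
class BondGraph:
    """Undirected bond graph with per-atom O/metal neighbour counts."""

    n_atoms: int
    edges: set[tuple[int, int]]
    coord_O: np.ndarray  # oxygen-neighbour count per atom
    coord_M: np.ndarray  # metal-neighbour count per atom

    def degree(self, i: int) -> int:
        return int(self.coord_O[i] + self.coord_M[i])

    @property
    def degrees(self) -> np.ndarray:
        return self.coord_O + self.coord_M

    def neighbours(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def subgraph(self, keep: np.ndarray, elements: list[str]) -> "BondGraph":
        """Restrict to edges with BOTH endpoints in ``keep`` (boolean mask).

        Atom indexing is preserved; excluded atoms simply end up with
        degree 0 and no incident edges.
        """
        edges = {(i, j) for i, j in self.edges if keep[i] and keep[j]}
        coord_O = np.zeros(self.n_atoms, dtype=int)
        coord_M = np.zeros(self.n_atoms, dtype=int)
        for i, j in edges:
            for a, b in ((i, j), (j, i)):
                if elements[b] == "O":
                    coord_O[a] += 1
                else:
                    coord_M[a] += 1
        return BondGraph(self.n_atoms, edges, coord_O, coord_M)


@dataclass
class ShellAssignment:
    """Core/shell split: shell = radial band of ``thickness`` below ``outer_radius``."""

    center: np.ndarray
    outer_radius: float
    thickness: float
    is_shell: np.ndarray  # boolean per atom

    @property
    def n_shell(self) -> int:
        return int(np.count_nonzero(self.is_shell))

    @property
    def n_core(self) -> int:
        return len(self.is_shell) - self.n_shell


def infer_bonds(structure: Structure, tolerance: float = DEFAULT_TOLERANCE) -> BondGraph:
    """Deduce the bond graph from coordinates via the covalent-radius cutoff."""
    if tolerance <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance}")
    elements = structure.elements
    radii = np.array([covalent_radius(e) for e in elements])
    pos = structure.positions
    n = len(structure)
    max_cutoff = tolerance * 2.0 * radii.max()
    tree = cKDTree(pos)
    candidate_pairs = tree.query_pairs(r=max_cutoff, output_type="ndarray")
    edges: set[tuple[int, int]] = set()
    coord_O = np.zeros(n, dtype=int)
    coord_M = np.zeros(n, dtype=int)
    for i, j in candidate_pairs:
        i, j = int(i), int(j)
        cutoff = tolerance * (radii[i] + radii[j])
        if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
            edges.add((min(i, j), max(i, j)))
            for a, b in ((i, j), (j, i)):
                if elements[b] == "O":
                    coord_O[a] += 1
                else:
                    coord_M[a] += 1
    return BondGraph(n, edges, coord_O, coord_M)


def compute_size(structure: Structure) -> float:
    """Particle size = maximum pairwise distance between two atoms (A).

    For a spherical particle this is the diameter. A single-atom structure
    has size 0.
    """
    pos = structure.positions
    if len(pos) < 2:
        import warnings

        warnings.warn("size of a single-atom structure is 0", stacklevel=2)
        return 0.0
    # convex-hull peeling is overkill at these sizes; the all-pairs scan is
    # vectorised and exact
    from scipy.spatial.distance import pdist

    return float(pdist(pos).max())


def assign_shell(structure: Structure, thickness: float) -> ShellAssignment:
    """Classify atoms as core/shell for a given shell thickness (A).

    Center is the centroid of all atomic positions; the outer radius is the
    largest centroid distance. An atom is shell iff its centroid distance
    is >= outer_radius - thickness, so any thickness >= size/2 makes every
    atom a shell atom.
    """
    if thickness <= 0:
        raise ValueError(f"shell thickness must be positive, got {thickness}")
    pos = structure.positions
    center = pos.mean(axis=0)
    radial = np.linalg.norm(pos - center, axis=1)
    outer = float(radial.max())
    is_shell = radial >= outer - thickness
    return ShellAssignment(center, outer, float(thickness), is_shell)


def freeze_shell(reference: ShellAssignment, structure: Structure) -> ShellAssignment:
    """Transfer a shell assignment onto another structure by atom index.

    Used when comparing an optimised structure against its parent: shell
    membership is decided once on the reference geometry and reattached to
    the (same-length, same-order) target without recomputation, so the set
    of shell atoms is identical in both.
    """
    if len(reference.is_shell) != len(structure):
        raise ValueError(
            f"reference assignment covers {len(reference.is_shell)} atoms, "
            f"structure has {len(structure)}"
        )
    return ShellAssignment(
        reference.center.copy(),
        reference.outer_radius,
        reference.thickness,
        reference.is_shell.copy(),
    )
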