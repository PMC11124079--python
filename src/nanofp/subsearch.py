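"""Subcomponent search: count appearances of a small query structure in the
shell of a larger nanoparticle.

Matching is element-label-preserving subgraph matching on the
shell-restricted bond graph. The default semantics are monomorphism (every
query edge must map to a target bond; extra target bonds among the matched
atoms are allowed); ``induced=True`` switches to the strict induced
variant. Embeddings that cover the same set of target atoms (query
automorphisms) collapse to a single counted appearance.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_build import DEFAULT_TOLERANCE, assign_shell, infer_bonds, ShellAssignment
from .structure_io import LocalPatternGraph, Structure

__all__ = ["MatchResult", "find_subcomponents", "structure_to_pattern"]


@dataclass
class MatchResult:
    """Automorphism-collapsed embeddings of a query in a target shell."""

    embeddings: list[dict[int, int]]  # query node -> target atom index
    count: int
    target_shell: ShellAssignment

    def matched_atom_sets(self) -> list[frozenset[int]]:
        return [frozenset(e.values()) for e in self.embeddings]


def structure_to_pattern(
    structure: Structure, tolerance: float = DEFAULT_TOLERANCE
) -> LocalPatternGraph:
    """Bond-infer a small XYZ query into a labelled pattern graph."""
    graph = infer_bonds(structure, tolerance=tolerance)
    return LocalPatternGraph(structure.elements, sorted(graph.edges))


def _pattern_to_nx(pattern: LocalPatternGraph) -> nx.Graph:
    g = nx.Graph()
    for i, label in enumerate(pattern.nodes):
        g.add_node(i, element=label)
    g.add_edges_from(pattern.edges)
    return g


def find_subcomponents(
    target: Structure,
    query: LocalPatternGraph,
    thickness: float,
    tolerance: float = DEFAULT_TOLERANCE,
    induced: bool = False,
) -> MatchResult:
    """Count appearances of ``query`` in the shell of ``target``.

    All query atoms must land on shell atoms; bonds between shell and core
    atoms do not belong to the searched graph. A thickness of at least half
    the particle size searches the whole compound. A query larger than the
    shell graph simply yields count 0.
    """
    if len(query) == 0:
        raise ValueError("query pattern is empty")
    shell = assign_shell(target, thickness)
    bonds = infer_bonds(target, tolerance=tolerance)
    g = nx.Graph()
    elements = target.elements
    for i in np.flatnonzero(shell.is_shell):
        g.add_node(int(i), element=elements[int(i)])
    for i, j in bonds.edges:
        if shell.is_shell[i] and shell.is_shell[j]:
            g.add_edge(i, j)
    q = _pattern_to_nx(query)

    node_match = nx.algorithms.isomorphism.categorical_node_match("element", None)
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, q, node_match=node_match)
    iterator = (
        matcher.subgraph_isomorphisms_iter()
        if induced
        else matcher.subgraph_monomorphisms_iter()
    )
    seen: set[frozenset[int]] = set()
    embeddings: list[dict[int, int]] = []
    for mapping in iterator:  # mapping: target node -> query node
        atoms = frozenset(mapping)
        if atoms in seen:
            continue
        seen.add(atoms)
        embeddings.append({qn: tn for tn, qn in mapping.items()})
    return MatchResult(embeddings=embeddings, count=len(embeddings), target_shell=shell)


def write_matches_xyz(
    target: Structure, result: MatchResult, path
) -> None:
    """Write matched atoms as a multi-model XYZ (one frame per appearance)."""
    from pathlib import Path

    lines: list[str] = []
    for k, emb in enumerate(result.embeddings):
        atoms = sorted(emb.values())
        lines.append(str(len(atoms)))
        lines.append(f"match {k + 1} of {result.count}")
        for i in atoms:
            a = target.atoms[i]
            x, y, z = a.position
            lines.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
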