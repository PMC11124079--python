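"""Independent brute-force oracles used by the test-suite only.

These deliberately avoid the package's bond/shell/counting code paths:
bonds come from a plain O(n^2) distance loop over a locally duplicated
radius table, the shell from a hand-rolled centroid computation, the
fingerprint layout from an explicit enumeration into an index dictionary,
and subgraph matches from exhaustive injective-mapping enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# local copy of the radii actually used by the fixtures (Cordero values)
RADII = {"O": 0.66, "Ti": 1.60, "Al": 1.21, "Zn": 1.22, "Mg": 1.41, "Fe": 1.32, "Cu": 1.32}
Z = {"O": 8, "Al": 13, "Ti": 22, "Fe": 26, "Cu": 29, "Zn": 30, "Mg": 12}


def naive_bonds(elements, positions, tolerance=1.15):
    """All-pairs cutoff bonds as a sorted list of index pairs."""
    n = len(elements)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(positions[i], positions[j])
            if d <= tolerance * (RADII[elements[i]] + RADII[elements[j]]):
                edges.append((i, j))
    return edges


def naive_shell_mask(positions, thickness):
    pos = np.asarray(positions, float)
    center = pos.mean(axis=0)
    radial = np.sqrt(((pos - center) ** 2).sum(axis=1))
    return radial >= radial.max() - thickness


def naive_size(positions):
    best = 0.0
    for a, b in itertools.combinations(positions, 2):
        best = max(best, math.dist(a, b))
    return best


def layout_positions(max_bonds):
    """label-string -> vector position, built by explicit list enumeration."""
    m = max_bonds
    w = m + 1
    labels = []
    for kind in ("O", "M"):
        for c in range(1, m + 1):
            labels.append(f"{kind}({c})")
    for kind in ("O", "M"):
        for x in range(w):
            for y in range(w):
                labels.append(f"{kind}({x},{y})")
    grid = [(x, y) for x in range(w) for y in range(w)]
    for kind in ("O-O", "M-M", "O-M"):
        a, b = kind.split("-")
        for x, y in grid:
            for u, v in grid:
                labels.append(f"{a}({x},{y})-{b}({u},{v})")
    return {label: 6 + i for i, label in enumerate(labels)}


def naive_fingerprint_vector(elements, positions, thickness, max_bonds, tolerance=1.15):
    """Full-length packed vector computed entirely by brute force."""
    m = max_bonds
    index = layout_positions(m)
    vec = np.zeros(6 + len(index))
    shell = naive_shell_mask(positions, thickness)
    edges = [
        (i, j)
        for i, j in naive_bonds(elements, positions, tolerance)
        if shell[i] and shell[j]
    ]
    n = len(elements)
    n_o = [0] * n
    n_m = [0] * n
    for i, j in edges:
        for a, b in ((i, j), (j, i)):
            if elements[b] == "O":
                n_o[a] += 1
            else:
                n_m[a] += 1

    def kind(i):
        return "O" if elements[i] == "O" else "M"

    def env(i):
        return n_o[i], n_m[i]

    metal = next(e for e in elements if e != "O")
    vec[0] = thickness
    vec[1] = m
    vec[2] = naive_size(positions)
    vec[3] = Z[metal]
    vec[4] = sum(1 for i in range(n) if shell[i] and elements[i] == "O")
    vec[5] = sum(1 for i in range(n) if shell[i] and elements[i] != "O")
    for i in range(n):
        if not shell[i]:
            continue
        deg = n_o[i] + n_m[i]
        if deg > m:
            continue
        if deg >= 1:
            vec[index[f"{kind(i)}({deg})"]] += 1
        x, y = env(i)
        vec[index[f"{kind(i)}({x},{y})"]] += 1
    for i, j in edges:
        if n_o[i] + n_m[i] > m or n_o[j] + n_m[j] > m:
            continue
        ki, kj = kind(i), kind(j)
        if ki == kj:
            # canonical slot: smaller row-major environment first
            pi = env(i)[0] * (m + 1) + env(i)[1]
            pj = env(j)[0] * (m + 1) + env(j)[1]
            (x, y), (u, v) = (env(i), env(j)) if pi <= pj else (env(j), env(i))
            vec[index[f"{ki}({x},{y})-{kj}({u},{v})"]] += 1
        else:
            o, t = (i, j) if ki == "O" else (j, i)
            vec[index[f"O{env(o)!s}-M{env(t)!s}".replace(" ", "")]] += 1
    return vec


def naive_subgraph_count(
    target_elements, target_edges, query_labels, query_edges, induced=False
):
    """Count distinct matched atom sets via exhaustive injective mappings."""
    edge_set = {frozenset(e) for e in target_edges}
    k = len(query_labels)
    nodes = range(len(target_elements))
    q_edges = [frozenset(e) for e in query_edges]
    q_non_edges = [
        frozenset((i, j))
        for i in range(k)
        for j in range(i + 1, k)
        if frozenset((i, j)) not in set(q_edges)
    ]
    found = set()
    for perm in itertools.permutations(nodes, k):
        if any(target_elements[perm[i]] != query_labels[i] for i in range(k)):
            continue
        if any(frozenset((perm[i], perm[j])) not in edge_set for i, j in (tuple(e) for e in q_edges)):
            continue
        if induced and any(
            frozenset((perm[i], perm[j])) in edge_set for i, j in (tuple(e) for e in q_non_edges)
        ):
            continue
        found.add(frozenset(perm))
    return len(found)
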