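"""Synthetic fixtures: spherical metal-oxide particles cut from ideal
lattices, an "optimisation-like" coordination-raising perturbation, and
QSAR tables with planted linear/logistic effects.

The lattices are deliberately idealised — rocksalt MO, a fluorite-type
MO2 stand-in for rutile, and a vacancy-ordered rocksalt M2O3 stand-in for
corundum. They give controllable stoichiometry and coordination
statistics for testing; they are NOT crystallographically faithful to
anatase/rutile/corundum and their counts must never be compared with
structures from real crystallographic generators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .elements import atomic_number
from .qsar import QSARDataset
from .structure_io import Atom, Structure

__all__ = ["LatticeSpec", "make_particle", "perturb_optimise", "make_qsar_dataset"]

LatticeKind = Literal["rocksalt", "rutile", "corundum"]


@dataclass(frozen=True)
class LatticeSpec:
    """Recipe for a sphere cut from an ideal lattice.

    lattice: "rocksalt" (MO), "rutile" (MO2, fluorite-type stand-in) or
    "corundum" (M2O3, vacancy-ordered rocksalt stand-in).
    """

    lattice: LatticeKind
    lattice_constant: float
    metal: str
    diameter: float

    def __post_init__(self) -> None:
        if self.lattice not in ("rocksalt", "rutile", "corundum"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        if self.lattice_constant <= 0:
            raise ValueError("lattice_constant must be positive")
        if self.diameter < 2 * self.lattice_constant:
            raise ValueError(
                f"diameter {self.diameter} too small: need >= 2 x lattice constant "
                f"({2 * self.lattice_constant})"
            )
        atomic_number(self.metal)  # validates the symbol


def _rocksalt_sites(half_steps: int, a: float):
    """Sites of the NaCl lattice on a (a/2)-grid; parity of i+j+k sets species."""
    h = a / 2.0
    rng = range(-half_steps, half_steps + 1)
    for i, j, k in itertools.product(rng, rng, rng):
        species = "M" if (i + j + k) % 2 == 0 else "O"
        yield species, np.array([i * h, j * h, k * h]), (i, j, k)


def _fluorite_sites(cells: int, a: float):
    """Fluorite MO2: metal on FCC, oxygen on the simple-cubic (a/2) hole grid."""
    fcc_basis = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    o_basis = [
        (0.25, 0.25, 0.25), (0.75, 0.25, 0.25), (0.25, 0.75, 0.25), (0.25, 0.25, 0.75),
        (0.75, 0.75, 0.25), (0.75, 0.25, 0.75), (0.25, 0.75, 0.75), (0.75, 0.75, 0.75),
    ]
    rng = range(-cells, cells + 1)
    for i, j, k in itertools.product(rng, rng, rng):
        origin = np.array([i, j, k], dtype=float)
        for b in fcc_basis:
            yield "M", (origin + b) * a, (i, j, k, b)
        for b in o_basis:
            yield "O", (origin + b) * a, (i, j, k, b)


def _corundum_sites(half_steps: int, a: float):
    """M2O3 stand-in: rocksalt with every third metal site vacant."""
    for species, pos, (i, j, k) in _rocksalt_sites(half_steps, a):
        if species == "M" and ((i + j + k) // 2) % 3 == 0:
            continue
        yield species, pos, (i, j, k)


def make_particle(spec: LatticeSpec, seed: int = 0, jitter: float = 0.0) -> Structure:
    """Cut a spherical particle of the requested lattice around the origin.

    All lattice sites within diameter/2 of the origin are kept, in a
    deterministic (sorted) order. ``jitter`` adds a seeded Gaussian
    displacement of that amplitude (A) to every atom, useful for generating
    distinct random fixtures; jitter 0 is the ideal cut.
    """
    a = spec.lattice_constant
    radius = spec.diameter / 2.0
    if spec.lattice == "rocksalt":
        steps = int(np.ceil(radius / (a / 2.0))) + 1
        sites = _rocksalt_sites(steps, a)
    elif spec.lattice == "rutile":
        cells = int(np.ceil(radius / a)) + 1
        sites = _fluorite_sites(cells, a)
    else:
        steps = int(np.ceil(radius / (a / 2.0))) + 1
        sites = _corundum_sites(steps, a)

    picked: list[tuple[str, np.ndarray]] = []
    for species, pos, _ in sites:
        if np.linalg.norm(pos) <= radius + 1e-9:
            picked.append((species, pos))
    if not any(s == "M" for s, _ in picked) or not any(s == "O" for s, _ in picked):
        raise ValueError(
            f"diameter {spec.diameter} A too small to contain a formula unit "
            f"of the {spec.lattice} lattice (a={a})"
        )
    # stable deterministic order: sort by coordinates, oxygen first
    picked.sort(key=lambda sp: (sp[0], tuple(np.round(sp[1], 6))))
    rng = np.random.default_rng(seed)
    atoms = []
    for species, pos in picked:
        element = "O" if species == "O" else spec.metal
        if jitter > 0:
            pos = pos + rng.normal(scale=jitter, size=3)
        atoms.append(Atom.of(element, *pos))
    return Structure(
        atoms,
        comment=f"synthetic {spec.lattice} {spec.metal} oxide, d={spec.diameter} A, seed={seed}",
        source="synthetic",
    )


def perturb_optimise(
    structure: Structure,
    rewire_fraction: float,
    seed: int = 0,
    tolerance: float | None = None,
) -> Structure:
    """Emulate the effect of structural optimisation on shell coordination.

    A fraction of the singly-coordinated oxygen atoms is displaced to the
    midpoint of its bonded metal and the nearest other metal, which the
    bond-inference cutoff then reads as a higher coordination. Atom count
    and order are unchanged, so a frozen shell assignment carries over.
    Differencing original - perturbed fingerprints is positive at O(1).
    """
    from .graph_build import DEFAULT_TOLERANCE, infer_bonds

    if not 0.0 <= rewire_fraction <= 1.0:
        raise ValueError(f"rewire_fraction must be in [0, 1], got {rewire_fraction}")
    if rewire_fraction == 0.0:
        return Structure(list(structure.atoms), structure.comment, structure.source)
    tol = DEFAULT_TOLERANCE if tolerance is None else tolerance
    graph = infer_bonds(structure, tolerance=tol)
    adj = graph.neighbours()
    elements = structure.elements
    positions = structure.positions.copy()
    metal_idx = [i for i, e in enumerate(elements) if e != "O"]
    undercoordinated = [
        i
        for i, e in enumerate(elements)
        if e == "O" and graph.degree(i) == 1 and elements[next(iter(adj[i]))] != "O"
    ]
    rng = np.random.default_rng(seed)
    n_move = int(round(rewire_fraction * len(undercoordinated)))
    chosen = rng.choice(undercoordinated, size=n_move, replace=False) if n_move else []
    for i in chosen:
        bonded_metal = next(iter(adj[i]))
        others = [m for m in metal_idx if m != bonded_metal]
        if not others:
            continue
        dists = np.linalg.norm(positions[others] - positions[i], axis=1)
        nearest = others[int(np.argmin(dists))]
        positions[i] = 0.5 * (positions[bonded_metal] + positions[nearest])
    atoms = [
        Atom.of(e, *positions[i]) for i, e in enumerate(elements)
    ]
    return Structure(atoms, comment=structure.comment + " (perturbed)", source=structure.source)


def make_qsar_dataset(
    n: int,
    p: int,
    beta: np.ndarray,
    noise: float = 1.0,
    kind: Literal["linear", "logistic"] = "linear",
    seed: int = 0,
    intercept: float = 0.0,
) -> QSARDataset:
    """Standard-normal features with a planted linear/logistic effect.

    linear:   y = intercept + X beta + N(0, noise^2)
    logistic: P(y=1) = sigmoid(intercept + X beta); ``intercept`` skews the
    class balance for imbalance experiments. Deterministic given the seed.
    """
    beta = np.asarray(beta, dtype=float)
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if beta.shape != (p,):
        raise ValueError(f"beta must have length p={p}, got {beta.shape}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    eta = intercept + x @ beta
    if kind == "linear":
        y = eta + rng.normal(scale=noise, size=n)
    elif kind == "logistic":
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(n) < prob).astype(float)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    names = [f"x{i}" for i in range(p)]
    return QSARDataset(x, names, y)
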