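"""Periodic-table lookups used across the package.

Only the elements plausibly found in binary metal-oxide nanoparticles are
covered; the covalent-radius table ships as a versioned CSV under
``nanofp/data`` so the bond-inference cutoffs are auditable.
"""

from __future__ import annotations

import csv
from importlib import resources
from functools import lru_cache


class UnknownElementError(KeyError):
    """Raised when an element symbol has no entry in the packaged tables."""


@lru_cache(maxsize=1)
def _load_table() -> dict[str, tuple[int, float]]:
    table: dict[str, tuple[int, float]] = {}
    path = resources.files("nanofp.data").joinpath("covalent_radii.csv")
    with path.open("r", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            symbol, z, radius = row[0].strip(), int(row[1]), float(row[2])
            table[symbol] = (z, radius)
    return table


def atomic_number(symbol: str) -> int:
    """Atomic number for an element symbol (case-sensitive, e.g. ``"Ti"``)."""
    try:
        return _load_table()[symbol][0]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None


def covalent_radius(symbol: str) -> float:
    """Single-bond covalent radius in Angstrom."""
    try:
        return _load_table()[symbol][1]
    except KeyError:
        raise UnknownElementError(
            f"no covalent radius for element symbol: {symbol!r}"
        ) from None


def known_elements() -> frozenset[str]:
    return frozenset(_load_table())


def is_metal(symbol: str) -> bool:
    """True for every tabulated element that is not O/H/C/N or a halogen.

    The package only distinguishes oxygen from "the metal" of a binary
    oxide, so a coarse rule is sufficient.
    """
    return symbol in _load_table() and symbol not in {
        "H", "B", "C", "N", "O", "F", "P", "S", "Cl",
    }
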