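"""Predict a full fingerprint from (metal, size) alone, without a 3D
structure, via per-position log-linear regression.

For every counting position (sections 2-4 plus the two shell-count slots
of section 1) and every metal seen in training, ``log(1 + count)`` is
regressed on ``[1, log(size)]`` by least squares. Prediction inverts the
transform (``exp(.) - 1``), clamps at zero and rounds to an integer, so
shell counts that follow the usual power-law growth with size are
captured by two parameters per position and neither over-fitting nor
negative counts can occur. Positions that are zero across all training
data for a metal are hard-zeroed in prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .fingerprint import NanoFingerprint, fingerprint_length

__all__ = ["FingerprintGenerator", "fit_generator", "predict_fingerprint"]


@dataclass
class FingerprintGenerator:
    """Per-metal, per-position log-linear coefficients over log(size)."""

    max_bonds: int
    thickness: float
    # metal atomic number -> (length, 2) array of [intercept, slope]
    coefficients: dict[int, np.ndarray]
    # metal atomic number -> boolean mask of positions ever non-zero in training
    support: dict[int, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return fingerprint_length(self.max_bonds)

    def metals(self) -> list[int]:
        return sorted(self.coefficients)

    # -- serialisation ---------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "max_bonds": self.max_bonds,
            "thickness": self.thickness,
            "coefficients": {str(z): c.tolist() for z, c in self.coefficients.items()},
            "support": {str(z): s.astype(int).tolist() for z, s in self.support.items()},
            "training_meta": self.training_meta,
        }
        path.write_text(json.dumps(payload), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FingerprintGenerator":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            max_bonds=int(payload["max_bonds"]),
            thickness=float(payload["thickness"]),
            coefficients={
                int(z): np.asarray(c, dtype=float)
                for z, c in payload["coefficients"].items()
            },
            support={
                int(z): np.asarray(s, dtype=bool)
                for z, s in payload["support"].items()
            },
            training_meta=payload.get("training_meta", {}),
        )


# positions predicted as counts: section-1 slots 5 and 6 plus everything
# from section 2 onward; slots 0-3 are parameter echoes
_FIRST_COUNT_SLOT = 4


def fit_generator(
    training: Sequence[tuple[int, float, NanoFingerprint]],
) -> FingerprintGenerator:
    """Fit the generator from (metal atomic number, size A, fingerprint) triples.

    Requires a shared MAX and thickness and, per metal, at least 2
    training structures at 2 distinct sizes (otherwise the log-size slope
    is not identifiable; with exactly two points the fit interpolates them
    exactly).
    """
    if not training:
        raise ValueError("empty training set")
    max_set = {fp.max_bonds for _, _, fp in training}
    if len(max_set) != 1:
        raise ValueError(f"inconsistent MAX across training fingerprints: {sorted(max_set)}")
    thick_set = {fp.thickness for _, _, fp in training}
    if len(thick_set) != 1:
        raise ValueError(f"inconsistent thickness across training fingerprints: {sorted(thick_set)}")
    max_bonds = max_set.pop()
    length = fingerprint_length(max_bonds)

    by_metal: dict[int, list[tuple[float, np.ndarray]]] = {}
    for metal, size, fp in training:
        by_metal.setdefault(int(metal), []).append((float(size), fp.vector))

    coefficients: dict[int, np.ndarray] = {}
    support: dict[int, np.ndarray] = {}
    for metal, rows in by_metal.items():
        if len(rows) < 2:
            raise ValueError(
                f"metal Z={metal}: need >= 2 training structures, got {len(rows)}"
            )
        sizes = np.array([s for s, _ in rows])
        if len(np.unique(sizes)) < 2:
            raise ValueError(f"metal Z={metal}: need >= 2 distinct sizes")
        counts = np.vstack([v for _, v in rows])[:, _FIRST_COUNT_SLOT:]
        design = np.column_stack([np.ones_like(sizes), np.log(sizes)])
        response = np.log1p(counts)
        beta, *_ = np.linalg.lstsq(design, response, rcond=None)
        coefs = np.zeros((length, 2))
        coefs[_FIRST_COUNT_SLOT:] = beta.T
        coefficients[metal] = coefs
        mask = np.zeros(length, dtype=bool)
        mask[_FIRST_COUNT_SLOT:] = counts.max(axis=0) > 0
        support[metal] = mask
    return FingerprintGenerator(
        max_bonds=int(max_bonds),
        thickness=float(thick_set.pop()),
        coefficients=coefficients,
        support=support,
        training_meta={"n": len(training), "metals": sorted(by_metal)},
    )


def predict_fingerprint(
    gen: FingerprintGenerator, metal: int, size: float
) -> NanoFingerprint:
    """Generate the fingerprint of a (metal, size) pair never structurally built.

    Section-1 slots 1-4 echo the requested parameters; every counting slot
    is ``round(max(0, exp(b0 + b1*log(size)) - 1))`` under that metal's
    fitted coefficients, hard-zeroed outside the training support.
    """
    metal = int(metal)
    if metal not in gen.coefficients:
        raise ValueError(
            f"metal Z={metal} not seen in training (known: {gen.metals()})"
        )
    if size <= 0:
        raise ValueError(f"size must be positive, got {size}")
    coefs = gen.coefficients[metal]
    eta = coefs[:, 0] + coefs[:, 1] * np.log(size)
    counts = np.rint(np.clip(np.expm1(eta), 0.0, None))
    counts[~gen.support[metal]] = 0.0
    vector = counts
    vector[0] = gen.thickness
    vector[1] = gen.max_bonds
    vector[2] = size
    vector[3] = metal
    return NanoFingerprint(
        thickness=gen.thickness,
        max_bonds=gen.max_bonds,
        size=float(size),
        metal_atomic_number=metal,
        n_O_shell=int(vector[4]),
        n_M_shell=int(vector[5]),
        vector=vector,
    )
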