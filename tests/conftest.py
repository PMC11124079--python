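import numpy as np
import pytest

from nanofp import Atom, LatticeSpec, Structure, make_particle
from nanofp.structure_io import write_xyz


@pytest.fixture
def diatomic():
    """A bonded O-Ti pair, 1.95 A apart."""
    return Structure([Atom.of("O", 0, 0, 0), Atom.of("Ti", 1.95, 0, 0)])


@pytest.fixture
def linear_otio():
    """Linear O-Ti-O, both bonds within the cutoff."""
    return Structure(
        [Atom.of("O", -1.9, 0, 0), Atom.of("Ti", 0, 0, 0), Atom.of("O", 1.9, 0, 0)]
    )


@pytest.fixture(scope="session")
def al2o3_30():
    """30-atom alumina-stoichiometry cluster: exactly 18 O and 12 Al.

    Built from the idealised M2O3 lattice by taking the 12 metal and 18
    oxygen sites closest to the origin, so composition is exact by
    construction and the cluster spans roughly 13 A.
    """
    big = make_particle(LatticeSpec("corundum", 4.2, "Al", 16.0))
    o_atoms = sorted(
        (a for a in big.atoms if a.element == "O"),
        key=lambda a: (float(np.linalg.norm(a.position)), tuple(a.position)),
    )[:18]
    al_atoms = sorted(
        (a for a in big.atoms if a.element == "Al"),
        key=lambda a: (float(np.linalg.norm(a.position)), tuple(a.position)),
    )[:12]
    return Structure(o_atoms + al_atoms, comment="Al2O3 30-atom fixture")


@pytest.fixture
def al2o3_30_file(al2o3_30, tmp_path):
    return write_xyz(al2o3_30, tmp_path / "al2o3_30.xyz")


@pytest.fixture(scope="session")
def rocksalt_zno():
    """Rocksalt ZnO-like particle; interior atoms are 6-coordinate."""
    return make_particle(LatticeSpec("rocksalt", 4.2, "Zn", 18.0))


@pytest.fixture(scope="session")
def fluorite_tio2():
    """Fluorite-type TiO2 particle with singly-coordinated surface O."""
    return make_particle(LatticeSpec("rutile", 5.6, "Ti", 26.0))


@pytest.fixture
def random_particle_factory():
    """Small jittered particles for randomised oracle comparisons."""

    def make(seed: int, diameter: float = 9.5) -> Structure:
        rng = np.random.default_rng(seed)
        lattice = ["rocksalt", "rutile"][seed % 2]
        a = 4.2 if lattice == "rocksalt" else 4.4
        return make_particle(
            LatticeSpec(lattice, a, "Zn", diameter),
            seed=seed,
            jitter=float(rng.uniform(0.02, 0.12)),
        )

    return make
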