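import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nanofp import Atom, Structure, build_fingerprint, diff_fingerprints
from nanofp.fingerprint import (
    NanoFingerprint,
    PatternLabel,
    fingerprint_length,
    index_of,
    iter_labels,
)
from nanofp.graph_build import assign_shell, freeze_shell
from nanofp.synthetic import LatticeSpec, make_particle, perturb_optimise

from oracles import naive_fingerprint_vector

P = PatternLabel


class TestLength:
    def test_positive_only_max10(self):
        assert fingerprint_length(10, "positive-only") == 30226

    def test_inclusive_zero_max10(self):
        assert fingerprint_length(10, "inclusive-zero") == 44191

    def test_inclusive_zero_max1(self):
        assert fingerprint_length(1, "inclusive-zero") == 64

    @pytest.mark.parametrize("max_bonds", range(1, 11))
    def test_formula_matches_built_vector(self, diatomic, max_bonds):
        fp = build_fingerprint(diatomic, thickness=2.0, max_bonds=max_bonds)
        assert len(fp.vector) == fingerprint_length(max_bonds)

    def test_invalid_max(self):
        with pytest.raises(ValueError):
            fingerprint_length(0)

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            fingerprint_length(3, "bogus")


class TestIndexOf:
    @pytest.mark.parametrize("max_bonds", [1, 3, 5, 10])
    def test_section3_starts_at_O00(self, max_bonds):
        assert index_of(P.env("O", 0, 0), max_bonds) == 6 + 2 * max_bonds

    @pytest.mark.parametrize("max_bonds", [1, 3, 5, 10])
    def test_O0MAX_position(self, max_bonds):
        assert index_of(P.env("O", 0, max_bonds), max_bonds) == 6 + 2 * max_bonds + max_bonds

    @pytest.mark.parametrize("max_bonds", [1, 2, 3])
    def test_labels_distinct_in_range_and_tile(self, max_bonds):
        positions = [index_of(lab, max_bonds) for lab in iter_labels(max_bonds)]
        assert len(positions) == len(set(positions))
        length = fingerprint_length(max_bonds)
        assert all(6 <= p < length for p in positions)
        # sections 2 and 3 are tiled completely; section 4 canonical labels
        # cover the O-M block fully and the upper triangles of O-O / M-M
        w = max_bonds + 1
        b3 = 6 + 2 * max_bonds
        b4 = b3 + 2 * w * w
        sec2 = {p for p in positions if p < b3}
        sec3 = {p for p in positions if b3 <= p < b4}
        assert sec2 == set(range(6, b3))
        assert sec3 == set(range(b3, b4))
        om_block = set(range(b4 + 2 * w**4, fingerprint_length(max_bonds)))
        assert om_block <= {p for p in positions}
        n_canonical_sym = w * w * (w * w + 1) // 2
        assert sum(1 for p in positions if b4 <= p < b4 + w**4) == n_canonical_sym

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            index_of(P.atom("O", 4), 3)
        with pytest.raises(ValueError):
            index_of(P.env("M", 0, 4), 3)
        with pytest.raises(ValueError):
            index_of(P.atom("O", 0), 3)  # section-2 c starts at 1

    def test_symmetric_pair_canonicalised(self):
        a = index_of(P.pair("O-O", (0, 1), (1, 0)), 3)
        b = index_of(P.pair("O-O", (1, 0), (0, 1)), 3)
        assert a == b
        # O-M is NOT canonicalised: O env first, M env second
        c = index_of(P.pair("O-M", (0, 1), (1, 0)), 3)
        d = index_of(P.pair("O-M", (1, 0), (0, 1)), 3)
        assert c != d


class TestWorkedExamples:
    def test_diatomic(self, diatomic):
        from nanofp.graph_build import compute_size

        fp = build_fingerprint(diatomic, thickness=compute_size(diatomic), max_bonds=2)
        expected = {
            P.atom("O", 1): 1,
            P.atom("M", 1): 1,
            P.env("O", 0, 1): 1,
            P.env("M", 1, 0): 1,
            P.pair("O-M", (0, 1), (1, 0)): 1,
        }
        for lab, count in expected.items():
            assert fp.get(lab) == count, str(lab)
        idx = {index_of(lab, 2) for lab in expected}
        rest = [v for i, v in enumerate(fp.vector[6:], start=6) if i not in idx]
        assert all(v == 0 for v in rest)

    def test_linear_otio(self, linear_otio):
        fp = build_fingerprint(linear_otio, thickness=100.0, max_bonds=2)
        assert fp.get(P.atom("M", 2)) == 1
        assert fp.get(P.atom("O", 1)) == 2
        assert fp.get(P.env("M", 2, 0)) == 1
        assert fp.get(P.env("O", 0, 1)) == 2
        assert fp.get(P.pair("O-M", (0, 1), (2, 0))) == 2

    def test_section1(self, diatomic):
        fp = build_fingerprint(diatomic, thickness=3.0, max_bonds=4)
        assert fp.section1 == (3.0, 4, pytest.approx(1.95), 22, 1, 1)
        assert list(fp.vector[:6]) == [3.0, 4, pytest.approx(1.95), 22, 1, 1]


class TestBuildErrors:
    def test_two_metals(self):
        s = Structure(
            [Atom.of("O", 0, 0, 0), Atom.of("Ti", 2, 0, 0), Atom.of("Zn", 4, 0, 0)]
        )
        with pytest.raises(ValueError, match="more than one metal"):
            build_fingerprint(s, thickness=5.0, max_bonds=3)

    def test_no_metal(self):
        s = Structure([Atom.of("O", 0, 0, 0), Atom.of("O", 2, 0, 0)])
        with pytest.raises(ValueError, match="no metal"):
            build_fingerprint(s, thickness=5.0, max_bonds=3)

    def test_no_oxygen(self):
        s = Structure([Atom.of("Ti", 0, 0, 0), Atom.of("Ti", 2, 0, 0)])
        with pytest.raises(ValueError, match="no oxygen"):
            build_fingerprint(s, thickness=5.0, max_bonds=3)

    def test_bad_thickness(self, diatomic):
        with pytest.raises(ValueError):
            build_fingerprint(diatomic, thickness=-1.0, max_bonds=3)


class TestInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_section_sums(self, random_particle_factory, seed):
        s = random_particle_factory(seed)
        m = 6
        fp = build_fingerprint(s, thickness=3.0, max_bonds=m)
        from nanofp.graph_build import infer_bonds

        shell = assign_shell(s, 3.0)
        graph = infer_bonds(s).subgraph(shell.is_shell, s.elements)
        deg = graph.degrees
        els = s.elements
        for kind, is_kind in (("O", lambda e: e == "O"), ("M", lambda e: e != "O")):
            sec2 = sum(fp.get(P.atom(kind, c)) for c in range(1, m + 1))
            expected2 = sum(
                1
                for i, e in enumerate(els)
                if shell.is_shell[i] and is_kind(e) and 1 <= deg[i] <= m
            )
            assert sec2 == expected2
            sec3 = sum(
                fp.get(P.env(kind, x, y)) for x in range(m + 1) for y in range(m + 1)
            )
            expected3 = sum(
                1
                for i, e in enumerate(els)
                if shell.is_shell[i] and is_kind(e) and deg[i] <= m
            )
            assert sec3 == expected3
        # section-4 sums equal typed shell bond counts among degree<=MAX atoms
        def pair_sum(kind):
            grid = [(x, y) for x in range(m + 1) for y in range(m + 1)]
            if kind == "O-M":
                return sum(fp.get(P.pair(kind, a, b)) for a in grid for b in grid)
            return sum(
                fp.get(P.pair(kind, grid[i], grid[j]))
                for i in range(len(grid))
                for j in range(i, len(grid))
            )

        ok = lambda i: deg[i] <= m
        n_oo = sum(1 for i, j in graph.edges if els[i] == "O" and els[j] == "O" and ok(i) and ok(j))
        n_mm = sum(1 for i, j in graph.edges if els[i] != "O" and els[j] != "O" and ok(i) and ok(j))
        n_om = sum(1 for i, j in graph.edges if (els[i] == "O") != (els[j] == "O") and ok(i) and ok(j))
        assert pair_sum("O-O") == n_oo
        assert pair_sum("M-M") == n_mm
        assert pair_sum("O-M") == n_om

    def test_rigid_motion_invariance(self, random_particle_factory):
        s = random_particle_factory(2)
        fp0 = build_fingerprint(s, thickness=3.0, max_bonds=5)
        rng = np.random.default_rng(11)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-4, 4, 3)
        moved = Structure([Atom.of(a.element, *(rot @ a.position + shift)) for a in s.atoms])
        fp1 = build_fingerprint(moved, thickness=3.0, max_bonds=5)
        assert np.allclose(fp0.vector, fp1.vector)

    def test_atom_reordering_invariance(self, random_particle_factory):
        s = random_particle_factory(3)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(s))
        shuffled = Structure([s.atoms[i] for i in perm])
        fp0 = build_fingerprint(s, thickness=3.0, max_bonds=5)
        fp1 = build_fingerprint(shuffled, thickness=3.0, max_bonds=5)
        assert np.allclose(fp0.vector, fp1.vector)

    @pytest.mark.parametrize("seed", range(4))
    def test_brute_force_oracle(self, random_particle_factory, seed):
        s = random_particle_factory(seed)
        m = 4
        fp = build_fingerprint(s, thickness=2.5, max_bonds=m)
        expected = naive_fingerprint_vector(s.elements, s.positions, 2.5, m)
        assert np.allclose(fp.vector, expected)

    def test_env_splits_degree(self, random_particle_factory):
        # every shell atom's (x, y) satisfies x + y = its total coordination
        s = random_particle_factory(1)
        from nanofp.graph_build import infer_bonds

        shell = assign_shell(s, 3.0)
        sub = infer_bonds(s).subgraph(shell.is_shell, s.elements)
        for i in range(len(s)):
            if shell.is_shell[i]:
                assert sub.coord_O[i] + sub.coord_M[i] == sub.degrees[i]


class TestDiff:
    def test_self_diff_zero(self, fluorite_tio2):
        fp = build_fingerprint(fluorite_tio2, thickness=4.0, max_bonds=8)
        assert not diff_fingerprints(fp, fp).any()

    def test_removed_singly_coordinated_O(self, fluorite_tio2):
        from nanofp.graph_build import infer_bonds

        s = fluorite_tio2
        m = 10
        thickness = 1e6  # whole particle in the shell for both builds
        g = infer_bonds(s)
        victim = next(
            i for i, e in enumerate(s.elements) if e == "O" and g.degree(i) == 1
        )
        reduced = Structure([a for i, a in enumerate(s.atoms) if i != victim])
        fp_full = build_fingerprint(s, thickness=thickness, max_bonds=m)
        fp_red = build_fingerprint(reduced, thickness=thickness, max_bonds=m)
        d = diff_fingerprints(fp_full, fp_red)
        assert d[index_of(P.atom("O", 1), m)] == 1

    def test_perturb_optimise_positive_at_O1(self, fluorite_tio2):
        s = fluorite_tio2
        m, thickness = 10, 5.0
        shell = assign_shell(s, thickness)
        pert = perturb_optimise(s, rewire_fraction=0.5, seed=3)
        fp_raw = build_fingerprint(s, thickness, m)
        fp_opt = build_fingerprint(pert, thickness, m, shell=freeze_shell(shell, pert))
        d = diff_fingerprints(fp_raw, fp_opt)
        assert d[index_of(P.atom("O", 1), m)] > 0
        assert (d[:6] == 0).all()

    def test_parameter_mismatch(self, diatomic):
        a = build_fingerprint(diatomic, thickness=2.0, max_bonds=2)
        b = build_fingerprint(diatomic, thickness=2.0, max_bonds=3)
        with pytest.raises(ValueError, match="MAX"):
            diff_fingerprints(a, b)


class TestSerialisation:
    def test_text_round_trip(self, random_particle_factory, tmp_path):
        s = random_particle_factory(4)
        fp = build_fingerprint(s, thickness=3.0, max_bonds=5)
        f = fp.to_text(tmp_path / "fp.txt")
        again = NanoFingerprint.from_text(f)
        assert np.allclose(again.vector, fp.vector)
        assert again.section1 == fp.section1

    def test_sparse_format(self, diatomic, tmp_path):
        fp = build_fingerprint(diatomic, thickness=2.0, max_bonds=2)
        text = fp.to_text(tmp_path / "fp.txt").read_text()
        data_lines = [l for l in text.splitlines() if l and not l.startswith("#")]
        assert len(data_lines) == np.count_nonzero(fp.vector)

    def test_dense_csv(self, diatomic, tmp_path):
        import csv

        fp = build_fingerprint(diatomic, thickness=2.0, max_bonds=2)
        f = fp.to_dense_csv(tmp_path / "fp.csv")
        with f.open() as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 1 + len(fp.vector)
        labels = {r[1] for r in rows[1:]}
        assert "O(1)" in labels and "M(1,0)" in labels
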