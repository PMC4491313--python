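"""Cells, symmetry, reflection enumeration and structure factors."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gemmi

import sfxkit as sk
from sfxkit.crystal import FORM_FACTOR_WIDTH, _element_z
from sfxkit.symmetry import SUPPORTED_SYMBOLS, UnsupportedSpaceGroupError

C2_CELL = sk.UnitCell(162.0, 76.3, 151.0, 90.0, 109.0, 90.0)


class TestDSpacing:
    def test_monoclinic_c2_strong_spot(self):
        # the (31, -15, 24) reflection of the big monoclinic cell sits at 2.8 A
        assert round(sk.d_spacing(C2_CELL, (31, -15, 24)), 1) == 2.8

    def test_axis_aligned_orthorhombic(self):
        cell = sk.UnitCell(30.0, 40.0, 151.0)
        assert sk.d_spacing(cell, (0, 0, 1)) == pytest.approx(151.0)

    def test_zero_triple_rejected(self):
        with pytest.raises(ValueError):
            sk.d_spacing(C2_CELL, (0, 0, 0))

    @given(
        st.tuples(*(st.floats(10, 80) for _ in range(3)),
                  *(st.floats(70, 110) for _ in range(3))),
        st.tuples(*(st.integers(-8, 8) for _ in range(3))),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_explicit_basis_construction(self, cellpar, hkl):
        """Metric-tensor d equals 1/|h a* + k b* + l c*| built from explicit
        real-space basis vectors, and is symmetric under index negation."""
        if not any(hkl):
            return
        try:
            cell = sk.UnitCell(*cellpar)
        except ValueError:
            return  # degenerate angle combination
        amat = cell.orthogonalization_matrix()  # columns a, b, c
        astar = np.linalg.inv(amat).T  # columns a*, b*, c*
        svec = astar @ np.array(hkl, float)
        d_oracle = 1.0 / np.linalg.norm(svec)
        assert sk.d_spacing(cell, hkl) == pytest.approx(d_oracle, rel=1e-9)
        neg = tuple(-i for i in hkl)
        assert sk.d_spacing(cell, neg) == pytest.approx(d_oracle, rel=1e-9)

    def test_matches_gemmi(self):
        d_gemmi = C2_CELL.to_gemmi().calculate_d([31, -15, 24])
        assert sk.d_spacing(C2_CELL, (31, -15, 24)) == pytest.approx(d_gemmi, rel=1e-12)


class TestAsuMapping:
    def test_c2_orbit_maps_to_single_representative(self):
        sg = sk.SpaceGroupSetting.from_symbol("C2")
        orbit = [(1, 2, 3), (-1, 2, -3), (-1, -2, -3), (1, -2, 3)]
        reps = {sk.map_to_asu(h, sg) for h in orbit}
        assert len(reps) == 1
        # oracle: explicit application of every operator + inversion
        rots = [np.array(r) for r in sg.rotations]
        all_images = set()
        for h in orbit:
            for r in rots:
                img = tuple(np.array(h) @ r)
                all_images.add(img)
                all_images.add(tuple(-np.array(img)))
        assert reps.pop() in all_images

    def test_p1_friedel_fold(self):
        sg = sk.SpaceGroupSetting.from_symbol("P1")
        assert sk.map_to_asu((-1, -2, -3), sg) == (1, 2, 3)

    @pytest.mark.parametrize("symbol", SUPPORTED_SYMBOLS)
    def test_idempotent_and_orbit_consistent(self, symbol):
        sg = sk.SpaceGroupSetting.from_symbol(symbol)
        rng = np.random.default_rng(1)
        hkl = rng.integers(-9, 10, size=(50, 3))
        hkl = hkl[np.any(hkl != 0, axis=1)]
        reps = sk.map_to_asu_array(hkl, sg)
        assert np.array_equal(sk.map_to_asu_array(reps, sg), reps)
        # every orbit member maps to the same representative
        for rot in sg.rotations:
            assert np.array_equal(sk.map_to_asu_array(hkl @ rot, sg), reps)
        assert np.array_equal(sk.map_to_asu_array(-hkl, sg), reps)

    def test_operations_closed_under_composition(self):
        for symbol in SUPPORTED_SYMBOLS:
            sg = sk.SpaceGroupSetting.from_symbol(symbol)
            mats = {tuple(np.asarray(r).ravel()) for r in sg.rotations}
            for r1 in sg.rotations:
                for r2 in sg.rotations:
                    assert tuple((np.asarray(r1) @ np.asarray(r2)).ravel()) in mats

    def test_unsupported_symbol_raises(self):
        with pytest.raises(UnsupportedSpaceGroupError):
            sk.SpaceGroupSetting.from_symbol("P6322")


class TestEnumeration:
    def test_small_p1_matches_brute_force(self):
        cell = sk.UnitCell(10.0, 10.0, 10.0)
        sg = sk.SpaceGroupSetting.from_symbol("P1")
        got = sk.enumerate_unique_reflections(cell, sg, 100.0, 5.0)
        # brute force over |h|,|k|,|l| <= 2 with hemisphere deduplication
        seen = set()
        for h in range(-2, 3):
            for k in range(-2, 3):
                for l in range(-2, 3):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    d = sk.d_spacing(cell, (h, k, l))
                    if 5.0 <= d <= 100.0:
                        seen.add(max((h, k, l), (-h, -k, -l)))
        assert len(got) == len(seen)
        assert set(map(tuple, got.tolist())) == seen

    def test_c2_systematic_absences(self):
        cell = sk.UnitCell(30.0, 20.0, 25.0, 90.0, 105.0, 90.0)
        sg = sk.SpaceGroupSetting.from_symbol("C2")
        refl = sk.enumerate_unique_reflections(cell, sg, 50.0, 3.0)
        assert len(refl) > 100
        assert np.all((refl[:, 0] + refl[:, 1]) % 2 == 0)

    def test_absences_agree_with_gemmi(self):
        sg = sk.SpaceGroupSetting.from_symbol("P42_12")
        rng = np.random.default_rng(0)
        hkl = rng.integers(-6, 7, size=(200, 3))
        hkl = hkl[np.any(hkl != 0, axis=1)]
        ours = sg.absent_mask(hkl)
        ops = sg.gemmi_ops()
        theirs = np.array([ops.is_systematically_absent(list(map(int, h)))
                           for h in hkl])
        assert np.array_equal(ours, theirs)

    def test_d_min_beyond_cell_gives_empty_list(self):
        cell = sk.UnitCell(10.0, 10.0, 10.0)
        sg = sk.SpaceGroupSetting.from_symbol("P1")
        got = sk.enumerate_unique_reflections(cell, sg, 100.0, 20.0)
        assert len(got) == 0

    def test_parseval_monotonic_with_resolution(self, toy_structure):
        sums = []
        for d_min in (5.0, 4.0, 3.0, 2.5):
            sfs = sk.calc_structure_factors(toy_structure, 30.0, d_min)
            sums.append(np.sum(sfs.amplitudes**2))
        assert all(b > a for a, b in zip(sums, sums[1:]))


class TestStructureFactors:
    def setup_method(self):
        self.cell = sk.UnitCell(12.0, 15.0, 18.0)
        self.p1 = sk.SpaceGroupSetting.from_symbol("P1")

    def test_origin_atom_gives_form_factor_amplitudes(self):
        st_ = sk.ToyStructure(self.cell, self.p1, [sk.Atom("C", 0, 0, 0, b=0.0)])
        sfs = sk.calc_structure_factors(st_, 20.0, 3.0)
        s = 1.0 / sfs.d
        expected = 6.0 * np.exp(-FORM_FACTOR_WIDTH["C"] * s**2)
        assert np.allclose(sfs.amplitudes, expected, rtol=1e-12)
        assert np.allclose(np.degrees(np.angle(sfs.f)) % 360.0, 0.0, atol=1e-8)

    def test_half_cell_shift_alternates_h00_signs(self):
        st_ = sk.ToyStructure(self.cell, self.p1, [sk.Atom("C", 0.5, 0, 0, b=0.0)])
        sfs = sk.calc_structure_factors(st_, 20.0, 3.0)
        h00 = sfs.hkl[:, 1:].sum(axis=1) == 0
        f = sfs.f[h00]
        h = sfs.hkl[h00, 0]
        assert np.allclose(f.imag, 0.0, atol=1e-9)
        assert np.all(np.sign(f.real) == (-1.0) ** h)

    @pytest.mark.parametrize("symbol", ["P1", "C2", "P42_12"])
    def test_matches_direct_summation_oracle(self, symbol):
        """Direct complex sum over all atoms and symmetry copies, written
        independently with explicit loops."""
        cell = sk.UnitCell(14.0, 11.0, 13.0, 90.0, 97.0 if symbol == "C2" else 90.0, 90.0)
        if symbol == "P42_12":
            cell = sk.UnitCell(14.0, 14.0, 13.0)
        sg = sk.SpaceGroupSetting.from_symbol(symbol)
        struct = sk.random_structure(cell, sg, n_atoms=5, seed=4)
        sfs = sk.calc_structure_factors(struct, 20.0, 3.5)
        ops = [(np.array(op.rot, float) / op.DEN, np.array(op.tran, float) / op.DEN)
               for op in sg.gemmi_ops()]
        for h, f_fast in list(zip(sfs.hkl.tolist(), sfs.f))[::17]:
            f_slow = 0.0
            s2 = 1.0 / sk.d_spacing(cell, h) ** 2
            for at in struct.atoms:
                z = _element_z(at.element)
                w = FORM_FACTOR_WIDTH[at.element.upper()]
                ff = at.occ * z * np.exp(-w * s2) * np.exp(-at.b * s2 / 4)
                for rot, tran in ops:
                    x = rot @ np.array([at.x, at.y, at.z]) + tran
                    f_slow += ff * np.exp(2j * np.pi * np.dot(h, x))
            assert abs(f_fast - f_slow) <= 1e-8 * max(1.0, abs(f_slow))

    def test_friedel_symmetry_and_anomalous_breaking(self):
        struct = sk.random_structure(self.cell, self.p1, n_atoms=6, seed=1,
                                     anomalous_atom="FE", fpp=4.0)
        no_fpp = sk.ToyStructure(self.cell, self.p1, struct.atoms[:-1])
        sfs = sk.calc_structure_factors(no_fpp, 20.0, 3.0, anomalous=True)
        lut = {tuple(h): f for h, f in zip(sfs.hkl.tolist(), sfs.f)}
        diffs = [abs(abs(lut[h]) - abs(lut[(-h[0], -h[1], -h[2])]))
                 for h in lut if (-h[0], -h[1], -h[2]) in lut]
        assert max(diffs) < 1e-9  # no anomalous term: |F(h)| = |F(-h)|
        sfs2 = sk.calc_structure_factors(struct, 20.0, 3.0, anomalous=True)
        lut2 = {tuple(h): f for h, f in zip(sfs2.hkl.tolist(), sfs2.f)}
        diffs2 = [abs(abs(lut2[h]) - abs(lut2[(-h[0], -h[1], -h[2])]))
                  for h in lut2 if (-h[0], -h[1], -h[2]) in lut2]
        assert max(diffs2) > 1e-3  # f'' breaks some Friedel pair

    def test_lattice_translation_leaves_amplitudes_unchanged(self):
        struct = sk.random_structure(self.cell, self.p1, n_atoms=5, seed=2)
        shifted = sk.ToyStructure(
            self.cell, self.p1,
            [sk.Atom(a.element, a.x + 1.0, a.y + 2.0, a.z - 1.0, b=a.b, occ=a.occ)
             for a in struct.atoms],
        )
        f1 = sk.calc_structure_factors(struct, 20.0, 3.0)
        f2 = sk.calc_structure_factors(shifted, 20.0, 3.0)
        assert np.allclose(f1.amplitudes, f2.amplitudes, rtol=1e-10)

    def test_empty_structure_and_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            sk.calc_structure_factors(
                sk.ToyStructure(self.cell, self.p1, []), 20.0, 3.0)
        with pytest.raises(ValueError):
            sk.Atom("Xx", 0, 0, 0)


class TestPdbRoundTrip:
    def test_round_trip_preserves_structure(self, tmp_path, toy_structure):
        path = tmp_path / "toy.pdb"
        toy_structure.to_pdb(path)
        back = sk.ToyStructure.from_pdb(path, spacegroup="C2")
        assert len(back.atoms) == len(toy_structure.atoms)
        for a, b in zip(toy_structure.atoms, back.atoms):
            assert a.element.upper() == b.element.upper()
            assert np.allclose([a.x, a.y, a.z], [b.x, b.y, b.z], atol=1e-3)
            assert a.b == pytest.approx(b.b, abs=0.01)
        assert back.cell.a == pytest.approx(toy_structure.cell.a, abs=1e-3)
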