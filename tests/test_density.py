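"""Difference maps, sigma-level peak search, density profiles, anomalous
difference Fouriers."""

import numpy as np
import pandas as pd
import pytest

import sfxkit as sk
from sfxkit.density import MapGrid, synthesize_map
from sfxkit.validate import ScrambleSpec

from conftest import min_symmetry_distance


def _exact_merged(sfs, free_seed=0):
    df = pd.DataFrame({
        "h": sfs.hkl[:, 0], "k": sfs.hkl[:, 1], "l": sfs.hkl[:, 2],
        "d": sfs.d, "I": sfs.amplitudes**2, "sigma": 1.0, "n": 2,
        "I_A": sfs.amplitudes**2, "n_A": 1,
        "I_B": sfs.amplitudes**2, "n_B": 1,
        "free": np.random.default_rng(free_seed).random(len(sfs)) < 0.05,
    })
    return sk.MergedSet(sfs.cell, sfs.spacegroup, sfs.d_max, sfs.d_min, df)


@pytest.fixture(scope="module")
def omit_setup():
    cell = sk.UnitCell(24.0, 20.0, 26.0, 90.0, 100.0, 90.0)
    sg = sk.SpaceGroupSetting.from_symbol("P2_1")
    full = sk.random_structure(cell, sg, n_atoms=20, seed=6)
    omit = sk.ToyStructure(cell, sg, full.atoms[:-1])
    sfs_full = sk.calc_structure_factors(full, 20.0, 2.2)
    sfs_omit = sk.calc_structure_factors(omit, 20.0, 2.2)
    return {"cell": cell, "sg": sg, "full": full, "omit": omit,
            "sfs_full": sfs_full, "sfs_omit": sfs_omit,
            "site": full.atoms[-1].frac}


class TestSynthesis:
    def test_fourier_round_trip(self, toy_sfs):
        grid = synthesize_map(toy_sfs.cell, toy_sfs.hkl, toy_sfs.f,
                              d_min=toy_sfs.d_min)
        # analyse the synthesized map back into coefficients
        coeffs = np.fft.fftn(grid.values) * toy_sfs.cell.volume / grid.values.size
        shape = grid.shape
        recovered = np.array([
            coeffs[tuple((-h) % n for h, n in zip(hkl, shape))]
            for hkl in toy_sfs.hkl.tolist()
        ])
        # F000 was not synthesized, so compare after removing the mean term
        assert np.allclose(recovered, toy_sfs.f, atol=1e-6 * np.abs(toy_sfs.f).max())

    def test_aliasing_guard(self, toy_sfs):
        with pytest.raises(ValueError):
            synthesize_map(toy_sfs.cell, toy_sfs.hkl, toy_sfs.f,
                           d_min=toy_sfs.d_min, oversample=0.5)


class TestDifferenceMap:
    def test_null_difference_is_numerically_zero(self, omit_setup):
        sfs = omit_setup["sfs_full"]
        m = _exact_merged(sfs)
        grid = sk.difference_map(m, sfs)
        one_atom = sk.ToyStructure(
            omit_setup["cell"], omit_setup["sg"],
            [sk.Atom("C", 0.3, 0.4, 0.5, b=20.0)])
        ref = sk.calc_structure_factors(one_atom, 20.0, 2.2)
        ref_grid = synthesize_map(sfs.cell, ref.hkl, ref.f, d_min=2.2)
        assert np.abs(grid.values).max() < 1e-6 * np.abs(ref_grid.values).max()

    def test_omitted_atom_is_strongest_positive_peak(self, omit_setup):
        m = _exact_merged(omit_setup["sfs_full"])
        grid = sk.difference_map(m, omit_setup["sfs_omit"])
        peaks = sk.find_map_peaks(grid, sigma_level=3.0)
        top = peaks[0]
        assert top.sign > 0
        step = max(l / n for l, n in zip(omit_setup["cell"].lengths, grid.shape))
        dist = min_symmetry_distance(omit_setup["cell"], omit_setup["sg"],
                                     top.frac, omit_setup["site"])
        assert dist <= 0.5 * step

    def test_spurious_model_atom_is_strongest_negative_peak(self, omit_setup):
        m = _exact_merged(omit_setup["sfs_omit"])
        grid = sk.difference_map(m, omit_setup["sfs_full"])
        top = sk.find_map_peaks(grid, sigma_level=3.0)[0]
        assert top.sign < 0
        dist = min_symmetry_distance(omit_setup["cell"], omit_setup["sg"],
                                     top.frac, omit_setup["site"])
        step = max(l / n for l, n in zip(omit_setup["cell"].lengths, grid.shape))
        assert dist <= 0.5 * step

    def test_peak_height_invariant_to_global_amplitude_scale(self, omit_setup):
        m = _exact_merged(omit_setup["sfs_full"])
        m2 = m.copy()
        m2.df["I"] *= 7.3**2
        h1 = sk.find_map_peaks(sk.difference_map(m, omit_setup["sfs_omit"]),
                               3.0)[0].height_sigma
        h2 = sk.find_map_peaks(sk.difference_map(m2, omit_setup["sfs_omit"]),
                               3.0)[0].height_sigma
        assert h1 == pytest.approx(h2, rel=1e-3)

    def test_omit_peak_degrades_with_amplitude_noise(self, omit_setup):
        heights = []
        rng = np.random.default_rng(14)
        base = _exact_merged(omit_setup["sfs_full"])
        amp = np.sqrt(base.df["I"].to_numpy())
        noise = rng.standard_normal(len(amp)) * np.median(amp)
        for level in (0.0, 0.3, 0.9):
            m = base.copy()
            m.df["I"] = (amp + level * noise) ** 2
            grid = sk.difference_map(m, omit_setup["sfs_omit"])
            heights.append(sk.find_map_peaks(grid, 2.0)[0].abs_height)
        assert heights[0] > heights[1] > heights[2]


class TestFindMapPeaks:
    def test_constant_map_has_no_peaks(self):
        grid = MapGrid(sk.UnitCell(10, 10, 10), np.ones((8, 8, 8)))
        assert sk.find_map_peaks(grid) == []

    def test_planted_gaussian_blob(self):
        cell = sk.UnitCell(16.0, 16.0, 16.0)
        n = 32
        idx = np.indices((n, n, n))
        centre = np.array([10.0, 17.0, 24.0])
        r2 = np.sum((idx - centre[:, None, None, None]) ** 2, axis=0)
        vals = 100.0 * np.exp(-r2 / (2 * 2.0**2))
        grid = MapGrid(cell, vals)
        peaks = sk.find_map_peaks(grid, sigma_level=3.0)
        assert len(peaks) == 1
        expected = (100.0 - vals.mean()) / grid.sigma
        assert peaks[0].height_sigma == pytest.approx(expected, rel=0.05)
        assert np.allclose(np.array(peaks[0].frac) * n, centre, atol=0.3)

    def test_threshold_above_maximum_gives_empty_list(self):
        rng = np.random.default_rng(2)
        grid = MapGrid(sk.UnitCell(10, 10, 10), rng.standard_normal((12, 12, 12)))
        top = max(p.abs_height for p in sk.find_map_peaks(grid, 1.0))
        assert sk.find_map_peaks(grid, top * 1.01) == []


class TestDensityProfile:
    def test_profile_rises_then_plateaus_at_information_limit(self, omit_setup):
        """Data real to 3.0 A and scrambled beyond: the omit-site signal
        grows with the cutoff and levels off past 3.0 A."""
        m = _exact_merged(omit_setup["sfs_full"])
        scr = sk.scramble_intensities(m, ScrambleSpec(seed=4))
        data = sk.make_chimeric(m, scr, 3.0)
        ladder = [6.0, 4.5, 3.7, 3.0, 2.6, 2.3]
        prof = sk.density_profile(data, omit_setup["sfs_omit"],
                                  omit_setup["site"], ladder)
        h = dict(zip(prof["cutoff_d"], prof["height_sigma"]))
        assert h[3.0] > h[4.5] > h[6.0]
        assert abs(h[2.3] - h[2.6]) <= 0.10 * abs(h[2.6])

    def test_signal_site_beats_empty_site_at_every_rung(self, omit_setup):
        m = _exact_merged(omit_setup["sfs_full"])
        ladder = [5.0, 4.0, 3.0, 2.5]
        site = omit_setup["site"]
        prof = sk.density_profile(m, omit_setup["sfs_omit"], site, ladder)
        # a position far from every atom and symmetry copy
        empty = np.array([0.52, 0.13, 0.82])
        prof0 = sk.density_profile(m, omit_setup["sfs_omit"], empty, ladder)
        assert np.all(prof["height_sigma"].to_numpy() >
                      prof0["height_sigma"].to_numpy())

    def test_single_rung_equals_direct_map_value(self, omit_setup):
        m = _exact_merged(omit_setup["sfs_full"])
        prof = sk.density_profile(m, omit_setup["sfs_omit"],
                                  omit_setup["site"], [3.0])
        grid = sk.difference_map(m, omit_setup["sfs_omit"], cutoff_d=3.0)
        assert len(prof) == 1
        assert prof["height_sigma"].iloc[0] == pytest.approx(
            grid.value_at(omit_setup["site"]), rel=1e-9)


class TestAnomalousMap:
    @staticmethod
    def _setup(fpp, seed, n_patterns=800):
        cell = sk.UnitCell(18.0, 15.0, 20.0)
        sg = sk.SpaceGroupSetting.from_symbol("P1")
        struct = sk.random_structure(cell, sg, n_atoms=8, seed=4,
                                     anomalous_atom="FE", fpp=fpp)
        sfs = sk.calc_structure_factors(struct, 15.0, 3.5, anomalous=True)
        model = sk.calc_structure_factors(struct, 15.0, 3.5, anomalous=False)
        params = sk.SimulationParams(n_patterns=n_patterns, seed=seed,
                                     anomalous=True, excite_rate=0.3,
                                     noise_floor_frac=0.02)
        pats = sk.simulate_stills(sfs, params)
        merged = sk.monte_carlo_merge(pats, cell, sg, 15.0, 3.5,
                                      friedel_merge=False, split_seed=seed)
        return struct, model, merged

    def test_planted_scatterer_is_strongest_peak(self):
        struct, model, merged = self._setup(fpp=8.0, seed=11, n_patterns=1500)
        grid = sk.anomalous_difference_map(merged, model)
        top = sk.find_map_peaks(grid, sigma_level=3.0)[0]
        site = struct.atoms[-1].frac
        dist = min_symmetry_distance(struct.cell, struct.spacegroup,
                                     top.frac, site)
        step = max(l / n for l, n in zip(struct.cell.lengths, grid.shape))
        assert top.sign > 0
        assert dist <= 1.5 * step

    def test_no_anomalous_scatterer_rarely_exceeds_4_sigma(self):
        exceed = 0
        n_reps = 10
        for seed in range(n_reps):
            _, model, merged = self._setup(fpp=0.0, seed=seed, n_patterns=400)
            # low-resolution cutoff as in practice: few coefficients keep
            # the noise-field extreme below the contour level
            grid = sk.anomalous_difference_map(merged, model, cutoff_d=5.0)
            if sk.find_map_peaks(grid, sigma_level=4.0):
                exceed += 1
        assert exceed <= max(1, int(0.05 * n_reps) + 1)

    def test_peak_height_monotone_in_fpp(self):
        heights = []
        for fpp in (2.0, 4.0, 8.0):
            struct, model, merged = self._setup(fpp=fpp, seed=5,
                                                n_patterns=1000)
            grid = sk.anomalous_difference_map(merged, model)
            site = struct.atoms[-1].frac
            # absolute density: the sigma unit itself grows once the
            # anomalous signal dominates the map variance
            heights.append(grid.value_at(site, in_sigma=False))
        assert heights[0] < heights[1] < heights[2]

    def test_friedel_merged_input_rejected(self, merged_default, toy_sfs):
        with pytest.raises(ValueError):
            sk.anomalous_difference_map(merged_default, toy_sfs)
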