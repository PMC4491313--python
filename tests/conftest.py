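import numpy as np
import pytest

import sfxkit as sk


@pytest.fixture(scope="session")
def toy_structure():
    return sk.default_toy_structure()


@pytest.fixture(scope="session")
def toy_sfs(toy_structure):
    return sk.calc_structure_factors(toy_structure, 30.0, 2.5)


@pytest.fixture(scope="session")
def patterns_default(toy_sfs):
    params = sk.SimulationParams(n_patterns=500, seed=3)
    return sk.simulate_stills(toy_sfs, params)


@pytest.fixture(scope="session")
def merged_default(patterns_default, toy_structure):
    return sk.monte_carlo_merge(
        patterns_default, toy_structure.cell, toy_structure.spacegroup,
        30.0, 2.5, split_seed=5,
    )


@pytest.fixture(scope="session")
def c2_bench():
    """Noiseless C2 benchmark: ~5300 unique reflections to 2.8 A from
    2000 stills, used by the scramble/chimera and resolution-scan suites."""
    cell = sk.UnitCell(70.0, 40.0, 80.0, 90.0, 109.0, 90.0)
    sg = sk.SpaceGroupSetting.from_symbol("C2")
    structure = sk.random_structure(cell, sg, n_atoms=40, seed=2)
    sfs = sk.calc_structure_factors(structure, 40.0, 2.8)
    params = sk.SimulationParams(
        n_patterns=2000, seed=9, noise_floor_frac=0.0, noise_poisson_b=0.0,
    )
    patterns = sk.simulate_stills(sfs, params)
    merged = sk.monte_carlo_merge(patterns, cell, sg, 40.0, 2.8, split_seed=5)
    return {"structure": structure, "sfs": sfs, "merged": merged}


def min_symmetry_distance(cell, sg, frac_a, frac_b):
    """Minimum Cartesian distance between frac_a and any symmetry copy of
    frac_b (including lattice translations)."""
    ortho = cell.orthogonalization_matrix()
    frac_a = np.asarray(frac_a) % 1.0
    best = np.inf
    for op in sg.gemmi_ops():
        rot = np.array(op.rot, float) / op.DEN
        tran = np.array(op.tran, float) / op.DEN
        img = (rot @ (np.asarray(frac_b) % 1.0) + tran) % 1.0
        delta = (img - frac_a + 0.5) % 1.0 - 0.5
        best = min(best, float(np.linalg.norm(ortho @ delta)))
    return best
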