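"""Toy crystal structures and ground-truth structure factors.

A ``ToyStructure`` is a handful of point atoms with isotropic B factors
in a small unit cell; its structure factors, computed by direct
summation with single-Gaussian form factors, are the ground truth that
the still simulator, merger and density tools are tested against.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .symmetry import SpaceGroupSetting, map_to_asu_array, _lex_keys

__all__ = [
    "UnitCell",
    "Atom",
    "ToyStructure",
    "StructureFactorSet",
    "d_spacing",
    "enumerate_unique_reflections",
    "calc_structure_factors",
    "random_structure",
    "default_toy_structure",
]

# single-Gaussian form factors f(s) = Z * exp(-w s^2), s = 1/d.
# Z from the periodic table; widths (A^2) decrease for heavier elements.
FORM_FACTOR_WIDTH = {
    "H": 6.0, "C": 4.0, "N": 3.6, "O": 3.2, "NA": 3.0, "MG": 2.9,
    "P": 2.8, "S": 2.8, "CL": 2.7, "K": 2.6, "CA": 2.5, "V": 2.4,
    "MN": 2.3, "FE": 2.2, "ZN": 2.1, "SE": 2.0,
}


class UnknownElementError(ValueError):
    pass


def _element_z(symbol: str) -> int:
    el = gemmi.Element(symbol.capitalize())
    if el.atomic_number == 0:
        raise UnknownElementError(f"unknown element {symbol!r}")
    return el.atomic_number


@dataclass(frozen=True)
class UnitCell:
    """Unit cell with lengths in Angstrom and angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        if self.volume <= 0:
            raise ValueError("cell volume is not positive")

    @property
    def lengths(self):
        return (self.a, self.b, self.c)

    @property
    def angles(self):
        return (self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in self.angles)
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return float(self.a * self.b * self.c * np.sqrt(max(arg, 0.0)))

    def orthogonalization_matrix(self) -> np.ndarray:
        """Columns are the Cartesian cell vectors a, b, c (a along x)."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in self.angles)
        sg = np.sin(np.radians(self.gamma))
        v = np.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    def reciprocal_matrix(self) -> np.ndarray:
        """Columns are the Cartesian reciprocal vectors a*, b*, c*."""
        return np.linalg.inv(self.orthogonalization_matrix()).T

    def reciprocal_metric(self) -> np.ndarray:
        bmat = self.reciprocal_matrix()
        return bmat.T @ bmat

    def d_spacings(self, hkl: np.ndarray) -> np.ndarray:
        """Vectorised d-spacings for an (N, 3) index array."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        gstar = self.reciprocal_metric()
        s2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
        if np.any(s2 <= 0):
            raise ValueError("d-spacing undefined for the (0,0,0) reflection")
        return 1.0 / np.sqrt(s2)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.lengths, *self.angles)


def d_spacing(cell: UnitCell, hkl) -> float:
    """Resolution d = 1/|h a* + k b* + l c*| in Angstrom (triclinic metric)."""
    hkl = np.asarray(hkl)
    if hkl.shape != (3,):
        raise ValueError("hkl must be a single index triple")
    if not np.any(hkl):
        raise ValueError("d-spacing undefined for the (0,0,0) reflection")
    return float(cell.d_spacings(hkl[None, :])[0])


@dataclass
class Atom:
    """Point scatterer with fractional coordinates.

    ``fpp`` is the imaginary anomalous correction f'' in electrons; it
    breaks Friedel symmetry when structure factors are computed in
    anomalous mode.
    """

    element: str
    x: float
    y: float
    z: float
    b: float = 20.0
    occ: float = 1.0
    fpp: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.b < 0:
            raise ValueError("B factor must be non-negative")
        _element_z(self.element)  # validates element symbol

    @property
    def frac(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z]) % 1.0


@dataclass
class ToyStructure:
    cell: UnitCell
    spacegroup: SpaceGroupSetting
    atoms: list
    ligand_indices: tuple = ()

    def __post_init__(self):
        self.atoms = [
            dataclasses.replace(at, x=at.x % 1.0, y=at.y % 1.0, z=at.z % 1.0)
            for at in self.atoms
        ]

    # -- symmetry expansion -------------------------------------------
    def expanded_positions(self):
        """Positions, elements, B, occ, f'' for all symmetry copies."""
        ops = list(self.spacegroup.gemmi_ops())
        frac = np.array([[at.x, at.y, at.z] for at in self.atoms])
        pos, idx = [], []
        for op in ops:
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            pos.append((frac @ rot.T + tran) % 1.0)
            idx.append(np.arange(len(self.atoms)))
        return np.concatenate(pos), np.concatenate(idx)

    def mean_f_squared(self, s: np.ndarray) -> np.ndarray:
        """Sum over atoms of f(s)^2 (one asymmetric unit), for Wilson scaling."""
        s2 = np.asarray(s, dtype=float) ** 2
        total = np.zeros_like(s2)
        for at in self.atoms:
            z = _element_z(at.element)
            w = FORM_FACTOR_WIDTH.get(at.element.upper(), 3.0)
            total += (at.occ * z * np.exp(-w * s2)) ** 2
        return total

    # -- PDB round trip ------------------------------------------------
    def to_pdb(self, path) -> None:
        st = gemmi.Structure()
        st.cell = self.cell.to_gemmi()
        st.spacegroup_hm = self.spacegroup.hm_symbol
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        ligset = set(self.ligand_indices)
        for i, at in enumerate(self.atoms):
            res = gemmi.Residue()
            res.name = "LIG" if i in ligset else "TOY"
            res.seqid = gemmi.SeqId(i + 1, " ")
            res.het_flag = "H" if i in ligset else "A"
            ga = gemmi.Atom()
            ga.name = at.element.upper()
            ga.element = gemmi.Element(at.element.capitalize())
            ga.pos = gemmi.Position(
                *(self.cell.orthogonalization_matrix() @ at.frac)
            )
            ga.occ = at.occ
            ga.b_iso = at.b
            res.add_atom(ga)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))

    @classmethod
    def from_pdb(cls, path, spacegroup: str | None = None) -> "ToyStructure":
        st = gemmi.read_structure(str(path))
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
        symbol = spacegroup or st.spacegroup_hm or "P1"
        sg = SpaceGroupSetting.from_symbol(symbol.replace(" ", ""))
        frac_mat = np.linalg.inv(cell.orthogonalization_matrix())
        atoms, ligand = [], []
        i = 0
        for model in st:
            for chain in model:
                for res in chain:
                    for ga in res:
                        xyz = frac_mat @ np.array([ga.pos.x, ga.pos.y, ga.pos.z])
                        atoms.append(
                            Atom(ga.element.name, *(xyz % 1.0), b=ga.b_iso, occ=ga.occ)
                        )
                        if res.het_flag == "H" or res.name == "LIG":
                            ligand.append(i)
                        i += 1
            break
        return cls(cell, sg, atoms, tuple(ligand))


@dataclass
class StructureFactorSet:
    """Unique reflections with complex structure factors.

    ``friedel_separate`` marks anomalous mode, in which +h and -h keep
    distinct entries and may differ in amplitude.
    """

    cell: UnitCell
    spacegroup: SpaceGroupSetting
    d_max: float
    d_min: float
    hkl: np.ndarray  # (N, 3) int
    f: np.ndarray  # (N,) complex
    friedel_separate: bool = False

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=np.int64)
        self.f = np.asarray(self.f, dtype=complex)
        if len(self.hkl) != len(self.f):
            raise ValueError("hkl and f length mismatch")

    def __len__(self):
        return len(self.hkl)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.f)

    @property
    def phases_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.f))

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacings(self.hkl)

    def lookup(self) -> dict:
        """Map (h, k, l) tuple -> complex F, including Friedel conjugates."""
        table = {tuple(h): F for h, F in zip(self.hkl.tolist(), self.f)}
        if not self.friedel_separate:
            for h, F in list(table.items()):
                table.setdefault((-h[0], -h[1], -h[2]), np.conj(F))
        return table


def _index_bounds(cell: UnitCell, d_min: float):
    # |h| <= a/d_min since h = s . a_vec and |s| <= 1/d_min
    return tuple(int(np.ceil(length / d_min)) + 1 for length in cell.lengths)


def enumerate_unique_reflections(
    cell: UnitCell,
    sg: SpaceGroupSetting,
    d_max: float,
    d_min: float,
    friedel_merge: bool = True,
) -> np.ndarray:
    """All lattice-allowed unique reflections with d_min <= d <= d_max.

    Systematic absences are excluded, one representative per orbit of
    the Laue group (Friedel merged by default) is kept, and the result
    is sorted lexicographically by (h, k, l).
    """
    if not d_max > d_min > 0:
        raise ValueError("need d_max > d_min > 0")
    hmax, kmax, lmax = _index_bounds(cell, d_min)
    h = np.arange(-hmax, hmax + 1)
    k = np.arange(-kmax, kmax + 1)
    l = np.arange(-lmax, lmax + 1)
    grid = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    d = cell.d_spacings(grid)
    tol = 1e-9
    keep = (d >= d_min * (1 - tol)) & (d <= d_max * (1 + tol))
    grid = grid[keep]
    if len(grid) == 0:
        return np.empty((0, 3), dtype=np.int64)
    grid = grid[~sg.absent_mask(grid)]
    reps = map_to_asu_array(grid, sg, friedel_merge=friedel_merge)
    uniq = np.unique(reps, axis=0)
    order = np.argsort(_lex_keys(uniq))
    return uniq[order]


def calc_structure_factors(
    structure: ToyStructure,
    d_max: float,
    d_min: float,
    anomalous: bool = False,
) -> StructureFactorSet:
    """Direct-summation structure factors over all symmetry copies.

    F(hkl) = sum_atoms occ * f(s) * exp(-B s^2 / 4) * exp(2 pi i h.x),
    with f(s) = Z exp(-w s^2) (+ i f'' in anomalous mode).
    """
    if not structure.atoms:
        raise ValueError("structure has no atoms")
    sg = structure.spacegroup
    hkl = enumerate_unique_reflections(
        structure.cell, sg, d_max, d_min, friedel_merge=not anomalous
    )
    pos, atom_idx = structure.expanded_positions()
    s2 = 1.0 / structure.cell.d_spacings(hkl) ** 2
    z = np.array([_element_z(at.element) for at in structure.atoms], dtype=float)
    w = np.array(
        [FORM_FACTOR_WIDTH.get(at.element.upper(), 3.0) for at in structure.atoms]
    )
    b = np.array([at.b for at in structure.atoms])
    occ = np.array([at.occ for at in structure.atoms])
    fpp = np.array([at.fpp for at in structure.atoms])

    # per unique atom: occ * f(s) * Debye-Waller, shape (n_atoms, n_hkl)
    f_atom = occ[:, None] * z[:, None] * np.exp(-np.outer(w, s2)) * np.exp(
        -np.outer(b, s2) / 4.0
    )
    if anomalous:
        f_atom = f_atom.astype(complex)
        f_atom += 1j * occ[:, None] * fpp[:, None] * np.exp(-np.outer(b, s2) / 4.0)
    phase = np.exp(2j * np.pi * (pos @ hkl.T))  # (n_copies, n_hkl)
    f = np.einsum("ch,ch->h", f_atom[atom_idx], phase)
    return StructureFactorSet(
        structure.cell, sg, d_max, d_min, hkl, f, friedel_separate=anomalous
    )


# -- canned structures -------------------------------------------------

def random_structure(
    cell: UnitCell,
    sg: SpaceGroupSetting,
    n_atoms: int = 20,
    seed: int = 0,
    elements=("C", "N", "O"),
    b_range=(10.0, 40.0),
    anomalous_atom: str | None = None,
    fpp: float = 4.0,
) -> ToyStructure:
    """Random toy structure; optionally appends one anomalous scatterer."""
    rng = np.random.default_rng(seed)
    atoms = []
    for _ in range(n_atoms):
        atoms.append(
            Atom(
                element=str(rng.choice(elements)),
                x=rng.random(), y=rng.random(), z=rng.random(),
                b=float(rng.uniform(*b_range)),
            )
        )
    ligand = ()
    if anomalous_atom is not None:
        atoms.append(
            Atom(anomalous_atom, rng.random(), rng.random(), rng.random(),
                 b=float(np.mean(b_range)), fpp=fpp)
        )
        ligand = (len(atoms) - 1,)
    return ToyStructure(cell, sg, atoms, ligand)


def default_toy_structure(seed: int = 7) -> ToyStructure:
    """A ~20-atom C2 toy crystal used as the pipeline default."""
    cell = UnitCell(34.0, 22.0, 30.0, 90.0, 105.0, 90.0)
    sg = SpaceGroupSetting.from_symbol("C2")
    return random_structure(cell, sg, n_atoms=20, seed=seed)
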