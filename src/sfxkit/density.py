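"""Difference Fourier maps, sigma-level peak search, and ligand-density
profiling against resolution cutoffs.

Maps use unweighted difference coefficients (|F_o| - k e^{-Bs^2/4}|F_c|)
with model phases (the maximum-likelihood m/D weighting of a full
refinement engine is deliberately not emulated); an anomalous difference
Fourier uses (|F+| - |F-|) with model phase - 90 deg.  Map values are
reported in sigma units (rms of the mean-subtracted grid).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

import gemmi

from .crystal import StructureFactorSet, UnitCell
from .merge import MergedSet
from .symmetry import map_to_asu_array
from .validate import AmplitudeScaleModel, ScaleModel

logger = logging.getLogger(__name__)

__all__ = [
    "MapGrid", "MapPeak", "difference_map", "find_map_peaks",
    "density_profile", "anomalous_difference_map", "synthesize_map",
]


@dataclass
class MapGrid:
    """Real-space density on a periodic grid over one unit cell.

    Values are stored mean-subtracted; ``sigma`` is the rms density, the
    unit in which peak heights are quoted.
    """

    cell: UnitCell
    values: np.ndarray  # 3-D, fractional origin at grid point (0,0,0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.values = self.values - self.values.mean()

    @property
    def shape(self):
        return self.values.shape

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.mean(self.values**2)))

    def sigma_scaled(self) -> np.ndarray:
        s = self.sigma
        if s == 0:
            raise ValueError("constant map has no sigma unit")
        return self.values / s

    def value_at(self, frac, in_sigma: bool = True) -> float:
        """Trilinear interpolation at a fractional position."""
        frac = np.asarray(frac, dtype=float) % 1.0
        coords = (frac * self.shape).reshape(3, 1)
        v = float(ndimage.map_coordinates(self.values, coords, order=1,
                                          mode="grid-wrap")[0])
        return v / self.sigma if in_sigma else v

    def write_ccp4(self, path) -> None:
        grid = gemmi.FloatGrid(np.ascontiguousarray(self.values, dtype=np.float32))
        grid.unit_cell = self.cell.to_gemmi()
        grid.spacegroup = gemmi.SpaceGroup("P 1")
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))


def _grid_shape(cell: UnitCell, d_min: float, oversample: float) -> tuple:
    dims = []
    for length in cell.lengths:
        n = int(np.ceil(oversample * length / d_min))
        dims.append(n + (n % 2))  # even sizes
    return tuple(dims)


def synthesize_map(
    cell: UnitCell,
    hkl: np.ndarray,
    coeffs: np.ndarray,
    d_min: float,
    oversample: float = 3.0,
    friedel_complete: bool = True,
) -> MapGrid:
    """Inverse Fourier synthesis rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).

    With ``friedel_complete`` the conjugate term is added at -h for every
    coefficient (hemisphere input), making the map real.
    """
    shape = _grid_shape(cell, d_min, oversample)
    if any(n < 2 for n in shape):
        raise ValueError("grid too coarse for the requested resolution")
    hkl = np.asarray(hkl, dtype=np.int64)
    if np.any(np.abs(hkl) * 2 >= np.array(shape)):
        raise ValueError("grid too coarse: indices alias (raise oversample)")
    grid = np.zeros(shape, dtype=complex)
    filled = np.zeros(shape, dtype=bool)
    idx = tuple((-hkl[:, i]) % shape[i] for i in range(3))
    grid[idx] = coeffs
    filled[idx] = True
    if friedel_complete:
        idx_mate = tuple((hkl[:, i]) % shape[i] for i in range(3))
        take = ~filled[idx_mate]
        grid[tuple(ix[take] for ix in idx_mate)] = np.conj(coeffs[take])
    rho = np.fft.ifftn(grid).real * np.prod(shape) / cell.volume
    return MapGrid(cell, rho)


def _difference_coefficients(obs: MergedSet, model_sf: StructureFactorSet,
                             cutoff_d: float | None, scale: ScaleModel | None):
    df = obs.df
    keep = df["d"].to_numpy() >= (cutoff_d or 0.0) * (1 - 1e-9)
    hkl = obs.hkl[keep]
    lut = model_sf.lookup()
    fc = np.array([lut.get(tuple(h), np.nan) for h in hkl.tolist()], dtype=complex)
    missing = np.isnan(fc.real)
    if missing.mean() > 0.05:
        raise ValueError("model phases missing for more than 5% of the data")
    hkl, fc = hkl[~missing], fc[~missing]
    d = df["d"].to_numpy()[keep][~missing]
    fo = np.sqrt(np.clip(df["I"].to_numpy()[keep][~missing], 0.0, None))
    if scale is None:
        scale = AmplitudeScaleModel(model_sf, obs, cutoff_d).fit().scale
    s2 = 1.0 / d**2
    amp = fo - scale.apply(np.abs(fc), s2)
    phase = fc / np.where(np.abs(fc) > 0, np.abs(fc), 1.0)
    return hkl, amp * phase, d


def difference_map(
    obs: MergedSet,
    model_sf: StructureFactorSet,
    cutoff_d: float | None = None,
    scale: ScaleModel | None = None,
    oversample: float = 3.0,
) -> MapGrid:
    """Unweighted Fo-Fc difference map with model phases; (k, B) from the
    standardized scale fit unless supplied."""
    hkl, coeffs, d = _difference_coefficients(obs, model_sf, cutoff_d, scale)
    d_min = cutoff_d if cutoff_d is not None else float(d.min())
    return synthesize_map(obs.cell, hkl, coeffs, d_min, oversample)


@dataclass(frozen=True)
class MapPeak:
    frac: tuple          # fractional coordinates
    height_sigma: float  # signed height in sigma units
    sign: int

    @property
    def abs_height(self) -> float:
        return abs(self.height_sigma)


def _quadratic_refine(values: np.ndarray, index: tuple):
    """Per-axis 3-point quadratic refinement around a grid extremum."""
    offset = np.zeros(3)
    gain = 0.0
    f0 = values[index]
    for ax in range(3):
        lo = list(index); hi = list(index)
        lo[ax] = (index[ax] - 1) % values.shape[ax]
        hi[ax] = (index[ax] + 1) % values.shape[ax]
        fm, fp = values[tuple(lo)], values[tuple(hi)]
        denom = fm - 2 * f0 + fp
        if denom != 0:
            offset[ax] = 0.5 * (fm - fp) / denom
            gain += -0.125 * (fm - fp) ** 2 / denom
    return offset, f0 + gain


def find_map_peaks(map_grid: MapGrid, sigma_level: float = 3.0) -> list:
    """Local extrema with |height| >= sigma_level (in sigma units),
    positions refined by quadratic interpolation, sorted by |height|."""
    sigma = map_grid.sigma
    if sigma == 0:
        return []
    vals = map_grid.values
    peaks = []
    for sign, arr in ((+1, vals), (-1, -vals)):
        is_max = arr == ndimage.maximum_filter(arr, size=3, mode="wrap")
        strong = is_max & (arr >= sigma_level * sigma)
        for index in zip(*np.nonzero(strong)):
            offset, height = _quadratic_refine(arr, index)
            frac = ((np.array(index) + offset) / np.array(vals.shape)) % 1.0
            peaks.append(MapPeak(tuple(frac), sign * height / sigma, sign))
    peaks.sort(key=lambda p: -p.abs_height)
    return peaks


def density_profile(
    obs: MergedSet,
    model_sf: StructureFactorSet,
    site,
    cutoff_ladder,
    min_coefficients: int = 50,
    oversample: float = 3.0,
):
    """Difference-map height (sigma units) at a site for a ladder of
    high-resolution cutoffs; rungs with too few coefficients are skipped."""
    import pandas as pd

    d_all = obs.df["d"].to_numpy()
    rows = []
    for cutoff in sorted(set(float(c) for c in cutoff_ladder), reverse=True):
        n_in = int((d_all >= cutoff * (1 - 1e-9)).sum())
        if n_in < min_coefficients:
            logger.warning("cutoff %.3g A has only %d coefficients; skipped",
                           cutoff, n_in)
            continue
        grid = difference_map(obs, model_sf, cutoff_d=cutoff, oversample=oversample)
        rows.append({"cutoff_d": cutoff, "n_coefficients": n_in,
                     "height_sigma": grid.value_at(site)})
    return pd.DataFrame(rows)


def anomalous_difference_map(
    obs: MergedSet,
    model_sf: StructureFactorSet,
    cutoff_d: float | None = None,
    oversample: float = 3.0,
) -> MapGrid:
    """Anomalous difference Fourier from a Friedel-separate merge:
    coefficients (|F+| - |F-|) exp(i (phi_c - 90 deg))."""
    if not obs.friedel_separate:
        raise ValueError("anomalous map needs data merged with separate Friedel mates")
    df = obs.df
    hkl = obs.hkl
    mates = map_to_asu_array(-hkl, obs.spacegroup, friedel_merge=False)
    pos = {tuple(h): i for i, h in enumerate(hkl.tolist())}
    lut = model_sf.lookup()
    sel_hkl, coeffs, d_used = [], [], []
    for i, h in enumerate(hkl.tolist()):
        m = tuple(mates[i])
        j = pos.get(m)
        if j is None or j <= i or m == tuple(h):
            continue  # unpaired or centric; the j > i member emits the pair
        d = df["d"].iat[i]
        if cutoff_d is not None and d < cutoff_d * (1 - 1e-9):
            continue
        fc = lut.get(tuple(h))
        if fc is None or abs(fc) == 0:
            continue
        f_plus = np.sqrt(max(df["I"].iat[i], 0.0))
        f_minus = np.sqrt(max(df["I"].iat[j], 0.0))
        phase = np.angle(fc) - np.pi / 2.0
        sel_hkl.append(h)
        coeffs.append((f_plus - f_minus) * np.exp(1j * phase))
        d_used.append(d)
    if not sel_hkl:
        raise ValueError("no complete Friedel pairs for the anomalous map")
    d_min = cutoff_d if cutoff_d is not None else float(min(d_used))
    return synthesize_map(obs.cell, np.array(sel_hkl), np.array(coeffs),
                          d_min, oversample)
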