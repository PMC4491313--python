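"""Serial still-diffraction simulator.

Generates per-pattern lists of partial Bragg intensities with the
statistical structure Monte Carlo merging assumes: every pattern is a
randomly oriented crystal, a random subset of reflections is excited,
each recorded intensity is I = G * p * |F|^2 + noise with a per-shot
scale G (log-normal), a partiality p in (0, 1], and a Gaussian noise
model sigma(I) = sqrt(a^2 + b*|I|).  Optionally renders each pattern
onto a flat toy detector for the hit finder.

Partiality model: p = exp(-z^2 / 2) with z ~ N(0, sigma_m), where
sigma_m is the rocking/orientation spread in units of the intrinsic
reflection width.  sigma_m = 0 gives full reflections (p = 1); larger
sigma_m spreads p towards 0, degrading half-set agreement.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .crystal import StructureFactorSet

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationParams",
    "Observation",
    "StillPattern",
    "DetectorGeometry",
    "DetectorImage",
    "energy_to_wavelength",
    "simulate_stills",
    "render_pattern_image",
]

HC_KEV_ANGSTROM = 12.3984


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon wavelength in Angstrom from energy in keV (lambda = hc/E)."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_KEV_ANGSTROM / energy_kev


@dataclass
class SimulationParams:
    """Knobs of the still simulator; defaults give Table-1-like behaviour
    qualitatively (declining signal-to-noise with resolution)."""

    n_patterns: int = 1000
    scale_median: float = 1.0       # median of the log-normal per-shot scale G
    scale_sigma: float = 0.3        # log-sd of G
    sigma_m: float = 1.0            # rocking-width / partiality spread (dimensionless)
    noise_floor_frac: float = 0.05  # a = frac * median |F|^2
    noise_poisson_b: float = 1.0    # b in sigma = sqrt(a^2 + b |I|)
    excite_rate: float = 0.05       # Bernoulli thinning: fraction of reflections per still
    seed: int = 0
    anomalous: bool = False

    def __post_init__(self):
        if self.n_patterns < 0:
            raise ValueError("n_patterns must be >= 0")
        for name in ("scale_sigma", "sigma_m", "noise_floor_frac", "noise_poisson_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.scale_median <= 0:
            raise ValueError("scale_median must be positive")
        if not 0 < self.excite_rate <= 1:
            raise ValueError("excite_rate must lie in (0, 1]")

    @property
    def mean_scale(self) -> float:
        return self.scale_median * float(np.exp(self.scale_sigma**2 / 2))

    @property
    def mean_partiality(self) -> float:
        # E[exp(-z^2/2)] for z ~ N(0, sigma_m)
        return 1.0 / float(np.sqrt(1.0 + self.sigma_m**2))


@dataclass(frozen=True)
class Observation:
    hkl: tuple
    intensity: float
    sigma: float
    pattern_id: int


@dataclass
class StillPattern:
    """One simulated exposure: observed (pre-ASU) indices and intensities."""

    pattern_id: int
    orientation: np.ndarray  # 3x3 rotation matrix
    scale: float
    hkl: np.ndarray          # (n, 3) int, as observed
    intensity: np.ndarray    # (n,)
    sigma: np.ndarray        # (n,)

    def __len__(self):
        return len(self.hkl)

    def iter_observations(self):
        for h, i, s in zip(self.hkl.tolist(), self.intensity, self.sigma):
            yield Observation(tuple(h), float(i), float(s), self.pattern_id)


def simulate_stills(sfs: StructureFactorSet, params: SimulationParams) -> list:
    """Simulate a serial data set; same seed gives identical output."""
    if len(sfs) == 0:
        raise ValueError("structure-factor set is empty")
    if params.n_patterns == 0:
        return []
    root = np.random.SeedSequence(params.seed)
    s_orient, s_scale, s_excite, s_part, s_noise = root.spawn(5)
    rng_or = np.random.default_rng(s_orient)
    rng_g = np.random.default_rng(s_scale)
    rng_ex = np.random.default_rng(s_excite)
    rng_p = np.random.default_rng(s_part)
    rng_n = np.random.default_rng(s_noise)

    f2 = sfs.amplitudes**2
    noise_a = params.noise_floor_frac * float(np.median(f2))
    scales = params.scale_median * np.exp(
        params.scale_sigma * rng_g.standard_normal(params.n_patterns)
    )
    rotmats = Rotation.random(params.n_patterns, random_state=rng_or).as_matrix()
    sg = sfs.spacegroup
    n_refl = len(sfs)
    patterns = []
    for pid in range(params.n_patterns):
        mask = rng_ex.random(n_refl) < params.excite_rate
        idx = np.flatnonzero(mask)
        z = rng_p.standard_normal(len(idx)) * params.sigma_m
        p = np.exp(-0.5 * z * z)
        i_true = scales[pid] * p * f2[idx]
        sig = np.sqrt(noise_a**2 + params.noise_poisson_b * np.abs(i_true))
        i_obs = i_true + sig * rng_n.standard_normal(len(idx))
        # scatter observed indices over the orbit (pre-ASU indices)
        ops = sg.rotations
        op_pick = rng_ex.integers(0, len(ops), len(idx))
        hkl_obs = np.empty((len(idx), 3), dtype=np.int64)
        for j, rot in enumerate(ops):
            sel = op_pick == j
            hkl_obs[sel] = sfs.hkl[idx[sel]] @ rot
        if not sfs.friedel_separate:
            flip = rng_ex.random(len(idx)) < 0.5
            hkl_obs[flip] *= -1
        patterns.append(
            StillPattern(
                pattern_id=pid,
                orientation=rotmats[pid],
                scale=float(scales[pid]),
                hkl=hkl_obs,
                intensity=i_obs,
                sigma=np.maximum(sig, 1e-12),
            )
        )
    return patterns


# -- detector rendering ------------------------------------------------

@dataclass
class DetectorGeometry:
    """Flat single-panel detector; defaults follow a CSPAD-like setup
    (110 um pixels, 130 mm distance, 2.07 A beam)."""

    n_rows: int = 512
    n_cols: int = 512
    pixel_um: float = 110.0
    distance_mm: float = 130.0
    wavelength: float = 2.07
    beam_center: tuple = None  # (row, col), defaults to panel centre

    def __post_init__(self):
        if min(self.n_rows, self.n_cols) <= 0:
            raise ValueError("detector dimensions must be positive")
        for name in ("pixel_um", "distance_mm", "wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beam_center is None:
            self.beam_center = ((self.n_rows - 1) / 2.0, (self.n_cols - 1) / 2.0)


@dataclass
class DetectorImage:
    pixels: np.ndarray
    geometry: DetectorGeometry
    pattern_id: int = -1

    def __post_init__(self):
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("detector image contains non-finite pixels")


def render_pattern_image(
    pattern: StillPattern,
    sfs: StructureFactorSet,
    geometry: DetectorGeometry | None = None,
    background_level: float = 50.0,
    gain: float = 1.0,
    spot_sigma_px: float = 1.3,
    seed: int | None = None,
) -> DetectorImage:
    """Render a still as a 2-D image in ADU.

    Each observation becomes a Gaussian spot of integrated ADU gain*I at
    the flat-detector projection of its scattering vector; background is
    Poisson about ``background_level``.  Spots projecting off the panel
    are dropped with a log notice.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    geom = geometry or DetectorGeometry()
    rng = np.random.default_rng(
        pattern.pattern_id + 1 if seed is None else seed
    )
    img = rng.poisson(background_level, (geom.n_rows, geom.n_cols)).astype(float)

    bmat = sfs.cell.reciprocal_matrix()  # columns a*, b*, c*
    lam = geom.wavelength
    k_in = np.array([0.0, 0.0, 1.0 / lam])
    n_dropped = 0
    for h, inten in zip(pattern.hkl, pattern.intensity):
        if inten <= 0:
            continue
        q = pattern.orientation @ (bmat @ h)
        k_out = k_in + q
        norm = np.linalg.norm(k_out)
        if norm == 0:
            n_dropped += 1
            continue
        k_out *= (1.0 / lam) / norm
        if k_out[2] <= 0:
            n_dropped += 1
            continue
        x_mm = geom.distance_mm * k_out[0] / k_out[2]
        y_mm = geom.distance_mm * k_out[1] / k_out[2]
        col = geom.beam_center[1] + x_mm * 1000.0 / geom.pixel_um
        row = geom.beam_center[0] + y_mm * 1000.0 / geom.pixel_um
        if not (0 <= row < geom.n_rows and 0 <= col < geom.n_cols):
            n_dropped += 1
            continue
        _add_gaussian_spot(img, row, col, gain * float(inten), spot_sigma_px)
    if n_dropped:
        logger.warning(
            "pattern %d: %d reflections projected off-panel or backward",
            pattern.pattern_id, n_dropped,
        )
    return DetectorImage(img, geom, pattern.pattern_id)


def _add_gaussian_spot(img, row, col, total_adu, sigma_px):
    half = int(np.ceil(4 * sigma_px))
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0c, r1c = max(r0, 0), min(r1, img.shape[0])
    c0c, c1c = max(c0, 0), min(c1, img.shape[1])
    if r0c >= r1c or c0c >= c1c:
        return
    rr, cc = np.meshgrid(np.arange(r0c, r1c), np.arange(c0c, c1c), indexing="ij")
    g = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma_px**2))
    img[r0c:r1c, c0c:c1c] += total_adu * g / (2 * np.pi * sigma_px**2)


def mark_indexable(patterns, n_min: int = 15) -> np.ndarray:
    """Stand-in for autoindexing: a pattern is indexable iff it carries at
    least ``n_min`` observations."""
    return np.array([len(p) >= n_min for p in patterns])
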