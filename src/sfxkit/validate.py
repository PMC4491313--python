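"""Model-based data validation: intensity scrambling, chimeric splices,
a standardized scale-model R-factor engine, and the paired
stepwise-resolution ("effective resolution") comparison.

The R engine is deliberately minimal: against ground-truth model
amplitudes it fits only a linear scale k and an overall B factor,
|F_o| ~ k * exp(-B s^2/4) * |F_c|, and reports amplitude R factors over
work and cross-validation (free) reflections.  All of the validation
logic — per-resolution-bin scrambling, chimeric splicing, the paired
scan and deviation-point detection — is independent of which R engine
sits underneath.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .crystal import StructureFactorSet
from .merge import MergedSet
from .metrics import shell_edges_equal_count

logger = logging.getLogger(__name__)

__all__ = [
    "ScrambleSpec", "ScaleModel", "RefinementReport", "ResolutionScanReport",
    "scramble_intensities", "make_chimeric",
    "AmplitudeScaleModel", "ScaleFitResults", "scale_and_rfactors",
    "paired_resolution_scan", "detect_deviation_point",
    "DEFAULT_SPLICE_CUTOFFS",
]

DEFAULT_SPLICE_CUTOFFS = (5.8, 4.6, 4.0, 3.6, 3.4, 3.2, 3.0, 2.9)

_SCRAMBLE_COLS = ["I", "sigma", "n", "I_A", "n_A", "I_B", "n_B"]


@dataclass(frozen=True)
class ScrambleSpec:
    bin_size: int = 10
    seed: int = 0
    cutoffs: tuple = DEFAULT_SPLICE_CUTOFFS

    def __post_init__(self):
        if self.bin_size < 2:
            raise ValueError("scramble bin size must be >= 2")
        cuts = tuple(self.cutoffs)
        if any(b >= a for a, b in zip(cuts[:-1], cuts[1:])):
            raise ValueError("splice cutoffs must be strictly decreasing")


def scramble_intensities(merged: MergedSet, spec: ScrambleSpec) -> MergedSet:
    """Permute (I, sigma) within consecutive resolution bins of ``bin_size``
    reflections, leaving indices, d and free flags in place.

    Reflections are sorted by descending d (ties broken lexicographically
    by h, k, l) so the resolution dependence of the intensity statistics
    is preserved while the per-reflection assignment is destroyed.
    """
    out = merged.copy()
    df = out.df
    order = np.lexsort((df["l"], df["k"], df["h"], -df["d"].to_numpy()))
    rng = np.random.default_rng(spec.seed)
    values = df.iloc[order][_SCRAMBLE_COLS].to_numpy(dtype=object)
    for start in range(0, len(df), spec.bin_size):
        stop = min(start + spec.bin_size, len(df))
        perm = rng.permutation(stop - start)
        values[start:stop] = values[start:stop][perm]
    for j, col in enumerate(_SCRAMBLE_COLS):
        arr = np.empty(len(df), dtype=df[col].to_numpy().dtype)
        arr[order] = values[:, j]
        df[col] = arr
    out.provenance["scramble"] = {"bin_size": spec.bin_size, "seed": spec.seed}
    return out


def make_chimeric(original: MergedSet, scrambled: MergedSet, cutoff_d: float) -> MergedSet:
    """Real data at d >= cutoff, scrambled beyond; free flags follow the
    original reflection indices throughout."""
    if not np.array_equal(original.hkl, scrambled.hkl):
        raise ValueError("original and scrambled sets index different reflections")
    out = original.copy()
    beyond = out.df["d"].to_numpy() < cutoff_d
    out.df.loc[beyond, _SCRAMBLE_COLS] = scrambled.df.loc[beyond, _SCRAMBLE_COLS].to_numpy()
    out.df["free"] = original.df["free"].to_numpy()
    out.provenance["chimera_cutoff"] = cutoff_d
    return out


# -- scale-model R-factor engine --------------------------------------

@dataclass(frozen=True)
class ScaleModel:
    """Linear scale and overall B applied to calculated amplitudes."""

    k: float
    b: float

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("scale k must be positive")

    def apply(self, f_calc: np.ndarray, s2: np.ndarray) -> np.ndarray:
        return self.k * np.exp(-self.b * s2 / 4.0) * f_calc


def _r_factor(f_obs, f_scaled) -> float:
    denom = np.sum(f_obs)
    if denom == 0:
        return np.nan
    return float(np.sum(np.abs(f_obs - f_scaled)) / denom)


@dataclass
class RefinementReport:
    cutoff_d: float | None
    scale: ScaleModel
    r_work: float        # fractions, not percent
    r_free: float
    shell_curves: pd.DataFrame  # d_low d_high n_work n_free r_work r_free
    n_work: int
    n_free: int


class AmplitudeScaleModel:
    """Two-parameter (k, B) amplitude scale model, statsmodels-style.

    Parameters
    ----------
    model_sf : calculated structure factors supplying |F_c| and phases.
    data : merged intensity set; amplitudes are sqrt(max(I, 0)).
    cutoff_d : optional high-resolution cutoff (keep d >= cutoff_d).
    """

    def __init__(self, model_sf: StructureFactorSet, data: MergedSet,
                 cutoff_d: float | None = None):
        if model_sf.cell.lengths != data.cell.lengths or \
           model_sf.spacegroup.symbol != data.spacegroup.symbol:
            raise ValueError("model and data disagree on cell/symmetry")
        self.model_sf = model_sf
        self.data = data
        self.cutoff_d = cutoff_d

        lut = model_sf.lookup()
        df = data.df
        keep = df["d"].to_numpy() >= (cutoff_d or 0.0) * (1 - 1e-9)
        hkl = data.hkl[keep]
        fc = np.array([abs(lut.get(tuple(h), np.nan)) for h in hkl.tolist()])
        ok = ~np.isnan(fc)
        if (~ok).mean() > 0.05:
            raise ValueError("model lacks structure factors for >5% of the data")
        self.f_obs = np.sqrt(np.clip(df["I"].to_numpy()[keep][ok], 0.0, None))
        self.f_calc = fc[ok]
        self.d = df["d"].to_numpy()[keep][ok]
        self.s2 = 1.0 / self.d**2
        self.free = df["free"].to_numpy()[keep][ok].astype(bool)
        if (~self.free).sum() < 20:
            raise ValueError("need at least 20 work reflections")
        if not self.free.any():
            warnings.warn("empty free set; R_free will be reported as NaN")

    def _k_of_b(self, b: float, sel: np.ndarray) -> float:
        w = np.exp(-b * self.s2[sel] / 4.0) * self.f_calc[sel]
        denom = np.sum(w * w)
        return float(np.sum(self.f_obs[sel] * w) / denom) if denom > 0 else 1.0

    def fit(self, b_bounds=(-300.0, 300.0), shell_edges=None, n_shells: int = 12):
        """Least-squares fit of (k, B) on work reflections; returns
        :class:`ScaleFitResults`."""
        work = ~self.free

        def objective(b):
            k = self._k_of_b(b, work)
            resid = self.f_obs[work] - k * np.exp(-b * self.s2[work] / 4.0) * self.f_calc[work]
            return float(np.sum(resid * resid))

        res = minimize_scalar(objective, bounds=b_bounds, method="bounded",
                              options={"xatol": 1e-6})
        if not res.success:
            raise RuntimeError(f"scale/B fit failed to converge: {res}")
        b = float(res.x)
        k = self._k_of_b(b, work)
        if k <= 0:
            raise RuntimeError("fitted scale is non-positive (degenerate data)")
        scale = ScaleModel(k, b)
        f_scaled = scale.apply(self.f_calc, self.s2)

        if shell_edges is None:
            shell_edges = shell_edges_equal_count(self.d, min(n_shells, max(1, len(self.d) // 20)))
        rows = []
        for i, (lo, hi) in enumerate(zip(shell_edges[:-1], shell_edges[1:])):
            sel = (self.d <= lo * (1 + 1e-9)) & (self.d > hi * (1 + 1e-9))
            if i == len(shell_edges) - 2:
                sel |= np.isclose(self.d, shell_edges[-1], rtol=1e-9)
            sw, sf = sel & work, sel & self.free
            rows.append({
                "d_low": lo, "d_high": hi,
                "n_work": int(sw.sum()), "n_free": int(sf.sum()),
                "r_work": _r_factor(self.f_obs[sw], f_scaled[sw]) if sw.any() else np.nan,
                "r_free": _r_factor(self.f_obs[sf], f_scaled[sf]) if sf.any() else np.nan,
            })
        return ScaleFitResults(
            model=self,
            scale=scale,
            r_work=_r_factor(self.f_obs[work], f_scaled[work]),
            r_free=(_r_factor(self.f_obs[self.free], f_scaled[self.free])
                    if self.free.any() else np.nan),
            shell_curves=pd.DataFrame(rows),
        )


@dataclass
class ScaleFitResults:
    model: AmplitudeScaleModel
    scale: ScaleModel
    r_work: float
    r_free: float
    shell_curves: pd.DataFrame

    @property
    def n_work(self) -> int:
        return int((~self.model.free).sum())

    @property
    def n_free(self) -> int:
        return int(self.model.free.sum())

    def evaluate(self, d_min: float | None = None) -> tuple:
        """(R_work, R_free) of this fit on reflections with d >= d_min."""
        m = self.model
        sel = np.ones(len(m.d), dtype=bool) if d_min is None else m.d >= d_min * (1 - 1e-9)
        f_scaled = self.scale.apply(m.f_calc, m.s2)
        work, free = sel & ~m.free, sel & m.free
        return (_r_factor(m.f_obs[work], f_scaled[work]),
                _r_factor(m.f_obs[free], f_scaled[free]) if free.any() else np.nan)

    def report(self) -> RefinementReport:
        return RefinementReport(
            cutoff_d=self.model.cutoff_d, scale=self.scale,
            r_work=self.r_work, r_free=self.r_free,
            shell_curves=self.shell_curves,
            n_work=self.n_work, n_free=self.n_free,
        )

    def summary(self) -> str:
        lines = [
            "Amplitude scale model (|Fo| ~ k exp(-B s^2/4) |Fc|)",
            f"  cutoff d      : {self.model.cutoff_d}",
            f"  n_work/n_free : {self.n_work}/{self.n_free}",
            f"  k             : {self.scale.k:.6g}",
            f"  B overall     : {self.scale.b:.4f} A^2",
            f"  R_work        : {100 * self.r_work:.1f} %",
            f"  R_free        : {100 * self.r_free:.1f} %",
        ]
        return "\n".join(lines)


def scale_and_rfactors(
    model_sf: StructureFactorSet,
    data: MergedSet,
    cutoff_d: float | None = None,
    shell_edges=None,
    n_shells: int = 12,
) -> RefinementReport:
    """Fit the standardized scale model and report R_work/R_free overall
    and per shell, using only reflections with d >= cutoff_d."""
    fit = AmplitudeScaleModel(model_sf, data, cutoff_d).fit(
        shell_edges=shell_edges, n_shells=n_shells
    )
    return fit.report()


# -- paired stepwise-resolution scan -----------------------------------

@dataclass
class ResolutionScanReport:
    ladder: tuple
    rungs: pd.DataFrame       # d_low d_high r_free_low r_free_high delta_r_free
    effective_resolution: float
    tolerance: float


def paired_resolution_scan(
    model_sf: StructureFactorSet,
    data: MergedSet,
    cutoff_ladder,
    tolerance: float = 0.0,
    min_rung_reflections: int = 20,
) -> ResolutionScanReport:
    """Paired comparison over a ladder of high-resolution cutoffs.

    For each adjacent pair (d_low, d_high) the scale model is fitted at
    both cutoffs and both fits are evaluated on the common d >= d_low
    set; the declared effective resolution is the finest d_high whose
    inclusion does not worsen R_free by more than ``tolerance``
    (fractional R units).
    """
    ladder = tuple(sorted(set(float(x) for x in cutoff_ladder), reverse=True))
    if len(ladder) < 2:
        raise ValueError("cutoff ladder needs at least 2 rungs")
    d_all = data.df["d"].to_numpy()
    rows = []
    fits = {}
    for cutoff in ladder:
        n_in = int((d_all >= cutoff * (1 - 1e-9)).sum())
        if n_in < min_rung_reflections:
            logger.warning("rung %.3g A has %d (<%d) reflections; skipped",
                           cutoff, n_in, min_rung_reflections)
            continue
        fits[cutoff] = AmplitudeScaleModel(model_sf, data, cutoff).fit()
    usable = sorted(fits, reverse=True)
    for d_low, d_high in zip(usable[:-1], usable[1:]):
        _, rf_low = fits[d_low].evaluate(d_min=d_low)
        _, rf_high = fits[d_high].evaluate(d_min=d_low)
        rows.append({
            "d_low": d_low, "d_high": d_high,
            "r_free_low": rf_low, "r_free_high": rf_high,
            "delta_r_free": rf_high - rf_low,
        })
    rungs = pd.DataFrame(rows)
    good = rungs[rungs["delta_r_free"] <= tolerance + 1e-12]
    effective = float(good["d_high"].min()) if len(good) else float(usable[0])
    return ResolutionScanReport(tuple(usable), rungs, effective, tolerance)


def detect_deviation_point(
    reference_curve, test_curve, threshold: float = 0.10
) -> int | None:
    """First shell (index, low resolution first) from which the test
    R_free curve exceeds the reference by more than ``threshold`` in that
    shell and every finer one; None if it never does.

    The default threshold (10 R-factor points) sits between the few
    points of scale-model leakage a corrupted resolution range induces
    in clean shells through the global (k, B) fit and the tens of points
    that scrambled data add in their own shells.
    """
    ref = np.asarray(reference_curve, dtype=float)
    test = np.asarray(test_curve, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("curves are on different shell grids")
    excess = test - ref > threshold
    ok = ~(np.isnan(ref) | np.isnan(test))
    for i in range(len(ref)):
        tail = slice(i, None)
        if np.all(excess[tail] | ~ok[tail]) and np.any(ok[tail]):
            return i
    return None
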