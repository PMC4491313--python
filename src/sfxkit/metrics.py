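"""Half-set data-quality statistics per resolution shell.

Implements the serial-crystallography quality indicators: R_split (the
half-data-set R factor with its 1/sqrt(2) multiplicity correction),
CC1/2 (Pearson correlation of half-set intensities), the CC* estimate
of the correlation of the merged data with the true signal, a Student-t
significance test for CC1/2, the anomalous half-set correlation, mean
I/sigma, and a Wilson-slope overall-B estimate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .merge import MergedSet
from .symmetry import map_to_asu_array

__all__ = [
    "r_split", "cc_half", "cc_star", "cc_half_significance",
    "SignificanceResult", "ShellTable", "summarize_shells",
    "shell_edges_equal_count", "shell_edges_equal_volume",
    "anomalous_differences", "anomalous_cc", "wilson_b",
]


def r_split(half_a, half_b) -> float:
    """R_split in percent: 2^(-1/2) * sum|I_A - I_B| / (0.5 * sum(I_A + I_B))."""
    a = np.asarray(half_a, dtype=float)
    b = np.asarray(half_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("half-set intensity lists must be paired 1-D arrays")
    if len(a) == 0:
        raise ValueError("empty half-set pairing")
    denom = 0.5 * np.sum(a + b)
    if denom == 0:
        raise ZeroDivisionError("zero denominator in R_split")
    return float(100.0 * np.sum(np.abs(a - b)) / denom / np.sqrt(2.0))


def cc_half(half_a, half_b) -> float:
    """Pearson correlation between paired half-set intensities."""
    a = np.asarray(half_a, dtype=float)
    b = np.asarray(half_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need >= 3 paired reflections")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a half set")
    return float(np.corrcoef(a, b)[0, 1])


def cc_star(cc_half_value: float) -> float:
    """CC* = sqrt(2 CC1/2 / (1 + CC1/2)); undefined (NaN) for CC1/2 < 0."""
    if cc_half_value <= -1.0:
        raise ValueError("CC1/2 must exceed -1")
    if cc_half_value > 1.0:
        raise ValueError("CC1/2 cannot exceed 1")
    if cc_half_value < 0.0:
        warnings.warn("CC* undefined for negative CC1/2; returning NaN")
        return float("nan")
    return float(np.sqrt(2.0 * cc_half_value / (1.0 + cc_half_value)))


@dataclass(frozen=True)
class SignificanceResult:
    cc_half: float
    n: int
    t: float
    p_value: float  # one-sided, testing CC1/2 > 0


def cc_half_significance(cc_half_value: float, n: int) -> SignificanceResult:
    """Student-t significance of a CC1/2 against zero.

    t = CC * sqrt((n-2)/(1-CC^2)), one-sided P from t_{n-2}.
    """
    if n < 3:
        raise ValueError("need n >= 3 reflections")
    cc = float(cc_half_value)
    if abs(cc) >= 1.0:
        t = np.inf if cc > 0 else -np.inf
        return SignificanceResult(cc, n, float(t), 0.0 if cc > 0 else 1.0)
    t = cc * np.sqrt((n - 2) / (1.0 - cc * cc))
    p = float(sps.t.sf(t, df=n - 2))
    return SignificanceResult(cc, n, float(t), p)


# -- shell schemes -----------------------------------------------------

def shell_edges_equal_count(d: np.ndarray, n_shells: int) -> np.ndarray:
    """Descending d edges putting ~equal reflection counts in each shell."""
    d = np.sort(np.asarray(d, dtype=float))[::-1]
    if n_shells < 1 or len(d) < n_shells:
        raise ValueError("fewer reflections than shells")
    qs = np.linspace(0, 1, n_shells + 1)
    edges = np.quantile(d, 1 - qs)
    edges[0], edges[-1] = d[0], d[-1]
    return edges


def shell_edges_equal_volume(d_max: float, d_min: float, n_shells: int) -> np.ndarray:
    """Descending d edges with equal reciprocal-space volume (s^3) per shell."""
    s3 = np.linspace(d_max**-3, d_min**-3, n_shells + 1)
    return s3 ** (-1.0 / 3.0)


def _shell_masks(d: np.ndarray, edges: np.ndarray):
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = (d <= lo * (1 + 1e-9)) & (d > hi * (1 + 1e-9))
        if i == len(edges) - 2:
            sel |= np.isclose(d, edges[-1], rtol=1e-9)
        yield lo, hi, sel


# -- anomalous ---------------------------------------------------------

def anomalous_differences(merged: MergedSet) -> pd.DataFrame:
    """Join Friedel mates of a Friedel-separate merge.

    Returns one row per acentric pair with columns dI_A, dI_B (half-set
    Friedel differences), dI (merged difference), d.
    """
    if not merged.friedel_separate:
        raise ValueError("anomalous differences need a Friedel-separate merge")
    df = merged.df
    mates = map_to_asu_array(-merged.hkl, merged.spacegroup, friedel_merge=False)
    key = pd.MultiIndex.from_arrays([df["h"], df["k"], df["l"]])
    mate_key = pd.MultiIndex.from_arrays([mates[:, 0], mates[:, 1], mates[:, 2]])
    indexed = df.set_index(key)
    mate_rows = indexed.reindex(mate_key)
    centric = np.all(mates == merged.hkl, axis=1)
    plus_first = ~centric & (np.arange(len(df)) < indexed.index.get_indexer(mate_key))
    out = pd.DataFrame({
        "d": df["d"].to_numpy(),
        "dI": df["I"].to_numpy() - mate_rows["I"].to_numpy(),
        "dI_A": df["I_A"].to_numpy() - mate_rows["I_A"].to_numpy(),
        "dI_B": df["I_B"].to_numpy() - mate_rows["I_B"].to_numpy(),
    })[plus_first]
    return out.dropna()


def anomalous_cc(merged: MergedSet) -> float:
    """Pearson correlation of half-set Friedel differences."""
    pairs = anomalous_differences(merged)
    if len(pairs) < 3:
        raise ValueError("too few complete Friedel pairs for anomalous CC")
    return float(np.corrcoef(pairs["dI_A"], pairs["dI_B"])[0, 1])


# -- Wilson fit --------------------------------------------------------

def wilson_b(d: np.ndarray, intensity: np.ndarray, structure=None,
             n_bins: int = 12, d_fit_max: float | None = None) -> float:
    """Overall B from the Wilson slope of ln<I> (optionally normalised by
    the structure's sum f^2) against s^2; B = -2 * slope.

    Without a structure the raw slope also absorbs the form-factor
    falloff, so pass the composition when an absolute B is wanted.
    """
    d = np.asarray(d, float)
    inten = np.asarray(intensity, float)
    sel = inten > 0
    if d_fit_max is not None:
        sel &= d <= d_fit_max
    d, inten = d[sel], inten[sel]
    if len(d) < 2 * n_bins:
        raise ValueError("too few reflections for a Wilson fit")
    s2 = 1.0 / d**2
    norm = inten / structure.mean_f_squared(1.0 / d) if structure is not None else inten
    edges = np.quantile(s2, np.linspace(0, 1, n_bins + 1))
    x, y = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (s2 >= lo) & (s2 <= hi)
        if m.sum() < 3 or np.mean(norm[m]) <= 0:
            continue
        x.append(np.mean(s2[m]))
        y.append(np.log(np.mean(norm[m])))
    slope = np.polyfit(x, y, 1)[0]
    return float(-2.0 * slope)


# -- shell table -------------------------------------------------------

@dataclass
class ShellTable:
    """Per-shell quality metrics plus an overall row (dicts/DataFrame)."""

    edges: np.ndarray
    shells: pd.DataFrame
    overall: dict

    def __str__(self):
        lines = [self.shells.to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        lines.append("overall: " + "  ".join(
            f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
            for k, v in self.overall.items()))
        return "\n".join(lines)


def _metrics_for(sub: pd.DataFrame) -> dict:
    both = sub.dropna(subset=["I_A", "I_B"])
    both = both[(both["n_A"] > 0) & (both["n_B"] > 0)]
    row = {"n": len(sub)}
    ios = (sub["I"] / sub["sigma"]).replace([np.inf, -np.inf], np.nan).dropna()
    row["i_over_sigma"] = float(ios.mean()) if len(ios) else np.nan
    row["frac_i_over_sigma_gt1"] = float((ios > 1).mean()) if len(ios) else np.nan
    row["multiplicity"] = float(sub["n"].mean()) if len(sub) else np.nan
    if len(both) >= 3 and both["I_A"].std() > 0 and both["I_B"].std() > 0:
        cc = cc_half(both["I_A"], both["I_B"])
        row["cc_half"] = cc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["cc_star"] = cc_star(min(cc, 1.0)) if cc >= 0 else np.nan
        denom = 0.5 * float(np.sum(both["I_A"] + both["I_B"]))
        row["r_split"] = (r_split(both["I_A"], both["I_B"])
                          if denom != 0 else np.nan)
    else:
        row["cc_half"] = row["cc_star"] = row["r_split"] = np.nan
    return row


def summarize_shells(
    merged: MergedSet,
    n_shells: int = 10,
    scheme: str = "count",
    structure=None,
) -> ShellTable:
    """Build the per-shell quality table (R_split, CC1/2, CC*, I/sigma,
    completeness, multiplicity, anomalous CC where applicable)."""
    df = merged.df
    if len(df) < n_shells:
        raise ValueError("fewer reflections than shells")
    d = df["d"].to_numpy()
    if scheme == "count":
        edges = shell_edges_equal_count(d, n_shells)
    elif scheme == "volume":
        edges = shell_edges_equal_volume(d.max(), d.min(), n_shells)
    else:
        raise ValueError("scheme must be 'count' or 'volume'")

    from .merge import coverage_stats
    cov, cov_all = coverage_stats(merged, shell_edges=edges)

    anom = None
    if merged.friedel_separate:
        try:
            anom = anomalous_differences(merged)
        except ValueError:
            anom = None

    rows = []
    for i, (lo, hi, sel) in enumerate(_shell_masks(d, edges)):
        sub = df[sel]
        row = {"d_low": lo, "d_high": hi}
        row.update(_metrics_for(sub))
        row["completeness"] = cov["completeness"].iloc[i]
        if anom is not None and len(anom):
            pa = anom[(anom["d"] <= lo * (1 + 1e-9)) & (anom["d"] > hi * (1 - 1e-9))]
            row["cc_anom"] = (float(np.corrcoef(pa["dI_A"], pa["dI_B"])[0, 1])
                              if len(pa) >= 3 else np.nan)
        rows.append(row)
    shells = pd.DataFrame(rows)

    overall = {"d_low": float(d.max()), "d_high": float(d.min())}
    overall.update(_metrics_for(df))
    overall["completeness"] = cov_all["completeness"]
    if anom is not None and len(anom) >= 3:
        overall["cc_anom"] = float(np.corrcoef(anom["dI_A"], anom["dI_B"])[0, 1])
    try:
        overall["wilson_b"] = wilson_b(d, df["I"].to_numpy(), structure=structure)
    except (ValueError, TypeError):
        overall["wilson_b"] = np.nan
    return ShellTable(edges, shells, overall)
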