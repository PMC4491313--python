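"""Monte Carlo merging of still observations with half-set bookkeeping.

Observations are folded to the reciprocal asymmetric unit and averaged
per unique reflection with unweighted means (Monte Carlo philosophy: no
inverse-variance weighting); sigma(I) is the sample standard deviation
over sqrt(n).  Whole patterns are assigned to half-set A or B by a
seeded random split so the half-set statistics (R_split, CC1/2) are
meaningful; cross-validation (free) flags are drawn once per unique
reflection.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crystal import UnitCell
from .symmetry import SpaceGroupSetting, map_to_asu_array

__all__ = ["MergedSet", "monte_carlo_merge", "coverage_stats"]

MERGED_COLUMNS = ["h", "k", "l", "d", "I", "sigma", "n",
                  "I_A", "n_A", "I_B", "n_B", "free"]


@dataclass
class MergedSet:
    """Unique-reflection table after Monte Carlo merging.

    ``df`` columns: h k l d I sigma n I_A n_A I_B n_B free.  In
    Friedel-separate (anomalous) mode +h and -h keep distinct rows.
    """

    cell: UnitCell
    spacegroup: SpaceGroupSetting
    d_max: float
    d_min: float
    df: pd.DataFrame
    friedel_separate: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in MERGED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"merged table missing columns {missing}")
        if self.df.duplicated(subset=["h", "k", "l"]).any():
            raise ValueError("duplicate unique reflections in merged table")

    def __len__(self):
        return len(self.df)

    def copy(self) -> "MergedSet":
        return MergedSet(self.cell, self.spacegroup, self.d_max, self.d_min,
                         self.df.copy(), self.friedel_separate,
                         dict(self.provenance))

    @property
    def hkl(self) -> np.ndarray:
        return self.df[["h", "k", "l"]].to_numpy(dtype=np.int64)

    def amplitudes(self) -> np.ndarray:
        """|F_o| as sqrt(max(I, 0)); negative merged intensities truncate."""
        return np.sqrt(np.clip(self.df["I"].to_numpy(), 0.0, None))


def monte_carlo_merge(
    patterns,
    cell: UnitCell,
    sg: SpaceGroupSetting,
    d_max: float,
    d_min: float,
    friedel_merge: bool = True,
    split_seed: int = 0,
    split: str = "random",
    free_fraction: float = 0.05,
    single_obs_sigma: str = "obs",
) -> MergedSet:
    """Merge still patterns into a unique-reflection table.

    Parameters
    ----------
    split : "random" (seeded whole-pattern half-set split) or "parity"
        (even/odd pattern id, for deterministic tests).
    single_obs_sigma : for n = 1, "obs" uses the observation's own sigma,
        "nan" flags it as undefined.
    """
    patterns = list(patterns)
    if not patterns or all(len(p) == 0 for p in patterns):
        raise ValueError("no observations to merge")
    if split not in ("random", "parity"):
        raise ValueError("split must be 'random' or 'parity'")
    if not 0 <= free_fraction < 1:
        raise ValueError("free_fraction must lie in [0, 1)")

    hkl = np.concatenate([p.hkl for p in patterns])
    inten = np.concatenate([p.intensity for p in patterns])
    sig_obs = np.concatenate([p.sigma for p in patterns])
    pid = np.concatenate([np.full(len(p), p.pattern_id) for p in patterns])

    reps = map_to_asu_array(hkl, sg, friedel_merge=friedel_merge)
    ids = np.array(sorted({p.pattern_id for p in patterns}))
    if split == "parity":
        half_of = {i: i % 2 for i in ids}
    else:
        rng = np.random.default_rng(np.random.SeedSequence((split_seed, 0xA)))
        half_of = dict(zip(ids.tolist(), (rng.random(len(ids)) < 0.5).astype(int)))
    half = np.array([half_of[i] for i in pid])

    tab = pd.DataFrame({
        "h": reps[:, 0], "k": reps[:, 1], "l": reps[:, 2],
        "I": inten, "sig_obs": sig_obs, "half": half,
    })
    g = tab.groupby(["h", "k", "l"], sort=True)
    out = g.agg(
        I=("I", "mean"),
        sd=("I", lambda x: x.std(ddof=1)),
        n=("I", "size"),
        first_sig=("sig_obs", "first"),
    ).reset_index()
    for label, col_i, col_n in ((0, "I_A", "n_A"), (1, "I_B", "n_B")):
        sub = tab[tab["half"] == label].groupby(["h", "k", "l"], sort=True)
        agg = sub.agg(I=("I", "mean"), n=("I", "size"))
        agg.columns = [col_i, col_n]
        out = out.merge(agg, on=["h", "k", "l"], how="left")
    out["n_A"] = out["n_A"].fillna(0).astype(int)
    out["n_B"] = out["n_B"].fillna(0).astype(int)

    out["sigma"] = out["sd"] / np.sqrt(out["n"])
    single = out["n"] == 1
    if single_obs_sigma == "obs":
        out.loc[single, "sigma"] = out.loc[single, "first_sig"]
    else:
        out.loc[single, "sigma"] = np.nan
    out = out.drop(columns=["sd", "first_sig"])

    out["d"] = cell.d_spacings(out[["h", "k", "l"]].to_numpy())
    in_range = (out["d"] >= d_min * (1 - 1e-9)) & (out["d"] <= d_max * (1 + 1e-9))
    out = out[in_range].reset_index(drop=True)

    # free flags: one seeded draw per unique reflection
    rng_free = np.random.default_rng(np.random.SeedSequence((split_seed, 0xF)))
    out["free"] = rng_free.random(len(out)) < free_fraction

    out = out[MERGED_COLUMNS]
    return MergedSet(
        cell, sg, d_max, d_min, out,
        friedel_separate=not friedel_merge,
        provenance={"split_seed": split_seed, "split": split,
                    "n_patterns": len(patterns),
                    "free_fraction": free_fraction},
    )


def coverage_stats(
    merged: MergedSet,
    shell_edges: np.ndarray | None = None,
    n_shells: int = 10,
) -> tuple:
    """Per-shell and overall completeness (%) and mean multiplicity.

    Completeness counts observed unique reflections against the
    enumerated theoretical unique set for the same cell, symmetry and
    resolution range; multiplicity is observations per observed unique
    reflection.

    Returns (shell_table, overall) where overall is a dict.
    """
    from .crystal import enumerate_unique_reflections
    from .metrics import shell_edges_equal_count

    theo = enumerate_unique_reflections(
        merged.cell, merged.spacegroup, merged.d_max, merged.d_min,
        friedel_merge=not merged.friedel_separate,
    )
    if len(theo) == 0:
        raise ValueError("no theoretical reflections in range")
    d_theo = merged.cell.d_spacings(theo)
    if shell_edges is None:
        shell_edges = shell_edges_equal_count(d_theo, n_shells)
    d_obs = merged.df["d"].to_numpy()
    n_obs_per = merged.df["n"].to_numpy()

    rows = []
    for lo, hi in zip(shell_edges[:-1], shell_edges[1:]):
        # shell covers d in (hi, lo] going from low to high resolution
        sel_t = (d_theo <= lo * (1 + 1e-9)) & (d_theo > hi * (1 + 1e-9))
        sel_o = (d_obs <= lo * (1 + 1e-9)) & (d_obs > hi * (1 + 1e-9))
        n_t, n_o = int(sel_t.sum()), int(sel_o.sum())
        if n_t == 0:
            raise ValueError(f"empty theoretical shell {lo:.3f}-{hi:.3f} A")
        rows.append({
            "d_low": lo, "d_high": hi,
            "n_theoretical": n_t, "n_observed": n_o,
            "completeness": 100.0 * n_o / n_t,
            "multiplicity": float(n_obs_per[sel_o].mean()) if n_o else 0.0,
        })
    # include the exact d_min edge in the last shell
    at_edge_t = np.isclose(d_theo, shell_edges[-1], rtol=1e-9)
    at_edge_o = np.isclose(d_obs, shell_edges[-1], rtol=1e-9)
    rows[-1]["n_theoretical"] += int(at_edge_t.sum())
    rows[-1]["n_observed"] += int(at_edge_o.sum())
    rows[-1]["completeness"] = 100.0 * rows[-1]["n_observed"] / rows[-1]["n_theoretical"]

    shell_table = pd.DataFrame(rows)
    overall = {
        "completeness": 100.0 * len(merged) / len(theo),
        "multiplicity": float(n_obs_per.mean()) if len(merged) else 0.0,
        "n_theoretical": len(theo),
        "n_observed": len(merged),
    }
    return shell_table, overall
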