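"""Space-group settings and reciprocal-space asymmetric-unit mapping.

Supports the six settings needed for toy serial-crystallography work
(P1, P2_1, C2, C222_1, P422, P42_12).  Operator lists and the
systematic-absence test come from gemmi; the canonical-representative
(ASU) rule and all vectorised index plumbing live here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["SpaceGroupSetting", "SUPPORTED_SYMBOLS", "map_to_asu", "map_to_asu_array"]

# user symbol -> Hermann-Mauguin name understood by gemmi
_SYMBOL_TO_HM = {
    "P1": "P 1",
    "P2_1": "P 1 21 1",
    "P21": "P 1 21 1",
    "C2": "C 1 2 1",
    "C222_1": "C 2 2 21",
    "C2221": "C 2 2 21",
    "P422": "P 4 2 2",
    "P42_12": "P 4 21 2",
    "P4212": "P 4 21 2",
}

SUPPORTED_SYMBOLS = ("P1", "P2_1", "C2", "C222_1", "P422", "P42_12")


class UnsupportedSpaceGroupError(ValueError):
    """Raised for a space-group symbol outside the supported set."""


@dataclass(frozen=True)
class SpaceGroupSetting:
    """A supported space-group setting.

    Attributes
    ----------
    symbol : canonical short symbol, e.g. ``"C2"``.
    rotations : integer rotation parts of the point group, as matrices
        acting on (h, k, l) row vectors.
    centering : lattice centering letter (``P`` or ``C``).
    friedel : whether Friedel mates are merged by default.
    """

    symbol: str
    rotations: tuple = field(repr=False)
    centering: str = "P"
    friedel: bool = True

    # -- construction -------------------------------------------------
    @classmethod
    def from_symbol(cls, symbol: str, friedel: bool = True) -> "SpaceGroupSetting":
        key = symbol.replace(" ", "")
        if key not in _SYMBOL_TO_HM:
            raise UnsupportedSpaceGroupError(
                f"space group {symbol!r} not supported; choose from {SUPPORTED_SYMBOLS}"
            )
        canonical = {v: k for k, v in _SYMBOL_TO_HM.items() if k in SUPPORTED_SYMBOLS}
        hm = _SYMBOL_TO_HM[key]
        ops = gemmi.SpaceGroup(hm).operations()
        rotmats = []
        seen = set()
        for op in ops:
            # rotation part acting on hkl; gemmi's rot is scaled by DEN
            r = np.array(op.rot, dtype=np.int64) // op.DEN
            t = tuple(r.ravel())
            if t not in seen:  # drop pure-centering duplicates
                seen.add(t)
                rotmats.append(r)
        return cls(
            symbol=canonical[hm],
            rotations=tuple(rotmats),
            centering=hm[0],
            friedel=friedel,
        )

    # -- gemmi bridge -------------------------------------------------
    @property
    def hm_symbol(self) -> str:
        return _SYMBOL_TO_HM[self.symbol]

    def gemmi_ops(self) -> gemmi.GroupOps:
        return gemmi.SpaceGroup(self.hm_symbol).operations()

    # -- systematic absences ------------------------------------------
    def is_absent(self, hkl) -> bool:
        return self.gemmi_ops().is_systematically_absent(list(int(i) for i in hkl))

    def absent_mask(self, hkl: np.ndarray) -> np.ndarray:
        """Vectorised systematic-absence test (centering + screw axes)."""
        hkl = np.asarray(hkl, dtype=np.int64)
        absent = np.zeros(len(hkl), dtype=bool)
        ops = self.gemmi_ops()
        for op in ops:
            rot = np.array(op.rot, dtype=np.int64) // op.DEN
            tran = np.array(op.tran, dtype=np.float64) / op.DEN
            mapped = hkl @ rot
            same = np.all(mapped == hkl, axis=1)
            phase = hkl @ tran  # in cycles
            nonint = np.abs(phase - np.round(phase)) > 1e-9
            absent |= same & nonint
        return absent

    # -- hkl transforms ------------------------------------------------
    def hkl_equivalents(self, hkl: np.ndarray, friedel: bool | None = None) -> np.ndarray:
        """All point-group images of an (N, 3) index array: (n_ops, N, 3)."""
        if friedel is None:
            friedel = self.friedel
        hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        images = [hkl @ rot for rot in self.rotations]
        if friedel:
            images += [-im for im in images]
        return np.stack(images)

    @property
    def n_point_ops(self) -> int:
        return len(self.rotations)


def _lex_keys(hkl: np.ndarray) -> np.ndarray:
    """Scalar keys preserving lexicographic (h, k, l) order, |index| < 2^20."""
    h, k, l = (hkl[..., i].astype(np.int64) for i in range(3))
    m = 1 << 21
    return ((h + (m >> 1)) * m + (k + (m >> 1))) * m + (l + (m >> 1))


def map_to_asu_array(
    hkl: np.ndarray, sg: SpaceGroupSetting, friedel_merge: bool = True
) -> np.ndarray:
    """Canonical representative (lexicographically greatest orbit member)
    for each row of an (N, 3) Miller-index array."""
    images = sg.hkl_equivalents(hkl, friedel=friedel_merge)  # (n_ops, N, 3)
    keys = _lex_keys(images)  # (n_ops, N)
    best = np.argmax(keys, axis=0)  # (N,)
    n = images.shape[1]
    return images[best, np.arange(n), :]


def map_to_asu(hkl, sg: SpaceGroupSetting, friedel_merge: bool = True):
    """Map one (h, k, l) to its unique representative.

    In Friedel-separate mode also returns the Friedel sign: +1 if this
    reflection's proper orbit is the canonical member of the Friedel
    pair, -1 otherwise.
    """
    arr = np.asarray(hkl, dtype=np.int64).reshape(1, 3)
    rep = tuple(int(i) for i in map_to_asu_array(arr, sg, friedel_merge)[0])
    if friedel_merge:
        return rep
    mate = tuple(int(i) for i in map_to_asu_array(-arr, sg, friedel_merge=False)[0])
    sign = +1 if _lex_keys(np.array(rep)[None, :])[0] >= _lex_keys(np.array(mate)[None, :])[0] else -1
    return rep, sign


def friedel_mate_rep(hkl, sg: SpaceGroupSetting):
    """Representative of the Friedel mate of a Friedel-separate representative."""
    arr = -np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
    return map_to_asu_array(arr, sg, friedel_merge=False)
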