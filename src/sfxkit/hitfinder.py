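"""Bragg-spot finding on still images and hit/indexing tallies.

The peak rule follows the published serial-crystallography parameters:
a candidate pixel must exceed a hard ADU threshold (default 400) and be
the maximum of its 9x9 box (background box 4); the local background and
noise are estimated robustly from the 32 border pixels of the box
(median and 1.4826*MAD), the peak is kept at local S/N >= 4 with at
least 3 connected pixels above background + snr_min*noise, and a frame
is a hit when it carries more than ten Bragg peaks.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .simulate import DetectorImage

__all__ = ["Peak", "PeakList", "HitTally", "find_peaks", "classify_hit", "tally_rates"]

HIT_MIN_PEAKS = 10  # a hit has strictly more than this many peaks


@dataclass(frozen=True)
class Peak:
    row: float
    col: float
    integrated_adu: float
    n_pixels: int
    snr: float


@dataclass
class PeakList:
    pattern_id: int
    peaks: list = field(default_factory=list)

    def __len__(self):
        return len(self.peaks)


@dataclass(frozen=True)
class HitTally:
    """Frame bookkeeping; percentages are always derived, never stored."""

    frames: int
    hits: int
    indexed: int | None = None

    def __post_init__(self):
        if self.frames <= 0:
            raise ValueError("frame count must be positive")
        if not 0 <= self.hits <= self.frames:
            raise ValueError("hits must lie in [0, frames]")
        if self.indexed is not None and not 0 <= self.indexed <= self.hits:
            raise ValueError("indexed must lie in [0, hits]")

    @property
    def hit_percent(self) -> float:
        return round(100.0 * self.hits / self.frames, 1)

    @property
    def indexed_percent(self) -> float | None:
        if self.indexed is None:
            return None
        if self.hits == 0:
            return 0.0
        return round(100.0 * self.indexed / self.hits, 1)


def find_peaks(
    image: DetectorImage | np.ndarray,
    background_box: int = 4,
    snr_min: float = 4.0,
    min_pixels: int = 3,
    max_adu_threshold: float = 400.0,
    mask: np.ndarray | None = None,
    pattern_id: int | None = None,
) -> PeakList:
    """Locate Bragg peaks on a detector image (see module docstring)."""
    if isinstance(image, DetectorImage):
        pid = image.pattern_id if pattern_id is None else pattern_id
        img = image.pixels
    else:
        pid = -1 if pattern_id is None else pattern_id
        img = np.asarray(image, dtype=float)
    box = int(background_box)
    w = 2 * box + 1
    if w > min(img.shape):
        raise ValueError("background window larger than image")
    work = img.copy()
    if mask is not None:
        work[mask.astype(bool)] = -np.inf

    local_max = work == ndimage.maximum_filter(work, size=w, mode="constant", cval=-np.inf)
    cand = local_max & (work > max_adu_threshold)
    cand[:box, :] = cand[-box:, :] = False
    cand[:, :box] = cand[:, -box:] = False

    border_sel = np.ones((w, w), dtype=bool)
    border_sel[1:-1, 1:-1] = False
    struct = np.ones((3, 3), dtype=bool)  # 8-connectivity

    peaks = []
    for r, c in zip(*np.nonzero(cand)):
        win = img[r - box : r + box + 1, c - box : c + box + 1]
        border = win[border_sel]
        bg = float(np.median(border))
        spread = 1.4826 * float(np.median(np.abs(border - bg)))
        spread = max(spread, 1e-6)
        snr = (img[r, c] - bg) / spread
        if snr < snr_min:
            continue
        above = win > bg + snr_min * spread
        labels, _ = ndimage.label(above, structure=struct)
        comp = labels == labels[box, box]
        if labels[box, box] == 0 or comp.sum() < min_pixels:
            continue
        integrated = float(np.sum(win[comp] - bg))
        peaks.append(Peak(float(r), float(c), integrated, int(comp.sum()), float(snr)))

    # merge peaks closer than one background box; the brighter one wins
    peaks.sort(key=lambda p: -p.integrated_adu)
    kept = []
    for p in peaks:
        if all(max(abs(p.row - q.row), abs(p.col - q.col)) > box for q in kept):
            kept.append(p)
    return PeakList(pid, kept)


def classify_hit(peaks: PeakList) -> bool:
    """A frame is a hit iff it contains strictly more than ten Bragg peaks."""
    return len(peaks) > HIT_MIN_PEAKS


def tally_rates(frames: int, hits: int, indexed: int | None = None) -> HitTally:
    """Hit rate as a percentage of frames; indexing rate as a percentage of
    hits; both rounded to one decimal."""
    return HitTally(frames=frames, hits=hits, indexed=indexed)
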