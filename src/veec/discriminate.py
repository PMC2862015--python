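"""Bi-frequency discrimination of fish from other scatterers.

Swimbladdered fish (anchovy) backscatter slightly more at 38 than 120 kHz,
while zooplankton backscatter much more at 120 kHz.  Contrast is enhanced by
summing the two responses in the dB domain; a cell is classed as fish when
the dB sum exceeds -135 dB *and* Sv120 - Sv38 < +2 dB (the +2 dB margin
admits fish aggregations insonified more strongly by the narrower 120 kHz
beam).  Both inequalities are strict, exactly as the rule is stated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .echogram import BiFrequencyEchogram, EchogramFormatError

DEFAULT_SUM_THRESHOLD_DB = -135.0
DEFAULT_DIFF_THRESHOLD_DB = 2.0


@dataclass
class ScattererMasks:
    """Boolean fish/other masks partitioning every valid cell of a grid."""

    fish: np.ndarray
    other: np.ndarray

    def __post_init__(self):
        if self.fish.shape != self.other.shape:
            raise ValueError("fish/other masks must share one grid")
        if np.any(self.fish & self.other):
            raise ValueError("fish and other masks must be disjoint")


def sum_frequencies(b: BiFrequencyEchogram) -> np.ndarray:
    """dB-domain sum Sv38 + Sv120 (contrast enhancement).

    No-data in either channel propagates (NaN arithmetic).
    """
    if b.e38.sv_db.shape != b.e120.sv_db.shape:
        raise EchogramFormatError("frequency grids are misaligned")
    return b.e38.sv_db + b.e120.sv_db


def fish_mask(
    b: BiFrequencyEchogram,
    sum_threshold_db: float = DEFAULT_SUM_THRESHOLD_DB,
    diff_threshold_db: float = DEFAULT_DIFF_THRESHOLD_DB,
) -> ScattererMasks:
    """Classify every valid cell as fish or other.

    fish  <=>  (Sv38 + Sv120 > sum_threshold) and (Sv120 - Sv38 < diff_threshold)
    """
    total = sum_frequencies(b)
    with np.errstate(invalid="ignore"):
        diff = b.e120.sv_db - b.e38.sv_db
        valid = np.isfinite(total)
        fish = valid & (total > sum_threshold_db) & (diff < diff_threshold_db)
    other = valid & ~fish
    return ScattererMasks(fish=fish, other=other)


def split_echograms(
    b: BiFrequencyEchogram, m: ScattererMasks
) -> tuple[BiFrequencyEchogram, BiFrequencyEchogram]:
    """Split into fish and no-fish echograms at each frequency.

    Cells outside the respective mask become no-data; cellwise union of the
    two outputs restores the input.
    """
    if m.fish.shape != b.e38.sv_db.shape:
        raise EchogramFormatError("masks are not on the echogram grid")

    def _keep(e, mask):
        sv = np.where(mask, e.sv_db, np.nan)
        return e.with_sv(sv)

    fish = BiFrequencyEchogram(_keep(b.e38, m.fish), _keep(b.e120, m.fish))
    nofish = BiFrequencyEchogram(_keep(b.e38, m.other), _keep(b.e120, m.other))
    return fish, nofish
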