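"""Dosage-sensitive marker genotyping.

Formalizes the semi-quantitative readout of dominant PCR markers on an
aneuploid chromosome: band intensity scales with chromosome copy number
(euploid control ~= 1, monosomic ~= 0.5, nullisomic ~= 0), so plants are
classified T / M / D by thresholding per-marker intensities and taking a
majority vote over the focal-chromosome markers.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ParameterError

__all__ = ["MarkerPanel", "classify_copy_number", "genotype_plants",
           "DEFAULT_CUTOFFS"]

logger = logging.getLogger(__name__)

#: (absent_max, half_max): intensity <= absent_max -> 0 copies,
#: <= half_max -> 1 copy, else 2 copies.  Symmetric margins around the
#: theoretical band doses 0, 0.5 and 1.
DEFAULT_CUTOFFS = (0.2, 0.75)


@dataclass
class MarkerPanel:
    """Marker map plus a plant x marker intensity matrix.

    ``markers`` has columns ``marker_id`` and ``chromosome``; intensities
    are nonnegative, normalized so the euploid control band reads ~1.
    """

    markers: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if self.markers["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in panel")
        unknown = set(self.intensities.columns) - set(self.markers["marker_id"])
        if unknown:
            raise ValueError(f"intensity columns without a marker record: {sorted(unknown)}")
        if (self.intensities.to_numpy() < 0).any():
            raise ParameterError("marker intensities must be nonnegative")

    def focal_markers(self, chromosome: str) -> list[str]:
        m = self.markers
        return m.loc[m["chromosome"] == chromosome, "marker_id"].tolist()


def classify_copy_number(intensity: float | np.ndarray,
                         cutoffs: tuple[float, float] = DEFAULT_CUTOFFS):
    """Map a normalized band intensity to a copy number in {0, 1, 2}."""
    absent_max, half_max = cutoffs
    if not 0 <= absent_max < half_max:
        raise ParameterError("require 0 <= absent_max < half_max")
    arr = np.asarray(intensity, dtype=float)
    if (arr < 0).any():
        raise ParameterError("negative marker intensity")
    out = np.where(arr <= absent_max, 0, np.where(arr <= half_max, 1, 2))
    return int(out) if np.isscalar(intensity) else out


def genotype_plants(panel: MarkerPanel, focal_chromosome: str,
                    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Call each plant T / M / D from its focal-chromosome marker votes.

    Every focal marker votes a copy number; the majority wins and maps
    2 -> T, 1 -> M, 0 -> D.  Ties resolve to the lower copy number
    (conservative toward detecting chromosome loss) and are logged.
    Plants with no usable focal marker are called ``unknown``.

    Returns a frame indexed by plant with columns ``call``,
    ``copy_number`` (the winning vote, -1 for unknown), ``n_votes`` and
    ``tie`` (bool).
    """
    focal = panel.focal_markers(focal_chromosome)
    if not focal:
        raise ParameterError(f"no marker on focal chromosome {focal_chromosome}")
    present = [m for m in focal if m in panel.intensities.columns]
    rows = []
    class_of = {2: "T", 1: "M", 0: "D"}
    for plant, row in panel.intensities.iterrows():
        votes = row[present].dropna()
        if votes.empty:
            rows.append((plant, "unknown", -1, 0, False))
            continue
        copies = classify_copy_number(votes.to_numpy(), cutoffs)
        counts = Counter(np.atleast_1d(copies).tolist())
        best = max(counts.values())
        winners = sorted(c for c, k in counts.items() if k == best)
        tie = len(winners) > 1
        if tie:
            logger.info("plant %s: marker vote tie %s resolved to copy %d",
                        plant, dict(counts), winners[0])
        winner = winners[0]
        rows.append((plant, class_of[winner], winner, int(len(votes)), tie))
    return pd.DataFrame(rows, columns=["plant", "call", "copy_number",
                                       "n_votes", "tie"]).set_index("plant")
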