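"""Tertile binning of continuous trait scores into low/medium/high ranges.

Bin boundaries are the empirical 1/3 and 2/3 score percentiles (linear
interpolation of order statistics), so roughly one third of the cohort lands
in each range; participants with identical scores always share a bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANGE_ORDER = ("low", "medium", "high")
RANGE_CODE = {r: i for i, r in enumerate(RANGE_ORDER)}


@dataclass
class TraitBins:
    trait: str
    boundaries: tuple[float, float]
    assignment: dict[str, str]  # participant -> low/medium/high

    def code(self, participant: str) -> int:
        return RANGE_CODE[self.assignment[participant]]

    @property
    def counts(self) -> dict[str, int]:
        out = {r: 0 for r in RANGE_ORDER}
        for r in self.assignment.values():
            out[r] += 1
        return out


def tertile_bins(
    scores: Mapping[str, float] | pd.Series, trait: str = ""
) -> TraitBins:
    """Bin scores at the 1/3 and 2/3 percentiles.

    Scores at or below the lower boundary are "low", above the upper boundary
    "high", the rest "medium".
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    if len(scores) < 3:
        raise ValueError("need at least 3 participants for tertile binning")
    values = np.asarray(list(scores.values()), dtype=float)
    if np.ptp(values) == 0:
        raise ValueError(f"degenerate trait {trait or '?'}: all scores identical")
    b_low, b_high = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    assignment = {}
    for pid, v in scores.items():
        if v <= b_low:
            assignment[pid] = "low"
        elif v <= b_high:
            assignment[pid] = "medium"
        else:
            assignment[pid] = "high"
    return TraitBins(trait=trait, boundaries=(float(b_low), float(b_high)),
                     assignment=assignment)


def bin_all_traits(traits: pd.DataFrame) -> dict[str, TraitBins]:
    """Independent tertile binning per trait column, over the full cohort."""
    return {trait: tertile_bins(traits[trait], trait) for trait in traits.columns}


def bins_to_frame(bins: Mapping[str, TraitBins]) -> pd.DataFrame:
    rows = [
        (b.trait, pid, r)
        for b in bins.values()
        for pid, r in b.assignment.items()
    ]
    return pd.DataFrame(rows, columns=["trait", "participant", "bin"])
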