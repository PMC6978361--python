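"""Drug-effect classification from top-concentration viability fold changes.

Each drug is placed in one of four potency categories by comparing the
fold change of its viability readout at the highest tested
concentration against the negative-control (DMSO) growth distribution:

* ``lethal`` — fold change below 1: fewer viable cells at the end than
  at the start (net killing).
* ``sub_effective`` — growth, but more than ``k_sd`` standard
  deviations below the mean negative-control fold change (cytostatic or
  weakly toxic drugs).
* ``non_effective`` — within ``k_sd`` SD of the negative-control mean.
* ``growth_stimulatory`` — more than ``k_sd`` SD above it.

``k_sd`` defaults to 1; band boundaries belong to ``non_effective``
(claiming an effect requires strict exceedance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from ndrscreen.errors import ControlError, MetricError
from ndrscreen.screen_model import ROLE_DRUG, ROLE_NEG, ScreenTable

logger = logging.getLogger(__name__)


class DrugCategory(str, Enum):
    LETHAL = "lethal"
    SUB_EFFECTIVE = "sub_effective"
    NON_EFFECTIVE = "non_effective"
    GROWTH_STIMULATORY = "growth_stimulatory"


@dataclass(frozen=True)
class NegControlGrowthStats:
    """Mean and SD of negative-control per-well fold changes."""

    mean_fc: float
    sd_fc: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_fc) or self.mean_fc <= 0:
            raise ControlError(f"mean_fc must be finite and > 0, got {self.mean_fc}")
        if not np.isfinite(self.sd_fc) or self.sd_fc < 0:
            raise ControlError(f"sd_fc must be finite and >= 0, got {self.sd_fc}")

    @classmethod
    def from_wells(cls, plate_wells: pd.DataFrame) -> "NegControlGrowthStats":
        """Stats from the negative-control wells of a plate (sample SD)."""
        neg = plate_wells[plate_wells["role"] == ROLE_NEG]
        if len(neg) < 2:
            raise ControlError(f"need >= 2 negative-control wells, found {len(neg)}")
        if (neg["start_readout"] <= 0).any():
            raise ControlError("negative-control wells with start readout <= 0")
        fc = neg["end_readout"] / neg["start_readout"]
        return cls(mean_fc=float(fc.mean()), sd_fc=float(fc.std(ddof=1)))


def classify_drug(final_fc: float, stats: NegControlGrowthStats, k_sd: float = 1.0) -> DrugCategory:
    """Category of one drug from its top-concentration fold change.

    The four bands partition the positive reals: ``(0, 1)`` lethal,
    ``[1, mean - k_sd*sd)`` sub-effective, ``[mean - k_sd*sd,
    mean + k_sd*sd]`` non-effective, ``(mean + k_sd*sd, inf)``
    growth-stimulatory.
    """
    if not np.isfinite(final_fc) or final_fc <= 0:
        raise MetricError(f"final fold change must be finite and > 0, got {final_fc}")
    if not k_sd > 0:
        raise MetricError(f"k_sd must be > 0, got {k_sd}")
    lower = stats.mean_fc - k_sd * stats.sd_fc
    upper = stats.mean_fc + k_sd * stats.sd_fc
    if final_fc < 1.0:
        return DrugCategory.LETHAL
    if final_fc < lower:
        return DrugCategory.SUB_EFFECTIVE
    if final_fc > upper:
        return DrugCategory.GROWTH_STIMULATORY
    return DrugCategory.NON_EFFECTIVE


def classify_screen(
    table: ScreenTable,
    k_sd: float = 1.0,
    per_plate: bool = True,
) -> pd.DataFrame:
    """Classify every drug in a screen from its highest-concentration well.

    Negative-control fold-change statistics are computed per plate by
    default (``per_plate=False`` pools the whole screen). Drugs whose
    top-concentration well has an undefined fold change are skipped with
    a warning. Returns a DataFrame indexed by drug with columns
    ``final_fc``, ``category``, ``plate_id``, ``concentration``.
    """
    active = table.active()
    drugs = active[active["role"] == ROLE_DRUG]
    if drugs.empty:
        raise MetricError("screen contains no drug wells to classify")
    screen_stats = None
    if not per_plate:
        screen_stats = NegControlGrowthStats.from_wells(active)
    plate_stats: dict[str, NegControlGrowthStats] = {}
    rows = []
    for drug_name, grp in drugs.groupby("drug_name"):
        top = grp.loc[grp["concentration"].idxmax()]
        if top["start_readout"] <= 0:
            logger.warning(
                "drug %s: top-concentration well %s/%s has start readout <= 0; skipped",
                drug_name, top["plate_id"], top["well"],
            )
            continue
        pid = top["plate_id"]
        if per_plate:
            if pid not in plate_stats:
                plate_stats[pid] = NegControlGrowthStats.from_wells(
                    active[active["plate_id"] == pid]
                )
            stats = plate_stats[pid]
        else:
            stats = screen_stats
        final_fc = float(top["end_readout"] / top["start_readout"])
        rows.append(
            {
                "drug_name": drug_name,
                "plate_id": pid,
                "concentration": float(top["concentration"]),
                "final_fc": final_fc,
                "category": classify_drug(final_fc, stats, k_sd).value,
            }
        )
    return pd.DataFrame(rows).set_index("drug_name")


def category_counts(categories: pd.DataFrame) -> pd.Series:
    """Summary counts per category, including empty categories."""
    counts = categories["category"].value_counts()
    return counts.reindex([c.value for c in DrugCategory], fill_value=0)
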