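"""Fold-change computation and the NDR / GR / PI response metrics.

All three metrics normalize a drug-treated well against plate controls:

* ``NDR`` (normalized drug response) uses the per-well fold change
  (endpoint readout / start readout) of the drug well together with the
  median fold changes of the negative (DMSO) and positive (benzethonium
  chloride) controls::

      NDR = max(-1, (1 - 2^(log2 fc_drug / log2 fc_pos))
                    / (1 - 2^(log2 fc_neg / log2 fc_pos)))

  NDR = 1 means growth indistinguishable from the negative control,
  0 complete growth inhibition, -1 complete killing (the clamp floor),
  and values above 1 a growth-stimulatory effect.

* ``GR`` normalizes only to the negative control:
  ``GR = 2^(log2 fc_drug / log2 fc_neg) - 1``.

* ``PI`` (percent inhibition) uses endpoint readouts only:
  ``PI = (end_neg - end_drug) / (end_neg - end_pos)``, returned as a
  fraction; the x100 display scale is applied by :func:`scale_for_dss`.

The exponent base is fixed at 2: other bases give quantitatively similar
values but a fixed base keeps outputs reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ndrscreen.errors import ConfigurationError, ControlError, MetricError
from ndrscreen.screen_model import ROLE_DRUG, ROLE_NEG, ROLE_POS, ScreenTable

logger = logging.getLogger(__name__)

METRICS = ("NDR", "GR", "PI")

#: |log2(fold change)| below this is treated as a degenerate (non-growing /
#: non-dying) control and raises instead of producing near-infinities.
LOG2_GUARD = 1e-9


@dataclass(frozen=True)
class ControlSummary:
    """Per-plate control aggregates.

    ``fold_change_neg`` / ``fold_change_pos`` are medians of per-well
    fold changes (endpoint / start); the endpoint medians feed PI.
    """

    fold_change_neg: float
    fold_change_pos: float
    end_median_neg: float
    end_median_pos: float
    n_neg: int
    n_pos: int

    def __post_init__(self) -> None:
        for name in ("fold_change_neg", "fold_change_pos"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ControlError(f"{name} must be finite and > 0, got {v}")
        if self.n_neg < 2 or self.n_pos < 2:
            raise ControlError(
                f"need >= 2 wells per control role, got {self.n_neg} negative / {self.n_pos} positive"
            )


def fold_change(start: float, end: float) -> float:
    """Endpoint readout divided by start readout of the same well.

    Raises :class:`MetricError` when ``start <= 0`` (undefined fold change).
    """
    if not start > 0:
        raise MetricError(f"fold change undefined: start readout must be > 0, got {start}")
    return end / start


def _check_fc(value: float, name: str) -> None:
    if not np.isfinite(value) or value <= 0:
        raise MetricError(f"{name} must be finite and > 0, got {value}")


def ndr(fc_drug: float, fc_neg: float, fc_pos: float) -> float:
    """Normalized drug response of one condition, clamped at -1.

    Parameters are fold changes of the drug condition and of the
    negative / positive control conditions. Raises :class:`MetricError`
    for non-positive fold changes, a positive control with fold change 1
    (log2 zero, undefined exponent) or a non-growing negative control
    (zero denominator).
    """
    _check_fc(fc_drug, "fc_drug")
    _check_fc(fc_neg, "fc_neg")
    _check_fc(fc_pos, "fc_pos")
    lp = np.log2(fc_pos)
    ln = np.log2(fc_neg)
    if abs(lp) < LOG2_GUARD:
        raise MetricError("positive-control fold change is 1 (no signal change): NDR undefined")
    if abs(ln) < LOG2_GUARD:
        raise MetricError("negative-control fold change is 1 (non-growing): NDR undefined")
    raw = (1.0 - 2.0 ** (np.log2(fc_drug) / lp)) / (1.0 - 2.0 ** (ln / lp))
    return max(-1.0, raw)


def gr(fc_drug: float, fc_neg: float) -> float:
    """Growth-rate metric: 2^(log2 fc_drug / log2 fc_neg) - 1."""
    _check_fc(fc_drug, "fc_drug")
    _check_fc(fc_neg, "fc_neg")
    ln = np.log2(fc_neg)
    if abs(ln) < LOG2_GUARD:
        raise MetricError("negative-control fold change is 1 (non-growing): GR undefined")
    return 2.0 ** (np.log2(fc_drug) / ln) - 1.0


def pi(end_drug: float, end_neg: float, end_pos: float) -> float:
    """Percent inhibition from endpoint readouts, as a fraction.

    0 at the negative-control endpoint, 1 at the positive-control
    endpoint. Raises :class:`MetricError` when the two control endpoints
    coincide.
    """
    if end_neg == end_pos:
        raise MetricError("degenerate controls: negative and positive endpoint medians are equal")
    return (end_neg - end_drug) / (end_neg - end_pos)


def scale_for_dss(metric: str, value):
    """Transform a metric value onto the percent-inhibition scale fed to DSS.

    PI -> PI*100; GR -> 0.5*(1-GR)*100; NDR -> 0.5*(1-NDR)*100.
    Values outside [0, 100] are permitted (stimulatory / super-lethal
    responses). Accepts scalars or arrays.
    """
    value = np.asarray(value, dtype=float)
    if metric == "PI":
        out = value * 100.0
    elif metric in ("GR", "NDR"):
        out = 0.5 * (1.0 - value) * 100.0
    else:
        raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return out.item() if out.ndim == 0 else out


def aggregate_controls(plate_wells: pd.DataFrame, aggregation: str = "median_of_fold_changes") -> ControlSummary:
    """Summarize a plate's control wells into a :class:`ControlSummary`.

    Excluded wells are ignored. ``aggregation="median_of_fold_changes"``
    (default) takes the median of the per-well fold changes;
    ``"fold_change_of_medians"`` divides the median endpoint by the
    median start readout instead.
    """
    if aggregation not in ("median_of_fold_changes", "fold_change_of_medians"):
        raise ConfigurationError(f"unknown aggregation mode {aggregation!r}")
    summaries = {}
    for role in (ROLE_NEG, ROLE_POS):
        grp = plate_wells[plate_wells["role"] == role]
        if len(grp) < 2:
            raise ControlError(
                f"plate needs >= 2 {role} wells with valid readouts, found {len(grp)}"
            )
        if (grp["start_readout"] <= 0).any():
            raise ControlError(f"{role} wells with start readout <= 0: fold change undefined")
        if aggregation == "median_of_fold_changes":
            fc = float((grp["end_readout"] / grp["start_readout"]).median())
        else:
            fc = float(grp["end_readout"].median() / grp["start_readout"].median())
        summaries[role] = (fc, float(grp["end_readout"].median()), len(grp))
    return ControlSummary(
        fold_change_neg=summaries[ROLE_NEG][0],
        fold_change_pos=summaries[ROLE_POS][0],
        end_median_neg=summaries[ROLE_NEG][1],
        end_median_pos=summaries[ROLE_POS][1],
        n_neg=summaries[ROLE_NEG][2],
        n_pos=summaries[ROLE_POS][2],
    )


def per_well_metric(
    wells: pd.DataFrame, metric: str, summary: ControlSummary
) -> pd.Series:
    """Metric value for each well in ``wells`` given plate control summaries."""
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == "PI":
        return wells["end_readout"].map(
            lambda e: pi(e, summary.end_median_neg, summary.end_median_pos)
        )
    if (wells["start_readout"] <= 0).any():
        bad = wells.loc[wells["start_readout"] <= 0, "well"].tolist()
        raise MetricError(f"wells with start readout <= 0 (fold change undefined): {bad}")
    fc = wells["end_readout"] / wells["start_readout"]
    if metric == "NDR":
        return fc.map(lambda f: ndr(f, summary.fold_change_neg, summary.fold_change_pos))
    return fc.map(lambda f: gr(f, summary.fold_change_neg))


def score_screen(
    table: ScreenTable,
    metric: str = "NDR",
    aggregation: str = "median_of_fold_changes",
) -> ScreenTable:
    """Score every non-excluded drug well of a screen with one metric.

    Controls are aggregated per plate; the result is a copy of the table
    with ``fold_change`` and a metric column (``NDR``/``GR``/``PI``)
    added for drug wells, and per-plate control summaries recorded in
    ``metadata["control_summaries"]``.
    """
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    out = table.copy()
    out.wells[metric] = np.nan
    out.wells["fold_change"] = np.nan
    summaries: dict[str, ControlSummary] = {}
    for pid in out.plate_ids:
        plate = out.plate(pid)
        drug_mask = plate["role"] == ROLE_DRUG
        if not drug_mask.any():
            continue
        try:
            summary = aggregate_controls(plate, aggregation=aggregation)
            drug_wells = plate[drug_mask]
            values = per_well_metric(drug_wells, metric, summary)
        except (ControlError, MetricError) as exc:
            raise type(exc)(f"plate {pid}: {exc}") from exc
        summaries[pid] = summary
        out.wells.loc[values.index, metric] = values
        ok_start = drug_wells["start_readout"] > 0
        out.wells.loc[drug_wells.index[ok_start], "fold_change"] = (
            drug_wells.loc[ok_start, "end_readout"] / drug_wells.loc[ok_start, "start_readout"]
        )
    out.metadata["control_summaries"] = summaries
    out.metadata["metric"] = metric
    return out


def estimate_start_readout(plate_wells: pd.DataFrame, assumed_fold_change: float) -> float:
    """Estimate a plate-wide start readout from endpoint data alone.

    External datasets often record no baseline measurement; assuming a
    known negative-control fold change (e.g. the 3.2 observed for
    MDA-MB-231), the start readout is estimated as the median
    negative-control endpoint divided by that fold change, and applied
    uniformly to every well of the plate (uniform-seeding assumption).
    """
    if not assumed_fold_change > 0:
        raise MetricError(f"assumed fold change must be > 0, got {assumed_fold_change}")
    neg = plate_wells[plate_wells["role"] == ROLE_NEG]
    if neg.empty:
        raise ControlError("no negative-control wells: cannot estimate start readout")
    return float(neg["end_readout"].median()) / assumed_fold_change
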