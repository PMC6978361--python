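"""Plate- and screen-level quality and consistency statistics.

The Z'-factor summarizes how well a plate separates its negative and
positive control distributions after metric transformation::

    Z' = 1 - 3 * (sd_pos + sd_neg) / |mean_pos - mean_neg|

Z' is at most 1 (only with zero-variance controls); values above 0.5
mark a high-quality assay. Sample (n-1) standard deviations are used
throughout — control-well counts are small.

Replicate consistency is measured as the absolute per-well difference
between two scored replicate screens; time-point consistency as each
well's deviation from its median response across time points. The
overlapping coefficient — the integral of the pointwise minimum of two
normal densities — quantifies the separation of score distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from ndrscreen.errors import ControlError, MetricError
from ndrscreen.screen_model import ROLE_DRUG, ScreenTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    z_prime: float
    n_neg: int
    n_pos: int
    metric: str


def z_prime(neg_values, pos_values) -> float:
    """Z'-factor of one plate from metric-transformed control values."""
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ControlError(
            f"Z' needs >= 2 values per control group, got {neg.size} / {pos.size}"
        )
    mu_n, mu_p = neg.mean(), pos.mean()
    if mu_n == mu_p:
        raise ControlError("Z' undefined: control group means are equal")
    sd_n, sd_p = neg.std(ddof=1), pos.std(ddof=1)
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


def _scored_drug_wells(table: ScreenTable, metric: str) -> pd.DataFrame:
    if metric not in table.wells.columns:
        raise MetricError(f"table has no {metric!r} column; run score_screen first")
    wells = table.wells
    mask = (wells["role"] == ROLE_DRUG) & wells[metric].notna()
    return wells.loc[mask, ["plate_id", "well", metric]]


def _resolve_metric(table: ScreenTable, metric: str | None) -> str:
    if metric is not None:
        return metric
    metric = table.metadata.get("metric")
    if metric is None:
        raise MetricError("metric not given and not recorded in table metadata")
    return metric


def screen_z_prime(table: ScreenTable, metric: str | None = None, on_raw: bool = False) -> list[PlateQC]:
    """Per-plate Z' of a scored screen.

    By default control values are metric-transformed (each control
    well's own fold change / endpoint pushed through the scoring metric
    against the plate summaries); ``on_raw=True`` uses raw endpoint
    readouts instead.
    """
    from ndrscreen.response_metrics import aggregate_controls, per_well_metric
    from ndrscreen.screen_model import ROLE_NEG, ROLE_POS

    metric = _resolve_metric(table, metric)
    out = []
    for pid in table.plate_ids:
        plate = table.plate(pid)
        neg = plate[plate["role"] == ROLE_NEG]
        pos = plate[plate["role"] == ROLE_POS]
        if len(neg) < 2 or len(pos) < 2:
            continue
        if on_raw:
            neg_vals, pos_vals = neg["end_readout"], pos["end_readout"]
        else:
            summary = aggregate_controls(plate)
            neg_vals = per_well_metric(neg, metric, summary)
            pos_vals = per_well_metric(pos, metric, summary)
        out.append(
            PlateQC(
                plate_id=pid,
                z_prime=z_prime(neg_vals, pos_vals),
                n_neg=len(neg),
                n_pos=len(pos),
                metric="raw" if on_raw else metric,
            )
        )
    return out


def replicate_abs_diff(
    table_a: ScreenTable, table_b: ScreenTable, metric: str | None = None
) -> np.ndarray:
    """Absolute response difference at matching drug wells of two replicates.

    Wells are matched on (plate_id, well); unmatched wells are reported
    and dropped. A consistent replicate pair concentrates near zero.
    """
    metric = _resolve_metric(table_a, metric)
    a = _scored_drug_wells(table_a, metric)
    b = _scored_drug_wells(table_b, metric)
    merged = a.merge(b, on=["plate_id", "well"], suffixes=("_a", "_b"), how="outer", indicator=True)
    unmatched = int((merged["_merge"] != "both").sum())
    if unmatched:
        logger.warning("%d wells present in only one replicate were dropped", unmatched)
    both = merged[merged["_merge"] == "both"]
    if both.empty:
        raise MetricError("no matching scored drug wells between the replicates")
    return np.abs(both[f"{metric}_a"].to_numpy() - both[f"{metric}_b"].to_numpy())


def time_consistency(
    responses_by_time: Mapping[float, ScreenTable], metric: str | None = None
) -> np.ndarray:
    """Per-well deviations from the median response across time points.

    For every drug well present at all time points, returns
    ``response(t) - median over t`` for each time point, concatenated.
    A time-consistent metric concentrates these near zero.
    """
    if len(responses_by_time) < 2:
        raise MetricError("time consistency needs >= 2 time points")
    first = next(iter(responses_by_time.values()))
    metric = _resolve_metric(first, metric)
    frames = []
    for t, table in responses_by_time.items():
        df = _scored_drug_wells(table, metric).rename(columns={metric: t})
        frames.append(df.set_index(["plate_id", "well"]))
    wide = pd.concat(frames, axis=1, join="inner")
    if wide.empty:
        raise MetricError("no drug wells shared across all time points")
    med = wide.median(axis=1)
    return (wide.sub(med, axis=0)).to_numpy().ravel()


def overlap_coefficient(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Overlapping coefficient of two normal densities, in [0, 1].

    Integral of ``min(f1, f2)``. With equal variances this is the
    closed form ``2 * Phi(-|mu1 - mu2| / (2 * sigma))``; with unequal
    variances the densities cross twice and the integral is assembled
    from CDF masses of whichever density is smaller between crossings.
    """
    if not (sd1 > 0 and sd2 > 0):
        raise MetricError(f"standard deviations must be > 0, got {sd1}, {sd2}")
    if sd1 == sd2:
        return float(2.0 * norm.cdf(-abs(mu1 - mu2) / (2.0 * sd1)))
    # crossing points: quadratic in x from log f1(x) = log f2(x)
    a = 1.0 / sd1**2 - 1.0 / sd2**2
    b = -2.0 * (mu1 / sd1**2 - mu2 / sd2**2)
    c = mu1**2 / sd1**2 - mu2**2 / sd2**2 - 2.0 * np.log(sd2 / sd1)
    roots = np.sort(np.roots([a, b, c]).real)
    f1, f2 = norm(mu1, sd1), norm(mu2, sd2)
    edges = [-np.inf, *roots, np.inf]
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        mid = _interval_midpoint(lo, hi)
        # logpdf: far from both means the plain pdfs underflow to a 0.0 tie
        smaller = f1 if f1.logpdf(mid) <= f2.logpdf(mid) else f2
        total += smaller.cdf(hi) - smaller.cdf(lo)
    return float(min(1.0, total))


def _interval_midpoint(lo: float, hi: float) -> float:
    if np.isinf(lo):
        return hi - 1.0
    if np.isinf(hi):
        return lo + 1.0
    return 0.5 * (lo + hi)
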