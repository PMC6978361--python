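"""Ground-truth simulator for two-time-point viability screens.

Cell populations follow base-2 exponential growth: a well seeded with
signal ``S`` and growing at rate ``g`` (per hour) reads
``S * 2**(g*t)`` after ``t`` hours, so the doubling time is ``1/g``
(about 30 h for the default negative-control rate 0.03 h^-1) and the
half-life of a dying well is ``1/|g|``. Negative controls grow at
``g_neg``, positive controls decay at ``g_pos``, and a drug well's
effective rate interpolates between the two according to the drug's
true inhibition at its concentration.

Three stock scenarios probe the response metrics: fixed controls with a
drug fold-change sweep, a varying positive-control background, and a
varying negative-control growth rate. Scenario grids are specified
directly as fold changes (the normative quantities entering the
metrics); the growth rates are retained for trajectory simulation.

:func:`generate_synthetic_screen` lays the conditions out on 384-well
plates with DMSO/BzCl-style control wells, applies multiplicative
log-normal seeding and readout noise, and emits the ground truth (true
fold change, true NDR, true category) alongside the noisy screen table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ndrscreen.classification import DrugCategory, NegControlGrowthStats, classify_drug
from ndrscreen.errors import ConfigurationError
from ndrscreen.response_metrics import gr, ndr, pi
from ndrscreen.screen_model import (
    N_COLS,
    N_ROWS,
    ROLE_DRUG,
    ROLE_NEG,
    ROLE_POS,
    ScreenTable,
    WellRecord,
)

logger = logging.getLogger(__name__)

Range = tuple[float, float]


def _as_range(v) -> Range:
    if np.isscalar(v):
        return (float(v), float(v))
    lo, hi = float(v[0]), float(v[1])
    if hi < lo:
        raise ConfigurationError(f"range {v} is not ordered")
    return (lo, hi)


def _is_fixed(r: Range) -> bool:
    return r[0] == r[1]


@dataclass(frozen=True)
class SimulationScenario:
    """Growth rates and fold-change grids defining one simulated setting.

    ``fc_neg``, ``fc_pos`` and ``fc_drug`` are fold changes at the
    evaluation time, given either as a fixed value or a ``(lo, hi)``
    range to sweep; they are the normative inputs to the metrics. The
    per-hour rates ``g_neg`` / ``g_pos`` drive trajectory and screen
    simulation.
    """

    name: str
    g_neg: float | Range = 0.03
    g_pos: float | Range = -0.01
    duration: float = 72.0
    eval_time: float = 72.0
    fc_neg: float | Range = 4.0
    fc_pos: float | Range = 0.5
    fc_drug: float | Range = (0.5, 8.0)

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration}")
        if not 0 < self.eval_time <= self.duration:
            raise ConfigurationError(
                f"eval_time must lie in (0, duration], got {self.eval_time}"
            )
        for name in ("g_neg", "g_pos", "fc_neg", "fc_pos", "fc_drug"):
            _as_range(getattr(self, name))

    def scalar_rate(self, name: str) -> float:
        """Midpoint of a rate range (the rate itself when fixed)."""
        lo, hi = _as_range(getattr(self, name))
        return 0.5 * (lo + hi)


#: Fixed controls (4-fold growth vs 0.5-fold decay), drug sweep 0.5-8 folds.
SCENARIO_1 = SimulationScenario(name="s1")
#: Varying positive-control background: decay rates -0.015..-0.005 per hour,
#: fold changes 0.4-0.8.
SCENARIO_2 = SimulationScenario(name="s2", g_pos=(-0.015, -0.005), fc_pos=(0.4, 0.8))
#: Varying negative-control growth: rates 0.01..0.055 per hour, folds 2-15.
SCENARIO_3 = SimulationScenario(name="s3", g_neg=(0.01, 0.055), fc_neg=(2.0, 15.0))

SCENARIOS = {"s1": SCENARIO_1, "s2": SCENARIO_2, "s3": SCENARIO_3}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal noise on seeding and on each readout.

    ``seeding_cv`` is the coefficient of variation of the true per-well
    starting signal; ``readout_cv`` applies independently to every
    measured readout. Factors are mean-one log-normals; identical seeds
    give identical screens.
    """

    seeding_cv: float = 0.0
    readout_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seeding_cv < 0 or self.readout_cv < 0:
            raise ConfigurationError("noise CVs must be >= 0")

    def factors(self, rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
        if cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def grow(start: float, g: float, t: float) -> float:
    """Signal after ``t`` hours of base-2 exponential growth at rate ``g``."""
    if not start > 0:
        raise ConfigurationError(f"start must be > 0, got {start}")
    if t < 0:
        raise ConfigurationError(f"t must be >= 0, got {t}")
    return start * 2.0 ** (g * t)


def dose_series(top: float, n: int = 5, dilution_factor: float = 10.0) -> tuple[float, ...]:
    """Ascending concentration series: ``n`` steps of constant dilution.

    The default five 10-fold dilutions span a 10,000-fold range.
    """
    if n < 2:
        raise ConfigurationError(f"need >= 2 concentrations, got {n}")
    if not dilution_factor > 1:
        raise ConfigurationError(f"dilution factor must be > 1, got {dilution_factor}")
    if not top > 0:
        raise ConfigurationError(f"top concentration must be > 0, got {top}")
    return tuple(top / dilution_factor ** (n - 1 - i) for i in range(n))


def _grid(r: Range, size: int) -> np.ndarray:
    """Log-spaced grid over a fold-change range (single point when fixed)."""
    if _is_fixed(r):
        return np.array([r[0]])
    return np.geomspace(r[0], r[1], size)


def run_scenario(
    scenario: SimulationScenario,
    grid_size: int = 100,
    control_grid_size: int = 5,
) -> pd.DataFrame:
    """Evaluate all three metrics over a scenario's fold-change grids.

    The drug axis gets ``grid_size`` log-spaced fold changes; a varying
    control axis gets ``control_grid_size``. Endpoint readouts for PI
    assume a common unit start signal, so endpoints equal fold changes.
    Grid points with a negative-control fold change of 1 (metrics
    undefined) are skipped with a warning. Deterministic: no noise.
    """
    if grid_size < 2:
        raise ConfigurationError(f"grid_size must be >= 2, got {grid_size}")
    fc_drugs = _grid(_as_range(scenario.fc_drug), grid_size)
    fc_negs = _grid(_as_range(scenario.fc_neg), control_grid_size)
    fc_poss = _grid(_as_range(scenario.fc_pos), control_grid_size)
    rows = []
    for fc_n, fc_p in itertools.product(fc_negs, fc_poss):
        if np.isclose(fc_n, 1.0):
            logger.warning("skipping degenerate grid point: fc_neg = 1 (metrics undefined)")
            continue
        for fc_d in fc_drugs:
            rows.append(
                {
                    "scenario": scenario.name,
                    "fc_drug": fc_d,
                    "fc_neg": fc_n,
                    "fc_pos": fc_p,
                    "NDR": ndr(fc_d, fc_n, fc_p),
                    "GR": gr(fc_d, fc_n),
                    "PI": pi(fc_d, fc_n, fc_p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full synthetic screens


@dataclass(frozen=True)
class DrugPotency:
    """True 4PL inhibition profile of a simulated drug.

    Inhibition fraction at concentration ``c``::

        f(c) = bottom + (top - bottom) / (1 + (ec50 / c)**slope)

    0 maps to negative-control growth, 1 to positive-control decay;
    negative values model growth stimulation.
    """

    top: float
    bottom: float = 0.0
    ec50: float = 1e-7
    slope: float = 1.0

    def inhibition(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / c) ** self.slope)


def default_drug_panel(n_drugs: int, seed: int = 0) -> dict[str, DrugPotency]:
    """A reproducible panel cycling through the four potency classes.

    Lethal drugs reach full inhibition, sub-effective ones plateau at
    partial inhibition, non-effective drugs are flat at zero, and
    growth-stimulatory drugs have negative inhibition (faster growth
    than the negative control).
    """
    rng = np.random.default_rng(seed)
    archetypes = [
        ("lethal", lambda: DrugPotency(top=1.0, ec50=10 ** rng.uniform(-8, -6.5), slope=rng.uniform(0.8, 2.0))),
        ("subeff", lambda: DrugPotency(top=rng.uniform(0.3, 0.6), ec50=10 ** rng.uniform(-8, -6.5), slope=rng.uniform(0.8, 2.0))),
        ("noneff", lambda: DrugPotency(top=0.0)),
        ("stim", lambda: DrugPotency(top=-rng.uniform(0.3, 0.6), ec50=10 ** rng.uniform(-8, -6.5), slope=rng.uniform(0.8, 2.0))),
    ]
    panel = {}
    for i in range(n_drugs):
        label, make = archetypes[i % len(archetypes)]
        panel[f"{label}_{i + 1:03d}"] = make()
    return panel


def _well_labels() -> list[str]:
    rows = [chr(ord("A") + i) for i in range(N_ROWS)]
    return [f"{r}{c}" for r in rows for c in range(1, N_COLS + 1)]


def generate_synthetic_screen(
    n_drugs: int = 32,
    n_concentrations: int = 5,
    plates: int = 1,
    scenario: SimulationScenario = SCENARIO_1,
    noise: NoiseModel | None = None,
    true_potency: dict[str, DrugPotency] | None = None,
    base_start: float = 1000.0,
    controls_per_role: int = 16,
    top_concentration: float = 1e-5,
    dilution_factor: float = 10.0,
) -> tuple[ScreenTable, pd.DataFrame]:
    """Simulate a full screen and return ``(table, ground_truth)``.

    Each drug appears at ``n_concentrations`` dilutions; wells fill
    plates sequentially after ``controls_per_role`` negative and
    positive control wells per plate. Each well's effective growth rate
    is ``g_neg + f(c) * (g_pos - g_neg)`` with ``f`` the drug's true
    inhibition. Readouts are ``base_start`` times seeding noise, grown
    for ``scenario.duration`` hours, times readout noise per
    measurement.

    The ground-truth frame carries one row per well with the noise-free
    fold change, true NDR/GR/PI, and (for drug wells) the true category
    from the noise-free top-concentration fold change.
    """
    noise = noise or NoiseModel()
    if true_potency is None:
        true_potency = default_drug_panel(n_drugs, seed=noise.seed)
    if len(true_potency) != n_drugs:
        raise ConfigurationError(
            f"true_potency has {len(true_potency)} drugs, expected {n_drugs}"
        )
    capacity = N_ROWS * N_COLS - 2 * controls_per_role
    n_drug_wells = n_drugs * n_concentrations
    if n_drug_wells > plates * capacity:
        raise ConfigurationError(
            f"layout overflow: {n_drug_wells} drug wells do not fit on {plates} "
            f"plate(s) with capacity {capacity} each (384 wells minus "
            f"2 x {controls_per_role} controls)"
        )
    g_neg = scenario.scalar_rate("g_neg")
    g_pos = scenario.scalar_rate("g_pos")
    T = scenario.duration
    concs = dose_series(top_concentration, n_concentrations, dilution_factor)

    # condition list: controls per plate, then drug wells in panel order
    conditions = []  # (plate, well, role, drug, conc, rate)
    labels = _well_labels()
    drug_iter = iter(
        (drug, conc, g_neg + float(pot.inhibition([conc])[0]) * (g_pos - g_neg))
        for drug, pot in true_potency.items()
        for conc in concs
    )
    for p in range(plates):
        pid = f"SIMPLATE{p + 1}"
        cursor = 0
        for _ in range(controls_per_role):
            conditions.append((pid, labels[cursor], ROLE_NEG, None, None, g_neg))
            cursor += 1
        for _ in range(controls_per_role):
            conditions.append((pid, labels[cursor], ROLE_POS, None, None, g_pos))
            cursor += 1
        for _ in range(capacity):
            nxt = next(drug_iter, None)
            if nxt is None:
                break
            drug, conc, rate = nxt
            conditions.append((pid, labels[cursor], ROLE_DRUG, drug, conc, rate))
            cursor += 1
    if next(drug_iter, None) is not None:
        raise ConfigurationError("internal layout error: drug wells left over")

    n = len(conditions)
    rng = np.random.default_rng(noise.seed)
    seed_f = noise.factors(rng, noise.seeding_cv, n)
    read_start_f = noise.factors(rng, noise.readout_cv, n)
    read_end_f = noise.factors(rng, noise.readout_cv, n)

    rates = np.array([c[5] for c in conditions])
    true_start = base_start * seed_f
    true_end = true_start * 2.0 ** (rates * T)
    start_readout = true_start * read_start_f
    end_readout = true_end * read_end_f

    fc_neg_true = 2.0 ** (g_neg * T)
    fc_pos_true = 2.0 ** (g_pos * T)
    neg_stats = NegControlGrowthStats(mean_fc=fc_neg_true, sd_fc=0.0)

    records, truth_rows = [], []
    for i, (pid, well, role, drug, conc, rate) in enumerate(conditions):
        records.append(
            WellRecord(
                plate_id=pid,
                well=well,
                role=role,
                drug_name=drug,
                concentration=conc,
                start_readout=float(start_readout[i]),
                end_readout=float(end_readout[i]),
            )
        )
        fc_true = 2.0 ** (rate * T)
        truth_rows.append(
            {
                "plate_id": pid,
                "well": well,
                "role": role,
                "drug_name": drug,
                "concentration": conc,
                "true_rate": rate,
                "true_fc": fc_true,
                "true_NDR": ndr(fc_true, fc_neg_true, fc_pos_true),
                "true_GR": gr(fc_true, fc_neg_true),
                "true_PI": pi(fc_true, fc_neg_true, fc_pos_true),
            }
        )
    truth = pd.DataFrame(truth_rows)

    # true category per drug from its noise-free top-concentration fold change
    top_conc = concs[-1]
    categories = {}
    for drug, pot in true_potency.items():
        rate = g_neg + float(pot.inhibition([top_conc])[0]) * (g_pos - g_neg)
        categories[drug] = classify_drug(2.0 ** (rate * T), neg_stats).value
    truth["true_category"] = truth["drug_name"].map(categories)

    metadata = {
        "scenario": scenario.name,
        "duration_h": T,
        "g_neg": g_neg,
        "g_pos": g_pos,
        "noise": {"seeding_cv": noise.seeding_cv, "readout_cv": noise.readout_cv, "seed": noise.seed},
    }
    return ScreenTable.from_records(records, metadata), truth
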