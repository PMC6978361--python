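import numpy as np
import pandas as pd
import pytest

from ndrscreen import NoiseModel, ScreenTable, WellRecord, generate_synthetic_screen


def make_plate(
    plate_id="P1",
    drug_wells=(("drugA", 1e-7, 100.0, 200.0), ("drugA", 1e-6, 100.0, 150.0)),
    neg=((100.0, 400.0), (100.0, 410.0)),
    pos=((100.0, 50.0), (100.0, 52.0)),
):
    """Build a minimal valid plate: drug wells as (name, conc, start, end),
    controls as (start, end)."""
    records = []
    col = 1
    for name, conc, s, e in drug_wells:
        records.append(WellRecord(plate_id, f"A{col}", "drug", s, e, name, conc))
        col += 1
    for i, (s, e) in enumerate(neg, start=1):
        records.append(WellRecord(plate_id, f"B{i}", "negative_control", s, e))
    for i, (s, e) in enumerate(pos, start=1):
        records.append(WellRecord(plate_id, f"C{i}", "positive_control", s, e))
    return records


@pytest.fixture
def toy_table():
    return ScreenTable.from_records(make_plate())


@pytest.fixture
def toy_csv(tmp_path):
    """8-row toy CSV: 4 drug wells + 2 DMSO + 2 BzCl on one plate."""
    df = pd.DataFrame(
        {
            "plate_id": ["P1"] * 8,
            "well": ["A1", "A2", "A3", "A4", "B1", "B2", "C1", "C2"],
            "drug_name": ["drugA", "drugA", "drugB", "drugB", "DMSO", "DMSO", "BzCl", "BzCl"],
            "concentration": [1e-7, 1e-6, 1e-7, 1e-6, "", "", "", ""],
            "start_readout": [100.0] * 8,
            "end_readout": [200.0, 150.0, 300.0, 120.0, 400.0, 410.0, 50.0, 52.0],
        }
    )
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def noise_free_screen():
    """Deterministic 32-drug single-plate screen with its ground truth."""
    return generate_synthetic_screen(n_drugs=32, plates=1, noise=NoiseModel(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
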