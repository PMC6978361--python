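"""Data model for 384-well drug screens and CSV readers/writers.

A screen is a collection of wells, each carrying a plate identifier, a
well position (row letter A-P, column 1-24), a role (drug /
negative_control / positive_control / excluded) and two luminescence
readouts: one at the start of incubation and one at the endpoint.
Negative controls are vehicle-treated (DMSO) wells assumed to grow
unperturbed; positive controls (benzethonium chloride) are assumed fully
lethal, so their endpoint signal is the assay background.

The canonical in-memory container is a pandas DataFrame wrapped in
:class:`ScreenTable`; readers validate structural invariants row by row
and report offending rows rather than failing wholesale.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ndrscreen.errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

ROLE_DRUG = "drug"
ROLE_NEG = "negative_control"
ROLE_POS = "positive_control"
ROLE_EXCLUDED = "excluded"
ROLES = frozenset({ROLE_DRUG, ROLE_NEG, ROLE_POS, ROLE_EXCLUDED})

#: Default labels the reader maps onto control roles.
DEFAULT_CONTROL_LABELS = {"negative": "DMSO", "positive": "BzCl"}

#: Canonical column names of a screen table.
CANONICAL_COLUMNS = (
    "plate_id",
    "well",
    "role",
    "drug_name",
    "concentration",
    "start_readout",
    "end_readout",
    "toxicity_readout",
)

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")

# 384-well plate bounds
N_ROWS = 16
N_COLS = 24


def parse_well(well: str) -> tuple[str, int]:
    """Split a well label like ``"B07"`` into (row letter, 1-based column).

    Raises :class:`ValidationError` when the label falls outside the
    16 x 24 grid of a 384-well plate.
    """
    m = _WELL_RE.match(str(well).strip().upper())
    if not m:
        raise ValidationError(f"well label {well!r} is not within 384-well bounds (A1..P24)")
    row, col = m.group(1), int(m.group(2))
    if not 1 <= col <= N_COLS:
        raise ValidationError(f"well column {col} outside 1..{N_COLS} in label {well!r}")
    return row, col


@dataclass(frozen=True)
class WellRecord:
    """One well of a screen: annotations plus start/end readouts.

    ``drug_name`` and ``concentration`` are required exactly when
    ``role == "drug"``; control wells must leave both unset.
    Readouts are non-negative and finite; a zero start readout is legal
    at the data-model level but makes the fold change undefined, so
    metric operations reject such wells.
    """

    plate_id: str
    well: str
    role: str
    start_readout: float
    end_readout: float
    drug_name: str | None = None
    concentration: float | None = None
    toxicity_readout: float | None = None

    def __post_init__(self) -> None:
        parse_well(self.well)
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for well {self.well}")
        if self.role == ROLE_DRUG:
            if not self.drug_name:
                raise ValidationError(f"drug well {self.plate_id}/{self.well} lacks drug_name")
            if self.concentration is None or not self.concentration > 0:
                raise ValidationError(
                    f"drug well {self.plate_id}/{self.well} needs a positive concentration"
                )
        elif self.role in (ROLE_NEG, ROLE_POS):
            if self.drug_name or self.concentration is not None:
                raise ValidationError(
                    f"control well {self.plate_id}/{self.well} must not carry drug annotations"
                )
        for name in ("start_readout", "end_readout"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{name} of well {self.plate_id}/{self.well} must be finite and >= 0, got {v}"
                )
        if self.toxicity_readout is not None and (
            not np.isfinite(self.toxicity_readout) or self.toxicity_readout < 0
        ):
            raise ValidationError(
                f"toxicity_readout of well {self.plate_id}/{self.well} must be finite and >= 0"
            )


@dataclass
class ScreenTable:
    """A validated screen: a well-level DataFrame plus free-form metadata.

    The DataFrame always carries :data:`CANONICAL_COLUMNS`; extra columns
    (computed metrics, fold changes) are preserved by copies and writes.
    """

    wells: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValidationError(f"screen table missing canonical columns: {missing}")
        dup = self.wells.duplicated(subset=["plate_id", "well"])
        if dup.any():
            pairs = self.wells.loc[dup, ["plate_id", "well"]].itertuples(index=False)
            raise ValidationError(
                "duplicate (plate_id, well) pairs: " + ", ".join(f"{p}/{w}" for p, w in pairs)
            )

    def __len__(self) -> int:
        return len(self.wells)

    @property
    def plate_ids(self) -> list[str]:
        return list(self.wells["plate_id"].unique())

    def plate(self, plate_id: str) -> pd.DataFrame:
        return self.wells[self.wells["plate_id"] == plate_id]

    def active(self) -> pd.DataFrame:
        """Wells not marked excluded."""
        return self.wells[self.wells["role"] != ROLE_EXCLUDED]

    def copy(self) -> "ScreenTable":
        return ScreenTable(self.wells.copy(), dict(self.metadata))

    @classmethod
    def from_records(cls, records: Iterable[WellRecord], metadata: dict | None = None) -> "ScreenTable":
        rows = [
            {
                "plate_id": r.plate_id,
                "well": r.well,
                "role": r.role,
                "drug_name": r.drug_name,
                "concentration": r.concentration,
                "start_readout": r.start_readout,
                "end_readout": r.end_readout,
                "toxicity_readout": r.toxicity_readout,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return cls(df, metadata or {})

    def validate_controls(self, min_controls: int = 2) -> None:
        """Require >= ``min_controls`` wells of each control role on every plate
        that carries drug wells (needed for control medians and Z')."""
        for pid, plate in self.wells.groupby("plate_id"):
            if not (plate["role"] == ROLE_DRUG).any():
                continue
            n_neg = int((plate["role"] == ROLE_NEG).sum())
            n_pos = int((plate["role"] == ROLE_POS).sum())
            if n_neg < min_controls or n_pos < min_controls:
                raise ValidationError(
                    f"plate {pid}: needs >= {min_controls} wells of each control role, "
                    f"found {n_neg} negative / {n_pos} positive"
                )


def _coerce_readout(value, column: str, row_label) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row_label}: column {column!r} value {value!r} is not numeric")
    if not np.isfinite(v) or v < 0:
        raise ParseError(f"row {row_label}: column {column!r} must be finite and >= 0, got {v}")
    return v


def read_screen_table(
    path: str | Path,
    format_config: Mapping[str, str] | None = None,
    control_labels: Mapping[str, str] | None = None,
    metadata: dict | None = None,
) -> ScreenTable:
    """Read a per-well CSV into a validated :class:`ScreenTable`.

    Parameters
    ----------
    path
        CSV file with a header row; comma-separated, UTF-8.
    format_config
        Maps canonical column names (``plate_id``, ``well``, ``drug_name``,
        ``concentration``, ``start_readout``, ``end_readout``, optionally
        ``role`` and ``toxicity_readout``) onto the file's column names.
        Unmapped canonical names default to themselves.
    control_labels
        ``{"negative": label, "positive": label}``. When the file has no
        explicit role column, rows whose drug name equals one of these
        labels become control wells (default DMSO / BzCl).

    Raises
    ------
    ConfigurationError
        When a mapped column is absent from the file.
    ParseError
        When a readout does not parse as a non-negative number; the
        message names the offending row.
    ValidationError
        On duplicate wells or invariant violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    colmap = {c: c for c in CANONICAL_COLUMNS}
    colmap["role"] = "role"
    if format_config:
        colmap.update(format_config)
    labels = dict(DEFAULT_CONTROL_LABELS)
    if control_labels:
        labels.update(control_labels)

    raw = pd.read_csv(path, dtype=str)
    required = ["plate_id", "well", "start_readout", "end_readout"]
    for canon in required:
        if colmap[canon] not in raw.columns:
            raise ConfigurationError(
                f"required column {colmap[canon]!r} (for {canon}) not found in {path.name}; "
                f"available: {list(raw.columns)}"
            )

    has_role = colmap["role"] in raw.columns
    has_drug = colmap["drug_name"] in raw.columns
    has_conc = colmap["concentration"] in raw.columns
    has_tox = colmap["toxicity_readout"] in raw.columns

    records: list[WellRecord] = []
    flagged_zero_start = 0
    for idx, row in raw.iterrows():
        label = idx + 2  # 1-based file row, after the header
        drug_name = row[colmap["drug_name"]] if has_drug else None
        if pd.isna(drug_name) or drug_name == "":
            drug_name = None
        if has_role:
            role = str(row[colmap["role"]]).strip()
            if role not in ROLES:
                raise ParseError(f"row {label}: unknown role {role!r}")
        else:
            if drug_name == labels["negative"]:
                role, drug_name = ROLE_NEG, None
            elif drug_name == labels["positive"]:
                role, drug_name = ROLE_POS, None
            else:
                role = ROLE_DRUG
        conc = None
        if role == ROLE_DRUG:
            if not has_conc or pd.isna(row[colmap["concentration"]]):
                raise ParseError(f"row {label}: drug well lacks a concentration")
            conc = float(row[colmap["concentration"]])
        start = _coerce_readout(row[colmap["start_readout"]], colmap["start_readout"], label)
        end = _coerce_readout(row[colmap["end_readout"]], colmap["end_readout"], label)
        if start == 0:
            flagged_zero_start += 1
        tox = None
        if has_tox and not pd.isna(row[colmap["toxicity_readout"]]):
            tox = _coerce_readout(row[colmap["toxicity_readout"]], colmap["toxicity_readout"], label)
        try:
            records.append(
                WellRecord(
                    plate_id=str(row[colmap["plate_id"]]),
                    well=str(row[colmap["well"]]),
                    role=role,
                    drug_name=drug_name if role == ROLE_DRUG else None,
                    concentration=conc,
                    start_readout=start,
                    end_readout=end,
                    toxicity_readout=tox,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {label}: {exc}") from exc
    if flagged_zero_start:
        logger.warning(
            "%d wells have start_readout = 0; accepted at read time but their fold change "
            "is undefined and metric operations will reject them",
            flagged_zero_start,
        )
    return ScreenTable.from_records(records, metadata)


def exclude_wells(table: ScreenTable, labels: Iterable[str]) -> ScreenTable:
    """Mark wells whose drug name matches one of ``labels`` as excluded.

    Excluded wells are ignored by every downstream computation (control
    medians, scoring, QC). The operation is idempotent; labels matching
    nothing are a logged no-op. Returns a new table.
    """
    labels = set(labels)
    out = table.copy()
    if not labels:
        return out
    mask = out.wells["drug_name"].isin(labels)
    unmatched = labels - set(out.wells.loc[mask, "drug_name"].unique())
    if unmatched:
        logger.warning("exclusion labels matched no wells: %s", sorted(unmatched))
    out.wells.loc[mask, "role"] = ROLE_EXCLUDED
    return out


def write_results(table: ScreenTable, path: str | Path) -> Path:
    """Write a screen table (with any computed metric columns) to CSV.

    One row per well; an empty table yields a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.wells.to_csv(path, index=False)
    return path
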