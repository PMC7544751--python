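"""Simulated-vs-measured Hp(0.07) comparison and measurement fixtures.

Measured per-finger records are read from a small CSV dialect
(``worker_role, facility, finger, hp007_msv`` with a mandatory header,
dot decimals). :func:`compare` checks each simulated fingertip value
against the min-max envelope of the (optionally role-filtered)
measurements; a simulated value equal to a measured extreme counts as
within range — only a strict excess is flagged.
:func:`generate_fixture_measurements` emulates a dosimeter campaign by
drawing log-normal values around a template report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .dosimetry import DoseReport
from .scene import FINGERS

__all__ = [
    "MeasurementRecord",
    "FingerComparison",
    "ComparisonReport",
    "MeasurementValidationError",
    "load_measurements",
    "records_to_csv",
    "compare",
    "generate_fixture_measurements",
]

CSV_COLUMNS = ("worker_role", "facility", "finger", "hp007_msv")
WORKER_ROLES = ("nurse", "chemist", "physicist")


class MeasurementValidationError(ValueError):
    """Raised when a measurement table contains invalid rows."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid measurement rows:\n" + "\n".join(self.problems)
        )


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured fingertip Hp(0.07) value, mSv."""

    worker_role: str
    facility: str
    finger: str
    hp007_msv: float

    def __post_init__(self):
        if self.finger not in FINGERS:
            raise ValueError(f"unknown finger {self.finger!r}")
        if self.hp007_msv < 0:
            raise ValueError("hp007 must be >= 0")


@dataclass(frozen=True)
class FingerComparison:
    finger: str
    simulated_msv: float
    measured_min_msv: float
    measured_max_msv: float
    status: str  # within | below_min | exceeds_max
    excess_msv: float  # simulated - max when exceeding, else 0


@dataclass
class ComparisonReport:
    fingers: dict  # finger -> FingerComparison
    role_filter: Optional[str] = None

    def status(self, finger: str) -> str:
        return self.fingers[finger].status

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.fingers.values()])

    def summary(self) -> str:
        lines = []
        role = self.role_filter or "all roles"
        lines.append(f"Hp(0.07) simulated vs measured ({role})")
        for c in self.fingers.values():
            lines.append(
                f"  {c.finger:<6} sim {c.simulated_msv:7.3f} mSv  "
                f"measured [{c.measured_min_msv:.3f}, "
                f"{c.measured_max_msv:.3f}]  {c.status}"
                + (
                    f" (+{c.excess_msv:.3f} mSv)"
                    if c.status == "exceeds_max"
                    else ""
                )
            )
        return "\n".join(lines)

    def write(self, csv_path=None, json_path=None, provenance=None):
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            payload = {
                "role_filter": self.role_filter,
                "fingers": {
                    k: asdict(v) for k, v in self.fingers.items()
                },
            }
            if provenance:
                payload["provenance"] = provenance
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def load_measurements(path) -> list[MeasurementRecord]:
    """Read and validate a measurement CSV.

    Malformed rows (negative dose, unknown finger or role, missing
    fields) are collected and reported together with their line numbers
    in a :class:`MeasurementValidationError`.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise MeasurementValidationError(
            [f"missing required columns: {sorted(missing)}"]
        )
    records, problems = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        finger = str(row["finger"]).strip()
        role = str(row["worker_role"]).strip()
        if finger not in FINGERS:
            problems.append(f"line {line}: unknown finger {finger!r}")
            continue
        if role not in WORKER_ROLES:
            problems.append(f"line {line}: unknown worker_role {role!r}")
            continue
        try:
            value = float(row["hp007_msv"])
        except (TypeError, ValueError):
            problems.append(
                f"line {line}: hp007_msv {row['hp007_msv']!r} not numeric"
            )
            continue
        if not np.isfinite(value) or value < 0:
            problems.append(f"line {line}: hp007_msv {value!r} negative")
            continue
        records.append(
            MeasurementRecord(role, str(row["facility"]).strip(), finger,
                              value)
        )
    if problems:
        raise MeasurementValidationError(problems)
    return records


def records_to_csv(records: Iterable[MeasurementRecord], path) -> None:
    """Write records in the measurement CSV dialect."""
    df = pd.DataFrame([asdict(r) for r in records], columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def compare(
    simulated: DoseReport,
    measurements: Sequence[MeasurementRecord],
    role_filter: Optional[str] = None,
) -> ComparisonReport:
    """Compare simulated fingertip doses against measured envelopes.

    Fingers without any (filtered) measurement are omitted with a
    warning. Boundary convention: equality with an extreme is within.
    """
    recs = [
        r
        for r in measurements
        if role_filter is None or r.worker_role == role_filter
    ]
    out = {}
    for finger in FINGERS:
        if finger not in simulated.fingers:
            continue
        values = [r.hp007_msv for r in recs if r.finger == finger]
        if not values:
            warnings.warn(
                f"no measurements for finger {finger!r}; omitted",
                stacklevel=2,
            )
            continue
        sim = simulated.hp007(finger)
        lo, hi = min(values), max(values)
        if sim > hi:
            status, excess = "exceeds_max", sim - hi
        elif sim < lo:
            status, excess = "below_min", 0.0
        else:
            status, excess = "within", 0.0
        out[finger] = FingerComparison(finger, sim, lo, hi, status, excess)
    return ComparisonReport(fingers=out, role_filter=role_filter)


def generate_fixture_measurements(
    rng: np.random.Generator,
    template: DoseReport,
    spread: float,
    path=None,
    n_workers: int = 4,
    roles: Sequence[str] = ("nurse", "nurse", "nurse", "chemist"),
    facilities: Optional[Sequence[str]] = None,
) -> list[MeasurementRecord]:
    """Draw synthetic per-worker measurements around a template report.

    Values are log-normal around the template fingertip doses with
    log-space standard deviation ``spread`` (the geometric sd is
    ``exp(spread)``). Stands in for a physical dosimeter campaign.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    if facilities is None:
        facilities = [f"site-{i + 1}" for i in range(n_workers)]
    roles = list(roles)[:n_workers] + ["nurse"] * (n_workers - len(roles))
    records = []
    for w in range(n_workers):
        for finger in FINGERS:
            if finger not in template.fingers:
                continue
            base = template.hp007(finger)
            value = base * float(np.exp(spread * rng.standard_normal()))
            records.append(
                MeasurementRecord(roles[w], facilities[w], finger, value)
            )
    if path is not None:
        records_to_csv(records, path)
    return records
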