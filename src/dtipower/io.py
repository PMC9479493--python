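"""Tabular I/O: test-retest CSV reading, power-grid CSV writing, cohort dumps."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import PowerGridRow
from .exceptions import InvalidInputError
from .power import Scenario
from .reliability import TestRetestMatrix
from .trajectory import DecreaseModel, draw_subject, observe_session

__all__ = [
    "read_retest_csv",
    "write_power_csv",
    "read_power_csv",
    "dump_cohort_csv",
    "POWER_CSV_HEADER",
]

POWER_CSV_HEADER = ("rate_percent", "sem", "t_days", "m", "n_per_group", "power", "mc_se", "seed")


def read_retest_csv(path: str | Path) -> TestRetestMatrix:
    """Read a test-retest table: header ``subject,meas_1,...,meas_k``,
    one row per subject, complete design."""
    df = pd.read_csv(path)
    if df.shape[1] < 3 or df.columns[0] != "subject":
        raise InvalidInputError(
            f"{path}: expected header 'subject,meas_1,...,meas_k' with at least "
            f"two measurement columns, got {list(df.columns)}"
        )
    meas_cols = list(df.columns[1:])
    bad = [c for c in meas_cols if not c.startswith("meas_")]
    if bad:
        raise InvalidInputError(f"{path}: non-measurement columns after 'subject': {bad}")
    values = df[meas_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise InvalidInputError(f"{path}: missing cells are not supported (complete design required)")
    return TestRetestMatrix(values)


def write_retest_csv(matrix: TestRetestMatrix, path: str | Path) -> None:
    """Write a test-retest table in the ``subject,meas_1,...`` layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject"] + [f"meas_{j + 1}" for j in range(matrix.k)])
        for i, row in enumerate(matrix.values, start=1):
            writer.writerow([i] + [repr(float(v)) for v in row])


def write_power_csv(rows: Sequence[PowerGridRow], path: str | Path) -> None:
    """Write grid rows to CSV with the fixed column order and full float
    precision.  Deterministic: identical rows yield byte-identical files."""
    if len(rows) == 0:
        raise InvalidInputError("refusing to write an empty power grid")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(POWER_CSV_HEADER)
        for r in rows:
            writer.writerow(
                [
                    repr(float(r.annual_rate_percent)),
                    repr(float(r.sem)),
                    repr(float(r.t_days)),
                    r.m,
                    r.n_per_group,
                    repr(float(r.power)),
                    repr(float(r.mc_standard_error)),
                    r.seed,
                ]
            )


def read_power_csv(path: str | Path) -> pd.DataFrame:
    """Read back a power-grid CSV written by :func:`write_power_csv`."""
    df = pd.read_csv(path)
    if tuple(df.columns) != POWER_CSV_HEADER:
        raise InvalidInputError(f"{path}: unexpected columns {list(df.columns)}")
    return df


def dump_cohort_csv(scenario: Scenario, path: str | Path) -> None:
    """Write one simulated cohort (both groups, both sessions, every scan)
    for inspection: columns group,subject,session,t_days,scan_index,fa_value."""
    rng = np.random.default_rng(scenario.seed)
    no_decline = DecreaseModel(0.0, 0.0, scenario.decrease.anchor_fa)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "subject", "session", "t_days", "scan_index", "fa_value"])
        for group_name, group, decrease in (
            ("patient", scenario.patient_group, scenario.decrease),
            ("control", scenario.control_group, no_decline),
        ):
            for i in range(scenario.n_per_group):
                subj = draw_subject(group, decrease, rng, anchoring=scenario.anchoring)
                for session_name, t in (("baseline", 0.0), ("followup", scenario.t_days)):
                    obs = observe_session(subj, t, scenario.m, scenario.error, rng)
                    for j, fa in enumerate(obs.scans):
                        writer.writerow([group_name, i + 1, session_name, t, j + 1, repr(fa)])
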