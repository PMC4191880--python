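"""Readers and writers for the fixture and output tables.

All tabular I/O is plain CSV with documented headers.  The packaged
fixtures are the 21-subject paired-means cohort (``table6.csv``) and the
two-subject area/volume/Hb loss table (``table4.csv``).
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .population import SubjectSummary
from .rates import ClearanceCurve

SUBJECT_COLUMNS = [
    "subject",
    "retic_volume_fl",
    "total_volume_fl",
    "retic_hb_pg",
    "total_hb_pg",
    "retic_conc_gdl",
    "total_conc_gdl",
]

LOSS_COLUMNS = [
    "subject",
    "area_lost_um2",
    "volume_lost_fl",
    "hb_lost_pg",
    "area_pct",
    "volume_pct",
    "hb_pct",
]


def _read_csv_checked(path, required: list, label: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{label} file {path} is empty")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{label} file {path} is missing column(s): {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{label} file {path}: ignoring unknown column(s) {extra}")
    for col in required[1:]:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(np.argmax(bad.values)) + 2  # 1-based + header
            raise ValueError(
                f"{label} file {path}: non-numeric value in column "
                f"{col!r} at line {row}"
            )
        df[col] = pd.to_numeric(df[col])
    return df


def read_subject_table(path) -> List[SubjectSummary]:
    """Read a per-subject paired-means CSV into typed subject records."""
    df = _read_csv_checked(path, SUBJECT_COLUMNS, "subject table")
    return [
        SubjectSummary(
            subject_id=str(r["subject"]),
            retic_volume=r["retic_volume_fl"],
            total_volume=r["total_volume_fl"],
            retic_hb=r["retic_hb_pg"],
            total_hb=r["total_hb_pg"],
            retic_conc=r["retic_conc_gdl"],
            total_conc=r["total_conc_gdl"],
        )
        for _, r in df.iterrows()
    ]


def write_subject_table(subjects: List[SubjectSummary], path) -> None:
    rows = [
        {
            "subject": s.subject_id,
            "retic_volume_fl": s.retic_volume,
            "total_volume_fl": s.total_volume,
            "retic_hb_pg": s.retic_hb,
            "total_hb_pg": s.total_hb,
            "retic_conc_gdl": s.retic_conc,
            "total_conc_gdl": s.total_conc,
        }
        for s in subjects
    ]
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False)


def read_loss_table(path) -> pd.DataFrame:
    """Read an area/volume/Hb loss table (two-subject fixture dialect)."""
    return _read_csv_checked(path, LOSS_COLUMNS, "loss table")


def read_clearance_curve(path) -> ClearanceCurve:
    """Read a clearance curve CSV (``time_min,remaining_fraction``)."""
    df = _read_csv_checked(
        path, ["time_min", "remaining_fraction"], "clearance curve"
    )
    return ClearanceCurve(
        times=df["time_min"].to_numpy(),
        remaining_fraction=df["remaining_fraction"].to_numpy(),
    )


def write_clearance_curve(curve: ClearanceCurve, path) -> None:
    pd.DataFrame(
        {"time_min": curve.times, "remaining_fraction": curve.remaining_fraction}
    ).to_csv(path, index=False)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    return Path(resources.files("rbcmat") / "fixtures" / name)


def load_cohort() -> List[SubjectSummary]:
    """The packaged 21-subject paired-means cohort."""
    return read_subject_table(fixture_path("table6.csv"))


def load_loss_table() -> pd.DataFrame:
    """The packaged two-subject area/volume/Hb loss table."""
    return read_loss_table(fixture_path("table4.csv"))
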