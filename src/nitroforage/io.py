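"""Deterministic TSV writers for trajectories and summary tables.

All outputs are tab-separated UTF-8 with Unix newlines and '.' decimal
separator; identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import Trajectory

__all__ = ["write_table", "write_trajectory", "write_summary",
           "SUMMARY_COLUMNS"]

SUMMARY_COLUMNS = ["plant", "length_low_N_mm", "length_high_N_mm",
                   "difference_mm"]


def write_table(df: pd.DataFrame, path: str | Path,
                float_format: str = "%.6g") -> Path:
    """Write a DataFrame as deterministic TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=float_format,
              lineterminator="\n", encoding="utf-8")
    return path


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Tidy per-(time, compartment) trajectory TSV."""
    return write_table(traj.to_frame(), path)


def write_summary(summary: pd.DataFrame | None, path: str | Path) -> Path:
    """Write a mutant/split-root summary in the standard four-column shape.

    ``summary`` may be None or empty, producing a header-only file.  Length
    columns are written as integers (reported lengths are rounded to the
    nearest mm).
    """
    if summary is None or len(summary) == 0:
        df = pd.DataFrame(columns=SUMMARY_COLUMNS)
    else:
        missing = set(SUMMARY_COLUMNS) - set(summary.columns)
        if missing:
            raise ValueError(f"summary missing column(s): {sorted(missing)}")
        df = summary[SUMMARY_COLUMNS].copy()
        for col in SUMMARY_COLUMNS[1:]:
            df[col] = df[col].round().astype(int)
    return write_table(df, path)
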