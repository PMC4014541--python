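"""CSV input/output.

All interchange is plain UTF-8 CSV with a header row and decimal points.
Sample tables are long format, one row per blood sample::

    subject_id,time_min,ratio_tracer[,ratio_is]

or, for pre-computed enrichments::

    subject_id,time_min,ape_percent

Result tables carry one row per subject with the full AUC decomposition;
column names and order are stable across runs so outputs diff cleanly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError

__all__ = ["read_samples_csv", "write_results_csv", "read_tidy_results_csv"]

RESULT_COLUMNS = [
    "subject_id",
    "n_points",
    "auc_observed",
    "auc_tail",
    "auc_total",
    "dose_umol_per_kg",
    "ra",
    "exo_rate",
    "endo_ra",
    "tail_k_per_min",
    "tail_amplitude_ape",
    "tail_n_points",
    "tail_r_squared",
]


def read_samples_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format sample table; validates the required columns."""
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if not {"subject_id", "time_min"} <= cols:
        raise InputError(f"{path}: need columns 'subject_id' and 'time_min', got {sorted(cols)}")
    if "ratio_tracer" not in cols and "ape_percent" not in cols:
        raise InputError(f"{path}: need a 'ratio_tracer' or 'ape_percent' column")
    return frame


def write_results_csv(results: pd.DataFrame, path: str | Path) -> None:
    """Write a kinetics result table with the canonical column order."""
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise InputError(f"result table is missing columns {missing}")
    results[RESULT_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_tidy_results_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy per-subject table (subject_id, group[, occasion], endo_ra)."""
    frame = pd.read_csv(path)
    if "endo_ra" not in frame.columns:
        raise InputError(f"{path}: need an 'endo_ra' column")
    return frame
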