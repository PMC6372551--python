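"""Phenotype table I/O.

The interchange format is a CSV/TSV with one row per participant and
unit-suffixed biomarker columns (``melatonin_nM``, ``pgv_mm3``,
``tbv_cm3``) so that nanomolar/millimetre-cube units are explicit in the
file itself. The delimiter is inferred from the extension (.tsv/.tab ->
tab, otherwise comma).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .normative import VALID_GROUPS

logger = logging.getLogger("pinealnorm")

REQUIRED_COLUMNS = ["id", "group", "sex", "age", "iq", "melatonin_nM", "pgv_mm3", "tbv_cm3"]
OPTIONAL_COLUMNS = ["srs", "planted_outlier"]
#: biomarkers whose absence invalidates a row (listwise exclusion)
REQUIRED_BIOMARKERS = ["age", "iq", "melatonin_nM", "pgv_mm3", "tbv_cm3"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a phenotype table.

    Rows with missing required biomarkers are dropped with a logged
    count (listwise exclusion); a missing required column or an unknown
    group label is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    bad_group = ~df["group"].isin(VALID_GROUPS)
    if bad_group.any():
        row = int(df.index[bad_group][0]) + 2  # 1-based, after header
        raise ValueError(
            f"{path}: unknown group label {df.loc[bad_group, 'group'].iloc[0]!r} "
            f"at row {row} (expected one of {VALID_GROUPS})"
        )
    complete = df[REQUIRED_BIOMARKERS].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d row(s) with missing required biomarkers", path, n_dropped
        )
    df = df[complete].reset_index(drop=True)
    for col in REQUIRED_BIOMARKERS:
        df[col] = df[col].astype(float)
    if "srs" not in df.columns:
        df["srs"] = float("nan")
    return df


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    """Write a phenotype table (delimiter from the extension)."""
    path = Path(path)
    frame.to_csv(path, sep=_sep_for(path), index=False)
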