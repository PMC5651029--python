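"""CSV schemas and readers/writers for the package's tabular formats.

Three tidy CSV layouts are used throughout (UTF-8, header required):

time-course
    region, metabolite, carbon_position, time_min, replicate_id,
    enrichment_fraction, labeled_conc_umol_g
group table
    region, group, position, labeled_conc_umol_g, sem, n
peak table
    analyte, area_nonedited, area_edited, n_protons, ref_analyte,
    ref_area, ref_n_protons, ref_amount, tissue_mass_g
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import TIMECOURSE_COLUMNS

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_group_table_csv",
    "write_group_table_csv",
    "read_peak_table_csv",
]

GROUP_TABLE_COLUMNS = ("region", "group", "position",
                       "labeled_conc_umol_g", "sem", "n")
PEAK_TABLE_COLUMNS = ("analyte", "area_nonedited", "area_edited", "n_protons",
                      "ref_analyte", "ref_area", "ref_n_protons", "ref_amount")


def _check_columns(df: pd.DataFrame, required: tuple[str, ...],
                   path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_timecourse_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TIMECOURSE_COLUMNS, path)
    if (df["enrichment_fraction"] < 0).any() or \
            (df["enrichment_fraction"] > 1).any():
        raise ValueError(f"{path}: enrichment_fraction outside [0, 1]")
    if (df["time_min"] < 0).any():
        raise ValueError(f"{path}: negative time_min")
    return df


def write_timecourse_csv(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, TIMECOURSE_COLUMNS, path)
    df.to_csv(path, index=False)


def read_group_table_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, GROUP_TABLE_COLUMNS[:4], path)
    if (df["labeled_conc_umol_g"] < 0).any():
        raise ValueError(f"{path}: negative labelled concentrations")
    return df


def write_group_table_csv(df: pd.DataFrame, path: str | Path) -> None:
    _check_columns(df, GROUP_TABLE_COLUMNS[:4], path)
    df.to_csv(path, index=False)


def read_peak_table_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, PEAK_TABLE_COLUMNS[:2], path)
    return df
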