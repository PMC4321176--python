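"""Delimited-text input/output.

All files are tab-separated UTF-8 with "." decimals and "NA" for missing
values. Beta matrices have probe ids in the first column and sample ids in
the header row. Floats are written at a fixed precision so repeated writes
are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ANNOTATION_COLUMNS, BetaMatrix, derive_cpg_class

NA = "NA"
FLOAT_FORMAT = "%.10g"


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False)
    bad_cols = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad_cols:
        col = bad_cols[0]
        row = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
        raise ValueError(f"non-numeric cell at probe {row!r}, sample {col!r} in {path}")
    return df.astype(float)


def read_beta_matrix(path, detection_path=None, tissue: str = "") -> BetaMatrix:
    """Read a probe x sample beta matrix (and optional detection p-values)."""
    beta = _read_matrix(path)
    det = _read_matrix(detection_path) if detection_path is not None else None
    return BetaMatrix(beta, det, tissue=tissue)


def write_beta_matrix(matrix: BetaMatrix, path, detection_path=None) -> None:
    matrix.beta.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA,
                       index_label="probe_id")
    if detection_path is not None and matrix.detection_p is not None:
        matrix.detection_p.to_csv(detection_path, sep="\t", float_format=FLOAT_FORMAT,
                                  na_rep=NA, index_label="probe_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    required = {"sample_id", "subject_id", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "tissue"])
    if dup.any():
        raise ValueError(f"duplicate (subject, tissue) rows: {df.loc[dup, 'subject_id'].tolist()}")
    return df


def read_annotation(path) -> pd.DataFrame:
    """Read a probe annotation table, deriving CpG-density classes if absent.

    Probes with no preassigned class and complete island metrics are classed
    with :func:`~methmatch.datamodel.derive_cpg_class`; probes missing any
    metric become ``"uncategorized"``.
    """
    df = pd.read_csv(path, sep="\t", index_col="probe_id",
                     na_values=[NA], keep_default_na=False)
    if df.index.has_duplicates:
        raise ValueError("duplicate probe ids in annotation")
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    cls = df["cpg_class"].copy()
    needs = cls.isna() | (cls == "")
    for pid in df.index[needs]:
        gc, oe, ln = df.at[pid, "gc_content"], df.at[pid, "obs_exp_cpg_ratio"], df.at[pid, "island_length"]
        if pd.isna(gc) or pd.isna(oe) or pd.isna(ln):
            cls.at[pid] = "uncategorized"
        else:
            cls.at[pid] = derive_cpg_class(float(gc), float(oe), float(ln))
    df["cpg_class"] = cls
    for flag in ("snp_overlap", "polymorphic_cpg"):
        df[flag] = df[flag].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        ).fillna(False).astype(bool)
    return df


def write_results(table: pd.DataFrame, path, index: bool = False) -> None:
    """Write a per-probe result table as deterministic tab-separated text."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA, index=index)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
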