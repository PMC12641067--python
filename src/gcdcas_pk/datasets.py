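"""Dataset CSV dialect (NONMEM-convention-inspired).

Columns:

====== =====================================================================
ID     subject, integer
OCC    occasion, integer (occasion-relative TIME: each occasion restarts at 0)
TIME   h; for urine records the collection-interval end
EVID   0 observation / 1 dose
DVID   1 biomarker plasma µM, 2 biomarker urine µmol, 3 rifampicin plasma µM,
       4 probenecid plasma µM (empty on dose rows)
DV     observed value (empty on dose rows)
AMT    dose amount, mg (empty on observation rows)
DRUG   RIF / PROB (dose rows only)
USTART urine collection-interval start, h (DVID=2 rows only)
====== =====================================================================

Units are fixed by the dialect; there is no unit inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_core import DoseEvent, PROBENECID, RIFAMPICIN

__all__ = ["DatasetError", "read_dataset", "write_dataset", "records_to_dataset",
           "dataset_to_records", "doses_from_dataset", "DVID_TO_OBS", "OBS_TO_DVID"]

DVID_TO_OBS = {
    1: "biomarker_plasma",
    2: "biomarker_urine",
    3: "rifampicin_plasma",
    4: "probenecid_plasma",
}
OBS_TO_DVID = {v: k for k, v in DVID_TO_OBS.items()}
DRUG_CODES = {"RIF": RIFAMPICIN, "PROB": PROBENECID}
DRUG_TO_CODE = {v: k for k, v in DRUG_CODES.items()}

COLUMNS = ["ID", "OCC", "TIME", "EVID", "DVID", "DV", "AMT", "DRUG", "USTART"]


class DatasetError(ValueError):
    """Schema violation in a dataset file; messages carry the row number."""


def _fail(row: int | None, msg: str):
    where = f"row {row}: " if row is not None else ""
    raise DatasetError(where + msg)


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        _fail(None, f"missing column(s) {missing}")
    df = df[COLUMNS].copy()
    sort_key = df[["ID", "OCC", "TIME"]].to_numpy()
    if not all(
        tuple(a) <= tuple(b) for a, b in zip(sort_key[:-1], sort_key[1:])
    ):
        _fail(None, "rows must be sorted by (ID, OCC, TIME)")
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        evid = row["EVID"]
        if evid not in (0, 1):
            _fail(rowno, f"EVID must be 0 or 1, got {evid!r}")
        has_dv = pd.notna(row["DV"])
        has_amt = pd.notna(row["AMT"])
        if has_dv == has_amt:
            _fail(rowno, "exactly one of DV/AMT must be populated")
        if evid == 0:
            if not has_dv:
                _fail(rowno, "observation row (EVID=0) must carry DV")
            dvid = row["DVID"]
            if dvid not in DVID_TO_OBS:
                _fail(rowno, f"bad DVID {dvid!r}")
            if row["DV"] < 0:
                _fail(rowno, "DV must be >= 0")
            if dvid == 2:
                if pd.isna(row["USTART"]):
                    _fail(rowno, "urine row (DVID=2) requires USTART")
                if not row["USTART"] < row["TIME"]:
                    _fail(rowno, "urine interval requires USTART < TIME")
            elif pd.notna(row["USTART"]):
                _fail(rowno, "USTART is only valid on urine rows (DVID=2)")
        else:
            if not has_amt:
                _fail(rowno, "dose row (EVID=1) must carry AMT")
            if row["AMT"] <= 0:
                _fail(rowno, "AMT must be > 0")
            if row["DRUG"] not in DRUG_CODES:
                _fail(rowno, f"dose row DRUG must be one of {list(DRUG_CODES)}, got {row['DRUG']!r}")
    return df


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dataset CSV; returns the validated frame."""
    df = pd.read_csv(path, dtype={"DRUG": "string"})
    df["DRUG"] = df["DRUG"].astype(object).where(pd.notna(df["DRUG"]), np.nan)
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Validate and write a dataset CSV (lossless round-trip)."""
    validate_dataset(df).to_csv(path, index=False)


def records_to_dataset(records: pd.DataFrame, doses_by_occasion: dict) -> pd.DataFrame:
    """Combine simulated observation records with per-occasion dose events.

    ``records``: frame with ID, OCC, TIME, OBS, DV, USTART (simulate_trial
    output).  ``doses_by_occasion``: occasion index -> DoseEvent sequence,
    expanded to every subject.
    """
    obs = records.copy()
    obs["EVID"] = 0
    obs["DVID"] = obs["OBS"].map(OBS_TO_DVID)
    if obs["DVID"].isna().any():
        bad = obs.loc[obs["DVID"].isna(), "OBS"].unique()
        raise DatasetError(f"unknown observable(s) {list(bad)}")
    obs["AMT"] = np.nan
    obs["DRUG"] = np.nan
    rows = [obs[COLUMNS]]
    ids = sorted(records["ID"].unique())
    for occ, doses in doses_by_occasion.items():
        for d in doses:
            rows.append(pd.DataFrame({
                "ID": ids, "OCC": occ, "TIME": d.time, "EVID": 1,
                "DVID": np.nan, "DV": np.nan, "AMT": d.amount,
                "DRUG": DRUG_TO_CODE[d.drug], "USTART": np.nan,
            }))
    df = pd.concat(rows, ignore_index=True)
    # doses before observations at equal times
    df = df.sort_values(["ID", "OCC", "TIME", "EVID"],
                        ascending=[True, True, True, False],
                        kind="stable").reset_index(drop=True)
    return validate_dataset(df)


def dataset_to_records(df: pd.DataFrame) -> pd.DataFrame:
    """Observation rows of a validated dataset, in simulate_trial layout."""
    obs = df[df["EVID"] == 0].copy()
    obs["OBS"] = obs["DVID"].map(DVID_TO_OBS)
    return obs[["ID", "OCC", "TIME", "OBS", "DV", "USTART"]].reset_index(drop=True)


def doses_from_dataset(df: pd.DataFrame, occ: int) -> tuple:
    """Dose events of one occasion (shared regimen across subjects)."""
    d = df[(df["EVID"] == 1) & (df["OCC"] == occ)]
    if d.empty:
        return ()
    first = d[d["ID"] == d["ID"].iloc[0]]
    return tuple(
        DoseEvent(DRUG_CODES[r["DRUG"]], float(r["TIME"]), float(r["AMT"]))
        for _, r in first.iterrows()
    )
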