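"""Flat CSV trial-dataset dialect (NONMEM-inspired) reader/writer.

One row per dosing event or observation.  Columns::

    ID     subject identifier (int)
    TIME   minutes relative to the start of the propofol infusion
           (the pre-induction fentanyl bolus has negative TIME)
    EVID   1 dose, 0 observation
    CMT    dose compartment: 1 propofol central, 2 fentanyl central; 0 otherwise
    DVID   observation stream: 1 CP (mg/L), 2 CF (ng/mL), 3 BIS, 4 CO (L/min);
           0 for dose rows
    AMT    dose amount (mg propofol / µg fentanyl); empty for observations
    RATE   amount/min; 0 or empty = bolus, > 0 = infusion of duration AMT/RATE
    DV     observed value; empty for dose rows
    MDV    1 = ignore DV
    BLQ    1 = below the assay limit of quantification
    AGE, STUDY, WT   subject covariates (constant within ID)

Rows are sorted by (ID, TIME, EVID descending) so doses precede
observations at the same time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CovariateRecord

__all__ = ["COLUMNS", "DVID_LABEL", "TrialDataset", "SubjectData", "read_dataset", "write_dataset"]

COLUMNS = ["ID", "TIME", "EVID", "CMT", "DVID", "AMT", "RATE", "DV", "MDV", "BLQ",
           "AGE", "STUDY", "WT"]
DVID_LABEL = {1: "CP", 2: "CF", 3: "BIS", 4: "CO"}
_CMT_DRUG = {1: "propofol", 2: "fentanyl"}


@dataclass
class SubjectData:
    """One subject's dosing history, observations and covariates."""

    covariates: CovariateRecord
    boluses: list            # (time, drug, amount)
    infusions: list          # (t_start, t_stop, drug, rate)
    observations: pd.DataFrame  # TIME, DVID, DV, MDV, BLQ


class TrialDataset:
    """Validated longitudinal trial dataset in the flat CSV dialect."""

    def __init__(self, df: pd.DataFrame):
        self.df = _validate(df)

    @property
    def subject_ids(self):
        return list(dict.fromkeys(self.df["ID"].tolist()))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subject(self, subject_id) -> SubjectData:
        rows = self.df[self.df["ID"] == subject_id]
        if rows.empty:
            raise KeyError(f"no such subject: {subject_id}")
        first = rows.iloc[0]
        cov = CovariateRecord(subject_id=subject_id, age=float(first["AGE"]),
                              study=int(first["STUDY"]), weight=float(first["WT"]))
        boluses, infusions = [], []
        doses = rows[rows["EVID"] == 1]
        for _, r in doses.iterrows():
            drug = _CMT_DRUG[int(r["CMT"])]
            rate = 0.0 if pd.isna(r["RATE"]) else float(r["RATE"])
            if rate > 0:
                infusions.append((float(r["TIME"]), float(r["TIME"]) + float(r["AMT"]) / rate,
                                  drug, rate))
            else:
                boluses.append((float(r["TIME"]), drug, float(r["AMT"])))
        obs = rows[rows["EVID"] == 0][["TIME", "DVID", "DV", "MDV", "BLQ"]].reset_index(drop=True)
        return SubjectData(covariates=cov, boluses=boluses, infusions=infusions, observations=obs)

    def subjects(self):
        return [self.subject(sid) for sid in self.subject_ids]

    def resample_subjects(self, subject_ids) -> "TrialDataset":
        """Dataset with subjects drawn (possibly repeatedly) from this one.

        Resampled subjects are relabeled 1..n so that duplicates remain
        distinct individuals.
        """
        parts = []
        for new_id, sid in enumerate(subject_ids, start=1):
            block = self.df[self.df["ID"] == sid].copy()
            if block.empty:
                raise KeyError(f"no such subject: {sid}")
            block["ID"] = new_id
            parts.append(block)
        return TrialDataset(pd.concat(parts, ignore_index=True))


def _fail(row_idx, msg):
    # +2: header line and 1-based numbering, matching what a user sees in the file
    raise ValueError(f"dataset row {row_idx + 2}: {msg}")


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    df = df[COLUMNS].copy()
    for col in ("ID", "EVID", "CMT", "DVID", "MDV", "BLQ", "STUDY"):
        df[col] = df[col].fillna(0).astype(int)
    def _first(mask, msg):
        if mask.any():
            _fail(int(np.flatnonzero(mask.to_numpy())[0]), msg)

    dose = df["EVID"] == 1
    obs = ~dose
    _first(~df["EVID"].isin([0, 1]), "EVID must be 0 or 1")
    _first(dose & ~df["CMT"].isin(list(_CMT_DRUG)), "dose row has unknown CMT")
    _first(dose & (df["DVID"] != 0), "dose row must have DVID 0")
    _first(dose & (df["AMT"].isna() | (df["AMT"] < 0)), "dose row needs AMT >= 0")
    _first(dose & df["DV"].notna(), "dose row must have empty DV")
    _first(dose & (df["MDV"] != 1), "dose row must have MDV = 1")
    _first(dose & (df["RATE"].fillna(0) < 0), "negative RATE")
    _first(obs & ~df["DVID"].isin(list(DVID_LABEL)), "observation row has unknown DVID")
    _first(obs & (df["AMT"].notna() | df["RATE"].notna()),
           "observation row must have empty AMT and RATE")
    _first(obs & df["DV"].isna() & (df["MDV"] == 0),
           "observation row with MDV = 0 must carry a DV")
    # per-subject ordering and covariate constancy
    for sid, block in df.groupby("ID", sort=False):
        t = block["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            j = block.index[int(np.where(np.diff(t) < 0)[0][0]) + 1]
            _fail(j, f"non-monotone TIME within subject {sid}")
        same_t = block.duplicated(subset="TIME", keep=False)
        for tt, sub in block[same_t].groupby("TIME"):
            ev = sub["EVID"].to_numpy()
            if np.any(np.diff(ev) > 0):
                _fail(sub.index[0], f"doses must precede observations at TIME {tt} (subject {sid})")
        for col in ("AGE", "STUDY", "WT"):
            if block[col].nunique() != 1:
                _fail(block.index[0], f"covariate {col} varies within subject {sid}")
    return df.reset_index(drop=True)


def read_dataset(path) -> TrialDataset:
    """Read and validate a trial CSV (comma-separated, '.' decimals)."""
    df = pd.read_csv(path)
    return TrialDataset(df)


def write_dataset(dataset: TrialDataset | pd.DataFrame, path) -> None:
    df = dataset.df if isinstance(dataset, TrialDataset) else dataset
    df.to_csv(path, index=False)
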