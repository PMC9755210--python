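"""Study dataset container and NONMEM-style CSV round-tripping.

The on-disk dialect is a flat CSV with one row per event: columns ``ID``,
``TIME`` (h), ``EVID`` (1 = dose, 0 = observation), ``AMT`` (mg, dose rows),
``DV`` (ng/ml, observation rows), ``DVID`` (1 = ARI, 2 = DARI) plus subject
covariate columns (``WT``, ``AGE``, ``SEX``, ``PHEN``, ``DIPLO``, optional
laboratory and efficacy columns) repeated on every row of the subject.
Missing values are encoded ``"."``.  Floats are written with ``repr`` so the
write/read round trip is lossless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["StudyDataset", "DatasetError", "read_dataset", "write_dataset"]

ANALYTE_BY_DVID = {1: "ARI", 2: "DARI"}

_EVENT_COLS = ["id", "time", "evid", "amt", "dv", "dvid"]


class DatasetError(ValueError):
    """Malformed or inconsistent study dataset."""


@dataclass
class StudyDataset:
    """Dosing events, dual-analyte observations and subject covariates.

    ``subjects``: one row per subject (column ``id`` plus covariates).
    ``events``: long table with columns ``id, time, evid, amt, dv, dvid``.
    """

    subjects: pd.DataFrame
    events: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects["id"].to_numpy()

    def observations(self) -> pd.DataFrame:
        return self.events[self.events["evid"] == 0]

    def doses(self) -> pd.DataFrame:
        return self.events[self.events["evid"] == 1]

    @property
    def n_obs(self) -> int:
        return int((self.events["evid"] == 0).sum())

    def validate(self, raise_on_error: bool = True) -> list[str]:
        """Consistency checks; returns the list of problems found.

        Checks: observation DVIDs are known analyte codes, observed
        concentrations are positive, every observation falls at or after the
        subject's first dose, and every event row belongs to a known subject.
        """
        problems: list[str] = []
        known = set(self.subjects["id"])
        stray = set(self.events["id"]) - known
        if stray:
            problems.append(f"events for unknown subjects {sorted(stray)}")
        obs = self.observations()
        bad_dvid = obs.loc[~obs["dvid"].isin(ANALYTE_BY_DVID), "dvid"].unique()
        for code in bad_dvid:
            problems.append(f"unknown analyte code DVID={code}")
        if (obs["dv"] <= 0).any():
            bad = obs.loc[obs["dv"] <= 0, "id"].unique()
            problems.append(f"non-positive observed concentrations for subjects {list(bad)}")
        first_dose = self.doses().groupby("id")["time"].min()
        for sid, grp in obs.groupby("id"):
            if sid not in first_dose.index:
                problems.append(f"subject {sid} has observations but no doses")
            elif (grp["time"] < first_dose[sid]).any():
                problems.append(f"subject {sid} has observations before the first dose")
        if problems and raise_on_error:
            raise DatasetError("; ".join(problems))
        return problems

    def subset(self, ids: Sequence, renumber: bool = False) -> "StudyDataset":
        """Dataset restricted to ``ids`` (with repetition, e.g. bootstrap
        resamples); ``renumber`` assigns fresh sequential ids so duplicated
        subjects become distinct."""
        sub_rows, ev_rows = [], []
        for new_id, sid in enumerate(ids, start=1):
            srow = self.subjects[self.subjects["id"] == sid].copy()
            erow = self.events[self.events["id"] == sid].copy()
            if renumber:
                srow["id"] = new_id
                erow["id"] = new_id
            sub_rows.append(srow)
            ev_rows.append(erow)
        return StudyDataset(
            subjects=pd.concat(sub_rows, ignore_index=True),
            events=pd.concat(ev_rows, ignore_index=True),
        )

    def to_nonmem(self) -> pd.DataFrame:
        """Flat NONMEM-style frame with covariates merged onto every row."""
        ev = self.events.rename(columns={c: c.upper() for c in _EVENT_COLS})
        return ev.merge(self.subjects.rename(columns={"id": "ID"}), on="ID", how="left")

    @classmethod
    def from_nonmem(cls, df: pd.DataFrame) -> "StudyDataset":
        lower = {c.upper(): c for c in _EVENT_COLS}
        ev_cols = [c for c in df.columns if c in lower]
        events = df[ev_cols].rename(columns=lower)
        cov_cols = [c for c in df.columns if c not in lower]
        subjects = (
            df[["ID"] + cov_cols].drop_duplicates(subset="ID")
            .rename(columns={"ID": "id"}).reset_index(drop=True)
        )
        return cls(subjects=subjects, events=events.reset_index(drop=True))

    def equals(self, other: "StudyDataset") -> bool:
        try:
            pd.testing.assert_frame_equal(
                self.subjects.reset_index(drop=True),
                other.subjects.reset_index(drop=True),
                check_dtype=False,
            )
            pd.testing.assert_frame_equal(
                self.events.reset_index(drop=True),
                other.events.reset_index(drop=True),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True


def _format_value(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x):
        return "."
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return str(x)


def write_dataset(dataset: StudyDataset, path) -> None:
    """Write the NONMEM-style CSV ('.' for missing, lossless float repr)."""
    df = dataset.to_nonmem()
    buf = io.StringIO()
    buf.write(",".join(df.columns) + "\n")
    for row in df.itertuples(index=False):
        buf.write(",".join(_format_value(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _convert_column(s: pd.Series) -> pd.Series:
    s = s.replace(".", np.nan)
    try:
        return pd.to_numeric(s)
    except (ValueError, TypeError):
        return s


def read_dataset(path, validate: bool = True) -> StudyDataset:
    """Read a NONMEM-style CSV; malformed rows raise with line numbers."""
    raw = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    required = {"ID", "TIME", "EVID"}
    missing = required - set(raw.columns)
    if missing:
        raise DatasetError(f"missing required columns {sorted(missing)}")
    bad_lines = []
    for col in ("TIME", "EVID", "AMT", "DV", "DVID"):
        if col not in raw.columns:
            continue
        cleaned = raw[col].replace(".", np.nan)
        converted = pd.to_numeric(cleaned, errors="coerce")
        bad = cleaned.notna() & converted.isna()
        bad_lines.extend((int(i) + 2, col) for i in raw.index[bad])
    if bad_lines:
        desc = ", ".join(f"line {ln} ({col})" for ln, col in bad_lines[:10])
        raise DatasetError(f"malformed numeric fields: {desc}")
    df = raw.apply(_convert_column)
    dataset = StudyDataset.from_nonmem(df)
    dataset.events["evid"] = dataset.events["evid"].astype(int)
    if "dvid" in dataset.events:
        dvid = dataset.events["dvid"].fillna(0)
        dataset.events["dvid"] = dvid.astype(int)
    if validate:
        dataset.validate()
    return dataset
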