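"""NONMEM-dialect longitudinal event datasets (CSV).

Columns: ID (subject), TIME (h from first dose), EVID (0=observation,
1=dose), AMT (µg, dose rows), RATE (µg/h, dose rows), DV (ng/ml,
observation rows), MDV (1 on dose rows), WT (kg), INH (0/1 CYP3A4/5
inhibitor), OCC (1-based occasion index).  Infusion duration is encoded
implicitly as AMT/RATE.
"""

from __future__ import annotations

from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = ["PKEventDataset", "read_dataset", "write_dataset", "COLUMNS"]

COLUMNS = ["ID", "TIME", "EVID", "AMT", "RATE", "DV", "MDV", "WT", "INH", "OCC"]


class DatasetError(ValueError):
    """Raised when an event table violates the dataset contract."""


class PKEventDataset:
    """Validated longitudinal event table.

    Thin wrapper around a :class:`pandas.DataFrame` with the column
    dialect above.  Extra columns are preserved but ignored by the
    analysis modules.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise DatasetError(f"missing required column(s): {missing}")
        self.frame = frame.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.frame
        if (df["TIME"] < 0).any():
            row = int(df.index[df["TIME"] < 0][0])
            raise DatasetError(f"negative TIME at row {row}")
        for sid, g in df.groupby("ID", sort=False):
            t = g["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                row = int(g.index[1:][np.diff(t) < 0][0])
                raise DatasetError(
                    f"TIME not non-decreasing for subject {sid} at row {row}")
            occ = g["OCC"].to_numpy()
            if np.any(np.diff(occ) < 0):
                row = int(g.index[1:][np.diff(occ) < 0][0])
                raise DatasetError(
                    f"OCC not non-decreasing for subject {sid} at row {row}")
        doses = df[df["EVID"] == 1]
        bad = doses[~(doses["RATE"] > 0)]
        if len(bad):
            raise DatasetError(
                f"dose row with non-positive RATE at row {int(bad.index[0])}")
        bad = doses[~(doses["AMT"] > 0)]
        if len(bad):
            raise DatasetError(
                f"dose row with non-positive AMT at row {int(bad.index[0])}")
        bad = doses[doses["DV"].notna()]
        if len(bad):
            raise DatasetError(
                f"DV present on a dose row at row {int(bad.index[0])}")
        obs = df[df["EVID"] == 0]
        bad = obs[~(obs["DV"] >= 0)]
        if len(bad):
            raise DatasetError(
                f"observation row with missing/negative DV at row "
                f"{int(bad.index[0])}")
        if not set(df["EVID"].unique()) <= {0, 1}:
            raise DatasetError("EVID must be 0 or 1")
        if not set(df["INH"].unique()) <= {0, 1}:
            raise DatasetError("INH must be 0 or 1")

    # -- accessors -----------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(pd.unique(self.frame["ID"]))

    @property
    def n_subjects(self) -> int:
        return self.frame["ID"].nunique()

    @property
    def observations(self) -> pd.DataFrame:
        return self.frame[self.frame["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.frame[self.frame["EVID"] == 1]

    @property
    def n_observations(self) -> int:
        return int((self.frame["EVID"] == 0).sum())

    def subset(self, subject_ids: Union[Iterable, int, str]) -> "PKEventDataset":
        """Slice of the dataset for one subject or a list of subjects."""
        if np.isscalar(subject_ids):
            subject_ids = [subject_ids]
        mask = self.frame["ID"].isin(list(subject_ids))
        return PKEventDataset(self.frame[mask].copy(), validate=False)

    def equals(self, other: "PKEventDataset") -> bool:
        return self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return (f"PKEventDataset({self.n_subjects} subjects, "
                f"{self.n_observations} observations, {len(self)} rows)")


def read_dataset(path) -> PKEventDataset:
    """Read and validate a dataset CSV."""
    frame = pd.read_csv(path)
    return PKEventDataset(frame)


def write_dataset(dataset: PKEventDataset, path) -> None:
    """Write a dataset CSV (lossless round-trip with :func:`read_dataset`)."""
    dataset.frame.to_csv(path, index=False)
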