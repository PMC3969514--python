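"""Longitudinal datasets in the NONMEM CSV convention.

Columns: ID, TIME, AMT, RATE, DV, EVID, MDV, OCC, then any covariates.
EVID = 1 marks dose rows, MDV = 1 marks rows whose DV is ignored, and the
missing-value token is ".". The canonical in-memory container is a pandas
DataFrame wrapped by :class:`Dataset`, which also exposes per-subject
arrays ready for estimation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConfigurationError, ObservationRecord

__all__ = ["Dataset", "SubjectData", "read_nonmem_csv", "write_nonmem_csv"]

STANDARD_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "OCC"]


@dataclass
class SubjectData:
    """Static per-subject arrays used by the estimation engine."""

    subject_id: object
    times: np.ndarray  # observation times (n,)
    y: np.ndarray  # observed DV (n,)
    occasions: np.ndarray  # occasion index per observation (n,)
    dose_times: np.ndarray
    dose_amounts: np.ndarray
    dose_rates: np.ndarray
    covariates: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.times.size


class Dataset:
    """Dosing/observation records for a population, sorted by (ID, TIME)."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in STANDARD_COLUMNS:
            if col not in df.columns:
                if col == "OCC":
                    df["OCC"] = 1
                elif col == "RATE":
                    df["RATE"] = 0.0
                elif col == "MDV":
                    df["MDV"] = (df["EVID"] != 0).astype(int)
                else:
                    raise ConfigurationError(f"dataset is missing column {col}")
        df = df.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
        obs = (df["EVID"] == 0) & (df["MDV"] == 0)
        if obs.sum() == 0:
            raise ConfigurationError("dataset contains no observations")
        if (df["TIME"] < 0).any():
            raise ConfigurationError("negative TIME values")
        self.df = df
        self._obs_mask = obs.to_numpy()

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int(self._obs_mask.sum())

    @property
    def subject_ids(self):
        return list(dict.fromkeys(self.df["ID"].tolist()))

    @property
    def covariate_names(self):
        return [c for c in self.df.columns if c not in STANDARD_COLUMNS]

    def subjects(self):
        """List of :class:`SubjectData`, one per subject in ID order."""
        out = []
        for sid, g in self.df.groupby("ID", sort=False):
            dose = g["EVID"] == 1
            obs = (g["EVID"] == 0) & (g["MDV"] == 0)
            if dose.sum() == 0:
                raise ConfigurationError(f"subject {sid} has no dose records")
            cov = {c: float(g[c].iloc[0]) for c in self.covariate_names}
            out.append(
                SubjectData(
                    subject_id=sid,
                    times=g.loc[obs, "TIME"].to_numpy(dtype=float),
                    y=g.loc[obs, "DV"].to_numpy(dtype=float),
                    occasions=g.loc[obs, "OCC"].to_numpy(dtype=int),
                    dose_times=g.loc[dose, "TIME"].to_numpy(dtype=float),
                    dose_amounts=g.loc[dose, "AMT"].to_numpy(dtype=float),
                    dose_rates=g.loc[dose, "RATE"].fillna(0.0).to_numpy(dtype=float),
                    covariates=cov,
                )
            )
        return out

    def records(self):
        """Rows as :class:`ObservationRecord` objects (doses and observations)."""
        out = []
        for _, r in self.df.iterrows():
            if r["EVID"] == 1:
                out.append(
                    ObservationRecord(
                        subject_id=r["ID"],
                        time=float(r["TIME"]),
                        occasion=int(r["OCC"]),
                        is_dose=True,
                        amount=float(r["AMT"]),
                        rate=float(r["RATE"]) if pd.notna(r["RATE"]) else 0.0,
                    )
                )
            elif r["MDV"] == 0:
                out.append(
                    ObservationRecord(
                        subject_id=r["ID"],
                        time=float(r["TIME"]),
                        occasion=int(r["OCC"]),
                        dv=float(r["DV"]),
                    )
                )
        return out

    def fingerprint(self) -> str:
        """Stable content hash used to guard cross-fit comparisons."""
        h = hashlib.sha256()
        obs = self.df[["ID", "TIME", "DV", "EVID"]].to_csv(index=False)
        h.update(obs.encode())
        return h.hexdigest()[:16]

    def log_transformed(self) -> "Dataset":
        """Copy with DV replaced by log(DV) on observation rows."""
        df = self.df.copy()
        obs = ((df["EVID"] == 0) & df["DV"].notna()).to_numpy()
        dv = df.loc[obs, "DV"].astype(float)
        if (dv <= 0).any():
            raise ConfigurationError("cannot log-transform non-positive DV values")
        df.loc[obs, "DV"] = np.log(dv)
        return Dataset(df)


def read_nonmem_csv(path) -> Dataset:
    df = pd.read_csv(path, na_values=["."])
    missing = [c for c in ("ID", "TIME", "EVID") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"dataset is missing column(s) {missing}")
    return Dataset(df)


def write_nonmem_csv(dataset: Dataset, path) -> None:
    df = dataset.df.copy()
    cols = STANDARD_COLUMNS + dataset.covariate_names
    df = df[cols]
    df.to_csv(path, index=False, na_rep=".", float_format="%.10g")
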