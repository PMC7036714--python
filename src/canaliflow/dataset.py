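"""Long-format measurement tables consumed by the parameter fitter."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MeasurementDataSet", "OBSERVABLES"]

OBSERVABLES = ("nuclear", "total")
COLUMNS = ("time_days", "zone", "observable", "value", "sd", "n")


@dataclass
class MeasurementDataSet:
    """Rows of (time, zone, observable, value, sd, n).

    Values are normalized fold-changes (untreated mean = 1); ``sd`` may be
    NaN when replicate scatter is unknown, in which case the fitter falls
    back to relative weighting.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("empty dataset")
        if not df["observable"].isin(OBSERVABLES).all():
            bad = sorted(set(df["observable"]) - set(OBSERVABLES))
            raise ValueError(f"unknown observables: {bad}")
        if (df["value"] <= 0).any():
            raise ValueError("values must be positive fold-changes")
        for obs in df["observable"].unique():
            pass  # at least one row per present observable by construction
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def observables(self) -> tuple:
        return tuple(sorted(self.table["observable"].unique()))

    def renormalized(self, baseline_time: float = 0.0) -> "MeasurementDataSet":
        """Rescale each observable so its baseline-time mean equals 1.

        Values and standard deviations divide by the same factor, so the
        result is invariant to a common rescaling of the raw data.
        """
        df = self.table.copy()
        for obs, grp in df.groupby("observable"):
            at0 = grp[grp["time_days"] == baseline_time]["value"]
            if len(at0) == 0:
                continue
            scale = at0.mean()
            sel = df["observable"] == obs
            df.loc[sel, "value"] /= scale
            df.loc[sel, "sd"] /= scale
        return MeasurementDataSet(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementDataSet":
        return cls(pd.read_csv(path))

    @classmethod
    def from_arrays(cls, time_days, zone, observable, value,
                    sd=None, n=None) -> "MeasurementDataSet":
        m = len(value)
        return cls(pd.DataFrame({
            "time_days": np.asarray(time_days, float),
            "zone": np.asarray(zone, int),
            "observable": observable,
            "value": np.asarray(value, float),
            "sd": np.full(m, np.nan) if sd is None else np.asarray(sd, float),
            "n": np.ones(m, int) if n is None else np.asarray(n, int),
        }))
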