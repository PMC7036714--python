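"""Zonal profiles along the central-vein -> portal-vein axis.

A :class:`ZonalProfile` holds one summary statistic per lobule zone
(zone 1 = peri-central, zone ``n_zones`` = peri-portal) together with
its standard error, the per-zone sample size and exclusion flags for
boundary zones.  Diameter profiles use 18 zones, intensity profiles 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ZonalProfile", "normalize_profiles", "percent_change"]


@dataclass
class ZonalProfile:
    """Per-zone statistic along the CV-PV axis.

    Parameters
    ----------
    value :
        Per-zone statistic (micrometres for diameters, arbitrary units
        for intensities).  Missing zones are NaN.
    sem :
        Per-zone standard error of the mean; zeros are allowed.
    n :
        Number of samples contributing to each zone.
    excluded :
        Flags for zones dropped from analysis (e.g. the ~1 cell layer
        adjacent to CV and PV in diameter profiles).
    """

    value: np.ndarray
    sem: np.ndarray | None = None
    n: np.ndarray | None = None
    excluded: np.ndarray | None = None
    label: str = ""
    zone_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        nz = self.value.size
        if nz < 1:
            raise ValueError("profile needs at least one zone")
        self.sem = (np.zeros(nz) if self.sem is None
                    else np.asarray(self.sem, dtype=float))
        self.n = (np.ones(nz, dtype=int) if self.n is None
                  else np.asarray(self.n, dtype=int))
        self.excluded = (np.zeros(nz, dtype=bool) if self.excluded is None
                         else np.asarray(self.excluded, dtype=bool))
        if not (self.sem.size == self.n.size == self.excluded.size == nz):
            raise ValueError("per-zone arrays must have equal length")
        if np.any(self.sem[np.isfinite(self.sem)] < 0):
            raise ValueError("sem must be non-negative")
        keep = ~self.excluded & np.isfinite(self.value)
        # excluded or empty zones may be NaN; included zones may be NaN only
        # when flagged missing by the caller, which is legal.
        self.zone_index = np.arange(1, nz + 1)

    @property
    def n_zones(self) -> int:
        return self.value.size

    @property
    def included(self) -> np.ndarray:
        """Boolean mask of zones that enter summary statistics."""
        return ~self.excluded & np.isfinite(self.value)

    def mean(self) -> float:
        """Mean over included zones."""
        if not self.included.any():
            return float("nan")
        return float(self.value[self.included].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zone": self.zone_index, "value": self.value, "sem": self.sem,
             "n": self.n, "excluded": self.excluded.astype(int)}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "ZonalProfile":
        df = pd.read_csv(path)
        return cls(value=df["value"].to_numpy(),
                   sem=df["sem"].to_numpy() if "sem" in df else None,
                   n=df["n"].to_numpy() if "n" in df else None,
                   excluded=df["excluded"].to_numpy().astype(bool)
                   if "excluded" in df else None,
                   label=label)


def normalize_profiles(profile: ZonalProfile,
                       reference: ZonalProfile) -> ZonalProfile:
    """Element-wise fold-change ``profile / reference``.

    Standard errors are propagated in quadrature on the relative scale:
    ``sem_ratio = ratio * sqrt((sem_a/a)^2 + (sem_b/b)^2)``.  Zones whose
    reference value is zero (or missing) become NaN rather than inf.
    """
    if profile.n_zones != reference.n_zones:
        raise ValueError("zone counts differ: "
                         f"{profile.n_zones} vs {reference.n_zones}")
    a, b = profile.value, reference.value
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b != 0, a / b, np.nan)
        rel = np.sqrt(np.where(a != 0, (profile.sem / a) ** 2, 0.0)
                      + np.where(b != 0, (reference.sem / b) ** 2, 0.0))
        sem = np.abs(ratio) * rel
    return ZonalProfile(value=ratio, sem=sem,
                        n=np.minimum(profile.n, reference.n),
                        excluded=profile.excluded | reference.excluded,
                        label=f"{profile.label}/{reference.label}")


def percent_change(a: ZonalProfile, b: ZonalProfile):
    """Per-zone and mean percent change ``100 * (a/b - 1)``.

    Returns ``(per_zone, mean)`` where the mean is taken over zones that
    are included in both profiles.  The mean percent change equals the
    mean of the per-zone changes by definition.
    """
    ratio = normalize_profiles(a, b)
    per_zone = 100.0 * (ratio.value - 1.0)
    keep = ratio.included
    mean = float(per_zone[keep].mean()) if keep.any() else float("nan")
    return per_zone, mean
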