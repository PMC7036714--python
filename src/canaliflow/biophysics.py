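"""Canalicular pressure, apical cortical tension and strain along the lobule.

The bile-canalicular network of one lobule is collapsed to a serial chain
of ``n_zones`` zones from the central vein (CV, zone 1) to the portal vein
(PV, zone ``n``), each zone being a bundle of ``channels_per_zone``
parallel tubes of measured diameter.  Bile salts and other osmolytes are
actively secreted into every zone; isotonic water follow-up converts the
solute flux into a volumetric inflow

    q_z = osmolyte_secretion_z / canalicular_osmolarity        [m^3/s]

The accumulated flow drains toward the PV outlet, and the pressure
profile follows from Hagen-Poiseuille resistance per unit length,
``r_z = 128 mu / (pi d_z^4 N_z)``, integrated backward from the outlet
pressure.  Within a zone the inflow is distributed uniformly, so the flow
is piecewise linear and the trapezoidal integration below is exact.

Apical cortical tension follows the law of Laplace for a cylindrical
membrane, ``T_z = P_z d_z / 2`` (gauge pressure relative to the tissue,
whose pressure defines zero), and membrane strain is the relative
diameter change ``eps_z = d_z / d_z0 - 1`` against a baseline geometry.

After a partial hepatectomy the total bile-salt pool is conserved
(intra-hepatic bile acids are a few percent of it), so the remnant must
transport the full pool: secretion per remnant mass scales as
``1 / mass_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CanalicularNetworkModel",
    "PressureProfile",
    "TensionProfile",
    "scale_secretion_for_resection",
    "solve_pressure",
    "compute_tension_strain",
    "tension_fold_change",
    "stimulus_from_mechanics",
    "calibrate_outlet_pressure",
    "regeneration_tension_fold",
    "UNTREATED_DIAMETER_RANGE_UM",
    "POST_PH_1P5D_DIAMETER_RANGE_UM",
]

# Zonal BC diameter ranges (micrometres, CV -> PV, 18 zones): untreated
# liver and 1.5 days after partial hepatectomy.
UNTREATED_DIAMETER_RANGE_UM = (1.96, 2.27)
POST_PH_1P5D_DIAMETER_RANGE_UM = (2.40, 2.61)


@dataclass
class CanalicularNetworkModel:
    """Zonated serial-tube model of the canalicular network.

    diameter_um is ordered CV -> PV.  osmolyte_secretion is the per-zone
    solute flux in mol/s for the *whole-body* baseline; after resection it
    is scaled per remnant mass (see :func:`scale_secretion_for_resection`).
    """

    diameter_um: np.ndarray
    zone_length_um: float = 15.0
    channels_per_zone: float = 1.0
    viscosity: float = 1.5e-3                 # Pa s, bile
    outlet_pressure: float = 20.0             # Pa at the PV / duct end
    osmolyte_secretion: np.ndarray | None = None   # mol/s per zone
    canalicular_osmolarity: float = 300.0     # mol/m^3 (isotonic)
    liver_mass_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.diameter_um = np.asarray(self.diameter_um, dtype=float)
        if self.osmolyte_secretion is None:
            self.osmolyte_secretion = np.full(self.n_zones, 1.9e-14)
        self.osmolyte_secretion = np.asarray(self.osmolyte_secretion, float)
        if np.any(self.diameter_um <= 0):
            raise ValueError("diameters must be positive")
        if self.zone_length_um <= 0 or self.viscosity <= 0:
            raise ValueError("zone length and viscosity must be positive")
        if not 0 < self.liver_mass_fraction <= 1:
            raise ValueError("liver_mass_fraction must be in (0, 1]")
        if self.channels_per_zone < 1:
            raise ValueError("need at least one channel per zone")
        if self.osmolyte_secretion.size != self.n_zones:
            raise ValueError("secretion array length must equal n_zones")
        if np.any(self.osmolyte_secretion < 0):
            raise ValueError("secretion must be non-negative")

    @property
    def n_zones(self) -> int:
        return self.diameter_um.size

    @property
    def water_inflow(self) -> np.ndarray:
        """Per-zone isotonic water inflow, m^3/s (per remnant mass unit)."""
        return (self.osmolyte_secretion / self.liver_mass_fraction
                / self.canalicular_osmolarity)

    @classmethod
    def baseline(cls, n_zones: int = 18, *,
                 target_pressure_ratio: float = 30.0,
                 **kwargs) -> "CanalicularNetworkModel":
        """Untreated reference network.

        Diameters interpolate the untreated zonal range linearly across
        zones, and the outlet pressure is calibrated so that the CV-zone
        pressure exceeds the PV outlet pressure ``target_pressure_ratio``-fold.
        """
        lo, hi = UNTREATED_DIAMETER_RANGE_UM
        net = cls(diameter_um=np.linspace(lo, hi, n_zones), **kwargs)
        net.outlet_pressure = calibrate_outlet_pressure(
            net, target_ratio=target_pressure_ratio)
        return net

    def with_diameters(self, diameter_um) -> "CanalicularNetworkModel":
        return replace(self, diameter_um=np.asarray(diameter_um, float))


@dataclass
class PressureProfile:
    """Zone-centre pressures (Pa), ordered CV -> PV."""

    pressure: np.ndarray
    outlet_pressure: float
    outlet_flow: float          # m^3/s leaving at the PV end
    total_inflow: float         # sum of zonal water inflows

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("non-finite pressure")
        if np.any(np.diff(self.pressure) > 1e-9 * self.pressure[0]):
            raise ValueError("pressure must be non-increasing CV -> PV")

    @property
    def cv_pv_ratio(self) -> float:
        """CV-zone pressure relative to the PV outlet pressure."""
        return float(self.pressure[0] / self.outlet_pressure)


@dataclass
class TensionProfile:
    """Apical cortical tension (N/m), strain and relative stimulus per zone."""

    tension: np.ndarray
    strain: np.ndarray
    stimulus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tension = np.asarray(self.tension, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if np.any(self.tension < 0):
            raise ValueError("tension must be non-negative")
        if np.any(self.strain < -1):
            raise ValueError("strain cannot be below -1")


def scale_secretion_for_resection(baseline_flux, mass_fraction: float):
    """Solute flux per remnant liver mass under a conserved bile-salt pool.

    Removing ``1 - mass_fraction`` of the liver leaves the body's bile-salt
    pool essentially intact, so the remnant transports ``1/mass_fraction``
    times the baseline flux per unit mass.
    """
    if mass_fraction <= 0 or mass_fraction > 1:
        raise ValueError("mass_fraction must be in (0, 1]")
    return np.asarray(baseline_flux, dtype=float) / mass_fraction


def solve_pressure(network: CanalicularNetworkModel) -> PressureProfile:
    """Distributed-inflow Hagen-Poiseuille pressure profile.

    The flow is piecewise linear in the axial coordinate (uniform inflow
    within each zone), so trapezoidal integration of ``dP = r Q dx`` over
    half-zones is exact; pressures are reported at zone centres, integrated
    backward from the PV outlet.
    """
    d = network.diameter_um * 1e-6
    if np.any(d <= 0):
        raise ValueError("zero diameter gives infinite resistance")
    n = network.n_zones
    L = network.zone_length_um * 1e-6
    r = 128.0 * network.viscosity / (np.pi * d ** 4 * network.channels_per_zone)
    q = network.water_inflow
    q_boundary = np.concatenate([[0.0], np.cumsum(q)])  # flow at zone edges
    p_boundary = np.empty(n + 1)
    p_boundary[n] = network.outlet_pressure
    for z in range(n - 1, -1, -1):
        p_boundary[z] = (p_boundary[z + 1]
                         + r[z] * L * 0.5 * (q_boundary[z] + q_boundary[z + 1]))
    q_centre = q_boundary[:-1] + 0.5 * q
    p_centre = (p_boundary[1:]
                + r * (L / 2.0) * 0.5 * (q_centre + q_boundary[1:]))
    return PressureProfile(pressure=p_centre,
                           outlet_pressure=network.outlet_pressure,
                           outlet_flow=float(q_boundary[-1]),
                           total_inflow=float(q.sum()))


def calibrate_outlet_pressure(network: CanalicularNetworkModel,
                              target_ratio: float = 30.0) -> float:
    """Outlet pressure making CV-zone pressure = target_ratio x outlet.

    The gauge (outlet-relative) profile is independent of the outlet
    pressure, so the calibration is a one-line rearrangement.
    """
    if target_ratio <= 1:
        raise ValueError("target_ratio must exceed 1")
    probe = replace(network, outlet_pressure=0.0)
    gauge_cv = solve_pressure(probe).pressure[0]
    return float(gauge_cv / (target_ratio - 1.0))


def compute_tension_strain(pressure: PressureProfile,
                           diameter_um,
                           baseline_diameter_um) -> TensionProfile:
    """Laplace tension ``T = P d / 2`` and strain ``d/d0 - 1`` per zone."""
    d = np.asarray(diameter_um, dtype=float) * 1e-6
    d0 = np.asarray(baseline_diameter_um, dtype=float) * 1e-6
    if d.size != pressure.pressure.size or d0.size != d.size:
        raise ValueError("zone counts do not match")
    if np.any(d0 <= 0):
        raise ValueError("baseline diameter must be positive")
    tension = pressure.pressure * d / 2.0
    strain = d / d0 - 1.0
    return TensionProfile(tension=tension, strain=strain)


def tension_fold_change(condition: TensionProfile,
                        baseline: TensionProfile):
    """Per-zone tension ratio and its CV-PV mean.

    Zones with zero baseline tension yield NaN and are dropped from the
    mean.
    """
    if condition.tension.size != baseline.tension.size:
        raise ValueError("zone counts do not match")
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(baseline.tension > 0,
                        condition.tension / baseline.tension, np.nan)
    mean = float(np.nanmean(fold)) if np.isfinite(fold).any() else float("nan")
    return fold, mean


def stimulus_from_mechanics(tension_fold, strain, rule: str = "tension"):
    """Relative mechanical stimulus per zone.

    rule = "tension": stimulus is the tension fold-change itself (the
    fold is already evaluated on the strained geometry since the measured
    diameters enter the Laplace law).  rule = "tension_strain": the fold
    is additionally weighted by ``1 + strain``.  Both give stimulus 1 at
    baseline by construction.
    """
    fold = np.asarray(tension_fold, dtype=float)
    eps = np.asarray(strain, dtype=float)
    if np.any(fold[np.isfinite(fold)] < 0):
        raise ValueError("negative tension fold")
    if rule == "tension":
        return fold
    if rule == "tension_strain":
        return fold * (1.0 + eps)
    raise ValueError(f"unknown stimulus rule: {rule!r}")


def regeneration_tension_fold(
        resection_fraction: float = 0.68,
        diameters_post_um=None,
        baseline: CanalicularNetworkModel | None = None,
        rule: str = "tension"):
    """Predicted zonal tension fold-change for the regenerating liver.

    Builds the untreated network (measured zonal diameters, calibrated
    outlet), scales secretion for the remnant under pool conservation,
    re-solves the pressure with the dilated post-resection diameters and
    applies the Laplace law in both conditions.

    Returns ``(fold_per_zone, mean_fold, TensionProfile_condition)``.
    """
    if not 0 <= resection_fraction < 1:
        raise ValueError("resection_fraction must be in [0, 1)")
    if baseline is None:
        baseline = CanalicularNetworkModel.baseline()
    if diameters_post_um is None:
        lo, hi = POST_PH_1P5D_DIAMETER_RANGE_UM
        diameters_post_um = np.linspace(lo, hi, baseline.n_zones)
    mass_fraction = 1.0 - resection_fraction
    p0 = solve_pressure(baseline)
    t0 = compute_tension_strain(p0, baseline.diameter_um,
                                baseline.diameter_um)
    post = replace(baseline, diameter_um=np.asarray(diameters_post_um, float),
                   liver_mass_fraction=mass_fraction)
    p1 = solve_pressure(post)
    t1 = compute_tension_strain(p1, post.diameter_um, baseline.diameter_um)
    fold, mean = tension_fold_change(t1, t0)
    t1.stimulus = stimulus_from_mechanics(fold, t1.strain, rule=rule)
    return fold, mean, t1
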