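"""Synthetic lobule phantoms and forward-simulated measurement tables.

Every downstream stage of the pipeline is testable against these
generators: a 3D multi-channel voxel phantom (bile-canaliculi marker,
nuclei, apical marker) with known zonated tube diameters and nuclear
intensities, a mechanical stimulus trajectory driven by the biophysical
model, and noisy nuclear/total-YAP time-course tables generated from the
quasi-steady state of the YAP model.  Ground truth is recorded before
blur and noise are applied.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import biophysics as bp
from . import hippo
from .dataset import MeasurementDataSet

__all__ = [
    "LobulePhantomSpec", "TimeCourseSpec", "GroundTruth",
    "generate_lobule_stack", "generate_stimulus_trajectory",
    "generate_yap_dataset", "write_fixtures", "verify_fixtures",
    "liver_mass_recovery",
]

# Confocal acquisition geometry: (z, y, x) micrometres per voxel.
DEFAULT_VOXEL_SIZE = (0.3, 0.28, 0.28)


@dataclass
class LobulePhantomSpec:
    """Recipe for one 3D lobule phantom.

    The canalicular network is rendered as a piecewise-linear random-walk
    centerline between the CV and PV landmarks (plus side branches), with
    the local tube diameter taken from the zone the centerline passes
    through.  Nuclei are non-overlapping ellipsoids with zone-assigned
    intensities; the apical channel is a thin shell around the tubes.
    """

    stack_shape: tuple = (48, 64, 520)          # (z, y, x) voxels
    voxel_size: tuple = DEFAULT_VOXEL_SIZE      # micrometres per axis
    cv_landmark: tuple | None = None            # voxel coords (z, y, x)
    pv_landmark: tuple | None = None
    n_zones: int = 18
    zonal_diameter: np.ndarray | None = None    # um per zone, CV -> PV
    network_branching: float = 1.0              # branch points / 100 um
    n_nuclei: int = 120
    zonal_nuclear_intensity: np.ndarray | None = None  # 10 zones, a.u.
    apical_marker_level: float = 150.0
    foreground_level: float = 200.0
    background: float = 10.0
    psf_sigma: float = 0.2                      # um, Gaussian blur
    shot_noise: float = 0.0                     # sd = shot * sqrt(signal)
    read_noise: float = 0.0                     # additive Gaussian sd
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.stack_shape)
        if len(shape) != 3 or min(shape) < 8:
            raise ValueError("stack_shape must be 3D with at least 8 voxels "
                             "per axis")
        self.stack_shape = shape
        if self.cv_landmark is None:
            self.cv_landmark = (shape[0] // 2, shape[1] // 2, 2)
        if self.pv_landmark is None:
            self.pv_landmark = (shape[0] // 2, shape[1] // 2, shape[2] - 3)
        self.cv_landmark = tuple(float(v) for v in self.cv_landmark)
        self.pv_landmark = tuple(float(v) for v in self.pv_landmark)
        if self.cv_landmark == self.pv_landmark:
            raise ValueError("cv_landmark and pv_landmark must differ")
        if self.zonal_diameter is None:
            lo, hi = bp.UNTREATED_DIAMETER_RANGE_UM
            self.zonal_diameter = np.linspace(lo, hi, self.n_zones)
        self.zonal_diameter = np.asarray(self.zonal_diameter, float)
        if self.zonal_diameter.size != self.n_zones:
            raise ValueError("zonal_diameter length must equal n_zones")
        if np.any(self.zonal_diameter <= 0):
            raise ValueError("diameters must be positive")
        if self.zonal_nuclear_intensity is None:
            self.zonal_nuclear_intensity = np.full(10, 100.0)
        self.zonal_nuclear_intensity = np.asarray(
            self.zonal_nuclear_intensity, float)
        if self.shot_noise < 0 or self.read_noise < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class TimeCourseSpec:
    """Design of a forward-simulated YAP measurement table.

    The default design (6 time points x 10 zones x 2 observables x 1
    replicate) yields 120 measurements; the composition is configurable,
    the count is truncated to ``n_points_target``.
    """

    time_points: tuple = (0.0, 0.8, 1.5, 2.0, 3.0, 5.0)   # days post-PH
    zones: int = 10
    replicates: int = 1
    true_params: hippo.HippoParams = field(
        default_factory=hippo.HippoParams.reference)
    stimulus_trajectory: pd.DataFrame | None = None   # time_days, zone, stimulus
    resection_fraction: float = 0.68
    regrowth_halftime: float = 2.5
    noise_cv: float = 0.1
    n_points_target: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points, float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("time points must be non-negative and strictly "
                             "increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        design = len(t) * self.zones * 2 * self.replicates
        if design < self.n_points_target:
            raise ValueError(f"design yields {design} points, fewer than "
                             f"target {self.n_points_target}")


@dataclass
class GroundTruth:
    """Pre-noise truth of a phantom or forward simulation.

    Voxel-level masks are kept as arrays in memory; serialization via
    :meth:`to_dict` covers the numeric truth, while masks round-trip
    through the TIFF files written by :func:`write_fixtures`.
    """

    zonal_diameter: np.ndarray | None = None
    zonal_nuclear_intensity: np.ndarray | None = None
    nucleus_zone: np.ndarray | None = None
    nucleus_intensity: np.ndarray | None = None
    apical_marker_level: float | None = None
    bc_mask: np.ndarray | None = None
    nuclei_labels: np.ndarray | None = None
    centerline: np.ndarray | None = None       # (k, 3) voxel indices
    true_params: dict | None = None
    stimulus_trajectory: pd.DataFrame | None = None

    _ARRAY_FIELDS = ("zonal_diameter", "zonal_nuclear_intensity",
                     "nucleus_zone", "nucleus_intensity", "centerline")

    def to_dict(self) -> dict:
        out = {}
        for name in self._ARRAY_FIELDS:
            v = getattr(self, name)
            out[name] = None if v is None else np.asarray(v).tolist()
        out["apical_marker_level"] = self.apical_marker_level
        out["true_params"] = self.true_params
        if self.stimulus_trajectory is not None:
            out["stimulus_trajectory"] = self.stimulus_trajectory.to_dict(
                orient="list")
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        kw = {}
        for name in cls._ARRAY_FIELDS:
            v = d.get(name)
            kw[name] = None if v is None else np.asarray(v)
        kw["apical_marker_level"] = d.get("apical_marker_level")
        kw["true_params"] = d.get("true_params")
        st = d.get("stimulus_trajectory")
        if st is not None:
            kw["stimulus_trajectory"] = pd.DataFrame(st)
        return cls(**kw)


# ---------------------------------------------------------------------
# phantom rendering
# ---------------------------------------------------------------------

def _axis_fraction(coords_vox, cv, pv, voxel_size):
    """Relative position along the CV -> PV axis, clipped to [0, 1]."""
    vs = np.asarray(voxel_size, float)
    x = (np.asarray(coords_vox, float) - np.asarray(cv, float)) * vs
    axis = (np.asarray(pv, float) - np.asarray(cv, float)) * vs
    return np.clip(x @ axis / (axis @ axis), 0.0, 1.0)


def _zone_of_fraction(p, n_zones):
    return np.clip(np.ceil(np.asarray(p) * n_zones).astype(int), 1, n_zones)


def _render_centerline(spec: LobulePhantomSpec, rng):
    """Tube centerline as (voxel indices (k, 3), dense points in um)."""
    shape = np.array(spec.stack_shape)
    vs = np.asarray(spec.voxel_size)
    cv = np.asarray(spec.cv_landmark, float)
    pv = np.asarray(spec.pv_landmark, float)
    axis_um = (pv - cv) * vs
    length_um = float(np.linalg.norm(axis_um))
    max_r_vox = (spec.zonal_diameter.max() / 2) / vs.min()
    if length_um < 5.0:
        raise ValueError(
            f"stack too small: CV-PV axis is {length_um:.1f} um, need >= 5 um "
            "to contain one tube path")
    if np.any(shape - 2 * max_r_vox < 4):
        raise ValueError(
            "stack too small: lateral extent cannot contain the tube "
            f"diameter {spec.zonal_diameter.max():.2f} um plus margin")
    e1 = axis_um / length_um
    # perpendicular basis for lateral jitter
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ tmp) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, tmp); e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)

    step = 0.5 * vs.min()
    n_step = int(length_um / step) + 1
    s = np.linspace(0.0, length_um, n_step)
    jitter2 = np.cumsum(rng.normal(0.0, 0.18, n_step))
    jitter3 = np.cumsum(rng.normal(0.0, 0.18, n_step))
    # pin the walk to the landmarks at both ends (Brownian bridge)
    jitter2 -= np.linspace(jitter2[0], jitter2[-1], n_step)
    jitter3 -= np.linspace(jitter3[0], jitter3[-1], n_step)
    pts_um = (cv * vs)[None, :] + s[:, None] * e1[None, :] \
        + jitter2[:, None] * e2[None, :] + jitter3[:, None] * e3[None, :]

    # side branches
    n_branch = int(round(spec.network_branching * length_um / 100.0))
    branch_pts = []
    for _ in range(n_branch):
        start = pts_um[rng.integers(0, n_step)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        blen = rng.uniform(4.0, 10.0)
        bs = np.arange(0.0, blen, step)
        branch_pts.append(start[None, :] + bs[:, None] * direction[None, :])
    if branch_pts:
        pts_um = np.vstack([pts_um] + branch_pts)

    idx = np.round(pts_um / vs[None, :]).astype(int)
    margin = np.maximum(np.ceil(max_r_vox * vs.min() / vs).astype(int) + 1, 1)
    idx = np.clip(idx, margin, shape - 1 - margin)
    pts_um = np.clip(pts_um, margin * vs, (shape - 1 - margin) * vs)
    return np.unique(idx, axis=0), pts_um


def _apply_optics(img, spec: LobulePhantomSpec, rng):
    """PSF blur followed by signal-dependent and additive read noise."""
    vs = np.asarray(spec.voxel_size)
    if spec.psf_sigma > 0:
        img = ndi.gaussian_filter(img, sigma=spec.psf_sigma / vs)
    if spec.shot_noise > 0:
        img = img + rng.normal(0.0, 1.0, img.shape) \
            * spec.shot_noise * np.sqrt(np.maximum(img, 0.0))
    if spec.read_noise > 0:
        img = img + rng.normal(0.0, spec.read_noise, img.shape)
    return np.maximum(img, 0.0)


def generate_lobule_stack(spec: LobulePhantomSpec):
    """Render (bc_stack, nuclei_stack, marker_stack, GroundTruth).

    All three channels share the stack shape; blur and noise are the last
    steps, and the returned :class:`GroundTruth` records pre-noise masks
    and the true zonal values.
    """
    rng = np.random.default_rng(spec.seed)
    vs = np.asarray(spec.voxel_size)
    shape = spec.stack_shape

    centerline, points_um = _render_centerline(spec, rng)
    cl_mask = np.zeros(shape, dtype=bool)
    cl_mask[tuple(centerline.T)] = True
    # coarse pass: voxelized centerline bounds the search region, then
    # exact sub-voxel distances to the dense polyline define the tube so
    # the rendered radius is free of centerline quantization
    coarse, indices = ndi.distance_transform_edt(
        ~cl_mask, sampling=vs, return_indices=True)
    max_r = spec.zonal_diameter.max() / 2.0
    near = coarse <= max_r + 2.0 * vs.max()
    near_idx = np.argwhere(near)
    from scipy.spatial import cKDTree
    tree = cKDTree(points_um)
    dist_exact, nn = tree.query(near_idx * vs, workers=1)
    dist = np.full(shape, np.inf)
    dist[tuple(near_idx.T)] = dist_exact
    nearest = np.stack([indices[a] for a in range(3)], axis=-1)
    p_near = _axis_fraction(nearest.reshape(-1, 3), spec.cv_landmark,
                            spec.pv_landmark, vs).reshape(shape)
    zone_near = _zone_of_fraction(p_near, spec.n_zones)
    radius = spec.zonal_diameter[zone_near - 1] / 2.0
    bc_mask = dist <= radius

    bc = spec.background + spec.foreground_level * bc_mask.astype(float)

    # nuclei: non-overlapping ellipsoids away from the tube
    labels = np.zeros(shape, dtype=np.int32)
    semi_um = np.array([2.2, 2.8, 2.8])
    centers, zones10, intensities = [], [], []
    margin = np.ceil(semi_um / vs).astype(int) + 1
    tries = 0
    # the coarse EDT is defined everywhere; keep nucleus centres clear of
    # the widest possible tube plus the largest nuclear semi-axis
    clearance = max_r + semi_um.max() + 0.5
    while len(centers) < spec.n_nuclei and tries < 50 * spec.n_nuclei:
        tries += 1
        c = np.array([rng.integers(m, s - m) for m, s in zip(margin, shape)])
        if coarse[tuple(c)] <= clearance:
            continue
        if centers and np.min(np.linalg.norm(
                (np.array(centers) - c) * vs, axis=1)) < 2.2 * semi_um.max():
            continue
        centers.append(c)
    nuc = np.full(shape, spec.background, dtype=float)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    for k, c in enumerate(centers, start=1):
        p = _axis_fraction(c[None, :], spec.cv_landmark, spec.pv_landmark,
                           vs)[0]
        z10 = int(_zone_of_fraction(p, 10))
        inten = float(spec.zonal_nuclear_intensity[z10 - 1])
        lo = np.maximum(c - margin, 0)
        hi = np.minimum(c + margin + 1, shape)
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        rel = [(g[sl] - c[a]) * vs[a] / semi_um[a] for a, g in
               enumerate((zz, yy, xx))]
        inside = rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2 <= 1.0
        labels[sl][inside] = k
        nuc[sl][inside] = spec.background + inten
        zones10.append(z10)
        intensities.append(inten)

    # apical marker: thin shell around the tube surface
    shell_um = 0.56
    outside = ndi.distance_transform_edt(~bc_mask, sampling=vs)
    shell = (~bc_mask) & (outside <= shell_um)
    marker = spec.background + spec.apical_marker_level * shell.astype(float)

    bc = _apply_optics(bc, spec, rng)
    nuc = _apply_optics(nuc, spec, rng)
    marker = _apply_optics(marker, spec, rng)

    truth = GroundTruth(
        zonal_diameter=spec.zonal_diameter.copy(),
        zonal_nuclear_intensity=spec.zonal_nuclear_intensity.copy(),
        nucleus_zone=np.array(zones10, dtype=int),
        nucleus_intensity=np.array(intensities, dtype=float),
        apical_marker_level=spec.apical_marker_level,
        bc_mask=bc_mask, nuclei_labels=labels, centerline=centerline)
    return bc, nuc, marker, truth


# ---------------------------------------------------------------------
# stimulus trajectory and YAP time courses
# ---------------------------------------------------------------------

def liver_mass_recovery(t_days, resection_fraction: float,
                        halftime: float = 2.5, steepness: float = 2.0):
    """Logistic remnant-mass fraction m(t): f at t=0, -> 1 as t -> inf.

    The halftime is the midpoint of the logistic (regrowth is fastest
    around it, matching the proliferation peak about two days after
    resection); steepness is the logistic rate in 1/day.
    """
    if not 0 <= resection_fraction < 1:
        raise ValueError("resection_fraction must be in [0, 1)")
    if halftime <= 0 or steepness <= 0:
        raise ValueError("recovery curve must be increasing: halftime and "
                         "steepness must be positive")
    t = np.asarray(t_days, dtype=float)
    f = 1.0 - resection_fraction
    l = 1.0 / (1.0 + np.exp(-steepness * (t - halftime)))
    l0 = 1.0 / (1.0 + np.exp(steepness * halftime))
    return f + (1.0 - f) * (l - l0) / (1.0 - l0)


def generate_stimulus_trajectory(
        resection_fraction: float,
        regrowth_halftime: float = 2.5,
        network: bp.CanalicularNetworkModel | None = None,
        t_grid=None,
        steepness: float = 2.0,
        rule: str = "tension") -> pd.DataFrame:
    """Per-(time, zone) relative mechanical stimulus after resection.

    Osmolyte secretion per remnant mass scales as 1/m(t) under the
    conserved bile-salt pool, with the logistic mass recovery m(t); the
    tension fold-change against the untreated network defines the
    stimulus.  ``resection_fraction = 0`` gives stimulus 1 everywhere.
    """
    if not 0 <= resection_fraction < 1:
        raise ValueError("resection_fraction must be in [0, 1)")
    if network is None:
        network = bp.CanalicularNetworkModel.baseline()
    if t_grid is None:
        t_grid = np.linspace(0.0, 7.0, 29)
    t_grid = np.asarray(t_grid, dtype=float)
    p0 = bp.solve_pressure(network)
    t0 = bp.compute_tension_strain(p0, network.diameter_um,
                                   network.diameter_um)
    m = liver_mass_recovery(t_grid, resection_fraction,
                            halftime=regrowth_halftime, steepness=steepness)
    rows = []
    from dataclasses import replace
    for t, mf in zip(t_grid, m):
        cond = replace(network, liver_mass_fraction=float(mf))
        p = bp.solve_pressure(cond)
        tp = bp.compute_tension_strain(p, cond.diameter_um,
                                       network.diameter_um)
        fold, _ = bp.tension_fold_change(tp, t0)
        stim = bp.stimulus_from_mechanics(fold, tp.strain, rule=rule)
        for z in range(network.n_zones):
            rows.append((t, z + 1, float(stim[z])))
    return pd.DataFrame(rows, columns=["time_days", "zone", "stimulus"])


def _interp_zones(profile_values, n_from: int, n_to: int):
    """Resample a zonal profile to a different zone count (midpoints)."""
    p_from = (np.arange(n_from) + 0.5) / n_from
    p_to = (np.arange(n_to) + 0.5) / n_to
    return np.interp(p_to, p_from, profile_values)


def generate_yap_dataset(spec: TimeCourseSpec) -> MeasurementDataSet:
    """Forward-simulate a noisy nuclear/total YAP measurement table.

    Observables come from the quasi-steady state of the YAP model at the
    per-(time, zone) stimulus, multiplied by lognormal noise of the
    stated coefficient of variation, then renormalized so the untreated
    (t = 0) mean is 1 per observable.  Time 0 is the pre-resection
    baseline (stimulus 1).
    """
    rng = np.random.default_rng(spec.seed)
    params = spec.true_params
    times = np.asarray(spec.time_points, float)

    if spec.stimulus_trajectory is None:
        traj = generate_stimulus_trajectory(
            spec.resection_fraction, spec.regrowth_halftime,
            t_grid=times[times > 0] if (times > 0).any() else np.array([1.0]))
    else:
        traj = spec.stimulus_trajectory
    net_zones = int(traj["zone"].max())

    rows = []
    for t in times:
        if t == 0:
            stim10 = np.ones(spec.zones)
        else:
            at_t = traj[np.isclose(traj["time_days"], t)]
            if len(at_t) == 0:
                raise ValueError(f"stimulus trajectory has no entry at t={t}")
            prof = at_t.sort_values("zone")["stimulus"].to_numpy()
            stim10 = _interp_zones(prof, net_zones, spec.zones)
        try:
            nuc, tot = hippo.normalized_observables(params, stim10)
        except hippo.NoSteadyStateError as exc:
            raise ValueError(f"invalid true parameters: {exc}") from exc
        if np.any(~np.isfinite(nuc)):
            raise ValueError(f"true parameters admit no steady state at "
                             f"t={t}")
        for z in range(spec.zones):
            for obs, val in (("nuclear", nuc[z]), ("total", tot[z])):
                for _ in range(spec.replicates):
                    if spec.noise_cv > 0:
                        sigma = np.sqrt(np.log1p(spec.noise_cv ** 2))
                        noise = rng.lognormal(-sigma ** 2 / 2.0, sigma)
                    else:
                        noise = 1.0
                    v = val * noise
                    rows.append((t, z + 1, obs, v,
                                 spec.noise_cv * v if spec.noise_cv > 0
                                 else np.nan,
                                 spec.replicates))
    df = pd.DataFrame(rows, columns=["time_days", "zone", "observable",
                                     "value", "sd", "n"])
    df = df.iloc[:spec.n_points_target]
    ds = MeasurementDataSet(df)
    return ds.renormalized(baseline_time=0.0)


# ---------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixtures(output_dir, specs: dict) -> dict:
    """Write phantom stacks / tables for each named spec; return a manifest.

    Phantom channels go to multi-page 16-bit TIFF (ZYX), tables to CSV,
    ground truth to JSON, and the manifest records a SHA-256 checksum per
    file so regeneration and corruption are detectable.
    """
    import tifffile

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"fixtures": {}, "files": {}}
    for name, spec in specs.items():
        entry: dict = {"type": type(spec).__name__, "seed": spec.seed}
        if isinstance(spec, LobulePhantomSpec):
            bc, nuc, marker, truth = generate_lobule_stack(spec)
            for channel, img in (("bc", bc), ("nuclei", nuc),
                                 ("marker", marker)):
                path = out / f"{name}_{channel}.tif"
                tifffile.imwrite(
                    path, np.clip(np.round(img), 0, 65535).astype(np.uint16))
            tifffile.imwrite(out / f"{name}_bc_mask.tif",
                             truth.bc_mask.astype(np.uint8))
            tifffile.imwrite(out / f"{name}_nuclei_labels.tif",
                             truth.nuclei_labels.astype(np.uint16))
            (out / f"{name}_truth.json").write_text(
                json.dumps(truth.to_dict(), indent=1, sort_keys=True))
        elif isinstance(spec, TimeCourseSpec):
            ds = generate_yap_dataset(spec)
            ds.to_csv(out / f"{name}_yap_data.csv")
            truth = GroundTruth(
                true_params=asdict_params(spec.true_params),
                stimulus_trajectory=spec.stimulus_trajectory)
            (out / f"{name}_truth.json").write_text(
                json.dumps(truth.to_dict(), indent=1, sort_keys=True))
        else:
            raise TypeError(f"unknown spec type for {name!r}: {type(spec)}")
        manifest["fixtures"][name] = entry
    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["files"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def verify_fixtures(output_dir) -> list:
    """Names of files whose checksum no longer matches the manifest."""
    out = Path(output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return [name for name, digest in manifest["files"].items()
            if not (out / name).exists() or _sha256(out / name) != digest]


def asdict_params(params: hippo.HippoParams) -> dict:
    d = asdict(params)
    d["fixed_to_one"] = sorted(d["fixed_to_one"])
    d["free"] = sorted(d["free"])
    return d
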