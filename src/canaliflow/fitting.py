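"""Weighted least-squares estimation of the free YAP-model parameters.

The nine free parameters are estimated by fitting the closed-form
quasi-steady-state observables (normalized nuclear and total YAP) to a
long-format measurement table, with a per-(time, zone) mechanical
stimulus supplied by the biophysical stage.  Optimization runs in
log-parameter space (rates are positive and scale-free) from
Latin-hypercube multi-starts; non-identifiable parameters are expected
for this model family and are reported, never hidden — the fitted
stimulus-response curve and its activation threshold are the
well-determined quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import hippo
from .dataset import MeasurementDataSet

__all__ = [
    "FitConfig", "FitResult", "MeasurementDataSet",
    "row_stimuli", "objective", "fit", "parameter_recovery",
    "pearson_correlation",
]

_QSS_PENALTY = 1.0e3     # residual per row where no steady state exists


@dataclass
class FitConfig:
    """Bounds, multi-start design and weighting for the fitter."""

    n_starts: int = 50
    seed: int = 0
    bounds_decades: float = 3.0      # bounds: nominal x 10^(+-decades)
    bounds: dict = field(default_factory=dict)   # per-param (lo, hi) override
    fix: frozenset = frozenset()     # free params held at their nominal value
    weighting: str = "auto"          # 1/sd where given, else relative
    renormalize: bool = True         # rescale data to baseline mean 1
    xtol: float = 1e-10
    ftol: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.bounds_decades <= 0:
            raise ValueError("bounds_decades must be positive")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")
        self.fix = frozenset(self.fix)

    def log_bounds(self, names, nominal) -> tuple:
        lo, hi = [], []
        for name, nom in zip(names, nominal):
            if name in self.bounds:
                l, h = self.bounds[name]
            else:
                l = nom * 10.0 ** (-self.bounds_decades)
                h = nom * 10.0 ** self.bounds_decades
            lo.append(np.log10(l))
            hi.append(np.log10(h))
        return np.array(lo), np.array(hi)


@dataclass
class FitResult:
    """Best-fit parameters plus convergence and curve diagnostics."""

    params: hippo.HippoParams
    free_values: dict
    objective: float
    success: bool
    starts: list
    curve: hippo.StimulusResponseCurve | None = None
    threshold: hippo.ThresholdResult | None = None

    def __post_init__(self) -> None:
        if self.objective < 0:
            raise ValueError("objective must be non-negative")


def row_stimuli(dataset: MeasurementDataSet,
                trajectory: pd.DataFrame,
                zones: int | None = None) -> np.ndarray:
    """Per-row stimulus for a dataset from a (time, zone, stimulus) table.

    Trajectory zones are resampled to the dataset's zone count by
    midpoint interpolation; time 0 maps to the untreated baseline
    (stimulus 1).
    """
    df = dataset.table
    zones = int(df["zone"].max()) if zones is None else zones
    net_zones = int(trajectory["zone"].max())
    p_from = (np.arange(net_zones) + 0.5) / net_zones
    p_to = (np.arange(zones) + 0.5) / zones
    out = np.empty(len(df))
    for t, sel in df.groupby("time_days").groups.items():
        if t == 0:
            out[sel] = 1.0
            continue
        at_t = trajectory[np.isclose(trajectory["time_days"], t)]
        if len(at_t) == 0:
            raise ValueError(f"no stimulus available at time {t}")
        prof = np.interp(p_to, p_from,
                         at_t.sort_values("zone")["stimulus"].to_numpy())
        out[sel] = prof[df.loc[sel, "zone"].to_numpy() - 1]
    return out


def _residuals(free_log, free_names, fixed: hippo.HippoParams,
               values, sds, obs_is_nuclear, stimulus, weighting):
    params = _params_from_log(free_log, free_names, fixed)
    if params is None:
        return np.full(len(values), _QSS_PENALTY)
    uniq, inv = np.unique(stimulus, return_inverse=True)
    try:
        nuc, tot = hippo.normalized_observables(params, uniq)
    except hippo.NoSteadyStateError:
        return np.full(len(values), _QSS_PENALTY)
    pred = np.where(obs_is_nuclear, nuc[inv], tot[inv])
    res = np.empty(len(values))
    bad = ~np.isfinite(pred)
    res[bad] = _QSS_PENALTY
    ok = ~bad
    use_sd = ok & np.isfinite(sds) & (sds > 0) if weighting == "auto" \
        else np.zeros(len(values), bool)
    res[use_sd] = (values[use_sd] - pred[use_sd]) / sds[use_sd]
    rel = ok & ~use_sd
    res[rel] = (values[rel] - pred[rel]) / pred[rel]
    return res


def _params_from_log(free_log, free_names, fixed):
    vals = {n: 10.0 ** v for n, v in zip(free_names, free_log)}
    full = {n: vals.get(n, getattr(fixed, n)) for n in fixed.free_names}
    try:
        return fixed.with_free([full[n] for n in fixed.free_names])
    except ValueError:
        return None


def _prepare(dataset, config):
    ds = dataset.renormalized() if config.renormalize else dataset
    df = ds.table
    return (df["value"].to_numpy(), df["sd"].to_numpy(),
            (df["observable"] == "nuclear").to_numpy())


def objective(free_params, dataset: MeasurementDataSet,
              fixed: hippo.HippoParams, stimulus,
              config: FitConfig | None = None) -> float:
    """Weighted sum of squared residuals at the given free parameters.

    ``free_params`` is a dict (name -> value) or an array ordered like
    ``fixed.free_names``; ``stimulus`` is a per-row array or a
    (time, zone, stimulus) trajectory table.  Rows whose steady state
    does not exist contribute a large finite penalty.
    """
    config = config or FitConfig()
    if isinstance(stimulus, pd.DataFrame):
        stimulus = row_stimuli(dataset, stimulus)
    stimulus = np.asarray(stimulus, float)
    if stimulus.size != len(dataset):
        raise ValueError("stimulus must supply one value per dataset row")
    values, sds, is_nuc = _prepare(dataset, config)
    if isinstance(free_params, dict):
        names = tuple(sorted(free_params))
        theta = np.log10([free_params[n] for n in names])
    else:
        names = fixed.free_names
        theta = np.log10(np.asarray(free_params, float))
    res = _residuals(theta, names, fixed, values, sds, is_nuc,
                     stimulus, config.weighting)
    return float(res @ res)


def fit(dataset: MeasurementDataSet, config: FitConfig,
        fixed: hippo.HippoParams, stimulus) -> FitResult:
    """Multi-start bounded least squares in log-parameter space.

    Starts are a seeded Latin hypercube over the log bounds plus the
    nominal parameter point; the best start is re-polished at tight
    tolerance, and the result carries the fitted stimulus-response curve
    and its activation threshold.  Deterministic for a fixed seed.
    """
    if isinstance(stimulus, pd.DataFrame):
        stimulus = row_stimuli(dataset, stimulus)
    stimulus = np.asarray(stimulus, float)
    values, sds, is_nuc = _prepare(dataset, config)
    free_names = tuple(n for n in fixed.free_names if n not in config.fix)
    nominal = np.array([getattr(fixed, n) for n in free_names])
    lo, hi = config.log_bounds(free_names, nominal)

    sampler = qmc.LatinHypercube(d=len(free_names), seed=config.seed)
    starts = qmc.scale(sampler.random(config.n_starts), lo, hi)
    starts[0] = np.clip(np.log10(nominal), lo, hi)   # include the nominal

    args = (free_names, fixed, values, sds, is_nuc, stimulus,
            config.weighting)
    records, solutions = [], []
    for k, x0 in enumerate(starts):
        try:
            sol = least_squares(_residuals, x0, args=args, bounds=(lo, hi),
                                method="trf", xtol=config.xtol,
                                ftol=config.ftol, max_nfev=400)
            records.append({"start": k, "cost": 2.0 * sol.cost,
                            "converged": bool(sol.success)})
            solutions.append((2.0 * sol.cost, sol.x))
        except Exception as exc:   # optimizer blow-up: count, keep going
            records.append({"start": k, "cost": np.inf, "converged": False,
                            "error": str(exc)})
    converged = [s for s, r in zip(solutions, records) if np.isfinite(s[0])]
    if not converged:
        return FitResult(params=fixed, free_values={}, objective=np.inf,
                         success=False, starts=records)
    best_cost, best_x = min(converged, key=lambda s: s[0])
    polish = least_squares(_residuals, best_x, args=args, bounds=(lo, hi),
                           method="trf", xtol=1e-12, ftol=1e-12,
                           max_nfev=800)
    best_x = polish.x
    best_cost = 2.0 * polish.cost
    params = _params_from_log(best_x, free_names, fixed)
    curve = hippo.stimulus_response(params)
    thr = hippo.activation_threshold(curve)
    return FitResult(params=params,
                     free_values={n: 10.0 ** v
                                  for n, v in zip(free_names, best_x)},
                     objective=float(best_cost), success=True,
                     starts=records, curve=curve, threshold=thr)


def parameter_recovery(truth: hippo.HippoParams, design, n_replicates: int,
                       config: FitConfig) -> pd.DataFrame:
    """Bias/RMSE of the free parameters and the threshold over replicates.

    Each replicate regenerates the design with a fresh seed, fits it and
    records the estimates.  Parameters with relative RMSE above 100% are
    flagged practically non-identifiable; parameters held fixed by the
    config are excluded from the report.  Failed fits are counted in the
    attached ``.attrs['n_failed']``.
    """
    from dataclasses import replace as dc_replace
    from .synthetic import generate_yap_dataset, generate_stimulus_trajectory

    free_names = tuple(n for n in truth.free_names if n not in config.fix)
    times = np.asarray(design.time_points, float)
    traj = (design.stimulus_trajectory
            if design.stimulus_trajectory is not None
            else generate_stimulus_trajectory(design.resection_fraction,
                                              design.regrowth_halftime,
                                              t_grid=times[times > 0]))
    true_curve = hippo.stimulus_response(truth)
    true_thr = hippo.activation_threshold(true_curve).value
    estimates, thresholds, n_failed = [], [], 0
    for rep in range(n_replicates):
        spec = dc_replace(design, seed=design.seed + 1000 * rep + 1,
                          stimulus_trajectory=traj)
        ds = generate_yap_dataset(spec)
        cfg = dc_replace(config, seed=config.seed + rep)
        result = fit(ds, cfg, truth, row_stimuli(ds, traj))
        if not result.success:
            n_failed += 1
            continue
        estimates.append([result.free_values[n] for n in free_names])
        thresholds.append(result.threshold.value
                          if result.threshold.value is not None else np.nan)
    est = np.array(estimates)
    rows = []
    for j, name in enumerate(free_names):
        true_val = getattr(truth, name)
        e = est[:, j]
        bias = e.mean() - true_val
        rmse = np.sqrt(np.mean((e - true_val) ** 2))
        rows.append({"parameter": name, "true": true_val,
                     "mean_estimate": e.mean(), "bias": bias, "rmse": rmse,
                     "rel_rmse": rmse / true_val,
                     "identifiable": rmse / true_val <= 1.0})
    thr = np.asarray(thresholds, float)
    thr_ok = thr[np.isfinite(thr)]
    if true_thr is not None and thr_ok.size:
        rmse = np.sqrt(np.mean((thr_ok - true_thr) ** 2))
        rows.append({"parameter": "threshold", "true": true_thr,
                     "mean_estimate": thr_ok.mean(),
                     "bias": thr_ok.mean() - true_thr, "rmse": rmse,
                     "rel_rmse": rmse / true_thr,
                     "identifiable": rmse / true_thr <= 1.0})
    report = pd.DataFrame(rows)
    report.attrs["n_failed"] = n_failed
    report.attrs["n_replicates"] = n_replicates
    return report


def pearson_correlation(x, y) -> float:
    """Product-moment correlation with listwise deletion of missing pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])
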