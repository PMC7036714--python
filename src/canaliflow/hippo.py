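"""Mass-action / Michaelis-Menten model of YAP regulation by apical tension.

Seven species in two compartments describe the five regulatory mechanisms
of hepatocyte YAP: synthesis, degradation, (in)activation by a
mechano-sensor, cytoplasmic sequestration by a sequestration factor (SF),
and nuclear-cytoplasmic shuttling:

    S    active mechano-sensor          S_i  inactivated sensor
    Y_c  active cytoplasmic YAP         Y_i  inactivated cytoplasmic YAP
    C    Y_i:SF complex                 SF   free sequestration factor
    Y_n  nuclear YAP

    dS/dt   = k_sens_on S_i - k_sens_off S h(u)
    dY_c/dt = k_syn + k_react Y_i - V_inact S Y_c/(K_inact + Y_c)
              - k_in Y_c + k_out Y_n (V_nuc/V_cyt)
    dY_i/dt = V_inact S Y_c/(K_inact + Y_c) - (k_react + k_deg) Y_i
              - k_bind Y_i SF + k_unbind C
    dC/dt   = k_bind Y_i SF - k_unbind C
    dY_n/dt = k_in Y_c (V_cyt/V_nuc) - k_out Y_n

with the conservation laws S + S_i = S_tot and SF + C = SF_tot closing
the system.  The mechanical stimulus u (relative apical tension, u = 1
untreated) drives sensor inactivation through the saturating activation
function ``h(u) = u^n / (K_sens^n + u^n)``; the cooperativity ``n``
(``sensor_hill``) models clustering of the mechano-sensor and is a
structural constant of the scheme, not a fitted rate (n = 1 recovers
plain Michaelis-Menten sensing; see docs/MODEL_NOTES.md).

The model has 16 parameters: 14 kinetic constants plus the two measured
compartment volumes.  Five kinetic constants do not affect the (suitably
normalized) steady state and are fixed to 1; the remaining nine are free
and estimated from data.  The quasi-steady state has a closed form, used
both for fitting and for the stimulus-response analysis; a multi-start
numerical root finder provides an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "HippoParams", "HippoState", "StimulusResponseCurve", "ThresholdResult",
    "NoSteadyStateError", "MultipleSteadyStatesError",
    "rhs", "integrate", "quasi_steady_state", "observables",
    "normalized_observables", "stimulus_response", "activation_threshold",
    "effective_hill", "threshold_robustness",
    "DEFAULT_STIMULUS_GRID",
]

PARAM_NAMES_KINETIC = (
    "k_syn", "k_deg", "V_inact", "K_inact", "k_react",
    "k_sens_off", "K_sens", "k_sens_on", "k_bind", "k_unbind",
    "k_in", "k_out", "S_tot", "SF_tot",
)
PARAM_NAMES_MEASURED = ("V_nuc", "V_cyt")

# Five constants that drop out of the normalized steady state: they set
# concentration/time-scale units only.  K_sens stays free because it
# positions the activation switch on the stimulus axis.
DEFAULT_FIXED_TO_ONE = frozenset(
    {"K_inact", "S_tot", "SF_tot", "k_unbind", "k_sens_on"})
DEFAULT_FREE = frozenset(
    {"k_syn", "k_deg", "V_inact", "k_react", "k_sens_off", "K_sens",
     "k_bind", "k_in", "k_out"})

DEFAULT_STIMULUS_GRID = np.linspace(0.25, 8.0, 1551)


class NoSteadyStateError(RuntimeError):
    """The reaction scheme has no non-negative steady state here.

    Happens when the maximal inactivation capacity V_inact * S falls
    below the net synthesis throughput: active YAP then grows without
    bound.
    """


class MultipleSteadyStatesError(RuntimeError):
    """Multi-start root finding found distinct steady states."""


@dataclass
class HippoParams:
    """The 16-parameter YAP regulation model (plus structural constants).

    Rates are in 1/day on the concentration scale set by the unit-fixed
    constants; volumes are in cubic micrometres.
    """

    k_syn: float = 0.2        # YAP synthesis, conc/day
    k_deg: float = 1.0        # degradation of inactive cytoplasmic YAP, 1/day
    V_inact: float = 2.73     # max sensor-driven YAP inactivation, conc/day
    K_inact: float = 1.0      # Michaelis constant of inactivation, conc
    k_react: float = 0.1      # YAP reactivation, 1/day
    k_sens_off: float = 3.0   # stimulus-driven sensor inactivation, 1/day
    K_sens: float = 3.0       # half-saturation of stimulus action, fold
    k_sens_on: float = 1.0    # sensor reactivation, 1/day
    k_bind: float = 10.0      # Y_i + SF association, 1/(conc day)
    k_unbind: float = 1.0     # complex dissociation, 1/day
    k_in: float = 0.1         # nuclear import of active YAP, 1/day
    k_out: float = 1.2        # nuclear export, 1/day
    S_tot: float = 1.0        # total sensor, conc
    SF_tot: float = 1.0       # total sequestration factor, conc
    V_nuc: float = 400.0      # nuclear volume, um^3 (measured)
    V_cyt: float = 4800.0     # cytoplasmic volume, um^3 (measured)
    sensor_hill: float = 1.0  # structural cooperativity of stimulus sensing
    fixed_to_one: frozenset = field(default=DEFAULT_FIXED_TO_ONE)
    free: frozenset = field(default=DEFAULT_FREE)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES_KINETIC + PARAM_NAMES_MEASURED:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sensor_hill < 1:
            raise ValueError("sensor_hill must be >= 1")
        self.fixed_to_one = frozenset(self.fixed_to_one)
        self.free = frozenset(self.free)
        if len(self.fixed_to_one) != 5:
            raise ValueError("exactly 5 parameters are fixed to one")
        if len(self.free) != 9:
            raise ValueError("exactly 9 parameters are free")
        allnames = set(PARAM_NAMES_KINETIC)
        if self.fixed_to_one & self.free:
            raise ValueError("fixed and free sets overlap")
        if (self.fixed_to_one | self.free) != allnames:
            raise ValueError("fixed + free must cover the 14 kinetic "
                             "parameters exactly")
        for name in self.fixed_to_one:
            if getattr(self, name) != 1.0:
                raise ValueError(f"{name} is declared fixed-to-one but is "
                                 f"{getattr(self, name)}")

    # -- reference parameter set -------------------------------------
    @classmethod
    def reference(cls) -> "HippoParams":
        """Switch-like reference regime.

        Calibrated so that the tangent-at-inflection activation threshold
        of the stimulus-response curve sits at 1.75-fold relative tension,
        with strong sequestration (most cytoplasmic YAP bound to SF) and
        a cooperative mechano-sensor (sensor_hill = 4).
        """
        return cls(K_sens=3.0704, sensor_hill=4.0)

    # -- free-parameter plumbing --------------------------------------
    @property
    def free_names(self) -> tuple:
        return tuple(sorted(self.free))

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names])

    def with_free(self, values) -> "HippoParams":
        values = np.asarray(values, dtype=float)
        upd = dict(zip(self.free_names, values))
        return replace(self, **upd)

    def stimulus_activation(self, u):
        """Saturating (optionally cooperative) stimulus activation h(u)."""
        u = np.asarray(u, dtype=float)
        n = self.sensor_hill
        return u ** n / (self.K_sens ** n + u ** n)


@dataclass
class HippoState:
    """Seven-species compartment state (per-compartment concentrations)."""

    S: float
    S_i: float
    Y_c: float
    Y_i: float
    C: float
    SF: float
    Y_n: float

    _FIELDS = ("S", "S_i", "Y_c", "Y_i", "C", "SF", "Y_n")

    def __post_init__(self) -> None:
        for name in self._FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative concentration: {name}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self._FIELDS])

    def check_conservation(self, params: HippoParams,
                           rtol: float = 1e-8) -> None:
        if not np.isclose(self.S + self.S_i, params.S_tot, rtol=rtol):
            raise ValueError("sensor conservation violated")
        if not np.isclose(self.SF + self.C, params.SF_tot, rtol=rtol):
            raise ValueError("SF conservation violated")

    def total_yap(self, params: HippoParams) -> float:
        """Volume-weighted total YAP amount / total volume."""
        return ((params.V_cyt * (self.Y_c + self.Y_i + self.C)
                 + params.V_nuc * self.Y_n)
                / (params.V_cyt + params.V_nuc))


def rhs(state: HippoState, params: HippoParams, stimulus: float) -> np.ndarray:
    """Time derivatives of the seven species at the given stimulus."""
    if stimulus < 0:
        raise ValueError("stimulus must be non-negative")
    s = state
    p = params
    h = float(p.stimulus_activation(stimulus))
    inact = p.V_inact * s.S * s.Y_c / (p.K_inact + s.Y_c)
    dS = p.k_sens_on * s.S_i - p.k_sens_off * s.S * h
    dY_c = (p.k_syn + p.k_react * s.Y_i - inact
            - p.k_in * s.Y_c + p.k_out * s.Y_n * (p.V_nuc / p.V_cyt))
    dY_i = (inact - (p.k_react + p.k_deg) * s.Y_i
            - p.k_bind * s.Y_i * s.SF + p.k_unbind * s.C)
    dC = p.k_bind * s.Y_i * s.SF - p.k_unbind * s.C
    dY_n = p.k_in * s.Y_c * (p.V_cyt / p.V_nuc) - p.k_out * s.Y_n
    return np.array([dS, -dS, dY_c, dY_i, dC, -dC, dY_n])


# ---------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------

def _rhs_reduced(t, y, params, stim_fn):
    """Reduced 5-state rhs (S, Y_c, Y_i, C, Y_n) using the conservation laws."""
    p = params
    S, Y_c, Y_i, C, Y_n = y
    u = stim_fn(t)
    h = float(p.stimulus_activation(u))
    S_i = p.S_tot - S
    SF = p.SF_tot - C
    inact = p.V_inact * S * Y_c / (p.K_inact + Y_c)
    return [
        p.k_sens_on * S_i - p.k_sens_off * S * h,
        (p.k_syn + p.k_react * Y_i - inact
         - p.k_in * Y_c + p.k_out * Y_n * (p.V_nuc / p.V_cyt)),
        inact - (p.k_react + p.k_deg) * Y_i - p.k_bind * Y_i * SF
        + p.k_unbind * C,
        p.k_bind * Y_i * SF - p.k_unbind * C,
        p.k_in * Y_c * (p.V_cyt / p.V_nuc) - p.k_out * Y_n,
    ]


def integrate(params: HippoParams, stimulus, t_grid,
              initial: HippoState | None = None,
              rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the reaction system over ``t_grid`` (days).

    ``stimulus`` is a scalar (constant stimulus) or a callable ``t -> u``.
    Returns ``(t_grid, states)`` with one :class:`HippoState` per time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    stim_fn = stimulus if callable(stimulus) else (lambda t: stimulus)
    if initial is None:
        initial = quasi_steady_state(params, float(stim_fn(t_grid[0])))
    y0 = [initial.S, initial.Y_c, initial.Y_i, initial.C, initial.Y_n]
    sol = solve_ivp(_rhs_reduced, (t_grid[0], t_grid[-1]), y0,
                    t_eval=t_grid, args=(params, stim_fn),
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else 'start'}"
            f": {sol.message}")
    states = []
    for k in range(sol.t.size):
        S, Y_c, Y_i, C, Y_n = sol.y[:, k]
        states.append(HippoState(
            S=max(S, 0.0), S_i=max(params.S_tot - S, 0.0),
            Y_c=max(Y_c, 0.0), Y_i=max(Y_i, 0.0),
            C=max(C, 0.0), SF=max(params.SF_tot - C, 0.0),
            Y_n=max(Y_n, 0.0)))
    return t_grid, states


# ---------------------------------------------------------------------
# quasi-steady state
# ---------------------------------------------------------------------

def _qss_arrays(params: HippoParams, u):
    """Vectorized closed-form quasi-steady state.

    Setting the rhs to zero gives, in order: the sensor balance, the
    pinned inactive pool Y_i = k_syn / k_deg (inactivation throughput
    must equal degradation at stationarity), the complex from the binding
    equilibrium, and active YAP from the synthesis/inactivation balance
    Y_c = K_inact F / (V_inact S - F) with F = k_syn (k_react + k_deg) /
    k_deg.  Entries where no steady state exists (V_inact S <= F) are NaN.
    """
    p = params
    u = np.asarray(u, dtype=float)
    h = p.stimulus_activation(u)
    S = p.k_sens_on * p.S_tot / (p.k_sens_on + p.k_sens_off * h)
    F = p.k_syn * (p.k_react + p.k_deg) / p.k_deg
    den = p.V_inact * S - F
    with np.errstate(divide="ignore", invalid="ignore"):
        Y_c = np.where(den > 0, p.K_inact * F / np.where(den > 0, den, 1.0),
                       np.nan)
    Y_i = np.full_like(u, p.k_syn / p.k_deg)
    C = np.full_like(u, p.SF_tot * p.k_bind * (p.k_syn / p.k_deg)
                     / (p.k_unbind + p.k_bind * (p.k_syn / p.k_deg)))
    Y_n = (p.k_in / p.k_out) * (p.V_cyt / p.V_nuc) * Y_c
    return {"S": S, "S_i": p.S_tot - S, "Y_c": Y_c, "Y_i": Y_i,
            "C": C, "SF": p.SF_tot - C, "Y_n": Y_n}


def _qss_numeric(params: HippoParams, u: float, n_starts: int = 10,
                 seed: int = 0) -> HippoState:
    """Multi-start root finding on the reduced system; flags multiplicity."""
    p = params
    rng = np.random.default_rng(seed)
    scale = max(1.0, p.k_syn / p.k_deg)
    roots = []
    for _ in range(n_starts):
        y0 = [rng.uniform(0, p.S_tot), rng.uniform(0, 5 * scale),
              rng.uniform(0, 5 * scale), rng.uniform(0, p.SF_tot),
              rng.uniform(0, 5 * scale * p.V_cyt / p.V_nuc)]
        sol = root(lambda y: _rhs_reduced(0.0, y, p, lambda t: u), y0,
                   method="hybr", tol=1e-13)
        y = sol.x
        res = np.max(np.abs(_rhs_reduced(0.0, y, p, lambda t: u)))
        if sol.success and res < 1e-9 and np.all(y > -1e-12) \
                and y[0] <= p.S_tot + 1e-9 and y[3] <= p.SF_tot + 1e-9:
            roots.append(np.clip(y, 0, None))
    if not roots:
        raise NoSteadyStateError(
            f"no non-negative steady state found at stimulus {u}")
    ref = roots[0]
    for other in roots[1:]:
        if not np.allclose(ref, other, rtol=1e-6, atol=1e-9):
            raise MultipleSteadyStatesError(
                f"distinct steady states at stimulus {u}")
    S, Y_c, Y_i, C, Y_n = ref
    return HippoState(S=S, S_i=p.S_tot - S, Y_c=Y_c, Y_i=Y_i, C=C,
                      SF=p.SF_tot - C, Y_n=Y_n)


def quasi_steady_state(params: HippoParams, stimulus: float,
                       method: str = "analytic", **kwargs) -> HippoState:
    """Steady state of the reaction system at a fixed stimulus.

    ``method='analytic'`` evaluates the closed-form solution (the scheme
    is solvable species-by-species at stationarity); ``method='numeric'``
    solves rhs = 0 by multi-start root finding from random feasible
    initializations and raises if distinct roots are found.
    """
    if method == "numeric":
        return _qss_numeric(params, float(stimulus), **kwargs)
    if method != "analytic":
        raise ValueError(f"unknown method {method!r}")
    vals = _qss_arrays(params, float(stimulus))
    if not np.isfinite(vals["Y_c"]):
        raise NoSteadyStateError(
            f"V_inact * S <= F at stimulus {stimulus}: active YAP grows "
            "without bound, no steady state")
    return HippoState(**{k: float(v) for k, v in vals.items()})


# ---------------------------------------------------------------------
# observables and stimulus-response
# ---------------------------------------------------------------------

def observables(state: HippoState, params: HippoParams,
                baseline: HippoState | None = None):
    """(nuclear, total) YAP signals; normalized when a baseline is given.

    nuclear is proportional to Y_n; total is the volume-weighted mean
    concentration over both compartments.  With ``baseline`` (the state
    at stimulus 1) both are divided by their baseline values so the
    untreated condition reads 1.0.
    """
    nuc = state.Y_n
    tot = state.total_yap(params)
    if baseline is None:
        return nuc, tot
    nuc0 = baseline.Y_n
    tot0 = baseline.total_yap(params)
    if nuc0 <= 0 or tot0 <= 0:
        raise ValueError("baseline signal is zero; cannot normalize")
    return nuc / nuc0, tot / tot0


def normalized_observables(params: HippoParams, stimulus):
    """Vectorized (nuclear, total) fold-changes at quasi-steady state.

    Both observables are normalized to their values at stimulus 1.
    Stimuli without a steady state yield NaN.
    """
    u = np.asarray(stimulus, dtype=float)
    vals = _qss_arrays(params, u)
    base = _qss_arrays(params, 1.0)
    if not np.isfinite(base["Y_c"]):
        raise NoSteadyStateError("no steady state at baseline stimulus 1")
    nuc = vals["Y_n"] / base["Y_n"]
    w_c = params.V_cyt
    tot = (w_c * (vals["Y_c"] + vals["Y_i"] + vals["C"])
           + params.V_nuc * vals["Y_n"])
    tot0 = (w_c * (base["Y_c"] + base["Y_i"] + base["C"])
            + params.V_nuc * base["Y_n"])
    return nuc, tot / tot0


@dataclass
class StimulusResponseCurve:
    """Normalized nuclear/total YAP vs relative mechanical stimulus."""

    stimulus: np.ndarray
    nuclear: np.ndarray
    total: np.ndarray
    ok: np.ndarray                 # False where no steady state exists
    monotone: bool = True
    hill: float = float("nan")

    def __post_init__(self) -> None:
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        if np.any(self.stimulus < 0):
            raise ValueError("stimulus grid must be non-negative")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"stimulus": self.stimulus,
                             "nuclear": self.nuclear, "total": self.total})


def effective_hill(stimulus, response) -> float:
    """Effective Hill coefficient from the log-log slope at half-rise.

    For a pure Hill curve ``b + A u^n / (K^n + u^n)`` the slope of
    ``log(y - b)`` against ``log u`` at the half-rise point is n/2, so
    twice that slope recovers n exactly.
    """
    u = np.asarray(stimulus, dtype=float)
    y = np.asarray(response, dtype=float)
    ok = np.isfinite(y) & (u > 0)
    u, y = u[ok], y[ok]
    if y.size < 5 or np.ptp(y) <= 0:
        return float("nan")
    b, a = y.min(), y.max()
    i_half = int(np.argmin(np.abs((y - b) / (a - b) - 0.5)))
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.gradient(np.log(np.maximum(y - b, 1e-300)), np.log(u))
    return float(2.0 * slope[i_half])


def stimulus_response(params: HippoParams,
                      stimulus_grid=None) -> StimulusResponseCurve:
    """Quasi-steady-state stimulus-response curve over a stimulus grid.

    The grid must cover the baseline stimulus 1.  Grid points without a
    steady state are flagged (partial curve), never silently dropped.
    """
    grid = (DEFAULT_STIMULUS_GRID if stimulus_grid is None
            else np.asarray(stimulus_grid, dtype=float))
    if grid.min() > 1 or grid.max() < 1:
        raise ValueError("stimulus grid must cover the baseline value 1")
    nuc, tot = normalized_observables(params, grid)
    ok = np.isfinite(nuc)
    dn = np.diff(nuc[ok])
    monotone = bool(np.all(dn >= -1e-9 * np.abs(nuc[ok][:-1])))
    curve = StimulusResponseCurve(stimulus=grid, nuclear=nuc, total=tot,
                                  ok=ok, monotone=monotone)
    curve.hill = effective_hill(grid, nuc)
    return curve


# ---------------------------------------------------------------------
# activation threshold
# ---------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Activation threshold of a stimulus-response curve.

    ``value`` is None when the curve has no threshold (flat or without an
    inflection); ``alternatives`` holds all methods side by side.
    """

    value: float | None
    method: str
    reason: str = ""
    alternatives: dict = field(default_factory=dict)


def _tangent_threshold(u, y):
    dy = np.gradient(y, u)
    d2 = np.gradient(dy, u)
    sign_flip = np.where(np.diff(np.sign(d2)) < 0)[0]   # convex -> concave
    if sign_flip.size == 0:
        return None, "no inflection point"
    i = int(sign_flip[np.argmax(dy[sign_flip])])
    if dy[i] <= 0:
        return None, "non-rising inflection"
    base = y[0]
    return float(u[i] - (y[i] - base) / dy[i]), ""


def _crossing(u, y, level):
    above = y >= level
    if not above.any() or above[0]:
        return None
    i = int(np.argmax(above))
    u0, u1, y0, y1 = u[i - 1], u[i], y[i - 1], y[i]
    return float(u0 + (level - y0) * (u1 - u0) / (y1 - y0))


def activation_threshold(curve: StimulusResponseCurve,
                         method: str = "tangent") -> ThresholdResult:
    """Stimulus at which nuclear YAP switches on.

    tangent (default): intersection of the tangent at the inflection
    point with the pre-activation baseline level (the curve value at the
    low end of the grid).  half_rise / rise10: stimulus at 50% / 10% of
    the rise above baseline.  A flat or non-sigmoidal curve yields a
    "no threshold" result rather than a number.
    """
    if method not in ("tangent", "half_rise", "rise10"):
        raise ValueError(f"unknown threshold method {method!r}")
    ok = curve.ok & np.isfinite(curve.nuclear)
    u, y = curve.stimulus[ok], curve.nuclear[ok]
    alts: dict = {}
    if u.size < 10 or np.ptp(y) < 1e-3 * max(abs(y[0]), 1e-12):
        return ThresholdResult(None, method, "flat curve", alts)
    tangent, why = _tangent_threshold(u, y)
    alts["tangent"] = tangent
    base, top = y[0], y.max()
    alts["half_rise"] = _crossing(u, y, base + 0.5 * (top - base))
    alts["rise10"] = _crossing(u, y, base + 0.1 * (top - base))
    value = alts[method]
    reason = why if (value is None and method == "tangent") else (
        "" if value is not None else "no crossing")
    return ThresholdResult(value, method, reason, alts)


def threshold_robustness(params: HippoParams, factor: float = 2.0,
                         stimulus_grid=None):
    """Threshold shift under +-factor perturbation of each free rate constant.

    Half-saturation constants (K_sens) rescale the stimulus axis trivially
    and are not rate constants, so the probe covers the free kinetic
    *rates* only.  Returns a list of records with the relative threshold
    change; perturbations that lose the threshold are reported as such,
    never clipped.
    """
    rates = sorted(set(params.free) - {"K_sens", "K_inact"})
    base = activation_threshold(stimulus_response(params, stimulus_grid))
    if base.value is None:
        raise ValueError("reference curve has no threshold")
    records = []
    for name in rates:
        for f in (1.0 / factor, factor):
            pert = replace(params, **{name: getattr(params, name) * f})
            thr = activation_threshold(stimulus_response(pert, stimulus_grid))
            rel = (abs(thr.value - base.value) / base.value
                   if thr.value is not None else float("inf"))
            records.append({"param": name, "factor": f,
                            "threshold": thr.value, "rel_change": rel})
    return base.value, records
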