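"""Parameter sensitivity analyses over the 50 reported quantities.

Three complementary views of the same question — which of the kinetic
constants move the time-averaged concentrations — are provided:

* logarithmic sensitivity intensities ``S = (P/f) |f(P+h) - f(P-h)| / 2h``
  with ``h = 0.01 P`` and ``f`` the time-averaged concentration over a
  96 h window sampled hourly;
* partial rank correlation coefficients (PRCC) between each parameter
  and each quantity over Latin-hypercube samples drawn within +/-1% of
  nominal, all parameters perturbed simultaneously;
* fuzzy alpha-cut bands: each parameter carries a triangular membership
  function whose alpha-cut interval is ``P (1 +/- 0.01 (1 - alpha))``;
  the band is the spread of the time-averaged quantity over that
  interval (vertex evaluation by default).

Parameters whose nominal value is zero in a scenario (for instance the
p53 synthesis rate in p53-null cells) carry no relative perturbation;
their sensitivities are defined as zero and they are excluded from
PRCC/fuzzy variation, with the exclusion recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .parameters import KINETIC_PARAM_NAMES, ParameterSet
from .registry import N_REPORTED, REPORTED_NAMES
from .rhs import derived_quantities
from .scenarios import Scenario, make_scenario
from .simulate import IntegrationError, SimulationResult, integrate

__all__ = ["SensitivityReport", "PrccReport", "FuzzyBand",
           "average_concentration", "averaged_quantities", "log_sensitivity",
           "log_sensitivity_report", "average_log_sensitivity",
           "prcc_analysis", "partial_rank_correlation", "fuzzy_analysis"]

#: default averaging window (hours) and sampling interval per the
#: time-averaged concentration definition
DEFAULT_T = 96.0
DEFAULT_DT = 1.0


# ---------------------------------------------------------------------
# time-averaged concentrations
# ---------------------------------------------------------------------

def average_concentration(result: SimulationResult, quantity: str,
                          t0: float = 0.0, dt: float = DEFAULT_DT,
                          T: float = DEFAULT_T) -> float:
    """Mean of a reported quantity over N = floor(T/dt) hourly samples.

    Samples are taken at ``t0 + j dt`` for j = 1..N by interpolation on
    the dense trajectory; the plain arithmetic mean matches the
    discrete-sum definition (no trapezoid weighting).
    """
    n = int(np.floor(T / dt))
    t_last = t0 + n * dt
    if result.times[-1] + 1e-9 < t_last or result.times[0] > t0:
        raise ValueError(f"result does not span [{t0}, {t_last}] h")
    times = t0 + dt * np.arange(1, n + 1)
    idx = REPORTED_NAMES.index(quantity) if quantity in REPORTED_NAMES else None
    if idx is None:
        raise KeyError(f"unknown quantity {quantity!r}")
    series = _reported_series(result)
    return float(np.mean(np.interp(times, result.times, series[idx])))


def _reported_series(result: SimulationResult) -> np.ndarray:
    traj = result.trajectories
    out = np.empty((N_REPORTED, traj.shape[1]))
    for j in range(traj.shape[1]):
        out[:, j] = derived_quantities(traj[:, j])
    return out


def averaged_quantities(result: SimulationResult, t0: float = 0.0,
                        dt: float = DEFAULT_DT, T: float = DEFAULT_T
                        ) -> np.ndarray:
    """All 50 time-averaged quantities at once (vectorised)."""
    n = int(np.floor(T / dt))
    if result.times[-1] + 1e-9 < t0 + n * dt:
        raise ValueError("result too short for the averaging window")
    times = t0 + dt * np.arange(1, n + 1)
    sampled = np.empty((result.trajectories.shape[0], n))
    for i in range(result.trajectories.shape[0]):
        sampled[i] = np.interp(times, result.times, result.trajectories[i])
    means = sampled.mean(axis=1)
    # conservation totals are linear, so the average of the total equals
    # the total of the averages
    return derived_quantities(means)


def _scenario_run(params: ParameterSet, scenario: Scenario,
                  T: float = DEFAULT_T) -> SimulationResult:
    ps = scenario.apply(params)
    return integrate(ps, t_end=T + 1.0, init_overrides=scenario.init_overrides)


# ---------------------------------------------------------------------
# logarithmic sensitivity intensities
# ---------------------------------------------------------------------

@dataclass
class SensitivityReport:
    scenario: str
    quantities: List[str]
    parameters: List[str]
    matrix: np.ndarray            # |quantities| x |parameters|
    undefined: List[Tuple[str, str]] = field(default_factory=list)
    settings: Dict[str, float] = field(default_factory=dict)
    averages: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, q in enumerate(self.quantities):
            for j, p in enumerate(self.parameters):
                recs.append((self.scenario, q, p, self.matrix[i, j]))
        return pd.DataFrame(recs, columns=["scenario", "quantity",
                                           "parameter", "value"])


def log_sensitivity(params: ParameterSet, quantity: str, parameter: str,
                    h_fraction: float = 0.01,
                    scenario: Optional[Scenario] = None,
                    T: float = DEFAULT_T) -> float:
    """Logarithmic sensitivity intensity of one quantity to one parameter.

    Central difference with ``h = h_fraction * P``; both perturbed runs
    start from the scenario's standard initial state.  Zero-valued
    parameters return 0 by definition.
    """
    scenario = scenario or make_scenario()
    base = scenario.apply(params)
    p0 = base[parameter]
    if p0 == 0.0:
        return 0.0
    h = h_fraction * p0
    f = {}
    for sign in (+1, -1, 0):
        ps = base.with_edits({parameter: p0 + sign * h})
        res = integrate(ps, t_end=T + 1.0,
                        init_overrides=scenario.init_overrides)
        f[sign] = average_concentration(res, quantity, T=T)
    if f[0] == 0.0:
        return float("nan")
    return float((p0 / f[0]) * abs(f[+1] - f[-1]) / (2.0 * h))


def log_sensitivity_report(params: ParameterSet,
                           scenario: Optional[Scenario] = None,
                           quantities: Sequence[str] = REPORTED_NAMES,
                           parameters: Sequence[str] = KINETIC_PARAM_NAMES,
                           h_fraction: float = 0.01,
                           T: float = DEFAULT_T) -> SensitivityReport:
    """Matrix of intensities for many quantities/parameters at once.

    Each parameter costs two integrations regardless of how many
    quantities are reported.
    """
    scenario = scenario or make_scenario()
    base = scenario.apply(params)
    q_idx = [REPORTED_NAMES.index(q) for q in quantities]
    base_res = integrate(base, t_end=T + 1.0,
                         init_overrides=scenario.init_overrides)
    f0 = averaged_quantities(base_res, T=T)
    matrix = np.zeros((len(quantities), len(parameters)))
    undefined = []
    for j, pname in enumerate(parameters):
        p0 = base[pname]
        if p0 == 0.0:
            continue
        h = h_fraction * p0
        f = {}
        try:
            for sign in (+1, -1):
                ps = base.with_edits({pname: p0 + sign * h})
                res = integrate(ps, t_end=T + 1.0,
                                init_overrides=scenario.init_overrides)
                f[sign] = averaged_quantities(res, T=T)
        except IntegrationError:
            for q in quantities:
                undefined.append((q, pname))
            matrix[:, j] = np.nan
            continue
        for i, qi in enumerate(q_idx):
            if f0[qi] == 0.0:
                undefined.append((quantities[i], pname))
                matrix[i, j] = np.nan
            else:
                matrix[i, j] = (p0 / f0[qi]) * abs(f[+1][qi] - f[-1][qi]) / (2 * h)
    report = SensitivityReport(scenario.label, list(quantities),
                               list(parameters), matrix, undefined,
                               {"h_fraction": h_fraction, "T": T,
                                "dt": DEFAULT_DT, "t0": 0.0})
    report.averages = average_log_sensitivity(report)
    return report


def average_log_sensitivity(report: SensitivityReport) -> np.ndarray:
    """Per-quantity average intensity: row means over the parameters.

    Undefined entries are excluded from the mean; their count is kept in
    the report's ``undefined`` list.
    """
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.where(np.isfinite(report.matrix),
                                   report.matrix, np.nan), axis=1)


# ---------------------------------------------------------------------
# PRCC over Latin-hypercube samples
# ---------------------------------------------------------------------

@dataclass
class PrccReport:
    scenario: str
    parameters: List[str]
    quantities: List[str]
    prcc: np.ndarray             # |quantities| x |parameters|
    p_values: np.ndarray
    n_samples: int
    perturbation: float
    seed: int
    excluded: List[str] = field(default_factory=list)
    n_failed: int = 0
    flags: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, q in enumerate(self.quantities):
            for j, p in enumerate(self.parameters):
                recs.append((self.scenario, q, p, self.prcc[i, j],
                             self.p_values[i, j]))
        return pd.DataFrame(recs, columns=["scenario", "quantity", "parameter",
                                           "prcc", "p_value"])


def partial_rank_correlation(X: np.ndarray, y: np.ndarray
                             ) -> Tuple[np.ndarray, np.ndarray]:
    """PRCC of each column of X against y, partialling out the others.

    Rank-transform all variables, regress each on the remaining columns,
    and correlate the residuals; p-values from the t statistic on
    ``n - 2 - (number of partialled variables)`` degrees of freedom.
    """
    n, k = X.shape
    Xr = np.apply_along_axis(stats.rankdata, 0, X)
    yr = stats.rankdata(y)
    prcc = np.empty(k)
    pvals = np.empty(k)
    dof = n - 2 - (k - 1)
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(Xr, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, Xr[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, yr, rcond=None)
        rx = Xr[:, j] - others @ beta_x
        ry = yr - others @ beta_y
        # a residual with essentially no variance (constant output, or a
        # parameter fully explained by the others) carries no correlation
        if (rx ** 2).sum() < 1e-12 * n or (ry ** 2).sum() < 1e-12 * n:
            prcc[j], pvals[j] = 0.0, 1.0
            continue
        denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
        prcc[j] = r
        if dof <= 0 or abs(r) >= 1.0:
            pvals[j] = 0.0 if abs(r) >= 1.0 else 1.0
        else:
            tstat = r * np.sqrt(dof / (1.0 - r ** 2))
            pvals[j] = float(2 * stats.t.sf(abs(tstat), dof))
    return prcc, pvals


def prcc_analysis(params: ParameterSet, n_samples: int = 1000,
                  perturbation: float = 0.01, seed: int = 0,
                  scenario: Optional[Scenario] = None,
                  parameters: Sequence[str] = KINETIC_PARAM_NAMES,
                  quantities: Sequence[str] = REPORTED_NAMES,
                  distribution: str = "uniform",
                  T: float = DEFAULT_T) -> PrccReport:
    """PRCC between parameters and time-averaged quantities.

    All listed parameters are perturbed simultaneously within
    ``+/- perturbation`` of nominal using Latin-hypercube sampling
    (uniform box by default; ``distribution='truncnorm'`` maps the box
    to a +/-3 sigma truncated normal).  Failed integrations are dropped;
    more than 10% failures aborts the analysis.
    """
    scenario = scenario or make_scenario()
    base = scenario.apply(params)
    active = [p for p in parameters if base[p] != 0.0]
    excluded = [p for p in parameters if base[p] == 0.0]
    flags = []
    if n_samples <= len(active) + 2:
        flags.append(f"n_samples={n_samples} close to parameter count; "
                     "p-values unreliable")
    sampler = qmc.LatinHypercube(d=len(active), seed=seed)
    unit = sampler.random(n_samples)
    if distribution == "truncnorm":
        z = stats.truncnorm.ppf(unit, -3.0, 3.0) / 3.0
    elif distribution == "uniform":
        z = 2.0 * unit - 1.0
    else:
        raise ValueError("distribution must be 'uniform' or 'truncnorm'")
    nominal = np.array([base[p] for p in active])
    samples = nominal * (1.0 + perturbation * z)
    X, Y = [], []
    n_failed = 0
    for row in samples:
        ps = base.with_edits(dict(zip(active, row)))
        try:
            res = integrate(ps, t_end=T + 1.0,
                            init_overrides=scenario.init_overrides)
            Y.append(averaged_quantities(res, T=T))
            X.append(row)
        except IntegrationError:
            n_failed += 1
    if n_failed > 0.1 * n_samples:
        raise RuntimeError(f"{n_failed}/{n_samples} sample integrations failed")
    X = np.asarray(X)
    Y = np.asarray(Y)
    q_idx = [REPORTED_NAMES.index(q) for q in quantities]
    prcc = np.zeros((len(quantities), len(parameters)))
    pvals = np.ones((len(quantities), len(parameters)))
    col_of = {p: j for j, p in enumerate(parameters)}
    for i, qi in enumerate(q_idx):
        y = Y[:, qi]
        if np.allclose(y, y[0]):
            flags.append(f"{quantities[i]}: zero variance, PRCC set to 0")
            continue
        r, pv = partial_rank_correlation(X, y)
        for p, rj, pj in zip(active, r, pv):
            prcc[i, col_of[p]] = rj
            pvals[i, col_of[p]] = pj
    return PrccReport(scenario.label, list(parameters), list(quantities),
                      prcc, pvals, n_samples - n_failed, perturbation, seed,
                      excluded, n_failed, flags)


# ---------------------------------------------------------------------
# fuzzy alpha-cut uncertainty bands
# ---------------------------------------------------------------------

@dataclass
class FuzzyBand:
    scenario: str
    parameters: List[str]
    quantities: List[str]
    alpha_levels: List[float]
    #: band[q][p][a] = max - min of the averaged quantity over the cut
    bands: np.ndarray            # |quantities| x |parameters| x |alphas|
    excluded: List[str] = field(default_factory=list)
    max_fraction: float = 0.01

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, q in enumerate(self.quantities):
            for j, p in enumerate(self.parameters):
                for k, a in enumerate(self.alpha_levels):
                    recs.append((self.scenario, q, p, a, self.bands[i, j, k]))
        return pd.DataFrame(recs, columns=["scenario", "quantity", "parameter",
                                           "alpha", "band"])


def fuzzy_analysis(params: ParameterSet,
                   parameters: Sequence[str],
                   alpha_levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
                   scenario: Optional[Scenario] = None,
                   quantities: Sequence[str] = REPORTED_NAMES,
                   max_fraction: float = 0.01,
                   mode: str = "vertex",
                   grid_points: int = 21,
                   T: float = DEFAULT_T) -> FuzzyBand:
    """Maximum uncertainty bands from triangular fuzzy parameters.

    For each parameter and alpha, the cut interval is
    ``[P (1 - max_fraction (1-alpha)), P (1 + max_fraction (1-alpha))]``;
    alpha = 0 is the widest (+/-1%) interval, alpha = 1 the crisp value.
    ``mode='vertex'`` evaluates the interval endpoints plus the nominal
    value; ``mode='grid'`` scans ``grid_points`` values for non-monotone
    responses.
    """
    for a in alpha_levels:
        if not 0.0 <= a <= 1.0:
            raise ValueError("alpha levels must lie in [0, 1]")
    scenario = scenario or make_scenario()
    base = scenario.apply(params)
    active = [p for p in parameters if base[p] != 0.0]
    excluded = [p for p in parameters if base[p] == 0.0]
    q_idx = [REPORTED_NAMES.index(q) for q in quantities]
    cache: Dict[float, np.ndarray] = {}

    def averaged_at(pname: str, value: float) -> np.ndarray:
        ps = base.with_edits({pname: value})
        res = integrate(ps, t_end=T + 1.0,
                        init_overrides=scenario.init_overrides)
        return averaged_quantities(res, T=T)

    bands = np.zeros((len(quantities), len(parameters), len(alpha_levels)))
    col_of = {p: j for j, p in enumerate(parameters)}
    for pname in active:
        p0 = base[pname]
        f_nom = averaged_at(pname, p0)
        for k, alpha in enumerate(alpha_levels):
            half = max_fraction * (1.0 - alpha) * p0
            if half == 0.0:
                continue
            if mode == "vertex":
                values = [p0 - half, p0, p0 + half]
                evals = [averaged_at(pname, p0 - half), f_nom,
                         averaged_at(pname, p0 + half)]
            elif mode == "grid":
                values = np.linspace(p0 - half, p0 + half, grid_points)
                evals = [averaged_at(pname, v) for v in values]
            else:
                raise ValueError("mode must be 'vertex' or 'grid'")
            arr = np.asarray(evals)
            spread = arr.max(axis=0) - arr.min(axis=0)
            bands[:, col_of[pname], k] = spread[q_idx]
    return FuzzyBand(scenario.label, list(parameters), list(quantities),
                     list(alpha_levels), bands, excluded, max_fraction)
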