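"""Least-squares estimation of Gaussian incidence and remission rates.

The directional derivative of prevalence along cohort lines, obtained
analytically from the fitted prevalence surface, is matched to the
illness-death model right-hand side

    (1-p) i(a) - p r(a) - p (1-p) m(a) (R(a)-1) / (1 + p (R(a)-1))

with i and r each a three-parameter Gaussian in age.  The six coefficients
(amplitude, location, width per rate) minimize the sum of squared residuals
over a grid of evaluation ages.  Minimization uses a derivative-free
Nelder-Mead simplex with deterministic multi-starts; widths are optimized on
the log scale so they stay positive without explicit bounds.  Amplitudes are
left unconstrained during optimization; negative estimates are truncated to
zero only in the reporting tables, with truncation flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .exceptions import ConfigError, EstimationError, InvalidParameterError
from .idm import RateParameterSet

__all__ = [
    "EvaluationGrid",
    "OptimizerConfig",
    "ConvergenceReport",
    "RateEstimateTable",
    "rate_equation_objective",
    "estimate_rates",
    "rates_table",
    "find_peaks",
]

INCIDENCE_SCALE = 1000.0  # incidence reported per 1,000 person-years
REMISSION_SCALE = 100.0   # remission reported per 100 person-years


@dataclass(frozen=True)
class EvaluationGrid:
    """Ages and calendar time at which the model equation is evaluated.

    Ages must lie strictly inside the observable range [19, 74] so the
    prevalence derivative is always interpolated, never extrapolated.
    """

    ages: np.ndarray = field(default_factory=lambda: np.arange(20.0, 74.0))
    t: float = 2017.0
    sex: str | None = None
    center: str | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        if ages.size == 0:
            raise ConfigError("evaluation grid must be non-empty")
        if np.any(np.diff(ages) <= 0):
            raise ConfigError("evaluation ages must be strictly increasing")
        if ages.min() <= 19.0 or ages.max() >= 74.0:
            raise ConfigError("evaluation ages must lie inside [19, 74]")
        object.__setattr__(self, "ages", ages)


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for the multi-start Nelder-Mead minimization."""

    max_iter: int = 4000
    fatol: float = 1e-14
    xatol: float = 1e-9
    n_polish: int = 3
    seed: int | None = None          # accepted for interface symmetry
    starts: tuple | None = None      # optional explicit start tuples
    start: RateParameterSet | None = None  # warm start (used alone if given)


@dataclass
class ConvergenceReport:
    objective: float
    n_evaluations: int
    start_index: int
    converged: bool
    n_starts: int


# Deterministic multi-starts (amp_i, loc_i, wid_i, amp_r, loc_r, wid_r):
# locations sweep {20, 45, 70} and two starts flip an amplitude sign so a
# descent path exists toward negative-amplitude optima as well.
_DEFAULT_STARTS = (
    (0.004, 20.0, 15.0, 0.03, 70.0, 20.0),
    (0.004, 45.0, 15.0, 0.03, 45.0, 20.0),
    (0.004, 70.0, 15.0, 0.03, 20.0, 20.0),
    (0.002, 20.0, 25.0, 0.05, 60.0, 15.0),
    (0.008, 30.0, 10.0, 0.01, 70.0, 25.0),
    (-0.004, 45.0, 15.0, 0.03, 70.0, 20.0),
    (0.004, 20.0, 15.0, -0.03, 70.0, 20.0),
    (0.001, 35.0, 20.0, 0.005, 50.0, 30.0),
)


def _surface_arrays(grid: EvaluationGrid, prev_surface, m_curve, mrr_curve):
    p, dp = prev_surface.prevalence_and_derivative(
        grid.t, grid.ages, grid.sex, grid.center
    )
    p = np.asarray(p, dtype=float)
    dp = np.asarray(dp, dtype=float)
    m = np.asarray(m_curve(grid.ages), dtype=float)
    big_r = np.asarray(mrr_curve(grid.ages), dtype=float)
    if np.any(big_r <= 0):
        raise ConfigError("mortality rate ratio curve must be > 0 on the grid")
    excess = p * (1.0 - p) * m * (big_r - 1.0) / (1.0 + p * (big_r - 1.0))
    return grid.ages, p, dp, excess


def _residuals(theta, ages, p, dp, excess):
    amp_i, loc_i, wid_i, amp_r, loc_r, wid_r = theta
    i = amp_i * np.exp(-(((ages - loc_i) / wid_i) ** 2))
    r = amp_r * np.exp(-(((ages - loc_r) / wid_r) ** 2))
    return dp - ((1.0 - p) * i - p * r - excess)


def rate_equation_objective(
    params: RateParameterSet,
    grid: EvaluationGrid,
    prev_surface,
    m_curve,
    mrr_curve,
) -> float:
    """Sum of squared residuals of the model equation over the grid ages.

    ``prev_surface`` is anything exposing ``prevalence_and_derivative(t,
    ages, sex, center)`` — a fitted prevalence surface or an exact synthetic
    truth surface; ``m_curve`` and ``mrr_curve`` are callables age → value.
    """
    if params.incidence.width <= 0 or params.remission.width <= 0:
        raise InvalidParameterError("Gaussian widths must be > 0")
    ages, p, dp, excess = _surface_arrays(grid, prev_surface, m_curve, mrr_curve)
    res = _residuals(params.as_array(), ages, p, dp, excess)
    return float(res @ res)


def _pack(theta6):
    """Natural parameters -> optimizer vector (log widths)."""
    z = np.asarray(theta6, dtype=float).copy()
    z[2] = np.log(z[2])
    z[5] = np.log(z[5])
    return z


def _unpack(z):
    theta = np.asarray(z, dtype=float).copy()
    # cap log-widths: outside e^±30 years nothing is meaningful, and the
    # bounds keep the simplex away from overflow/zero-division territory
    theta[2] = np.exp(min(max(theta[2], -30.0), 30.0))
    theta[5] = np.exp(min(max(theta[5], -30.0), 30.0))
    return theta


def estimate_rates(
    prev_surface,
    m_curve,
    mrr_curve,
    grid: EvaluationGrid,
    config: OptimizerConfig | None = None,
) -> tuple[RateParameterSet, ConvergenceReport]:
    """Minimize the model-equation sum of squares over the six coefficients.

    Runs Nelder-Mead from each deterministic start (or from the single warm
    start in ``config.start``), keeps the best final objective (ties to the
    lowest start index), then polishes the winner with simplex restarts.
    Fully deterministic for a given configuration.
    """
    config = config or OptimizerConfig()
    ages, p, dp, excess = _surface_arrays(grid, prev_surface, m_curve, mrr_curve)

    n_evals = 0

    def objective(z):
        nonlocal n_evals
        n_evals += 1
        res = _residuals(_unpack(z), ages, p, dp, excess)
        return float(res @ res)

    if config.start is not None:
        starts = (tuple(config.start.as_array()),)
    elif config.starts is not None:
        starts = tuple(config.starts)
    else:
        starts = _DEFAULT_STARTS
    if not starts:
        raise ConfigError("optimizer needs at least one start")

    options = {
        "maxiter": config.max_iter,
        "maxfev": config.max_iter,
        "fatol": config.fatol,
        "xatol": config.xatol,
    }

    best = None
    for idx, s in enumerate(starts):
        z0 = _pack(s)
        res = minimize(objective, z0, method="Nelder-Mead", options=options)
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.fun < best[0] - 1e-300 or (
            res.fun == best[0] and idx < best[2]
        ):
            best = (res.fun, res.x, idx, bool(res.success))
    if best is None:
        raise EstimationError("all optimizer starts failed")

    fbest, zbest, start_idx, success = best
    for _ in range(config.n_polish):
        res = minimize(objective, zbest, method="Nelder-Mead", options=options)
        if np.all(np.isfinite(res.x)) and res.fun < fbest:
            improvement = fbest - res.fun
            fbest, zbest = res.fun, res.x
            success = success or bool(res.success)
            if improvement <= config.fatol * max(1.0, abs(fbest)):
                break
        else:
            break

    params = RateParameterSet.from_array(_unpack(zbest))
    report = ConvergenceReport(
        objective=float(fbest), n_evaluations=n_evals,
        start_index=start_idx, converged=success, n_starts=len(starts),
    )
    return params, report


def find_peaks(params: RateParameterSet, age_range=(19.0, 74.0)) -> dict:
    """Peak (age, value) of each rate over the closed observable age range.

    If a Gaussian's location lies outside the range, the peak clamps to the
    nearest boundary age — the true peak may then lie beyond the observable
    range.  Values are in natural per-person-year units and may be negative
    (for negative amplitudes the truncated reported curve is zero).
    """
    lo, hi = age_range
    out = {}
    for name, g in (("incidence", params.incidence),
                    ("remission", params.remission)):
        if g.amplitude >= 0:
            age = float(np.clip(g.location, lo, hi))
        else:
            # raw curve is maximal where the Gaussian is smallest in |.|
            age = float(lo if abs(lo - g.location) >= abs(hi - g.location) else hi)
        out[name] = (age, float(g(age)))
    return out


@dataclass(frozen=True)
class RateEstimateTable:
    """Reporting table: per-age rates (and CI bands) in publication units.

    Incidence is per 1,000 person-years, remission per 100 person-years;
    negative point estimates or band edges are truncated to zero with
    flags.  Peaks are the maxima of the reported (truncated) curves over
    the table's age grid.
    """

    table: pd.DataFrame
    peak_incidence: tuple
    peak_remission: tuple

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _truncate(values):
    v = np.asarray(values, dtype=float)
    flags = v < 0
    return np.where(flags, 0.0, v), flags


def rates_table(
    params: RateParameterSet,
    ages=None,
    bands: dict | None = None,
) -> RateEstimateTable:
    """Build the reporting table from estimated parameters.

    Parameters
    ----------
    params : RateParameterSet
        Estimated Gaussian coefficients (natural per-PY units).
    ages : array-like, optional
        Reporting ages within [19, 74]; defaults to integer ages 19-74.
    bands : dict, optional
        Output of :func:`idmrates.bootstrap.percentile_band` — per-age
        (lower, upper) tuples under keys "incidence" and "remission", in
        natural units.
    """
    if ages is None:
        ages = np.arange(19, 75)
    ages = np.asarray(ages, dtype=float)
    if ages.min() < 19 or ages.max() > 74:
        raise ConfigError("reporting ages must lie within [19, 74]")

    inc_raw = np.asarray(params.incidence(ages), dtype=float)
    rem_raw = np.asarray(params.remission(ages), dtype=float)
    inc, inc_flag = _truncate(inc_raw)
    rem, rem_flag = _truncate(rem_raw)

    data = {
        "age": ages,
        "incidence_per_1000py": inc * INCIDENCE_SCALE,
        "inc_truncated": inc_flag,
        "remission_per_100py": rem * REMISSION_SCALE,
        "rem_truncated": rem_flag,
    }
    if bands is not None:
        for key, scale, tag in (
            ("incidence", INCIDENCE_SCALE, "inc"),
            ("remission", REMISSION_SCALE, "rem"),
        ):
            lo, hi = bands[key]
            lo_t, lo_flag = _truncate(lo)
            hi_t, hi_flag = _truncate(hi)
            data[f"{tag}_lo"] = lo_t * scale
            data[f"{tag}_hi"] = hi_t * scale
            data[f"{tag}_ci_truncated"] = lo_flag | hi_flag
    table = pd.DataFrame(data)

    k_inc = int(np.argmax(table["incidence_per_1000py"].to_numpy()))
    k_rem = int(np.argmax(table["remission_per_100py"].to_numpy()))
    return RateEstimateTable(
        table=table,
        peak_incidence=(float(ages[k_inc]),
                        float(table["incidence_per_1000py"].iloc[k_inc])),
        peak_remission=(float(ages[k_rem]),
                        float(table["remission_per_100py"].iloc[k_rem])),
    )
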