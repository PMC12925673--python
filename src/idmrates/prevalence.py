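"""Survey-weighted logit-polynomial prevalence surface.

The logit of point prevalence is modeled as a polynomial in age plus a
linear calendar-time term, additive sex and study-center effects, and an
optional age x sex interaction.  The model is fit by weighted binomial
maximum likelihood on cells aggregated per (center, sex, period, age) —
equivalent, up to a constant, to the participant-level weighted likelihood.

The fitted object exposes the exact analytic directional derivative
(d/dt + d/da) p through the chain rule of the logistic link; no finite
differences are involved.  The age-polynomial degrees of freedom are chosen
by leave-one-cell-out cross-validation on squared prediction error of cell
prevalence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConfigError, EmptyDataError, FitError
from .synthetic import PERIOD_MIDPOINTS

__all__ = [
    "AGE_CENTER",
    "AGE_SCALE",
    "T_CENTER",
    "PrevalenceFit",
    "aggregate_cells",
    "fit_logit_polynomial",
    "select_df_loocv",
    "prevalence_and_derivative",
]

AGE_CENTER = 46.5   # midpoint of the 19-74 observable range
AGE_SCALE = 27.5    # half-range; scaled ages span [-1, 1]
T_CENTER = 2017.0   # midpoint between the two cross-section midpoints

_CASE_COLS = {"anxiety": "case_anx", "depression": "case_dep"}
_CELL_KEYS = ["center", "sex", "period", "age"]


def aggregate_cells(records: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Aggregate participant records into weighted binomial cells.

    Applies the complete-case rule first (rows with missing case status for
    the requested condition are dropped), then sums weights and weighted
    cases per (center, sex, period, age) cell.  Cells with zero total weight
    are omitted.

    Returns a DataFrame with columns center, sex, period, age, w_cases,
    w_total, n.
    """
    col = _case_column(condition)
    if records.empty:
        raise EmptyDataError("no participant records supplied")
    complete = records.dropna(subset=[col]).copy()
    if complete.empty:
        raise EmptyDataError(
            f"all records have missing case status for {condition!r}"
        )
    complete["_wc"] = complete["weight"] * complete[col].astype(float)
    g = complete.groupby(_CELL_KEYS, observed=True, sort=True)
    cells = g.agg(
        w_cases=("_wc", "sum"), w_total=("weight", "sum"), n=("weight", "size")
    ).reset_index()
    cells = cells[cells["w_total"] > 0].reset_index(drop=True)
    return cells


def _case_column(condition: str) -> str:
    try:
        return _CASE_COLS[condition]
    except KeyError:
        raise ConfigError(
            f"condition must be one of {sorted(_CASE_COLS)}, got {condition!r}"
        ) from None


@dataclass(frozen=True)
class PrevalenceFit:
    """Fitted logit-scale prevalence surface p(t, a | sex, center).

    Coefficients are stored against named design columns; ages enter as
    centered/scaled powers ((a - age_center) / age_scale)**j so the analytic
    derivative is a simple power-series derivative on the linear predictor.
    """

    params: np.ndarray
    columns: tuple
    df: int
    sexes: tuple
    centers: tuple
    age_sex_interaction: bool
    periods: tuple = (1, 2)
    age_center: float = AGE_CENTER
    age_scale: float = AGE_SCALE
    t_center: float = T_CENTER
    period_midpoints: dict = field(default_factory=lambda: dict(PERIOD_MIDPOINTS))
    age_range: tuple = (19.0, 74.0)

    @property
    def has_time(self) -> bool:
        """Calendar time enters only when more than one cross-section exists."""
        return len(self.periods) > 1

    # -- design construction -------------------------------------------------

    def _design(self, t, age, sex, center, d_age: bool = False):
        """Design matrix rows (or their exact age-derivative)."""
        age = np.atleast_1d(np.asarray(age, dtype=float))
        t = np.broadcast_to(np.asarray(t, dtype=float), age.shape)
        x = (age - self.age_center) / self.age_scale
        n = age.size
        cols = []
        # intercept and time
        cols.append(np.zeros(n) if d_age else np.ones(n))
        for j in range(1, self.df + 1):
            if d_age:
                cols.append(j * x ** (j - 1) / self.age_scale)
            else:
                cols.append(x ** j)
        if self.has_time:
            cols.append(np.zeros(n) if d_age else (t - self.t_center))
        male = None
        if len(self.sexes) > 1:
            male = np.broadcast_to(
                np.asarray(np.asarray(sex) == "male", dtype=float), age.shape
            )
            cols.append(np.zeros(n) if d_age else male)
        if len(self.centers) > 1:
            center_arr = np.broadcast_to(np.asarray(center, dtype=object), age.shape)
            for c in self.centers[1:]:
                ind = np.asarray(center_arr == c, dtype=float)
                cols.append(np.zeros(n) if d_age else ind)
        if self.age_sex_interaction and male is not None:
            for j in range(1, self.df + 1):
                if d_age:
                    cols.append(male * j * x ** (j - 1) / self.age_scale)
                else:
                    cols.append(male * x ** j)
        return np.column_stack(cols)

    # -- evaluation ----------------------------------------------------------

    def linear_predictor(self, t, age, sex=None, center=None):
        return self._design(t, age, sex, center) @ self.params

    def prevalence(self, t, age, sex=None, center=None):
        eta = self.linear_predictor(t, age, sex, center)
        p = 1.0 / (1.0 + np.exp(-eta))
        return p if np.ndim(age) else float(p[0])

    def prevalence_and_derivative(self, t, age, sex=None, center=None):
        """Return (p, dp) with dp = (d/dt + d/da) p, exactly via the chain rule."""
        age_arr = np.atleast_1d(np.asarray(age, dtype=float))
        lo, hi = self.age_range
        if np.any(age_arr < lo) or np.any(age_arr > hi):
            warnings.warn(
                f"evaluating prevalence surface outside the observed "
                f"age range [{lo}, {hi}]", stacklevel=2,
            )
        X = self._design(t, age, sex, center)
        dX = self._design(t, age, sex, center, d_age=True)
        eta = X @ self.params
        # d(eta)/dt is the coefficient of the linear time term (0 if absent)
        dt_slope = self.params[self.df + 1] if self.has_time else 0.0
        deta = dX @ self.params + dt_slope
        p = 1.0 / (1.0 + np.exp(-eta))
        dp = p * (1.0 - p) * deta
        if np.ndim(age):
            return p, dp
        return float(p[0]), float(dp[0])

    # -- persistence ---------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.tolist(),
            "columns": list(self.columns),
            "df": self.df,
            "sexes": list(self.sexes),
            "centers": list(self.centers),
            "age_sex_interaction": self.age_sex_interaction,
            "periods": list(self.periods),
            "age_center": self.age_center,
            "age_scale": self.age_scale,
            "t_center": self.t_center,
            "period_midpoints": {str(k): v for k, v in self.period_midpoints.items()},
            "age_range": list(self.age_range),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PrevalenceFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            params=np.asarray(d["params"]),
            columns=tuple(d["columns"]),
            df=int(d["df"]),
            sexes=tuple(d["sexes"]),
            centers=tuple(d["centers"]),
            age_sex_interaction=bool(d["age_sex_interaction"]),
            periods=tuple(d["periods"]),
            age_center=d["age_center"],
            age_scale=d["age_scale"],
            t_center=d["t_center"],
            period_midpoints={int(k): v for k, v in d["period_midpoints"].items()},
            age_range=tuple(d["age_range"]),
        )


def _column_names(df, sexes, centers, interaction, periods=(1, 2)) -> tuple:
    names = ["const"] + [f"age^{j}" for j in range(1, df + 1)]
    if len(periods) > 1:
        names.append("time")
    if len(sexes) > 1:
        names.append("male")
    if len(centers) > 1:
        names += [f"center[{c}]" for c in centers[1:]]
    if interaction and len(sexes) > 1:
        names += [f"age^{j}:male" for j in range(1, df + 1)]
    return tuple(names)


def _cell_design(cells, df, sexes, centers, interaction, periods):
    meta = PrevalenceFit(
        params=np.zeros(1), columns=(), df=df, sexes=sexes, centers=centers,
        age_sex_interaction=interaction, periods=periods,
    )
    t = cells["period"].map(PERIOD_MIDPOINTS).to_numpy(dtype=float)
    X = meta._design(t, cells["age"].to_numpy(dtype=float),
                     cells["sex"].to_numpy(), cells["center"].to_numpy())
    y = (cells["w_cases"] / cells["w_total"]).to_numpy(dtype=float)
    w = cells["w_total"].to_numpy(dtype=float)
    return X, y, w


def _fit_cells(cells, df, sexes, centers, interaction, periods=(1, 2),
               start_params=None):
    X, y, w = _cell_design(cells, df, sexes, centers, interaction, periods)
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start_params, maxiter=200)
    if not np.all(np.isfinite(res.params)):
        raise FitError(
            f"non-finite coefficients for df={df} "
            "(possible separation or degenerate cells)"
        )
    if not getattr(res, "converged", True):
        raise FitError(f"IRLS did not converge for df={df}")
    return res.params, X, y


def _irls_logit(X, y, w, start, maxiter=25, tol=1e-10):
    """Minimal weighted-logistic IRLS used for the many LOOCV refits.

    Same weighted binomial likelihood as the statsmodels fit (verified in
    tests); implemented inline because cross-validation refits the model
    once per held-out cell and the per-fit overhead dominates otherwise.
    """
    beta = np.asarray(start, dtype=float).copy()
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wt = w * mu * (1.0 - mu)
        wt = np.maximum(wt, 1e-12)
        z = eta + (y - mu) / (mu * (1.0 - mu) + 1e-300)
        xtw = X.T * wt
        beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        if not np.all(np.isfinite(beta_new)):
            raise FitError("IRLS produced non-finite coefficients")
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            return beta_new
        beta = beta_new
    return beta


def fit_logit_polynomial(
    records: pd.DataFrame,
    condition: str,
    df: int = 3,
    age_sex_interaction: bool = True,
) -> PrevalenceFit:
    """Fit the weighted logit-polynomial prevalence model.

    Parameters
    ----------
    records : DataFrame
        Participant records (see the synthetic generator for the schema).
        Rows with missing case status for ``condition`` are dropped.
    condition : {"anxiety", "depression"}
    df : int
        Age-polynomial degrees of freedom (1-6); df=3 means a cubic.
    age_sex_interaction : bool
        Whether each sex gets its own age-polynomial shape (default True).
    """
    if not 1 <= df <= 6:
        raise ConfigError(f"df must be in 1..6, got {df}")
    cells = records if _is_cells(records) else aggregate_cells(records, condition)
    if cells.groupby(["center", "sex", "period"], observed=True)["age"].nunique().min() < 2:
        raise FitError("need >= 2 distinct ages per stratum")
    sexes = tuple(sorted(cells["sex"].unique()))
    centers = tuple(sorted(cells["center"].unique()))
    periods = tuple(int(p) for p in sorted(cells["period"].unique()))
    params, _, _ = _fit_cells(cells, df, sexes, centers, age_sex_interaction,
                              periods)
    age = cells["age"].to_numpy(dtype=float)
    return PrevalenceFit(
        params=params,
        columns=_column_names(df, sexes, centers, age_sex_interaction, periods),
        df=df, sexes=sexes, centers=centers,
        age_sex_interaction=age_sex_interaction, periods=periods,
        age_range=(float(age.min()), float(age.max())),
    )


def _is_cells(frame: pd.DataFrame) -> bool:
    return {"w_cases", "w_total"}.issubset(frame.columns)


def select_df_loocv(
    data: pd.DataFrame,
    condition: str | None = None,
    candidate_dfs=(1, 2, 3, 4, 5),
    age_sex_interaction: bool = True,
) -> int:
    """Choose the age-polynomial df by leave-one-cell-out cross-validation.

    For each candidate df, every aggregated cell is in turn held out, the
    model refit, and the held-out cell's prevalence predicted; the df with
    the smallest mean squared prediction error (probability scale) wins,
    ties broken toward the smaller df.

    ``data`` may be raw participant records (``condition`` then required)
    or an already-aggregated cell table.
    """
    candidate_dfs = tuple(candidate_dfs)
    if not candidate_dfs:
        raise ConfigError("candidate df set must be non-empty")
    if _is_cells(data):
        cells = data
    else:
        if condition is None:
            raise ConfigError("condition is required with raw records")
        cells = aggregate_cells(data, condition)
    n_cells = len(cells)
    if n_cells < 2:
        raise EmptyDataError("need at least 2 cells for cross-validation")
    if len(candidate_dfs) == 1:
        return candidate_dfs[0]

    sexes = tuple(sorted(cells["sex"].unique()))
    centers = tuple(sorted(cells["center"].unique()))
    periods = tuple(sorted(cells["period"].unique()))

    scores = {}
    for df in candidate_dfs:
        full_params, X, y = _fit_cells(cells, df, sexes, centers,
                                       age_sex_interaction, periods)
        w = cells["w_total"].to_numpy(dtype=float)
        sq_err = np.empty(n_cells)
        keep = np.ones(n_cells, dtype=bool)
        for i in range(n_cells):
            keep[i] = False
            try:
                beta = _irls_logit(X[keep], y[keep], w[keep], full_params)
            except (FitError, np.linalg.LinAlgError):
                sq_err[i] = np.nan
                keep[i] = True
                continue
            keep[i] = True
            pred = 1.0 / (1.0 + np.exp(-(X[i] @ beta)))
            sq_err[i] = (pred - y[i]) ** 2
        scores[df] = float(np.nanmean(sq_err))

    return min(scores, key=lambda d: (scores[d], d))


def prevalence_and_derivative(fit: PrevalenceFit, t, age, sex=None, center=None):
    """Functional alias for :meth:`PrevalenceFit.prevalence_and_derivative`."""
    return fit.prevalence_and_derivative(t, age, sex, center)
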