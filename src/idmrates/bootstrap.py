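"""Nonparametric bootstrap of the full estimation pipeline.

Participants are resampled with replacement within (center, period) strata —
preserving the two-cross-section design — carrying their survey weights.
Each replicate re-runs complete-case filtering, the prevalence fit (at the
fixed, previously selected df), and the least-squares rate estimation,
warm-started at the point estimate.  Percentile confidence bands are taken
from the empirical replicate quantiles; negative band edges are truncated to
zero only after the percentiles are computed.

Replicate seeds derive from the master seed by a counter scheme
(``default_rng([master_seed, b])``), so the ensemble is independent of
execution order and parallel workers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .estimation import EvaluationGrid, OptimizerConfig, estimate_rates
from .exceptions import ConfigError, EnsembleError
from .prevalence import (
    PrevalenceFit,
    _cell_design,
    _column_names,
    _irls_logit,
    fit_logit_polynomial,
)

__all__ = ["BootstrapEnsemble", "bootstrap_rates", "percentile_band"]


@dataclass
class BootstrapEnsemble:
    """Converged replicate rate curves on the reporting grid."""

    ages: np.ndarray
    incidence: np.ndarray     # (n_kept, n_ages), per PY
    remission: np.ndarray     # (n_kept, n_ages), per PY
    params: list = field(repr=False)
    n_requested: int = 0
    n_failed: int = 0
    master_seed: int | None = None

    @property
    def n_kept(self) -> int:
        return self.incidence.shape[0]


def bootstrap_rates(
    records: pd.DataFrame,
    condition: str,
    df: int,
    grid: EvaluationGrid,
    m_curve,
    mrr_curve,
    B: int,
    seed: int,
    age_sex_interaction: bool = True,
    start=None,
    n_jobs: int = 1,
    max_failure_fraction: float = 0.2,
) -> BootstrapEnsemble:
    """Bootstrap the prevalence-fit → rate-estimation pipeline.

    Parameters
    ----------
    records : DataFrame
        Participant records (pre-complete-case; filtering is re-applied in
        every replicate).
    condition : {"anxiety", "depression"}
    df : int
        Age-polynomial degrees of freedom, fixed across replicates (the
        cross-validated selection is not repeated inside the bootstrap).
    grid : EvaluationGrid
        Stratum and ages on which replicate rate curves are stored.
    m_curve, mrr_curve : callables
        Smooth mortality and rate-ratio curves (held fixed; they come from
        external tabulations, not from the resampled survey).
    B : int
        Number of bootstrap replicates.
    seed : int
        Master seed; replicate b uses ``default_rng([seed, b])``.
    start : RateParameterSet, optional
        Warm start for replicate estimations; defaults to the point
        estimate computed from the full data.
    n_jobs : int
        joblib workers; results are identical for any worker count.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")

    point_fit = fit_logit_polynomial(records, condition, df,
                                     age_sex_interaction=age_sex_interaction)
    if start is None:
        start, _ = estimate_rates(point_fit, m_curve, mrr_curve, grid)

    sexes, centers = point_fit.sexes, point_fit.centers
    periods = point_fit.periods
    groups = records.groupby(["center", "period"], observed=True, sort=True)
    group_indices = [np.asarray(idx) for _, idx in groups.indices.items()]
    start_glm = point_fit.params
    columns = _column_names(df, sexes, centers, age_sex_interaction, periods)
    # moderate simplex tolerances: replicate-level noise dominates
    opt = dict(max_iter=2000, fatol=1e-12, xatol=1e-7, n_polish=1)

    # Precompute per-row cell codes and weighted case contributions so each
    # replicate reduces to two bincounts plus an IRLS refit on the fixed
    # cell universe (the pandas aggregation is only needed once).
    col = {"anxiety": "case_anx", "depression": "case_dep"}[condition]
    notna = records[col].notna().to_numpy()
    w_row = records["weight"].to_numpy(dtype=float)
    case_row = records[col].fillna(0).to_numpy(dtype=float)
    wc_row = w_row * case_row
    cell_keys = ["center", "sex", "period", "age"]
    cell_grp = records.groupby(cell_keys, observed=True, sort=True)
    codes = cell_grp.ngroup().to_numpy()
    universe = cell_grp.size().reset_index()[cell_keys]
    universe["w_cases"] = 0.0
    universe["w_total"] = 1.0
    n_cells = len(universe)
    X_univ, _, _ = _cell_design(universe, df, sexes, centers,
                                age_sex_interaction, periods)

    def one(b):
        rng = np.random.default_rng([seed, b])
        ridx = np.concatenate([
            idx[rng.integers(0, idx.size, size=idx.size)]
            for idx in group_indices
        ])
        keep = notna[ridx]
        c = codes[ridx][keep]
        wt = np.bincount(c, weights=w_row[ridx][keep], minlength=n_cells)
        wc = np.bincount(c, weights=wc_row[ridx][keep], minlength=n_cells)
        mask = wt > 0
        try:
            beta = _irls_logit(X_univ[mask], wc[mask] / wt[mask], wt[mask],
                               start_glm)
            fit = PrevalenceFit(
                params=beta, columns=columns,
                df=df, sexes=sexes, centers=centers,
                age_sex_interaction=age_sex_interaction, periods=periods,
            )
            est, report = estimate_rates(
                fit, m_curve, mrr_curve, grid,
                OptimizerConfig(start=start, **opt),
            )
        except Exception:
            return None
        if not np.all(np.isfinite(est.as_array())):
            return None
        return est

    if n_jobs == 1:
        results = [one(b) for b in range(B)]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(one)(b) for b in range(B))

    kept = [est for est in results if est is not None]
    n_failed = B - len(kept)
    if n_failed > max_failure_fraction * B:
        raise EnsembleError(
            f"{n_failed}/{B} bootstrap replicates failed to converge"
        )
    ages = grid.ages
    incidence = np.array([est.incidence(ages) for est in kept])
    remission = np.array([est.remission(ages) for est in kept])
    return BootstrapEnsemble(
        ages=ages, incidence=incidence, remission=remission,
        params=kept, n_requested=B, n_failed=n_failed, master_seed=seed,
    )


def percentile_band(
    ensemble: BootstrapEnsemble,
    level: float = 0.95,
    truncate: bool = True,
) -> dict:
    """Per-age percentile confidence band from the bootstrap ensemble.

    Uses linear-interpolation empirical percentiles (numpy's default rule)
    at (1-level)/2 and 1-(1-level)/2.  With ``truncate`` (the reporting
    convention) negative band edges are set to zero *after* the percentile
    computation.

    Returns ``{"incidence": (lower, upper), "remission": (lower, upper)}``
    in natural per-person-year units.
    """
    if not 0.0 < level < 1.0:
        raise ConfigError(f"level must be in (0, 1), got {level}")
    if ensemble.n_kept < 2:
        raise EnsembleError("need >= 2 converged replicates for a band")
    q_lo, q_hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    out = {}
    for name, mat in (("incidence", ensemble.incidence),
                      ("remission", ensemble.remission)):
        lo = np.percentile(mat, q_lo, axis=0)
        hi = np.percentile(mat, q_hi, axis=0)
        if truncate:
            lo = np.maximum(lo, 0.0)
            hi = np.maximum(hi, 0.0)
        out[name] = (lo, hi)
    return out


def write_ensemble_csv(ensemble: BootstrapEnsemble, path) -> None:
    """Persist the ensemble as tidy CSV (replicate, age, incidence, remission)."""
    n, a = ensemble.incidence.shape
    df = pd.DataFrame({
        "replicate": np.repeat(np.arange(n), a),
        "age": np.tile(ensemble.ages, n),
        "incidence": ensemble.incidence.ravel(),
        "remission": ensemble.remission.ravel(),
    })
    df.to_csv(path, index=False)
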