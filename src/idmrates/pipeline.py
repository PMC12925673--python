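"""End-to-end analysis orchestration.

A single :class:`AnalysisConfig` (YAML-loadable) drives the whole chain:
obtain data (synthetic with known truth, or user-supplied CSVs), select the
age-polynomial df by cross-validation, fit the prevalence surface, smooth
the mortality inputs, estimate the Gaussian incidence/remission coefficients
per (condition, sex, center), optionally bootstrap confidence bands and
re-estimate under mortality-rate-ratio perturbations, and write a
deterministic file bundle.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import synthetic as syn
from .bootstrap import bootstrap_rates, percentile_band, write_ensemble_csv
from .estimation import (
    EvaluationGrid,
    OptimizerConfig,
    estimate_rates,
    find_peaks,
    rates_table,
)
from .exceptions import ConfigError
from .mortality import fit_log_mortality, fit_mrr, perturb_mrr
from .prevalence import aggregate_cells, fit_logit_polynomial, select_df_loocv

__all__ = ["AnalysisConfig", "StratumResult", "run_study_analysis", "write_outputs"]


@dataclass
class AnalysisConfig:
    """Configuration for one full analysis run.

    Exactly one of ``participants`` (with ``mortality`` and ``mrr`` paths)
    or ``synthetic`` must be provided.
    """

    participants: str | None = None
    mortality: str | None = None
    mrr: str | None = None
    synthetic: dict | None = None
    conditions: tuple = ("anxiety", "depression")
    df: int | None = None
    df_candidates: tuple = (1, 2, 3, 4, 5)
    age_sex_interaction: bool = True
    grid_age_min: int = 20
    grid_age_max: int = 73
    bootstrap_B: int = 0
    mrr_factors: tuple = ()
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        has_paths = self.participants is not None
        has_syn = self.synthetic is not None
        if has_paths == has_syn:
            raise ConfigError(
                "exactly one of `participants` or `synthetic` must be set"
            )
        if has_paths and (self.mortality is None or self.mrr is None):
            raise ConfigError(
                "`mortality` and `mrr` paths are required with `participants`"
            )
        if self.bootstrap_B < 0:
            raise ConfigError("bootstrap_B must be >= 0 (0 skips CIs)")
        if any(f <= 0 for f in self.mrr_factors):
            raise ConfigError("mrr perturbation factors must be > 0")
        self.conditions = tuple(self.conditions)
        self.df_candidates = tuple(self.df_candidates)
        self.mrr_factors = tuple(self.mrr_factors)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["conditions"] = list(self.conditions)
        data["df_candidates"] = list(self.df_candidates)
        data["mrr_factors"] = list(self.mrr_factors)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class StratumResult:
    """Everything estimated for one (condition, sex, center)."""

    condition: str
    sex: str
    center: str
    params: object
    report: object
    table: object                  # RateEstimateTable
    peaks: dict
    ensemble: object = None
    sensitivity: pd.DataFrame | None = None


def _load_inputs(config: AnalysisConfig):
    """Return (records, mortality tables per sex, MRR tables per condition, log)."""
    log = []
    if config.synthetic is not None:
        block = dict(config.synthetic)
        truth_cfg = syn.TruthConfig(**block.pop("truth", {}))
        n = int(block.pop("n_per_stratum", 2000))
        centers = tuple(block.pop("centers", syn.DEFAULT_CENTERS))
        sexes = tuple(block.pop("sexes", syn.SEXES))
        missingness = float(block.pop("missingness", 0.06))
        dispersion = float(block.pop("weight_dispersion", 0.3))
        if block:
            raise ConfigError(f"unknown synthetic keys: {sorted(block)}")
        truth = syn.make_truth(truth_cfg, centers=centers)
        records = syn.sample_study(
            truth, n, centers=centers, sexes=sexes,
            missingness=missingness, weight_dispersion=dispersion,
            seed=config.seed,
        )
        mort = {s: truth.stratum(s, "anxiety").mortality_table(s) for s in sexes}
        mrr = {c: truth.stratum(sexes[0], c).mrr_table(c)
               for c in config.conditions}
        log.append(f"synthetic study: n_per_stratum={n}, centers={centers}, "
                   f"sexes={sexes}, missingness={missingness}, "
                   f"weight_dispersion={dispersion}")
        return records, mort, mrr, truth, log

    records = syn.read_participants(config.participants)
    sexes = tuple(sorted(records["sex"].unique()))
    mort = {s: syn.MortalityTable.from_csv(config.mortality, sex=s)
            for s in sexes}
    mrr = {c: syn.MRRCurve.from_csv(config.mrr, condition=c)
           for c in config.conditions}
    log.append(f"loaded {len(records)} participant records "
               f"from {config.participants}")
    return records, mort, mrr, None, log


def run_study_analysis(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns a result bundle (dict).

    Bundle keys: ``config``, ``df`` (selected df per condition),
    ``results`` (mapping (condition, sex, center) -> StratumResult),
    ``log`` (list of str).
    """
    records, mort_tables, mrr_tables, truth, log = _load_inputs(config)
    log.append(f"seed={config.seed}")

    sexes = tuple(sorted(records["sex"].unique()))
    centers = tuple(sorted(records["center"].unique()))
    grid_ages = np.arange(config.grid_age_min, config.grid_age_max + 1, dtype=float)
    m_curves = {s: fit_log_mortality(mort_tables[s]) for s in sexes}

    results = {}
    df_by_condition = {}
    for condition in config.conditions:
        cells = aggregate_cells(records, condition)
        if config.df is not None:
            df = config.df
            log.append(f"{condition}: df fixed at {df}")
        else:
            df = select_df_loocv(cells, candidate_dfs=config.df_candidates,
                                 age_sex_interaction=config.age_sex_interaction)
            log.append(f"{condition}: LOOCV selected df={df} "
                       f"from {config.df_candidates}")
        df_by_condition[condition] = df
        prev_fit = fit_logit_polynomial(
            records, condition, df,
            age_sex_interaction=config.age_sex_interaction,
        )
        mrr_smooth = fit_mrr(mrr_tables[condition])

        for sex in sexes:
            for center in centers:
                grid = EvaluationGrid(ages=grid_ages, sex=sex, center=center)
                try:
                    params, report = estimate_rates(
                        prev_fit, m_curves[sex], mrr_smooth, grid,
                        OptimizerConfig(seed=config.seed),
                    )
                except Exception as exc:
                    raise type(exc)(
                        f"[estimation | {condition}/{sex}/{center}] {exc}"
                    ) from exc

                ensemble = bands = None
                if config.bootstrap_B > 0:
                    ensemble = bootstrap_rates(
                        records, condition, df, grid,
                        m_curves[sex], mrr_smooth,
                        B=config.bootstrap_B, seed=config.seed,
                        age_sex_interaction=config.age_sex_interaction,
                        start=params, n_jobs=config.n_jobs,
                    )
                    bands = percentile_band(ensemble)
                    log.append(
                        f"{condition}/{sex}/{center}: bootstrap B="
                        f"{config.bootstrap_B}, failed={ensemble.n_failed}"
                    )
                table = rates_table(params, ages=grid_ages, bands=bands)
                peaks = find_peaks(params)
                log.append(
                    f"{condition}/{sex}/{center}: objective="
                    f"{report.objective:.3e}, converged={report.converged}, "
                    f"truncated_ages="
                    f"{int(table.table['inc_truncated'].sum())}+"
                    f"{int(table.table['rem_truncated'].sum())}"
                )

                sens = None
                if config.mrr_factors:
                    rows = []
                    for label, factor in [("base", 1.0)] + [
                        (f"x{f:g}", f) for f in config.mrr_factors
                    ]:
                        curve = (mrr_smooth if factor == 1.0
                                 else perturb_mrr(mrr_smooth, factor))
                        p_f, _ = estimate_rates(
                            prev_fit, m_curves[sex], curve, grid,
                            OptimizerConfig(start=params),
                        ) if factor != 1.0 else (params, None)
                        t_f = rates_table(p_f, ages=grid_ages)
                        sub = t_f.table[["age", "incidence_per_1000py",
                                         "remission_per_100py"]].copy()
                        sub.insert(0, "scenario", label)
                        sub.insert(1, "mrr_factor", factor)
                        rows.append(sub)
                    sens = pd.concat(rows, ignore_index=True)
                    log.append(f"{condition}/{sex}/{center}: sensitivity "
                               f"factors {config.mrr_factors}")

                results[(condition, sex, center)] = StratumResult(
                    condition=condition, sex=sex, center=center,
                    params=params, report=report, table=table, peaks=peaks,
                    ensemble=ensemble, sensitivity=sens,
                )

    return {
        "config": config,
        "df": df_by_condition,
        "results": results,
        "truth": truth,
        "log": log,
    }


def _slug(*parts) -> str:
    return "_".join(str(p).replace(" ", "-") for p in parts)


def write_outputs(bundle: dict, directory, force: bool = False) -> list:
    """Write the bundle to ``directory``; refuses to overwrite without force.

    Emits rates_/params_/sensitivity_/ensemble_ files per stratum plus
    ``run_log.txt`` and ``config_echo.yaml``.  Returns the written paths.
    """
    directory = os.fspath(directory)
    if os.path.isdir(directory) and os.listdir(directory) and not force:
        raise FileExistsError(
            f"output directory {directory!r} is non-empty; pass force=True "
            "(--force) to overwrite"
        )
    os.makedirs(directory, exist_ok=True)
    written = []

    def path(name):
        p = os.path.join(directory, name)
        written.append(p)
        return p

    import json

    for key, res in bundle.get("results", {}).items():
        slug = _slug(*key)
        res.table.to_csv(path(f"rates_{slug}.csv"))
        payload = {
            "incidence": dataclasses.asdict(res.params.incidence),
            "remission": dataclasses.asdict(res.params.remission),
            "objective": res.report.objective,
            "converged": res.report.converged,
            "start_index": res.report.start_index,
            "peaks": {k: {"age": v[0], "value_per_py": v[1]}
                      for k, v in res.peaks.items()},
            "df": bundle["df"][res.condition],
        }
        with open(path(f"params_{slug}.json"), "w") as fh:
            json.dump(payload, fh, indent=2)
        if res.sensitivity is not None:
            res.sensitivity.to_csv(path(f"sensitivity_{slug}.csv"), index=False)
        if res.ensemble is not None:
            write_ensemble_csv(res.ensemble, path(f"ensemble_{slug}.csv"))

    with open(path("run_log.txt"), "w") as fh:
        fh.write("\n".join(bundle.get("log", [])) + "\n")
    bundle["config"].to_yaml(path("config_echo.yaml"))
    return written
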