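"""Synthetic study generator with known illness-death ground truth.

Emulates the structure of a large multi-center cross-sectional survey of
moderate-to-severe anxiety/depressive symptoms: two cross-sections (calendar
midpoints 2015.5 and 2018.5), five study centers, ages 19–74, per-participant
correction weights, and binary case status per condition from a screening
cut-off.  Case status is drawn binomially from a prevalence surface that is
itself produced by the forward illness-death cohort solver, so every
downstream estimation stage can be validated against exact ground truth.

True transition rates are time-constant: both cross-sections then share a
single prevalence curve p(a) and the directional derivative (∂t + ∂a)p
equals dp/da along a cohort, the cleanest identifiable test-bed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .idm import GaussianRate, RateParameterSet, pde_rhs_mrr, solve_cohort_prevalence

__all__ = [
    "SEXES",
    "CONDITIONS",
    "DEFAULT_CENTERS",
    "PERIOD_MIDPOINTS",
    "TruthConfig",
    "StratumTruth",
    "SyntheticTruth",
    "TruthSurface",
    "MortalityTable",
    "MRRCurve",
    "make_truth",
    "make_mortality_table",
    "make_mrr_curve",
    "sample_study",
    "write_participants",
    "read_participants",
]

SEXES = ("female", "male")
CONDITIONS = ("anxiety", "depression")
DEFAULT_CENTERS = ("Augsburg", "Freiburg", "Münster", "Berlin", "Hamburg")
PERIOD_MIDPOINTS = {1: 2015.5, 2: 2018.5}

AGE_MIN = 19
AGE_MAX = 74


@dataclass(frozen=True)
class MortalityTable:
    """Age-indexed general mortality rates for one sex (life-table style)."""

    sex: str
    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        if ages.size != rates.size:
            raise ConfigError("ages and rates must have equal length")
        if np.any(np.diff(ages) <= 0):
            raise ConfigError("ages must be strictly increasing")
        if np.any(rates < 0):
            raise ConfigError("mortality rates must be >= 0")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": self.ages, "sex": self.sex, "rate": self.rates}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sex: str | None = None) -> "MortalityTable":
        df = pd.read_csv(path)
        if sex is not None and "sex" in df.columns:
            df = df[df["sex"] == sex]
        if df.empty:
            raise ConfigError(f"no mortality rows found in {path} for sex={sex}")
        label = sex if sex is not None else (
            str(df["sex"].iloc[0]) if "sex" in df.columns else "all"
        )
        return cls(sex=label, ages=df["age"].to_numpy(),
                   rates=df["rate"].to_numpy())


@dataclass(frozen=True)
class MRRCurve:
    """Age-indexed mortality rate ratios (diseased vs susceptible)."""

    condition: str
    ages: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        ratios = np.asarray(self.ratios, dtype=float)
        if ages.size != ratios.size:
            raise ConfigError("ages and ratios must have equal length")
        if np.any(np.diff(ages) <= 0):
            raise ConfigError("ages must be strictly increasing")
        if np.any(ratios <= 0):
            raise ConfigError("mortality rate ratios must be > 0")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "ratios", ratios)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": self.ages, "condition": self.condition, "ratio": self.ratios}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: str | None = None) -> "MRRCurve":
        df = pd.read_csv(path)
        if condition is not None and "condition" in df.columns:
            df = df[df["condition"] == condition]
        if df.empty:
            raise ConfigError(f"no MRR rows found in {path} for {condition}")
        label = condition if condition is not None else (
            str(df["condition"].iloc[0]) if "condition" in df.columns else "all"
        )
        return cls(condition=label, ages=df["age"].to_numpy(),
                   ratios=df["ratio"].to_numpy())


def make_mortality_table(intercept: float, slope: float, ages=None,
                         sex: str = "female") -> MortalityTable:
    """Gompertz-type mortality fixture: ``m(a) = intercept * exp(slope * (a - 19))``."""
    if intercept < 0:
        raise ConfigError(f"Gompertz intercept must be >= 0, got {intercept}")
    if ages is None:
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
    ages = np.asarray(ages)
    rates = intercept * np.exp(slope * (ages - AGE_MIN))
    return MortalityTable(sex=sex, ages=ages, rates=rates)


def make_mrr_curve(base: float, age_slope: float = 0.0, ages=None,
                   condition: str = "anxiety") -> MRRCurve:
    """Age-linear MRR fixture: ``R(a) = base + age_slope * (a - 19)``."""
    if ages is None:
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
    ages = np.asarray(ages)
    ratios = base + age_slope * (ages - AGE_MIN)
    if np.any(ratios <= 0):
        raise ConfigError("MRR curve must be > 0 at all tabulated ages")
    return MRRCurve(condition=condition, ages=ages, ratios=ratios)


@dataclass(frozen=True)
class TruthConfig:
    """Generating parameters for one (sex, condition) stratum.

    Defaults describe a plausible remitting common-mental-disorder setting:
    incidence peaking at the young end of the observable range, remission
    rising into old age, Gompertz susceptible mortality and a constant
    twofold mortality rate ratio.
    """

    incidence_amplitude: float = 0.004   # per PY
    incidence_location: float = 20.0     # years
    incidence_width: float = 18.0        # years
    remission_amplitude: float = 0.04    # per PY
    remission_location: float = 72.0     # years
    remission_width: float = 20.0        # years
    gompertz_intercept: float = 1e-4     # m0 at age 19, per PY
    gompertz_slope: float = 0.09         # per year of age
    mrr_base: float = 2.0
    mrr_slope: float = 0.0               # per year of age
    p_start: float = 0.05                # prevalence at age 19
    age_min: int = AGE_MIN
    age_max: int = AGE_MAX

    def rates(self) -> RateParameterSet:
        return RateParameterSet(
            incidence=GaussianRate(self.incidence_amplitude,
                                   self.incidence_location,
                                   self.incidence_width),
            remission=GaussianRate(self.remission_amplitude,
                                   self.remission_location,
                                   self.remission_width),
        )

    def validate(self) -> None:
        if not 0.0 <= self.p_start <= 1.0:
            raise ConfigError(f"p_start must be in [0, 1], got {self.p_start}")
        if self.gompertz_intercept < 0:
            raise ConfigError("gompertz_intercept must be >= 0")
        ages = np.array([self.age_min, self.age_max], dtype=float)
        if np.any(self.mrr_base + self.mrr_slope * (ages - self.age_min) <= 0):
            raise ConfigError("MRR must stay > 0 over the age range")
        self.rates()  # raises on non-positive widths


@dataclass(frozen=True)
class StratumTruth:
    """Ground truth for one (sex, condition): rates plus derived p(a)."""

    config: TruthConfig
    rates: RateParameterSet
    _grid: np.ndarray = field(repr=False)
    _prevalence: np.ndarray = field(repr=False)

    def incidence(self, age):
        return self.rates.incidence(age)

    def remission(self, age):
        return self.rates.remission(age)

    def mort_susceptible(self, age):
        c = self.config
        return c.gompertz_intercept * np.exp(c.gompertz_slope * (np.asarray(age, dtype=float) - c.age_min))

    def mrr(self, age):
        c = self.config
        return c.mrr_base + c.mrr_slope * (np.asarray(age, dtype=float) - c.age_min)

    def mort_diseased(self, age):
        return self.mrr(age) * self.mort_susceptible(age)

    def prevalence(self, age):
        return np.interp(np.asarray(age, dtype=float), self._grid, self._prevalence)

    def general_mortality(self, age):
        """Population mortality m = (1-p) m0 + p m1 implied by the truth."""
        p = self.prevalence(age)
        m0 = self.mort_susceptible(age)
        return m0 * (1.0 + p * (self.mrr(age) - 1.0))

    def prevalence_derivative(self, age):
        """dp/da from the model equation itself (exactly consistent with p)."""
        return pde_rhs_mrr(self.prevalence(age), self.incidence(age),
                           self.remission(age), self.general_mortality(age),
                           self.mrr(age))

    def mortality_table(self, sex: str, ages=None) -> MortalityTable:
        if ages is None:
            ages = np.arange(self.config.age_min, self.config.age_max + 1)
        return MortalityTable(sex=sex, ages=np.asarray(ages),
                              rates=self.general_mortality(np.asarray(ages, dtype=float)))

    def mrr_table(self, condition: str, ages=None) -> MRRCurve:
        if ages is None:
            ages = np.arange(self.config.age_min, self.config.age_max + 1)
        return MRRCurve(condition=condition, ages=np.asarray(ages),
                        ratios=self.mrr(np.asarray(ages, dtype=float)))


@dataclass(frozen=True)
class SyntheticTruth:
    """Full study truth: per-(sex, condition) strata plus design constants."""

    strata: dict
    centers: tuple = DEFAULT_CENTERS
    period_midpoints: dict = field(default_factory=lambda: dict(PERIOD_MIDPOINTS))

    def stratum(self, sex: str, condition: str) -> StratumTruth:
        return self.strata[(sex, condition)]

    def surface(self, sex: str, condition: str) -> "TruthSurface":
        return TruthSurface(self.stratum(sex, condition))


@dataclass(frozen=True)
class TruthSurface:
    """Exact prevalence surface of a truth stratum.

    Provides the same ``prevalence_and_derivative`` interface as a fitted
    prevalence model, for noiseless (no-sampling) validation of the rate
    estimator.  Rates are time-constant, so calendar time is ignored.
    """

    truth: StratumTruth

    def prevalence_and_derivative(self, t, age, sex=None, center=None):
        p = self.truth.prevalence(age)
        dp = self.truth.prevalence_derivative(age)
        return p, dp


def _build_stratum(config: TruthConfig, step: float = 0.1) -> StratumTruth:
    config.validate()
    rates = config.rates()
    grid = np.round(np.arange(config.age_min, config.age_max + step / 2, step), 10)
    c = config

    def m0(a):
        return c.gompertz_intercept * np.exp(c.gompertz_slope * (a - c.age_min))

    def m1(a):
        return (c.mrr_base + c.mrr_slope * (a - c.age_min)) * m0(a)

    prev = solve_cohort_prevalence(
        c.p_start, c.age_min, grid,
        incidence=rates.incidence, remission=rates.remission,
        mort_susceptible=m0, mort_diseased=m1, max_step=step,
    )
    if np.any(prev < 0) or np.any(prev > 1):
        raise ConfigError("configuration produced prevalence outside [0, 1]")
    return StratumTruth(config=config, rates=rates, _grid=grid, _prevalence=prev)


def make_truth(config=None, seed=None, centers=DEFAULT_CENTERS) -> SyntheticTruth:
    """Build the study ground truth (deterministic given the configuration).

    Parameters
    ----------
    config : TruthConfig, dict, or mapping of (sex, condition) -> TruthConfig
        A single config is shared by all four (sex, condition) strata;
        a dict of per-stratum configs overrides individual strata.
    seed : int, optional
        Accepted for interface symmetry; the truth itself is deterministic.
    """
    if config is None:
        config = TruthConfig()
    if isinstance(config, dict) and not all(
        isinstance(k, tuple) for k in config
    ):
        config = TruthConfig(**config)

    if isinstance(config, TruthConfig):
        per_stratum = {(s, c): config for s in SEXES for c in CONDITIONS}
    else:
        base = TruthConfig()
        per_stratum = {}
        for s in SEXES:
            for c in CONDITIONS:
                cfg = config.get((s, c), base)
                if isinstance(cfg, dict):
                    cfg = TruthConfig(**cfg)
                per_stratum[(s, c)] = cfg

    cache: dict[TruthConfig, StratumTruth] = {}
    strata = {}
    for key, cfg in per_stratum.items():
        if cfg not in cache:
            cache[cfg] = _build_stratum(cfg)
        strata[key] = cache[cfg]
    return SyntheticTruth(strata=strata, centers=tuple(centers))


def default_truth(**overrides) -> SyntheticTruth:
    """The default study truth, optionally with TruthConfig field overrides."""
    return make_truth(replace(TruthConfig(), **overrides))


_CASE_COLS = {"anxiety": "case_anx", "depression": "case_dep"}


def sample_study(
    truth: SyntheticTruth,
    n_per_stratum: int,
    centers=None,
    sexes=SEXES,
    periods=(1, 2),
    missingness: float = 0.06,
    weight_dispersion: float = 0.3,
    seed=None,
) -> pd.DataFrame:
    """Draw participant records for each (center, sex, period) stratum.

    Ages are uniform on {19..74}; per-condition case status is Bernoulli
    with the truth's prevalence at the drawn age; weights are gamma with
    mean 1 and the given coefficient of variation; case indicators are set
    missing independently at the given rate (complete-case filtering is a
    downstream responsibility).
    """
    if n_per_stratum < 1:
        raise ConfigError("n_per_stratum must be >= 1")
    if not 0.0 <= missingness < 1.0:
        raise ConfigError("missingness must be in [0, 1)")
    centers = tuple(centers) if centers is not None else truth.centers
    sexes = tuple(sexes)
    periods = tuple(periods)
    if not centers or not sexes or not periods:
        raise ConfigError("strata specification must be non-empty")

    rng = np.random.default_rng(seed)
    cfg0 = next(iter(truth.strata.values())).config
    ages_all = np.arange(cfg0.age_min, cfg0.age_max + 1)

    frames = []
    for center in centers:
        for sex in sexes:
            for period in periods:
                ages = rng.choice(ages_all, size=n_per_stratum)
                if weight_dispersion > 0:
                    shape = 1.0 / weight_dispersion**2
                    weights = rng.gamma(shape, 1.0 / shape, size=n_per_stratum)
                else:
                    weights = np.ones(n_per_stratum)
                rec = {
                    "age": ages,
                    "sex": sex,
                    "center": center,
                    "period": period,
                    "weight": weights,
                }
                for cond, col in _CASE_COLS.items():
                    p = truth.stratum(sex, cond).prevalence(ages.astype(float))
                    cases = (rng.random(n_per_stratum) < p).astype("int64")
                    cases = pd.array(cases, dtype="Int64")
                    if missingness > 0:
                        miss = rng.random(n_per_stratum) < missingness
                        cases[miss] = pd.NA
                    rec[col] = cases
                frames.append(pd.DataFrame(rec))
    out = pd.concat(frames, ignore_index=True)
    out["age"] = out["age"].astype("int64")
    return out


def write_participants(records: pd.DataFrame, path) -> None:
    """Write the participant table as CSV (missing case status = empty field)."""
    records.to_csv(path, index=False)


def read_participants(path) -> pd.DataFrame:
    """Read a participant CSV, preserving missing case indicators."""
    df = pd.read_csv(path, dtype={"sex": str, "center": str})
    for col in _CASE_COLS.values():
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    df["age"] = df["age"].astype("int64")
    df["period"] = df["period"].astype("int64")
    return df


def truth_config_to_yaml(config: TruthConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.__dict__, fh, sort_keys=True)


def truth_config_from_yaml(path) -> TruthConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return TruthConfig(**data)
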