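"""Smooth age curves for general mortality and mortality rate ratios.

Tabulated life-table mortality rates and condition-specific mortality rate
ratios are turned into log-linear (Gompertz-type) age functions,
``exp(alpha + beta * a)``, by ordinary least squares on the log scale.
Log-linearity guarantees positivity everywhere and describes adult mortality
well; for the rate ratio it is a smoothness assumption, not a claim about
the data-generating process.

A uniform multiplicative perturbation of the rate-ratio curve (e.g. x0.85 /
x1.15) supports the robustness analysis of borrowing rate ratios from an
external population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DomainError
from .synthetic import MortalityTable, MRRCurve

__all__ = [
    "SmoothRateCurve",
    "fit_log_mortality",
    "fit_mrr",
    "perturb_mrr",
]


@dataclass(frozen=True)
class SmoothRateCurve:
    """Log-linear rate curve ``exp(intercept + slope * age)``.

    Evaluating outside ``age_range`` emits an extrapolation warning but
    returns the (always positive) extrapolated value.
    """

    kind: str
    intercept: float
    slope: float
    age_range: tuple

    def __call__(self, age):
        a = np.asarray(age, dtype=float)
        lo, hi = self.age_range
        if np.any(a < lo) or np.any(a > hi):
            warnings.warn(
                f"evaluating {self.kind} curve outside its fitted age range "
                f"[{lo}, {hi}]", stacklevel=2,
            )
        out = np.exp(self.intercept + self.slope * a)
        return out if out.ndim else float(out)

    def scaled(self, factor: float) -> "SmoothRateCurve":
        if factor <= 0:
            raise ConfigError(f"scale factor must be > 0, got {factor}")
        return SmoothRateCurve(
            kind=self.kind,
            intercept=self.intercept + float(np.log(factor)),
            slope=self.slope,
            age_range=self.age_range,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"kind": self.kind, "intercept": self.intercept,
                 "slope": self.slope, "age_range": list(self.age_range)},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SmoothRateCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], intercept=d["intercept"],
                   slope=d["slope"], age_range=tuple(d["age_range"]))


def _log_linear_fit(ages, values, kind: str, min_points: int) -> SmoothRateCurve:
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise DomainError(f"all tabulated {kind} values must be > 0")
    if ages.size < min_points:
        raise ConfigError(
            f"need >= {min_points} tabulated ages to fit a {kind} curve"
        )
    slope, intercept = np.polyfit(ages, np.log(values), deg=1)
    return SmoothRateCurve(kind=kind, intercept=float(intercept),
                           slope=float(slope),
                           age_range=(float(ages.min()), float(ages.max())))


def fit_log_mortality(table: MortalityTable) -> SmoothRateCurve:
    """Fit log m(a) = alpha + beta a to a tabulated general-mortality table."""
    return _log_linear_fit(table.ages, table.rates, "mortality", min_points=3)


def fit_mrr(curve: MRRCurve) -> SmoothRateCurve:
    """Fit log R(a) = alpha + beta a to a tabulated mortality-rate-ratio curve."""
    return _log_linear_fit(curve.ages, curve.ratios, "mrr", min_points=2)


def perturb_mrr(curve: SmoothRateCurve, factor: float) -> SmoothRateCurve:
    """Multiply the fitted rate-ratio curve by a constant factor (e.g. 0.85, 1.15)."""
    return curve.scaled(factor)
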