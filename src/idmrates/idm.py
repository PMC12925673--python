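"""Illness-death model primitives.

The illness-death model places a population into three states — susceptible,
diseased, dead — with transition rates: incidence ``i(a)`` (susceptible →
diseased), remission ``r(a)`` (diseased → susceptible), and mortality rates
``m0(a)`` among the susceptible and ``m1(a)`` among the diseased.  Along a
birth cohort the point prevalence ``p`` of the diseased state obeys

    dp/da = (1 - p) * i - p * r - p * (1 - p) * (m1 - m0)

Because ``m0`` is rarely observed directly, the population ("general")
mortality ``m = (1 - p) m0 + p m1`` and the mortality rate ratio
``R = m1 / m0`` can replace the state-specific rates, giving the equivalent
form implemented in :func:`pde_rhs_mrr`.

This module also provides the three-parameter Gaussian rate family used to
parameterize incidence and remission, a fixed-step Runge–Kutta cohort solver
(the forward oracle for the prevalence equation), and the Rogan–Gladen
misclassification adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InvalidParameterError

__all__ = [
    "GaussianRate",
    "RateParameterSet",
    "RatePoint",
    "gaussian_rate",
    "pde_rhs",
    "pde_rhs_mrr",
    "solve_cohort_prevalence",
    "adjust_prevalence",
]


@dataclass(frozen=True)
class GaussianRate:
    """Gaussian rate function ``amp * exp(-((a - loc) / wid)**2)``.

    Parameters
    ----------
    amplitude : float
        Peak rate per person-year.  May be negative during optimization;
        negative values are truncated to zero only at reporting time.
    location : float
        Age (years) at which the rate attains ``amplitude``.
    width : float
        Width parameter in years; must be strictly positive.
    """

    amplitude: float
    location: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise InvalidParameterError(
                f"Gaussian width must be > 0, got {self.width!r}"
            )

    def __call__(self, age):
        z = (np.asarray(age, dtype=float) - self.location) / self.width
        out = self.amplitude * np.exp(-z * z)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class RateParameterSet:
    """The six coefficients of the incidence and remission Gaussians."""

    incidence: GaussianRate
    remission: GaussianRate

    def as_array(self) -> np.ndarray:
        """Pack as [amp_i, loc_i, wid_i, amp_r, loc_r, wid_r]."""
        return np.array(
            [
                self.incidence.amplitude,
                self.incidence.location,
                self.incidence.width,
                self.remission.amplitude,
                self.remission.location,
                self.remission.width,
            ]
        )

    @classmethod
    def from_array(cls, theta) -> "RateParameterSet":
        a = np.asarray(theta, dtype=float)
        if a.shape != (6,):
            raise InvalidParameterError(f"expected 6 coefficients, got shape {a.shape}")
        return cls(
            incidence=GaussianRate(a[0], a[1], a[2]),
            remission=GaussianRate(a[3], a[4], a[5]),
        )


def gaussian_rate(age, g: GaussianRate):
    """Evaluate a :class:`GaussianRate` at one or more ages."""
    return g(age)


_CONSISTENCY_RTOL = 1e-8


@dataclass(frozen=True)
class RatePoint:
    """All model quantities at a single (age, time) point.

    Supply either the state-specific mortalities ``(m0, m1)`` or the
    population pair ``(m, R)``; when both are given they must be mutually
    consistent (``m = (1-p) m0 + p m1`` and ``R = m1/m0``).
    """

    p: float
    incidence: float
    remission: float
    mort_susceptible: float | None = None
    mort_diseased: float | None = None
    general_mortality: float | None = None
    mrr: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise DomainError(f"prevalence must be in [0, 1], got {self.p}")
        for name in ("incidence", "remission", "mort_susceptible",
                     "mort_diseased", "general_mortality"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be >= 0, got {v}")
        if self.mrr is not None and not self.mrr > 0:
            raise DomainError(f"mortality rate ratio must be > 0, got {self.mrr}")
        m0, m1 = self.mort_susceptible, self.mort_diseased
        if m0 is not None and m1 is not None:
            m = (1 - self.p) * m0 + self.p * m1
            if self.general_mortality is not None and not np.isclose(
                self.general_mortality, m, rtol=_CONSISTENCY_RTOL, atol=1e-15
            ):
                raise DomainError(
                    "general_mortality inconsistent with (p, m0, m1): "
                    f"{self.general_mortality} vs {m}"
                )
            if self.mrr is not None and m0 > 0 and not np.isclose(
                self.mrr, m1 / m0, rtol=_CONSISTENCY_RTOL
            ):
                raise DomainError(
                    f"mrr inconsistent with m1/m0: {self.mrr} vs {m1 / m0}"
                )


def pde_rhs(p, incidence, remission, mort_susceptible, mort_diseased):
    """Cohort-line prevalence derivative from state-specific mortalities.

    Returns ``(1-p) i - p r - p (1-p) (m1 - m0)``.  Accepts scalars or
    broadcastable arrays.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("prevalence must be in [0, 1]")
    out = (
        (1.0 - p) * incidence
        - p * remission
        - p * (1.0 - p) * (np.asarray(mort_diseased) - np.asarray(mort_susceptible))
    )
    return out if out.ndim else float(out)


def pde_rhs_mrr(p, incidence, remission, general_mortality, mrr):
    """Cohort-line prevalence derivative from general mortality and MRR.

    Substituting ``m0 = m / (1 + p (R - 1))`` and ``m1 = R m0`` into
    :func:`pde_rhs` gives

        (1-p) i - p r - p (1-p) m (R-1) / (1 + p (R-1))

    which is algebraically identical to :func:`pde_rhs` whenever ``m`` and
    ``R`` are computed from consistent ``(m0, m1, p)``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("prevalence must be in [0, 1]")
    mrr_arr = np.asarray(mrr, dtype=float)
    if np.any(mrr_arr <= 0):
        raise DomainError("mortality rate ratio must be > 0")
    m = np.asarray(general_mortality, dtype=float)
    if np.any(m < 0):
        raise DomainError("general mortality must be >= 0")
    excess = p * (1.0 - p) * m * (mrr_arr - 1.0) / (1.0 + p * (mrr_arr - 1.0))
    out = (1.0 - p) * incidence - p * remission - excess
    return out if out.ndim else float(out)


def rate_point_rhs(x: RatePoint) -> float:
    """Evaluate the prevalence derivative for a fully specified RatePoint."""
    if x.mort_susceptible is not None and x.mort_diseased is not None:
        return pde_rhs(x.p, x.incidence, x.remission,
                       x.mort_susceptible, x.mort_diseased)
    if x.general_mortality is not None and x.mrr is not None:
        return pde_rhs_mrr(x.p, x.incidence, x.remission,
                           x.general_mortality, x.mrr)
    raise InvalidParameterError(
        "RatePoint needs (m0, m1) or (general_mortality, mrr)"
    )


def solve_cohort_prevalence(
    p_start: float,
    age_start: float,
    age_grid,
    incidence,
    remission,
    mort_susceptible=None,
    mort_diseased=None,
    general_mortality=None,
    mrr=None,
    max_step: float = 0.1,
):
    """Integrate prevalence along a cohort line with classical RK4.

    With time-constant rates the directional derivative (∂t + ∂a) of
    prevalence equals d/da along the cohort line, so a one-dimensional ODE
    solve in age yields the prevalence curve.  The step size is fixed
    (≤ ``max_step`` years) for bitwise reproducibility.

    Parameters
    ----------
    p_start : float
        Prevalence at ``age_start``, in [0, 1].
    age_start : float
        Starting age; must equal the first grid point.
    age_grid : array-like
        Strictly increasing ages at which to report prevalence.
    incidence, remission : callables
        Age → rate per person-year.
    mort_susceptible, mort_diseased : callables, optional
        State-specific mortality rates; supply this pair *or* the next.
    general_mortality, mrr : callables, optional
        Population mortality and mortality rate ratio.

    Returns
    -------
    ndarray
        Prevalence at each grid age, clamped to [0, 1].
    """
    if not 0.0 <= p_start <= 1.0:
        raise DomainError(f"p_start must be in [0, 1], got {p_start}")
    grid = np.asarray(age_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidParameterError("age_grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise InvalidParameterError("age_grid must be strictly increasing")
    if not np.isclose(grid[0], age_start):
        raise InvalidParameterError("age_grid must start at age_start")

    use_mrr = general_mortality is not None and mrr is not None
    if not use_mrr and (mort_susceptible is None or mort_diseased is None):
        raise InvalidParameterError(
            "supply (mort_susceptible, mort_diseased) or (general_mortality, mrr)"
        )

    def rhs(a, p):
        p = min(max(p, 0.0), 1.0)  # guard roundoff before the domain check
        if use_mrr:
            return pde_rhs_mrr(p, incidence(a), remission(a),
                               general_mortality(a), mrr(a))
        return pde_rhs(p, incidence(a), remission(a),
                       mort_susceptible(a), mort_diseased(a))

    out = np.empty_like(grid)
    p = float(p_start)
    out[0] = p
    for k in range(1, grid.size):
        a0, a1 = grid[k - 1], grid[k]
        n_sub = max(1, int(np.ceil((a1 - a0) / max_step - 1e-12)))
        h = (a1 - a0) / n_sub
        a = a0
        for _ in range(n_sub):
            k1 = rhs(a, p)
            k2 = rhs(a + h / 2, p + h / 2 * k1)
            k3 = rhs(a + h / 2, p + h / 2 * k2)
            k4 = rhs(a + h, p + h * k3)
            p = p + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            p = min(max(p, 0.0), 1.0)
            a += h
        out[k] = p
    return out


def adjust_prevalence(p_obs, sensitivity: float, specificity: float):
    """Rogan–Gladen adjustment of apparent prevalence for test inaccuracy.

    Returns ``(p_adj, valid)`` where

        p_adj = (p_obs + specificity - 1) / (sensitivity + specificity - 1)

    and ``valid`` is False wherever the adjusted value falls outside [0, 1]
    (with imperfect screeners and low apparent prevalence the adjustment
    can go negative; such values must not be propagated downstream).
    """
    if not sensitivity + specificity > 1:
        raise InvalidParameterError(
            "sensitivity + specificity must exceed 1 for the adjustment "
            f"to be defined (got {sensitivity} + {specificity})"
        )
    p = np.asarray(p_obs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise DomainError("observed prevalence must be in [0, 1]")
    # grouping keeps the perfect-instrument case (sens = spec = 1) exact
    adj = (p + (specificity - 1.0)) / (sensitivity + specificity - 1.0)
    valid = (adj >= 0.0) & (adj <= 1.0)
    if adj.ndim:
        return adj, valid
    return float(adj), bool(valid)
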