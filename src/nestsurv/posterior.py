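"""Posterior summaries and decision statistics for the survival models.

Implements the reporting conventions of the analysis: equal-tailed quantile
tables (0.025, 0.250, 0.500, 0.750, 0.975), 95% highest-density intervals,
the probability of direction (pd) with its 0.9 biological-significance
threshold, period survival (daily survival compounded over the 30-day
incubation cycle), per-SD odds ratios, and predicted period-survival curves
along a single standardized covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

#: Quantile levels printed in the coefficient tables.
TABLE_QUANTILES = (0.025, 0.250, 0.500, 0.750, 0.975)

#: pd at or above this value is flagged as biologically significant.
PD_SIGNIFICANT = 0.9

#: Days in a full incubation cycle used for period survival.
INCUBATION_CYCLE_DAYS = 30

_MIN_DRAWS = 100


@dataclass(frozen=True)
class PosteriorSummary:
    """Summary row for one parameter's pooled posterior draws."""

    quantiles: dict
    mean: float
    hdi_low: float
    hdi_high: float
    pd: float
    n_draws: int

    @property
    def median(self) -> float:
        return self.quantiles[0.5]

    @property
    def significant(self) -> bool:
        return self.pd >= PD_SIGNIFICANT

    def as_series(self) -> pd.Series:
        data = {f"{q:.3f}": v for q, v in self.quantiles.items()}
        data.update(
            mean=self.mean, hdi_low=self.hdi_low, hdi_high=self.hdi_high, pd=self.pd
        )
        return pd.Series(data)


def _check_draws(draws) -> np.ndarray:
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < _MIN_DRAWS:
        raise ValueError(f"need at least {_MIN_DRAWS} draws, got {x.size}")
    return x


def pd_direction(draws) -> float:
    """Probability of direction: the posterior probability that the
    parameter is strictly positive or strictly negative, whichever is
    larger.  Draws exactly at zero are split evenly.  Ranges 0.5-1."""
    x = np.asarray(draws, dtype=float).ravel()
    p_pos = float(np.mean(x > 0) + 0.5 * np.mean(x == 0))
    return max(p_pos, 1.0 - p_pos)


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def summarize(draws, hdi_mass: float = 0.95) -> PosteriorSummary:
    """Empirical quantiles (linear interpolation), mean, HDI and pd."""
    x = _check_draws(draws)
    qs = np.quantile(x, TABLE_QUANTILES)
    lo, hi = hdi(x, hdi_mass)
    return PosteriorSummary(
        quantiles=dict(zip(TABLE_QUANTILES, map(float, qs))),
        mean=float(x.mean()),
        hdi_low=lo,
        hdi_high=hi,
        pd=pd_direction(x),
        n_draws=x.size,
    )


def period_survival(daily_draws, n_days: int = INCUBATION_CYCLE_DAYS) -> np.ndarray:
    """Expand daily survival draws over the full incubation cycle."""
    x = np.asarray(daily_draws, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("daily survival draws must lie in [0, 1]")
    return x**n_days


@dataclass(frozen=True)
class OddsRatio:
    """Per-SD odds ratio with its verbal direction."""

    ratio: float
    direction: str  # "more likely" / "less likely" / "no change"

    def __str__(self) -> str:
        if self.direction == "no change":
            return "odds unchanged (ratio 1.00)"
        return f"{self.ratio:.2f} times {self.direction} to survive per SD increase"


def odds_ratio_per_sd(beta: float) -> OddsRatio:
    """Odds ratio implied by a logit coefficient per standardized unit.

    Reported as ``exp(|beta|)`` with the direction carried verbally: a
    negative coefficient of -0.17 reads "1.19 times less likely to survive
    per SD increase".
    """
    beta = float(beta)
    if beta == 0:
        return OddsRatio(1.0, "no change")
    return OddsRatio(float(np.exp(abs(beta))), "more likely" if beta > 0 else "less likely")


def predicted_period_curve(
    intercept_draws,
    beta_draws,
    grid,
    n_days: int = INCUBATION_CYCLE_DAYS,
    offset_draws=None,
    band: float = 0.95,
) -> pd.DataFrame:
    """Predicted period survival along one standardized covariate.

    For each grid value g the per-draw daily survival is
    ``inverse-logit(b0 + beta * g + offset)`` (other covariates held at
    their mean, i.e. 0 after standardization; random effects at 0 unless an
    ``offset_draws`` vector is supplied), raised to ``n_days``, and
    summarized to a posterior mean with an equal-tailed credible band.
    """
    b0 = _check_draws(intercept_draws)
    b = _check_draws(beta_draws)
    if b0.size != b.size:
        raise ValueError("intercept and coefficient draws must align")
    off = np.zeros_like(b0) if offset_draws is None else np.asarray(offset_draws, float)
    grid = np.asarray(grid, dtype=float)
    alpha = (1.0 - band) / 2.0
    rows = []
    for g in grid:
        per = expit(b0 + b * g + off) ** n_days
        rows.append((g, per.mean(), np.quantile(per, alpha), np.quantile(per, 1 - alpha)))
    return pd.DataFrame(rows, columns=["grid", "mean", "lo", "hi"])


def summary_table(draws_by_name: dict, round_to: int | None = None) -> pd.DataFrame:
    """Coefficient table in the study's reporting layout.

    One row per parameter with the five quantile columns and pd; the
    intercept's pd is conventionally left blank in print but is reported
    here for completeness.
    """
    rows = {}
    for name, draws in draws_by_name.items():
        rows[name] = summarize(draws).as_series()
    out = pd.DataFrame(rows).T
    if round_to is not None:
        out = out.round(round_to)
    return out
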