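"""Bayesian hierarchical daily survival models for nests and females.

The sampling unit is the exposure day: nest (or female) *i* alive at the
start of day *j* survives to day *j + 1* with probability Φ_ij, modelled on
the logit scale as

    logit Φ_ij = β0 + β1·attempt_i + β2·conceal_i + β3·distance_ij
               + β4·duration_ij + β5·recess_ij [+ β6·nestage_ij]
               + Year_i + Site_i

with the nest-age term present only in the nest model.  Site is nested
within year: each (site, year) pair is its own random-effect level.  Every
coefficient and random-effect level carries an independent
Normal(mean 0, precision 0.001) prior; there is no variance hyperprior.
Covariates are z-scored by default so coefficients are per-SD effects.

Usage follows the statsmodels idiom::

    model = DailySurvivalModel.from_dataframe(exposure_df, outcome="nest")
    result = model.fit(McmcConfig.nest_default(seed=1))
    print(result.summary())
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from . import posterior as post
from .mcmc import Chains, McmcConfig, gelman_rubin, run_mcmc

logger = logging.getLogger(__name__)

NEST_COVARIATES = ("attempt", "concealment", "distance", "duration", "recesses", "nest_age")
FEMALE_COVARIATES = ("attempt", "concealment", "distance", "duration", "recesses")

_OUTCOME_COLUMNS = {"nest": "nest_alive", "female": "female_alive"}

#: R-hat threshold above which chains are considered non-converged.
RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome, fixed effects and random effects a model carries."""

    outcome: str
    fixed: tuple
    random_effects: bool = True
    prior_precision: float = 0.001

    def __post_init__(self):
        if self.outcome not in _OUTCOME_COLUMNS:
            raise ValueError("outcome must be 'nest' or 'female'")
        if self.outcome == "female" and "nest_age" in self.fixed:
            raise ValueError("the female model excludes nest age")

    @classmethod
    def nest(cls, random_effects: bool = True) -> "ModelSpec":
        return cls(outcome="nest", fixed=NEST_COVARIATES, random_effects=random_effects)

    @classmethod
    def female(cls, random_effects: bool = True) -> "ModelSpec":
        return cls(outcome="female", fixed=FEMALE_COVARIATES, random_effects=random_effects)

    @classmethod
    def intercept_only(cls, outcome: str) -> "ModelSpec":
        """Period-survival variant: no covariates, no random effects."""
        return cls(outcome=outcome, fixed=(), random_effects=False)


def standardize(df: pd.DataFrame, covariates) -> tuple[pd.DataFrame, dict]:
    """Z-score covariate columns; returns the table and per-column (mean, SD).

    A raw change of one SD in a covariate then corresponds to one
    standardized unit, which is how the per-SD odds ratios are read.
    """
    out = df.copy()
    scalers = {}
    for c in covariates:
        x = df[c].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {c!r} has zero standard deviation")
        out[c] = (x - mu) / sd
        scalers[c] = (mu, sd)
    return out, scalers


def log_posterior(params, X, y, prior_precision: float = 0.001) -> float:
    """Log posterior of the Bernoulli-logit model up to a constant.

    Sum over exposure days of ``y log Φ + (1 - y) log(1 - Φ)`` with
    logit Φ = X @ params, plus the Normal(0, precision) log-prior on every
    parameter (coefficients and random-effect levels alike).
    """
    params = np.asarray(params, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates")
    eta = X @ params
    # y*eta - log(1 + e^eta), numerically stable
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = params.size
    logprior = float(
        0.5 * p * np.log(prior_precision / (2 * np.pi))
        - 0.5 * prior_precision * np.sum(params**2)
    )
    return loglik + logprior


def build_design(df: pd.DataFrame, spec: ModelSpec):
    """Design matrix with intercept, fixed effects and RE indicator columns.

    Random effects enter as indicator columns, one per year and one per
    (site, year) pair — site nested within year — each with the same
    Normal(0, precision 0.001) prior as the coefficients.
    """
    n = len(df)
    if n == 0:
        raise ValueError("empty exposure table")
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in spec.fixed:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    if spec.random_effects:
        years = sorted(df["year"].unique())
        for yv in years:
            cols.append((df["year"] == yv).to_numpy(dtype=float))
            names.append(f"year[{yv}]")
        pairs = sorted(set(zip(df["site"], df["year"])), key=lambda t: (t[1], t[0]))
        for s, yv in pairs:
            cols.append(((df["site"] == s) & (df["year"] == yv)).to_numpy(dtype=float))
            names.append(f"site[{s}:{yv}]")
    X = np.column_stack(cols)
    y = df[_OUTCOME_COLUMNS[spec.outcome]].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("fate column must be 0/1")
    return X, y, names


def _fold_random_effects(draws: np.ndarray, names: list) -> np.ndarray:
    """Hierarchical sum-to-zero reporting transform on draws (..., n_params).

    With site nested within year, a year's indicator equals the sum of its
    site indicators, so the raw year level and the mean of its site levels
    are confounded (and likewise the intercept and the year means) under
    the flat priors.  Per draw, each year's site-level mean is folded into
    that year's level and the year-level mean into the intercept; the
    centered levels and folded intercept are the identified quantities.
    Reporting convention only; sampling is unconstrained.
    """
    out = draws.copy()
    i0 = names.index("intercept")
    year_col = {c[5:-1]: j for j, c in enumerate(names) if c.startswith("year[")}
    site_by_year: dict = {}
    for j, c in enumerate(names):
        if c.startswith("site["):
            yr = c[5:-1].split(":")[1]
            site_by_year.setdefault(yr, []).append(j)
    for yr, idx in site_by_year.items():
        m = out[..., idx].mean(axis=-1)
        out[..., idx] -= m[..., None]
        if yr in year_col:
            out[..., year_col[yr]] += m
        else:
            out[..., i0] += m
    yidx = list(year_col.values())
    if yidx:
        m = out[..., yidx].mean(axis=-1)
        out[..., yidx] -= m[..., None]
        out[..., i0] += m
    return out


class DailySurvivalModel:
    """Known-fate daily survival model built from an exposure-day table."""

    def __init__(
        self,
        exposure: pd.DataFrame,
        spec: ModelSpec | None = None,
        outcome: str = "nest",
        standardize_covariates: bool = True,
    ):
        self.spec = spec or (ModelSpec.nest() if outcome == "nest" else ModelSpec.female())
        self.scalers: dict = {}
        data = exposure.reset_index(drop=True)
        if standardize_covariates and self.spec.fixed:
            data, self.scalers = standardize(data, self.spec.fixed)
        self.data = data
        self.exog, self.endog, self.param_names = build_design(data, self.spec)

    @classmethod
    def from_dataframe(cls, exposure: pd.DataFrame, outcome: str = "nest", **kw):
        return cls(exposure, outcome=outcome, **kw)

    @classmethod
    def intercept_only(cls, exposure: pd.DataFrame, outcome: str = "nest"):
        """Period-survival variant fit on the unfiltered exposure table."""
        return cls(exposure, spec=ModelSpec.intercept_only(outcome))

    def log_posterior(self, params) -> float:
        return log_posterior(params, self.exog, self.endog, self.spec.prior_precision)

    def default_config(self, seed: int = 0) -> McmcConfig:
        if self.spec.outcome == "female":
            return McmcConfig.female_default(seed)
        return McmcConfig.nest_default(seed)

    def fit(self, config: McmcConfig | None = None, seed: int | None = None):
        config = config or self.default_config(seed or 0)
        chains = run_mcmc(
            self.exog, self.endog, config, names=self.param_names,
            prior_precision=self.spec.prior_precision,
        )
        rhat = None
        if config.n_chains >= 2:
            # diagnose the identified (sum-to-zero reported) parameterization:
            # with flat priors the raw intercept and RE means are confounded
            # and only their sum is a meaningful quantity
            folded = _fold_random_effects(chains.draws, chains.names)
            rhat = gelman_rubin(folded)
        return DailySurvivalResults(model=self, chains=chains, config=config, rhat=rhat)


@dataclass
class DailySurvivalResults:
    """Posterior draws plus summaries for a fitted daily survival model."""

    model: DailySurvivalModel
    chains: Chains
    config: McmcConfig
    rhat: np.ndarray | None = None
    _reported: pd.DataFrame | None = field(default=None, repr=False)

    # -- draw access --------------------------------------------------------
    @property
    def param_names(self) -> list:
        return self.chains.names

    def draws(self, name: str | None = None) -> np.ndarray:
        """Pooled post burn-in, thinned draws (optionally for one parameter),
        with random-effect levels reported sum-to-zero: per draw, each RE
        family's mean is folded into the intercept and the levels centered.
        This is a reporting convention only; sampling is unconstrained."""
        flat = self._reported_draws()
        if name is None:
            return flat.to_numpy()
        return flat[name].to_numpy()

    def _reported_draws(self) -> pd.DataFrame:
        if self._reported is None:
            folded = _fold_random_effects(self.chains.draws, self.param_names)
            self._reported = pd.DataFrame(
                folded.reshape(-1, folded.shape[-1]), columns=self.param_names
            )
        return self._reported

    def converged(self, threshold: float = RHAT_THRESHOLD) -> bool:
        if self.rhat is None:
            raise ValueError("R-hat needs at least two chains")
        return bool(np.all(self.rhat < threshold))

    # -- summaries ----------------------------------------------------------
    def summary(self, round_to: int | None = 2, include_random_effects: bool = False):
        flat = self._reported_draws()
        keep = [
            c for c in flat.columns
            if include_random_effects or not (c.startswith("year[") or c.startswith("site["))
        ]
        table = post.summary_table({c: flat[c].to_numpy() for c in keep}, round_to=round_to)
        if self.rhat is not None:
            table["rhat"] = [
                round(float(r), 3) if round_to else float(r)
                for r, c in zip(self.rhat, self.param_names)
                if c in keep
            ]
        return table

    def summarize(self, name: str) -> post.PosteriorSummary:
        return post.summarize(self.draws(name))

    def daily_survival_draws(self, at_reference: bool = True) -> np.ndarray:
        """Daily survival draws at covariate means and random effects 0."""
        return expit(self.draws("intercept"))

    def period_survival(self, n_days: int = post.INCUBATION_CYCLE_DAYS) -> post.PosteriorSummary:
        return post.summarize(post.period_survival(self.daily_survival_draws(), n_days))

    def odds_ratio(self, name: str) -> post.OddsRatio:
        return post.odds_ratio_per_sd(self.summarize(name).median)

    def predicted_period_curve(self, name: str, grid=None, n_days: int = post.INCUBATION_CYCLE_DAYS):
        if grid is None:
            x = self.model.data[name].to_numpy(dtype=float)
            grid = np.linspace(x.min(), x.max(), 25)
        return post.predicted_period_curve(
            self.draws("intercept"), self.draws(name), grid, n_days=n_days
        )

    # -- interop and plotting ------------------------------------------------
    def to_inference_data(self):
        """Export the folded chains as an :class:`arviz.InferenceData`."""
        import arviz as az

        folded = _fold_random_effects(self.chains.draws, self.param_names)
        return az.from_dict(
            posterior={n: folded[:, :, j] for j, n in enumerate(self.param_names)}
        )

    def plot_predicted_period_curves(self, names=None, n_days: int = 30, path=None):
        """Predicted period-survival curves per covariate with 95% bands."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        names = list(names) if names is not None else [
            c for c in self.model.spec.fixed
        ]
        fig, axes = plt.subplots(
            1, len(names), figsize=(3.2 * len(names), 3.0), squeeze=False, sharey=True
        )
        for ax, name in zip(axes[0], names):
            curve = self.predicted_period_curve(name, n_days=n_days)
            ax.fill_between(curve.grid, curve.lo, curve.hi, alpha=0.25)
            ax.plot(curve.grid, curve["mean"])
            ax.set_xlabel(f"{name} (SD units)")
        axes[0][0].set_ylabel(f"{n_days}-day survival")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig

    # -- persistence --------------------------------------------------------
    def draws_frame(self) -> pd.DataFrame:
        """All pooled draws, one column per parameter (CSV-ready)."""
        return self._reported_draws().copy()

    def manifest(self) -> dict:
        """Run metadata: spec, config, seed and convergence diagnostics."""
        return {
            "outcome": self.model.spec.outcome,
            "fixed_effects": list(self.model.spec.fixed),
            "random_effects": self.model.spec.random_effects,
            "prior_precision": self.model.spec.prior_precision,
            "standardized": bool(self.model.scalers),
            "scalers": {k: list(v) for k, v in self.model.scalers.items()},
            "n_exposure_days": int(len(self.model.endog)),
            "n_failures": int(np.sum(self.model.endog == 0)),
            "mcmc": {
                "n_chains": self.config.n_chains,
                "n_iter": self.config.n_iter,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "seed": self.config.seed,
            },
            "rhat": {
                n: float(r) for n, r in zip(self.param_names, self.rhat)
            } if self.rhat is not None else None,
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)

    def __str__(self) -> str:
        head = (
            f"DailySurvivalResults(outcome={self.model.spec.outcome!r}, "
            f"n={len(self.model.endog)}, chains={self.config.n_chains})"
        )
        return head + "\n" + self.summary().to_string()
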