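"""Extended STIRPAT decomposition of anthropogenic Nr creation drivers.

The STIRPAT model (Stochastic Impacts by Regression on Population, Affluence
and Technology) regresses the natural log of an environmental impact I on the
logs of socioeconomic drivers. The extended form used here is

    ln I = a + b ln P + c ln A + d1 ln T1 + d2 ln T2 + e

with P population, A diet choice (animal-source share of food N intake) as the
affluence proxy, T1 energy intensity (energy per unit GDP) and T2 industrial
level (share of Nr creation from anthropogenic ammonification) as technology
proxies, and e the error term. The fit is ordinary least squares.

From a fitted elasticity beta and a driver's compound annual growth rate r,
the *effect coefficient* EC = (1 + r) ** beta is the multiplicative annual
effect of the driver on the impact, and the *contribution rate*

    100 * |EC - 1| / sum|EC - 1| * R^2

apportions the explained impact change across drivers (the rates sum to
100 * R^2 by construction).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

from .errors import DomainError, SingularityError

FACTORS = ("population", "diet_choice", "energy_intensity", "industrial_level")
_COEF_NAMES = {"population": "b", "diet_choice": "c",
               "energy_intensity": "d1", "industrial_level": "d2"}


@dataclass(frozen=True)
class StirpatDataset:
    """Annual driver series; all series must be strictly positive (logs)."""

    years: tuple[int, ...]
    impact: tuple[float, ...]
    population: tuple[float, ...]
    diet_choice: tuple[float, ...]
    energy_intensity: tuple[float, ...]
    industrial_level: tuple[float, ...]

    def __post_init__(self):
        n = len(self.years)
        for name in ("impact",) + FACTORS:
            series = getattr(self, name)
            if len(series) != n:
                raise ValueError(f"series {name!r} length {len(series)} != {n} years")
            if any(v <= 0 for v in series):
                raise DomainError(f"series {name!r} must be strictly positive")
        if n < 6:
            raise DomainError(
                f"need at least 6 time points for a 4-predictor fit, got {n}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StirpatDataset":
        """Build from a drivers table (columns year, I_GgN, population,
        diet_choice, energy_intensity, industrial_level)."""
        return cls(
            years=tuple(int(y) for y in frame["year"]),
            impact=tuple(float(v) for v in frame["I_GgN"]),
            population=tuple(float(v) for v in frame["population"]),
            diet_choice=tuple(float(v) for v in frame["diet_choice"]),
            energy_intensity=tuple(float(v) for v in frame["energy_intensity"]),
            industrial_level=tuple(float(v) for v in frame["industrial_level"]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "I_GgN": self.impact,
                "population": self.population,
                "diet_choice": self.diet_choice,
                "energy_intensity": self.energy_intensity,
                "industrial_level": self.industrial_level,
            }
        )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class StirpatFit:
    """OLS fit of the ln-linear model: elasticities with inference diagnostics."""

    intercept: float
    coefficients: Mapping[str, float]        # factor -> elasticity (b, c, d1, d2)
    std_errors: Mapping[str, float]
    t_values: Mapping[str, float]
    p_values: Mapping[str, float]
    stars: Mapping[str, str]
    vif: Mapping[str, float]
    r_squared: float
    adj_r_squared: float
    durbin_watson: float
    residual_sd: float
    nobs: int

    @property
    def symbols(self) -> dict[str, float]:
        """Coefficients under their conventional symbols a, b, c, d1, d2."""
        out = {"a": self.intercept}
        out.update({_COEF_NAMES[f]: v for f, v in self.coefficients.items()})
        return out


def _check_collinearity(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        offending: tuple[str, ...] = ()
        for a, b in itertools.combinations(X.columns, 2):
            xa, xb = X[a] - X[a].mean(), X[b] - X[b].mean()
            denom = float(np.sqrt((xa**2).sum() * (xb**2).sum()))
            if denom == 0 or abs(float((xa * xb).sum()) / denom) > 1 - 1e-12:
                offending = (a, b)
                break
        raise SingularityError(
            "perfectly collinear predictors in the STIRPAT design"
            + (f": {offending[0]} and {offending[1]}" if offending else ""),
            predictors=offending,
        )


def fit_stirpat(dataset: StirpatDataset) -> StirpatFit:
    """OLS on natural-log-transformed variables.

    Raises :class:`~nflow.errors.SingularityError` naming the offending
    predictors when the design is rank deficient.
    """
    X = pd.DataFrame(
        {factor: np.log(np.asarray(getattr(dataset, factor))) for factor in FACTORS}
    )
    y = np.log(np.asarray(dataset.impact))
    _check_collinearity(X)
    design = sm.add_constant(X)
    res = sm.OLS(y, design).fit()

    coef = {f: float(res.params[f]) for f in FACTORS}
    se = {f: float(res.bse[f]) for f in FACTORS}
    tvals = {f: float(res.tvalues[f]) for f in FACTORS}
    pvals = {f: float(res.pvalues[f]) for f in FACTORS}
    exog = design.to_numpy()
    vif = {
        f: float(variance_inflation_factor(exog, i + 1))  # +1 skips the constant
        for i, f in enumerate(FACTORS)
    }
    return StirpatFit(
        intercept=float(res.params["const"]),
        coefficients=coef,
        std_errors=se,
        t_values=tvals,
        p_values=pvals,
        stars={f: significance_stars(p) for f, p in pvals.items()},
        vif=vif,
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        durbin_watson=float(durbin_watson(res.resid)),
        residual_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        nobs=int(res.nobs),
    )


def annual_growth_rate(series: Sequence[float]) -> float:
    """Geometric (compound) annual growth rate over the full window."""
    series = list(series)
    if len(series) < 2:
        raise DomainError("need at least two points for a growth rate")
    first, last = float(series[0]), float(series[-1])
    if first <= 0 or last <= 0:
        raise DomainError("growth rate requires positive endpoints")
    return (last / first) ** (1.0 / (len(series) - 1)) - 1.0


def effect_coefficient(r: float, b: float) -> float:
    """Multiplicative annual effect (1 + r) ** b of a driver on the impact."""
    if 1.0 + r <= 0:
        raise DomainError(f"annual growth rate {r!r} implies a nonpositive base")
    return (1.0 + r) ** b


def contribution_rates(ecs: Mapping[str, float], r_squared: float) -> dict[str, float]:
    """Per-factor share of explained impact change, in percent.

    ``100 * |EC - 1| / sum|EC - 1| * R^2``; the shares sum to ``100 * R^2``
    and are invariant to factor ordering.
    """
    devs = {k: abs(ec - 1.0) for k, ec in ecs.items()}
    total = sum(devs.values())
    if total == 0:
        raise DomainError("all effect coefficients equal 1; contributions undefined")
    return {k: 100.0 * d / total * r_squared for k, d in devs.items()}


@dataclass(frozen=True)
class DriverDecomposition:
    """Per-factor growth rates, effect coefficients and contribution rates."""

    growth_rates: Mapping[str, float]       # fraction per year
    coefficients: Mapping[str, float]
    effect_coefficients: Mapping[str, float]
    contributions: Mapping[str, float]      # percent, sums to 100*R^2
    r_squared: float

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for f in self.growth_rates:
            rows.append(
                {
                    "factor": f,
                    "annual_growth_rate_pct": 100.0 * self.growth_rates[f],
                    "coefficient": self.coefficients[f],
                    "effect_coefficient": self.effect_coefficients[f],
                    "contribution_rate_pct": self.contributions[f],
                }
            )
        return pd.DataFrame(rows)


def decompose_drivers(
    dataset: StirpatDataset, fit: StirpatFit | None = None
) -> DriverDecomposition:
    """Full decomposition: fit (unless given), growth rates, ECs, contributions."""
    if fit is None:
        fit = fit_stirpat(dataset)
    growth = {f: annual_growth_rate(getattr(dataset, f)) for f in FACTORS}
    ecs = {f: effect_coefficient(growth[f], fit.coefficients[f]) for f in FACTORS}
    contrib = contribution_rates(ecs, fit.r_squared)
    return DriverDecomposition(
        growth_rates=growth,
        coefficients=dict(fit.coefficients),
        effect_coefficients=ecs,
        contributions=contrib,
        r_squared=fit.r_squared,
    )


def screen_factors(candidates: Mapping[str, Sequence[float]]):
    """Pearson correlations (on logs) and VIFs for candidate driver series.

    Returns ``(correlations, vifs)``; selection itself is a user decision.
    Constant series trigger an undefined-correlation warning and NaN entries.
    """
    if len(candidates) < 2:
        raise DomainError("need at least two candidate factors to screen")
    logs = {}
    for name, series in candidates.items():
        arr = np.asarray(series, dtype=float)
        if np.any(arr <= 0):
            raise DomainError(f"candidate series {name!r} must be strictly positive")
        if np.allclose(arr, arr[0]):
            warnings.warn(
                f"candidate series {name!r} is constant; its correlations are undefined",
                stacklevel=2,
            )
        logs[name] = np.log(arr)
    frame = pd.DataFrame(logs)
    corr = frame.corr(method="pearson")
    exog = sm.add_constant(frame, has_constant="add").to_numpy()
    names = list(frame.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vifs = {
            name: float(variance_inflation_factor(exog, i + 1))
            for i, name in enumerate(names)
        }
    return corr, vifs
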