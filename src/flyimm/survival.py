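"""LT50 estimation from daily survival counts via a binomial GLM.

Flies are counted alive each day after transfer onto fungus-covered medium;
the cumulative death fraction by day t is modelled as a binomial GLM with a
logit (or probit) link,

    g(P(dead by t)) = b0 + b1 t,

and the 50% lethal time is the dose-response midpoint LT50 = −b0/b1, with a
delta-method standard error.  A series with no partial-mortality day (all
alive then all dead) is completely separated; the estimator then falls back
to the midpoint between the last fully-alive and first fully-dead day and
flags the fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class SurvivalSeries:
    """Daily alive counts for one replicate."""

    day: np.ndarray
    alive: np.ndarray
    n_start: int
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.alive = np.asarray(self.alive, dtype=int)
        if len(self.day) != len(self.alive):
            raise ValueError("day and alive differ in length")
        if (np.diff(self.alive) > 0).any():
            raise ValueError("alive counts must be non-increasing")
        if (self.alive > self.n_start).any() or (self.alive < 0).any():
            raise ValueError("alive counts must lie in [0, n_start]")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, replicate: str = "rep1") -> "SurvivalSeries":
        n_start = int(frame["n_start"].iloc[0]) if "n_start" in frame else int(frame["alive"].max())
        return cls(frame["day"].to_numpy(), frame["alive"].to_numpy(), n_start, replicate)


@dataclass
class LT50Fit:
    lt50: float
    slope: float
    intercept: float
    se_lt50: float
    link: str
    separated: bool = False


def fit_lt50(series: SurvivalSeries, link: str = "logit") -> LT50Fit:
    """Fit the binomial GLM of cumulative deaths against day.

    Requires at least three distinct days and at least one day with partial
    mortality (0 < dead < n_start); without one the data are completely
    separated and the midpoint fallback applies.
    """
    if len(np.unique(series.day)) < 3:
        raise ValueError("need at least 3 distinct observation days")
    deaths = series.n_start - series.alive
    partial = (deaths > 0) & (deaths < series.n_start)
    if not partial.any():
        all_alive = series.day[deaths == 0]
        all_dead = series.day[deaths == series.n_start]
        if len(all_alive) == 0 or len(all_dead) == 0:
            raise ValueError("no mortality signal in the series")
        lt50 = 0.5 * (all_alive.max() + all_dead.min())
        return LT50Fit(float(lt50), math.inf, -math.inf, math.nan, link, separated=True)

    links = {"logit": sm.families.links.Logit(), "probit": sm.families.links.Probit()}
    if link not in links:
        raise ValueError(f"link must be one of {sorted(links)}")
    endog = np.column_stack([deaths, series.alive])
    exog = sm.add_constant(series.day)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, exog, family=sm.families.Binomial(link=links[link]))
        result = model.fit()
    b0, b1 = result.params
    if b1 == 0:
        raise ValueError("zero slope: LT50 undefined")
    lt50 = -b0 / b1
    # delta method: grad = (-1/b1, b0/b1^2)
    grad = np.array([-1.0 / b1, b0 / b1**2])
    se = float(np.sqrt(grad @ result.cov_params() @ grad))
    return LT50Fit(float(lt50), float(b1), float(b0), se, link)


def compare_lt50(
    series_a: Sequence[SurvivalSeries],
    series_b: Sequence[SurvivalSeries],
    link: str = "logit",
) -> tuple[float, float, float]:
    """Mean per-replicate LT50 of each group and the A/B ratio."""
    if not series_a or not series_b:
        raise ValueError("each group needs at least one replicate")
    mean_a = float(np.mean([fit_lt50(s, link).lt50 for s in series_a]))
    mean_b = float(np.mean([fit_lt50(s, link).lt50 for s in series_b]))
    return mean_a, mean_b, mean_a / mean_b
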