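"""Stand-age power models and the planted-vs-natural comparison.

Per-hectare stocks and NPP of young even-aged stands rise steeply with
stand age ``t`` and are summarised by the power law ``y = b0 * t^b1``,
fitted by unweighted nonlinear least squares to plot-level points (one
point per plot-year). Published parameter sets for both planted
("artificial") and naturally regenerated young beech stands in the
Western Carpathians ship as reference constants, enabling predictions and
origin comparisons without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerAgeModel",
    "StandAgeModel",
    "StandAgeResults",
    "NATURAL_REFERENCE",
    "PLANTED_REFERENCE",
    "fit_age_model",
    "predict_age",
    "compare_origins",
]

VARIABLES = (
    "foliage_stock",
    "woody_stock",
    "aboveground_stock",
    "woody_npp",
    "aboveground_npp",
)

#: maps the model variable to the column it is fitted to
VARIABLE_COLUMNS = {
    "foliage_stock": "foliage_stock_Mg_ha",
    "woody_stock": "woody_stock_Mg_ha",
    "aboveground_stock": "aboveground_stock_Mg_ha",
    "woody_npp": "woody_npp_Mg_ha_yr",
    "aboveground_npp": "anpp_Mg_ha_yr",
}


@dataclass(frozen=True)
class PowerAgeModel:
    """A stand-age power model ``y = b0 * t^b1`` for one variable.

    ``origin`` tags whether the parameters describe planted ("planted")
    or naturally regenerated ("natural") stands. Standard errors, p-values
    and fit metrics are optional (reference parameter sets carry the
    published SEs but no covariance).
    """

    variable: str
    origin: str
    b0: float
    b1: float
    b0_se: float = float("nan")
    b1_se: float = float("nan")
    b0_p: float = float("nan")
    b1_p: float = float("nan")
    r2: float = float("nan")
    mse: float = float("nan")

    def __post_init__(self):
        if self.b0 <= 0:
            raise ValueError("b0 must be strictly positive")

    def predict(self, t) -> float | np.ndarray:
        """Evaluate ``b0 * t^b1`` at stand age ``t`` (years)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr <= 0):
            raise ValueError("stand age must be strictly positive")
        out = self.b0 * t_arr**self.b1
        return float(out) if np.ndim(t) == 0 else out


#: Published stand-age parameters for naturally regenerated young beech
#: stands (Western Carpathians); stocks in Mg/ha, NPP in Mg/ha/yr, age in yr.
NATURAL_REFERENCE: dict[str, PowerAgeModel] = {
    "foliage_stock": PowerAgeModel("foliage_stock", "natural", 0.717, 0.889, 0.167, 0.084, 1e-4, 1e-4, 0.642, 2.458),
    "woody_stock": PowerAgeModel("woody_stock", "natural", 0.802, 1.844, 0.148, 0.064, 1e-4, 1e-4, 0.946, 250.0),
    "aboveground_stock": PowerAgeModel("aboveground_stock", "natural", 1.031, 1.777, 0.192, 0.064, 1e-4, 1e-4, 0.940, 287.5),
    "woody_npp": PowerAgeModel("woody_npp", "natural", 2.100, 0.790, 0.938, 0.161, 0.028, 1e-4, 0.287, 46.29),
    "aboveground_npp": PowerAgeModel("aboveground_npp", "natural", 2.700, 0.833, 0.940, 0.125, 0.005, 1e-4, 0.423, 57.43),
}

#: Published stand-age parameters for planted young beech stands
#: (same region and age range); used as the study's reference models.
PLANTED_REFERENCE: dict[str, PowerAgeModel] = {
    "foliage_stock": PowerAgeModel("foliage_stock", "planted", 0.00024, 3.763, 0.00006, 0.101, 1e-4, 1e-4, 0.890, 0.155),
    "woody_stock": PowerAgeModel("woody_stock", "planted", 0.00084, 4.044, 0.0002, 0.109, 1e-4, 1e-4, 0.886, 8.93),
    "aboveground_stock": PowerAgeModel("aboveground_stock", "planted", 0.00104, 4.010, 0.0002, 0.108, 1e-4, 1e-4, 0.886, 11.42),
    "woody_npp": PowerAgeModel("woody_npp", "planted", 0.00086, 3.622, 0.00048, 0.219, 0.072, 1e-4, 0.673, 4.53),
    "aboveground_npp": PowerAgeModel("aboveground_npp", "planted", 0.00124, 3.591, 0.0005, 0.165, 0.017, 1e-4, 0.774, 4.58),
}


class StandAgeModel:
    """Power model of a stand variable versus age, fitted by NLS.

    Parameters
    ----------
    ages, values
        Plot-level points: stand age (years) and the stock (Mg/ha) or NPP
        (Mg/ha/yr) value of each plot-year.
    variable, origin
        Labels carried into the results.
    """

    def __init__(self, ages, values, variable: str = "aboveground_stock", origin: str = "planted"):
        ages = np.asarray(ages, dtype=float)
        values = np.asarray(values, dtype=float)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("ages and values must be aligned 1-D arrays")
        if np.any(values < 0):
            raise ValueError("values must be non-negative")
        if np.any(ages <= 0):
            raise ValueError("ages must be strictly positive")
        if np.unique(ages).size < 4:
            raise ValueError("need at least 4 distinct ages to fit an age model")
        self.ages = ages
        self.values = values
        self.variable = variable
        self.origin = origin

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, variable: str, origin: str = "planted"
    ) -> "StandAgeModel":
        """Build from a stock or NPP table (see ``VARIABLE_COLUMNS``)."""
        col = VARIABLE_COLUMNS[variable]
        return cls(df["age_yr"], df[col], variable=variable, origin=origin)

    def fit(self) -> "StandAgeResults":
        """Unweighted NLS of ``y = b0 * t^b1``; ln-ln OLS start values."""
        t, y = self.ages, self.values
        pos = y > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(np.log(t[pos]), np.log(y[pos]), 1)
            x0 = np.array([np.exp(intercept), slope])
        else:
            x0 = np.array([max(y.mean(), 1e-6), 1.0])

        def fun(theta):
            return y - theta[0] * t ** theta[1]

        res = optimize.least_squares(fun, x0, method="lm", xtol=1e-10, ftol=1e-10)
        if not res.success:
            raise RuntimeError("stand-age model fit did not converge")
        n, p = y.size, 2
        sse = 2.0 * res.cost
        sst = float(np.sum((y - y.mean()) ** 2))
        s2 = sse / max(n - p, 1)
        cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
        bse = np.sqrt(np.diag(cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = res.x / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), max(n - p, 1))
        return StandAgeResults(
            model=PowerAgeModel(
                self.variable,
                self.origin,
                float(res.x[0]),
                float(res.x[1]),
                float(bse[0]),
                float(bse[1]),
                float(pvals[0]),
                float(pvals[1]),
                r2=1.0 - sse / sst if sst > 0 else float("nan"),
                mse=sse / n,
            ),
            cov_params=cov,
            n=n,
        )


@dataclass
class StandAgeResults:
    """Fitted stand-age power model plus uncertainty."""

    model: PowerAgeModel
    cov_params: np.ndarray
    n: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.model.b0, self.model.b1])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.model.b0_se, self.model.b1_se])

    @property
    def r2(self) -> float:
        return self.model.r2

    @property
    def mse(self) -> float:
        return self.model.mse

    def predict(self, t):
        return self.model.predict(t)

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                f"Stand-age power model: {m.variable} ({m.origin}), n = {self.n}",
                f"  b0 = {m.b0:.6g} (SE {m.b0_se:.3g}, p = {m.b0_p:.3g})",
                f"  b1 = {m.b1:.4f} (SE {m.b1_se:.3g}, p = {m.b1_p:.3g})",
                f"  R^2 = {m.r2:.3f}   MSE = {m.mse:.4g}",
            ]
        )


def fit_age_model(
    records, variable: str = "aboveground_stock", origin: str = "planted"
) -> PowerAgeModel:
    """Fit ``y = b0 * t^b1`` to (age, value) pairs; returns the model.

    ``records`` may be a sequence of ``(age, value)`` tuples or a
    DataFrame with an ``age_yr`` column and the variable's column.
    """
    if isinstance(records, pd.DataFrame):
        model = StandAgeModel.from_dataframe(records, variable, origin)
    else:
        arr = np.asarray(list(records), dtype=float)
        model = StandAgeModel(arr[:, 0], arr[:, 1], variable, origin)
    return model.fit().model


def predict_age(model: PowerAgeModel, t):
    """Evaluate a stand-age power model at age ``t`` (years)."""
    return model.predict(t)


def compare_origins(
    planted: dict[str, PowerAgeModel] | None = None,
    natural: dict[str, PowerAgeModel] | None = None,
    ages=range(5, 17),
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Planted-vs-natural predictions over a common age range.

    Returns a table with per-age predictions for both origins and the
    planted:natural ratio for every shared variable, plus the crossover
    age (where the ratio crosses 1, located by bisection) or ``None`` if
    the ratio never crosses inside the range.
    """
    planted = PLANTED_REFERENCE if planted is None else planted
    natural = NATURAL_REFERENCE if natural is None else natural
    ages = np.asarray(list(ages), dtype=float)
    shared = [v for v in VARIABLES if v in planted and v in natural]
    rows = []
    crossovers: dict[str, float | None] = {}
    for var in shared:
        pm, nm = planted[var], natural[var]
        for t in ages:
            p_val = pm.predict(t)
            n_val = nm.predict(t)
            rows.append(
                {
                    "variable": var,
                    "age_yr": t,
                    "planted": p_val,
                    "natural": n_val,
                    "ratio_planted_natural": p_val / n_val if n_val > 0 else np.inf,
                }
            )

        def log_ratio(t, pm=pm, nm=nm):
            return np.log(pm.predict(t)) - np.log(nm.predict(t))

        lo, hi = float(ages.min()), float(ages.max())
        if log_ratio(lo) == 0:
            crossovers[var] = lo
        elif log_ratio(lo) * log_ratio(hi) < 0:
            crossovers[var] = float(optimize.bisect(log_ratio, lo, hi, xtol=1e-6))
        else:
            crossovers[var] = None
    return pd.DataFrame(rows), crossovers
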