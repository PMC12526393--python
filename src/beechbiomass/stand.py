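"""Stand-level stocks, NPP accounting and age-class increments.

Tree-level predictions are scaled to per-hectare plot stocks through the
nominal planting density: with spacing ``a x b`` metres there are
``10^4 / (a * b)`` planting positions per hectare, so

    stock (Mg/ha) = mean single-tree biomass (Mg) * 10^4 / (a * b).

At the study's 1.6 m x 1.6 m spacing this is 3906.25 trees/ha. The
measured plot area and tree count enter only through the mean tree
biomass.

NPP accounting uses the deciduous turnover logic: foliage is fully shed
and regrown each year, so foliage NPP of a year equals that year's foliage
stock; woody NPP is the increment of woody stock between consecutive years
over living trees; ANPP is their sum.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "plot_stock",
    "compute_plot_stocks",
    "foliage_npp",
    "woody_npp",
    "compute_npp",
    "increment_by_age_class",
    "foliage_share",
    "AGE_CLASSES",
]

G_PER_MG = 1e6
M2_PER_HA = 1e4

#: age classes (closed intervals, years) used for increment pooling
AGE_CLASSES = {"<=5": (2, 5), "6-10": (6, 10), "11-15": (11, 15)}

STOCK_COLUMNS = [
    "site_id",
    "plot_id",
    "year",
    "age_yr",
    "n_trees",
    "w_avg_Mg",
    "foliage_stock_Mg_ha",
    "woody_stock_Mg_ha",
    "aboveground_stock_Mg_ha",
]

NPP_COLUMNS = [
    "site_id",
    "plot_id",
    "age_yr",
    "foliage_npp_Mg_ha_yr",
    "woody_npp_Mg_ha_yr",
    "anpp_Mg_ha_yr",
]


def _predict_grams(model, obs: pd.DataFrame) -> np.ndarray:
    d0 = obs["d0_mm"].to_numpy(dtype=float)
    h = obs["h_m"].to_numpy(dtype=float)
    return np.asarray(model.predict(d0=d0, h=h), dtype=float)


def plot_stock(
    observations: pd.DataFrame,
    foliage_model,
    woody_model,
    spacing_a: float = 1.6,
    spacing_b: float = 1.6,
) -> pd.Series:
    """Per-hectare biomass stock of one plot in one year.

    Parameters
    ----------
    observations
        Tree observations of a single plot-year (columns ``d0_mm``,
        ``h_m``, optionally ``alive``); all trees must be alive.
    foliage_model, woody_model
        Fitted tree-level models exposing ``predict(d0=..., h=...)`` in
        grams.
    spacing_a, spacing_b
        Planting spacing in metres; per-hectare density is
        ``10^4 / (spacing_a * spacing_b)``.
    """
    if len(observations) == 0:
        raise ValueError("empty plot: no observations")
    if spacing_a <= 0 or spacing_b <= 0:
        raise ValueError("spacing must be strictly positive")
    if "alive" in observations.columns and not observations["alive"].all():
        raise ValueError("plot_stock expects only living trees")
    density = M2_PER_HA / (spacing_a * spacing_b)
    fol_Mg = _predict_grams(foliage_model, observations) / G_PER_MG
    wood_Mg = _predict_grams(woody_model, observations) / G_PER_MG
    n = len(observations)
    w_avg = float(fol_Mg.sum() + wood_Mg.sum()) / n
    fol_stock = float(fol_Mg.mean()) * density
    wood_stock = float(wood_Mg.mean()) * density
    return pd.Series(
        {
            "site_id": observations["site_id"].iloc[0] if "site_id" in observations else "",
            "plot_id": observations["plot_id"].iloc[0] if "plot_id" in observations else "",
            "year": observations["year"].iloc[0] if "year" in observations else np.nan,
            "age_yr": observations["age_yr"].iloc[0] if "age_yr" in observations else np.nan,
            "n_trees": n,
            "w_avg_Mg": w_avg,
            "foliage_stock_Mg_ha": fol_stock,
            "woody_stock_Mg_ha": wood_stock,
            "aboveground_stock_Mg_ha": fol_stock + wood_stock,
        }
    )


def compute_plot_stocks(
    observations: pd.DataFrame,
    foliage_model,
    woody_model,
    spacing_a: float = 1.6,
    spacing_b: float = 1.6,
) -> pd.DataFrame:
    """Stocks for every (site, plot, year) in an observation table."""
    records = [
        plot_stock(group, foliage_model, woody_model, spacing_a, spacing_b)
        for _, group in observations.groupby(["site_id", "plot_id", "year"], sort=True)
    ]
    return pd.DataFrame(records)[STOCK_COLUMNS].reset_index(drop=True)


def foliage_npp(stock_record: pd.Series) -> float:
    """Foliage NPP of a plot-year (Mg/ha/yr).

    Equals the foliage stock: deciduous foliage turns over completely
    within the year, so the standing leaf mass is also the year's leaf
    production (and the year's litterfall).
    """
    return float(stock_record["foliage_stock_Mg_ha"])


def woody_npp(stock_year_t: pd.Series, stock_year_t_minus_1: pd.Series) -> float:
    """Woody NPP over one year (Mg/ha/yr): the stock increment.

    Both records must belong to the same plot at consecutive ages and be
    computed over trees alive in both years (trivially true without
    mortality). A negative increment is physically impossible for living
    trees and raises a data-quality warning, not an error.
    """
    for key in ("site_id", "plot_id"):
        if stock_year_t[key] != stock_year_t_minus_1[key]:
            raise ValueError("woody_npp requires records from the same plot")
    if int(stock_year_t["age_yr"]) - int(stock_year_t_minus_1["age_yr"]) != 1:
        raise ValueError(
            "woody_npp requires consecutive ages, got "
            f"{stock_year_t_minus_1['age_yr']} -> {stock_year_t['age_yr']}"
        )
    inc = float(
        stock_year_t["woody_stock_Mg_ha"] - stock_year_t_minus_1["woody_stock_Mg_ha"]
    )
    if inc < 0:
        warnings.warn(
            f"negative woody increment ({inc:.3f} Mg/ha/yr) for plot "
            f"{stock_year_t['site_id']}/{stock_year_t['plot_id']}: "
            "check the input series",
            UserWarning,
            stacklevel=2,
        )
    return inc


def compute_npp(stocks: pd.DataFrame) -> pd.DataFrame:
    """Annual NPP records from a plot-stock table.

    For each plot and each pair of consecutive ages, foliage NPP is the
    end-of-interval foliage stock, woody NPP the woody-stock increment,
    and ANPP their sum. The interval is labelled by its end age.
    """
    rows = []
    for (site, plot), group in stocks.groupby(["site_id", "plot_id"], sort=True):
        group = group.sort_values("age_yr")
        for prev, curr in zip(group.iloc[:-1].itertuples(), group.iloc[1:].itertuples()):
            prev_s = stocks.loc[prev.Index]
            curr_s = stocks.loc[curr.Index]
            w_npp = woody_npp(curr_s, prev_s)
            f_npp = foliage_npp(curr_s)
            rows.append(
                {
                    "site_id": site,
                    "plot_id": plot,
                    "age_yr": int(curr_s["age_yr"]),
                    "foliage_npp_Mg_ha_yr": f_npp,
                    "woody_npp_Mg_ha_yr": w_npp,
                    "anpp_Mg_ha_yr": f_npp + w_npp,
                }
            )
    return pd.DataFrame(rows, columns=NPP_COLUMNS)


def _age_class(age: int) -> str | None:
    for label, (lo, hi) in AGE_CLASSES.items():
        if lo <= age <= hi:
            return label
    return None


def increment_by_age_class(
    observations: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Mean annual diameter/height increments pooled by age class.

    Per plot and consecutive-year pair, the increment of the plot-mean
    ``d0`` (mm/yr) and plot-mean ``h`` (m/yr) is computed and assigned to
    the age class of the interval's end age (classes <=5, 6-10 and 11-15
    years; older intervals are excluded). Plot-level class means are then
    pooled per class, and a one-way ANOVA across classes tests whether the
    increments differ.

    Returns
    -------
    (table, anova)
        ``table`` has one row per age class with plot counts and mean
        increments; ``anova`` maps ``"d0"``/``"h"`` to ``(F, p)``. With a
        single usable class the ANOVA is skipped (``F`` and ``p`` NaN).
    """
    plot_rows = []
    for (site, plot), group in observations.groupby(["site_id", "plot_id"], sort=True):
        means = (
            group.groupby("age_yr")[["d0_mm", "h_m"]].mean().sort_index().reset_index()
        )
        for i in range(1, len(means)):
            end_age = int(means["age_yr"].iloc[i])
            label = _age_class(end_age)
            if label is None:
                continue
            plot_rows.append(
                {
                    "site_id": site,
                    "plot_id": plot,
                    "age_class": label,
                    "d0_inc_mm_yr": means["d0_mm"].iloc[i] - means["d0_mm"].iloc[i - 1],
                    "h_inc_m_yr": means["h_m"].iloc[i] - means["h_m"].iloc[i - 1],
                }
            )
    if not plot_rows:
        raise ValueError("no year-to-year intervals fall inside the age classes")
    per_plot = (
        pd.DataFrame(plot_rows)
        .groupby(["age_class", "site_id", "plot_id"], sort=False)[
            ["d0_inc_mm_yr", "h_inc_m_yr"]
        ]
        .mean()
        .reset_index()
    )
    usable = []
    for label in AGE_CLASSES:
        sub = per_plot[per_plot["age_class"] == label]
        if len(sub) == 0:
            continue
        if len(sub) < 2:
            warnings.warn(
                f"age class {label} has fewer than 2 plots; excluded from the ANOVA",
                UserWarning,
                stacklevel=2,
            )
            continue
        usable.append(label)
    table = (
        per_plot.groupby("age_class", sort=False)
        .agg(
            n_plots=("plot_id", "size"),
            d0_inc_mm_yr=("d0_inc_mm_yr", "mean"),
            h_inc_m_yr=("h_inc_m_yr", "mean"),
        )
        .reindex([c for c in AGE_CLASSES if c in per_plot["age_class"].values])
        .reset_index()
    )
    anova: dict[str, tuple[float, float]] = {}
    for key, col in (("d0", "d0_inc_mm_yr"), ("h", "h_inc_m_yr")):
        if len(usable) < 2:
            anova[key] = (float("nan"), float("nan"))
            continue
        samples = [
            per_plot.loc[per_plot["age_class"] == label, col].to_numpy()
            for label in usable
        ]
        pooled = np.concatenate(samples)
        if np.allclose(pooled, pooled[0]):
            anova[key] = (0.0, 1.0)  # identical increments everywhere
            continue
        f, p = stats.f_oneway(*samples)
        anova[key] = (float(f), float(p))
    return table, anova


def foliage_share(
    stocks: pd.DataFrame, npp: pd.DataFrame
) -> tuple[float, float, float, float]:
    """Pooled foliage shares (%) of aboveground stock and of ANPP.

    Returns ``(share_of_stock, share_of_anpp, sd_stock, sd_anpp)``, the
    mean and standard deviation over plot-years of
    ``100 * foliage / aboveground``. Records with zero aboveground mass
    contribute a zero share.
    """

    def _shares(num: pd.Series, den: pd.Series) -> np.ndarray:
        den_a = den.to_numpy(dtype=float)
        num_a = num.to_numpy(dtype=float)
        out = np.zeros_like(den_a)
        nz = den_a > 0
        out[nz] = 100.0 * num_a[nz] / den_a[nz]
        return out

    s_stock = _shares(stocks["foliage_stock_Mg_ha"], stocks["aboveground_stock_Mg_ha"])
    s_anpp = _shares(npp["foliage_npp_Mg_ha_yr"], npp["anpp_Mg_ha_yr"])
    return (
        float(s_stock.mean()),
        float(s_anpp.mean()),
        float(s_stock.std(ddof=1)) if len(s_stock) > 1 else 0.0,
        float(s_anpp.std(ddof=1)) if len(s_anpp) > 1 else 0.0,
    )
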