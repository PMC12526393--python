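"""Synthetic destructive-sample trees and plot remeasurement series.

The generators emulate the data a young-plantation biomass study produces:

* a destructive sample of trees (stem basal diameter ``d0`` in mm, height
  ``h`` in m, oven-dry foliage and woody mass in g) whose component masses
  follow power laws of ``d0`` with additive Gaussian noise whose variance
  itself grows as a power of ``d0`` -- exactly the heteroscedastic
  structure the weighting procedure in :mod:`beechbiomass.allometry`
  is designed to remove;
* an annual remeasurement series over sites x plots x years in which
  plot-mean diameter follows a power law of stand age and each tree keeps
  a persistent multiplicative deviation from the plot mean, so individual
  diameter and height trajectories are monotone (no mortality, matching
  the negligible mortality observed in young planted beech).

Everything is reproducible from ``GenerativeParams.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenerativeParams",
    "generate_sample_trees",
    "generate_stand_series",
    "write_sample_trees",
    "write_stand_series",
]

#: lognormal sigma of height noise around the height-diameter law
_HEIGHT_SIGMA_LN = 0.10
#: lognormal sigma of persistent per-tree size deviations in stand series
_TREE_SIGMA_LN = 0.15


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the synthetic-data generating process.

    Component masses follow ``mass = b0 * d0^b1 + eps`` with
    ``eps ~ N(0, alpha_var * d0^lambda_var)`` (g, d0 in mm); heights follow
    ``h = c0_h * d0^c1_h`` (m) with lognormal noise; plot-mean diameter
    grows as ``growth_k * age^growth_m`` (mm, age in yr).

    Defaults reproduce the fitted tree-level models of a young planted
    beech study in the Western Carpathians (foliage b0=0.00878, b1=2.63892;
    woody b0=0.01762, b1=2.93664; variance exponent ~1.85) so synthetic
    trees resemble the field sample. The noise scale ``alpha_var`` is
    bounded by the smallest trees: foliage mass at the minimum diameter
    (4 mm) is only ~0.34 g, and the additive noise sd there must stay well
    below it or the negative-mass redraw truncates the noise distribution
    and distorts the variance power law the weighting procedure relies on.
    The default 0.001 keeps redraws below ~0.2% of draws at 4 mm.
    """

    b0_fol: float = 0.00878
    b1_fol: float = 2.63892
    b0_wood: float = 0.01762
    b1_wood: float = 2.93664
    alpha_var: float = 0.001
    lambda_var: float = 1.85
    c0_h: float = 0.062
    c1_h: float = 0.98
    d0_range: tuple[float, float] = (4.0, 70.0)
    growth_k: float = 1.5
    growth_m: float = 1.377
    spacing_a: float = 1.6
    spacing_b: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        pos = {
            "b0_fol": self.b0_fol,
            "b1_fol": self.b1_fol,
            "b0_wood": self.b0_wood,
            "b1_wood": self.b1_wood,
            "c0_h": self.c0_h,
            "c1_h": self.c1_h,
            "growth_k": self.growth_k,
            "spacing_a": self.spacing_a,
            "spacing_b": self.spacing_b,
        }
        for name, value in pos.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.alpha_var < 0:
            raise ValueError("alpha_var must be non-negative")
        if self.lambda_var < 0:
            raise ValueError("lambda_var must be non-negative")
        if self.growth_m < 0:
            raise ValueError("growth_m must be non-negative")
        lo, hi = self.d0_range
        if not (lo > 0 and lo < hi):
            raise ValueError(f"d0_range must satisfy 0 < min < max, got {self.d0_range}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["d0_range"] = list(self.d0_range)
        return d


def _component_mass(
    rng: np.random.Generator, d0: np.ndarray, b0: float, b1: float, params: GenerativeParams
) -> np.ndarray:
    """Power-law mass with additive heteroscedastic noise, redrawn if <= 0.

    Redrawing (rather than clipping) keeps the variance function close to
    ``alpha_var * d0^lambda_var``; with realistic parameters the truncation
    only bites at the smallest diameters.
    """
    mean = b0 * d0**b1
    sd = np.sqrt(params.alpha_var * d0**params.lambda_var)
    mass = mean + rng.normal(0.0, 1.0, size=d0.size) * sd
    bad = mass <= 0
    # tiny trees can go negative; redraw those only
    while np.any(bad):
        mass[bad] = mean[bad] + rng.normal(0.0, 1.0, size=int(bad.sum())) * sd[bad]
        bad = mass <= 0
    return mass


def generate_sample_trees(params: GenerativeParams, n: int) -> pd.DataFrame:
    """Generate a destructive-sample tree table.

    Parameters
    ----------
    params
        Generative parameters; all randomness comes from ``params.seed``.
    n
        Number of trees; must be >= 50 so the downstream variance-profile
        grouping (sets of 25) has at least two full groups.

    Returns
    -------
    DataFrame with columns ``d0_mm``, ``h_m``, ``foliage_g``, ``woody_g``,
    one row per sampled tree.
    """
    if n < 50:
        raise ValueError(f"need n >= 50 sample trees, got {n}")
    rng = np.random.default_rng(params.seed)
    lo, hi = params.d0_range
    d0 = rng.uniform(lo, hi, size=n)
    h = params.c0_h * d0**params.c1_h
    if params.alpha_var > 0:
        h = h * rng.lognormal(0.0, _HEIGHT_SIGMA_LN, size=n)
        foliage = _component_mass(rng, d0, params.b0_fol, params.b1_fol, params)
        woody = _component_mass(rng, d0, params.b0_wood, params.b1_wood, params)
    else:
        # noise-free: every tree lies exactly on the power laws
        foliage = params.b0_fol * d0**params.b1_fol
        woody = params.b0_wood * d0**params.b1_wood
    return pd.DataFrame(
        {"d0_mm": d0, "h_m": h, "foliage_g": foliage, "woody_g": woody}
    )


def generate_stand_series(
    params: GenerativeParams,
    n_sites: int,
    n_plots: int,
    ages_by_site: list[list[int]],
    trees_per_plot: int,
) -> pd.DataFrame:
    """Generate an annual plot remeasurement series.

    Each site carries ``n_plots`` plots measured over the consecutive ages
    in its age list (one measurement campaign per year). Plot-mean diameter
    follows ``growth_k * age^growth_m``; each tree has a persistent
    lognormal size deviation so its diameter and height series are strictly
    increasing while the plot mean is. All trees stay alive.

    Returns
    -------
    DataFrame with columns ``site_id``, ``plot_id``, ``tag``, ``year``,
    ``age_yr``, ``d0_mm``, ``h_m``, ``alive``.
    """
    if n_sites <= 0 or n_plots <= 0 or trees_per_plot <= 0:
        raise ValueError("n_sites, n_plots and trees_per_plot must be positive")
    if len(ages_by_site) != n_sites:
        raise ValueError(
            f"ages_by_site has {len(ages_by_site)} entries for {n_sites} sites"
        )
    for ages in ages_by_site:
        if len(ages) == 0:
            raise ValueError("empty age list for a site")
        if list(ages) != list(range(ages[0], ages[0] + len(ages))):
            raise ValueError(f"age list must be consecutive integers, got {ages}")

    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, 0x5EED]).generate_state(1)[0]
    )
    base_year = 2020
    rows: list[dict] = []
    for s in range(n_sites):
        ages = list(ages_by_site[s])
        for p in range(n_plots):
            # persistent multiplicative deviation of each tree from the plot mean
            dev = rng.lognormal(0.0, _TREE_SIGMA_LN, size=trees_per_plot)
            hdev = rng.lognormal(0.0, _HEIGHT_SIGMA_LN, size=trees_per_plot)
            for k, age in enumerate(ages):
                mean_d0 = params.growth_k * float(age) ** params.growth_m
                d0 = mean_d0 * dev
                h = params.c0_h * d0**params.c1_h * hdev
                year = base_year + k
                for t in range(trees_per_plot):
                    rows.append(
                        {
                            "site_id": f"S{s + 1:02d}",
                            "plot_id": f"P{p + 1}",
                            "tag": f"T{t + 1:03d}",
                            "year": year,
                            "age_yr": age,
                            "d0_mm": d0[t],
                            "h_m": h[t],
                            "alive": True,
                        }
                    )
    return pd.DataFrame(rows)


def _write_with_metadata(
    df: pd.DataFrame, path: str | Path, params: GenerativeParams, extra: dict
) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {"params": params.to_dict(), **extra}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def write_sample_trees(
    df: pd.DataFrame, path: str | Path, params: GenerativeParams
) -> None:
    """Write a sample-tree table as CSV plus a JSON sidecar echoing params."""
    _write_with_metadata(df, path, params, {"kind": "sample_trees", "n": len(df)})


def write_stand_series(
    df: pd.DataFrame, path: str | Path, params: GenerativeParams
) -> None:
    """Write an observation series as CSV plus a JSON sidecar echoing params."""
    _write_with_metadata(df, path, params, {"kind": "stand_series", "n": len(df)})
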