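"""Sea-surface temperature reconstruction from shell calcite δ18O.

Equilibrium oxygen-isotope fractionation between calcite and water is
temperature dependent:

    1000 ln alpha = 2.78e6 / T^2 - 2.89          (T in Kelvin)
    alpha = (1000 + d18O_calcite[VSMOW]) / (1000 + d18O_water[VSMOW])

Solving for T gives the water temperature at which each carbonate sample
precipitated.  Shell measurements arrive on the VPDB scale and are moved
to VSMOW with the standard affine conversion; the ambient-water value
d18O_w is the modern local composition adjusted for the glacio-eustatic
ice-volume effect (lower-than-modern sea level means more ice, an
isotopically heavier ocean: +0.011 ‰ per metre of lowering).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .profiles import IsotopeProfile

__all__ = [
    "FractionationModel",
    "WaterModel",
    "SSTReconstructor",
    "NonPhysicalTemperatureError",
    "water_d18o",
    "vpdb_to_vsmow",
    "sst_from_d18o",
    "d18o_from_sst",
    "shell_sst_stats",
    "site_sst_summary",
    "compare_sst",
]

KELVIN_OFFSET = 273.15


class NonPhysicalTemperatureError(ValueError):
    """δ18O pair outside the domain of the fractionation equation."""


@dataclass(frozen=True)
class FractionationModel:
    """Calcite–water fractionation constants and the VPDB→VSMOW map."""

    a_coeff: float = 2.78e6  # K² scaling of 1000 ln alpha
    b_coeff: float = 2.89  # ‰ offset
    vsmow_slope: float = 1.03091
    vsmow_offset: float = 30.91  # ‰

    def __post_init__(self) -> None:
        if self.a_coeff <= 0:
            raise ValueError("a_coeff must be positive")


@dataclass(frozen=True)
class WaterModel:
    """Ambient-water δ18O: modern value plus ice-volume sea-level correction."""

    modern_d18o_w: float = 0.9  # ‰ VSMOW
    sea_level_m: float = 0.0  # metres vs modern; negative = below modern
    correction_per_m: float = 0.011  # ‰ per metre

    def __post_init__(self) -> None:
        if self.correction_per_m < 0:
            raise ValueError("correction_per_m must be >= 0")


def water_d18o(water: WaterModel) -> float:
    """Ambient δ18O_w (‰ VSMOW) for the water model.

    A sea level below modern means isotopically light water locked in ice
    sheets and an enriched ocean: d18O_w rises by ``correction_per_m`` per
    metre of lowering.  At modern sea level the modern value is returned
    unchanged.
    """
    return water.modern_d18o_w - water.sea_level_m * water.correction_per_m


def vpdb_to_vsmow(d: float | np.ndarray) -> float | np.ndarray:
    """Convert carbonate δ18O from the VPDB to the VSMOW scale."""
    return 1.03091 * np.asarray(d, dtype=float) + 30.91


def sst_from_d18o(
    d18o_s: float | np.ndarray,
    d18o_w: float | np.ndarray,
    model: FractionationModel = FractionationModel(),
) -> float | np.ndarray:
    """Water temperature (°C) from shell calcite δ18O (‰ VPDB).

    ``d18o_w`` is on the VSMOW scale; the shell value is converted
    internally.  Raises :class:`NonPhysicalTemperatureError` where
    1000 ln alpha + b <= 0 (no real temperature solves the equation).
    """
    d_smow = model.vsmow_slope * np.asarray(d18o_s, dtype=float) + model.vsmow_offset
    alpha = (1000.0 + d_smow) / (1000.0 + d18o_w)
    denom = 1000.0 * np.log(alpha) + model.b_coeff
    if np.any(denom <= 0):
        bad = np.atleast_1d(np.asarray(d18o_s, dtype=float))[
            np.atleast_1d(denom <= 0)
        ][0]
        raise NonPhysicalTemperatureError(
            f"δ18O_s = {bad:.3f}‰ gives no physical temperature "
            "(1000 ln α + b <= 0)"
        )
    t_kelvin = np.sqrt(model.a_coeff / denom)
    t = t_kelvin - KELVIN_OFFSET
    return float(t) if np.isscalar(d18o_s) else t


def d18o_from_sst(
    t_celsius: float | np.ndarray,
    d18o_w: float | np.ndarray,
    model: FractionationModel = FractionationModel(),
) -> float | np.ndarray:
    """Exact algebraic inverse: calcite δ18O (‰ VPDB) at a given temperature.

    Used by the forward simulator; round-trips with :func:`sst_from_d18o`
    to well below 1e-6 °C.
    """
    t = np.asarray(t_celsius, dtype=float)
    if np.any(t <= -KELVIN_OFFSET):
        raise ValueError("temperature at or below absolute zero")
    t_kelvin = t + KELVIN_OFFSET
    ln_alpha = (model.a_coeff / t_kelvin**2 - model.b_coeff) / 1000.0
    d_smow = np.exp(ln_alpha) * (1000.0 + d18o_w) - 1000.0
    d = (d_smow - model.vsmow_offset) / model.vsmow_slope
    return float(d) if np.isscalar(t_celsius) else d


class SSTReconstructor(TransformerMixin, BaseEstimator):
    """Transformer mapping shell δ18O (‰ VPDB) to water temperature (°C).

    Parameters mirror :class:`WaterModel` and :class:`FractionationModel`;
    ``d18o_w_override`` bypasses the sea-level arithmetic entirely when the
    ambient-water composition is known directly.
    """

    def __init__(
        self,
        modern_d18o_w: float = 0.9,
        sea_level_m: float = 0.0,
        correction_per_m: float = 0.011,
        d18o_w_override: float | None = None,
        model: FractionationModel = FractionationModel(),
    ):
        self.modern_d18o_w = modern_d18o_w
        self.sea_level_m = sea_level_m
        self.correction_per_m = correction_per_m
        self.d18o_w_override = d18o_w_override
        self.model = model

    @property
    def d18o_w_(self) -> float:
        if self.d18o_w_override is not None:
            return self.d18o_w_override
        return water_d18o(
            WaterModel(self.modern_d18o_w, self.sea_level_m, self.correction_per_m)
        )

    def fit(self, X=None, y=None) -> "SSTReconstructor":
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(sst_from_d18o(np.asarray(X, dtype=float), self.d18o_w_, self.model))

    def inverse_transform(self, X) -> np.ndarray:
        return np.asarray(d18o_from_sst(np.asarray(X, dtype=float), self.d18o_w_, self.model))


def shell_sst_stats(
    profile: IsotopeProfile,
    water: WaterModel = WaterModel(),
    model: FractionationModel = FractionationModel(),
) -> tuple[float, float, float]:
    """(t_min, t_mean, t_max) in °C over all samples of one shell."""
    if len(profile) == 0:
        raise ValueError(f"shell {profile.shell_id}: empty profile")
    dw = water_d18o(water)
    t = sst_from_d18o(np.asarray(profile.d18o), dw, model)
    return float(np.min(t)), float(np.mean(t)), float(np.max(t))


def site_sst_summary(
    per_shell: pd.DataFrame, habitat_filter: str = "all"
) -> pd.DataFrame:
    """Site-level mean ± sd of the per-shell minimum, mean and maximum SST.

    ``per_shell`` needs columns shell_id, site, t_min_c, t_mean_c, t_max_c
    (the sst_per_shell.csv schema).  Sample (n-1) standard deviation;
    single-shell sites report sd = 0 and are flagged.
    """
    rows = []
    for site, grp in per_shell.groupby("site", sort=True):
        n = len(grp)
        for stat, col in (("min", "t_min_c"), ("mean", "t_mean_c"), ("max", "t_max_c")):
            vals = grp[col].to_numpy()
            rows.append(
                {
                    "site": site,
                    "statistic": stat,
                    "mean_c": float(np.mean(vals)),
                    "sd_c": float(np.std(vals, ddof=1)) if n > 1 else 0.0,
                    "n_shells": n,
                    "single_shell": n == 1,
                    "habitat_filter": habitat_filter,
                }
            )
    return pd.DataFrame(rows)


def compare_sst(
    per_shell: pd.DataFrame, statistic: str = "mean"
) -> pd.DataFrame:
    """One-way ANOVA across sites plus all pairwise Welch t-tests.

    ``statistic`` selects which per-shell quantity (min | mean | max) is
    compared.  Sites with fewer than two shells are excluded (a variance
    cannot be formed).  Pairwise p-values are reported unadjusted and
    Holm-adjusted; the ANOVA appears as a first row with group_b = "".
    """
    col = {"min": "t_min_c", "mean": "t_mean_c", "max": "t_max_c"}[statistic]
    groups = {
        site: grp[col].to_numpy()
        for site, grp in per_shell.groupby("site", sort=True)
    }
    small = [s for s, v in groups.items() if len(v) < 2]
    if small:
        import warnings

        warnings.warn(
            f"excluding site(s) with < 2 shells from comparison: {small}",
            UserWarning,
            stacklevel=2,
        )
        groups = {s: v for s, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 sites with >= 2 shells each")

    sites = sorted(groups)
    f_stat, f_p = stats.f_oneway(*(groups[s] for s in sites))
    rows = [
        {
            "statistic": statistic,
            "test": "anova",
            "group_a": "all",
            "group_b": "",
            "t": float(f_stat),
            "p": float(f_p),
            "p_holm": float("nan"),
        }
    ]
    pairs = list(itertools.combinations(sites, 2))
    raw = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        raw.append((a, b, float(t), float(p)))
    if raw:
        p_holm = multipletests([p for *_, p in raw], method="holm")[1]
        for (a, b, t, p), ph in zip(raw, p_holm):
            rows.append(
                {
                    "statistic": statistic,
                    "test": "welch_t",
                    "group_a": a,
                    "group_b": b,
                    "t": t,
                    "p": p,
                    "p_holm": float(ph),
                }
            )
    return pd.DataFrame(rows)


def compare_reconstructions(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """t-test between two reconstructions of the same quantity.

    Used for the all-habitats vs open-coast-only sensitivity comparison;
    both the paired and the independent (Welch) reading are available.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
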