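"""Season-of-capture assignment from shell-edge δ18O against a quartile baseline.

Calcite δ18O anti-correlates with water temperature, so over an annual
cycle the pooled δ18O range of fully-sampled (baseline) shells spans the
local seasonal extremes: the highest δ18O records the coldest water
(winter), the lowest the warmest (summer).  The baseline range is split
into four equal-width bands, one per season; the δ18O of a shell's ventral
margin — the last carbonate deposited before capture — is located within
those bands.  The two intermediate bands are ambiguous between the warming
and cooling limbs of the cycle, so the ordinary-least-squares δ18O trend
over the final samples disambiguates: rising δ18O toward the edge means
cooling water (autumn), falling means warming (spring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .profiles import AnalysisConfig, IsotopeProfile

__all__ = [
    "SeasonalBaseline",
    "SeasonAssignment",
    "SeasonClassifier",
    "build_baseline",
    "edge_value",
    "edge_trend",
    "assign_season",
    "season_table",
    "BaselineError",
    "ReconciliationError",
]

BANDS = ("Q1", "Q2", "Q3", "Q4")  # Q1 = lowest δ18O (warmest), Q4 = highest (coldest)
SEASONS = ("winter", "spring", "summer", "autumn")

#: OLS slopes with magnitude below this are treated as flat (exact ties).
FLAT_SLOPE_TOL = 1e-12


class BaselineError(ValueError):
    """No usable baseline shells, or a degenerate pooled range."""


class ReconciliationError(ValueError):
    """Season and provenance tables disagree on the shell id set."""


@dataclass(frozen=True)
class SeasonalBaseline:
    """Pooled δ18O range of a site's baseline shells, split into four bands."""

    site: str
    d18o_min: float
    d18o_max: float
    boundaries: tuple[float, float, float]
    source_shells: tuple[str, ...]
    filter: str = "all"  # all | open_coast_only
    mode: str = "range"  # range | distribution

    def __post_init__(self) -> None:
        if not self.d18o_min < self.d18o_max:
            raise BaselineError(
                f"degenerate baseline range [{self.d18o_min}, {self.d18o_max}]"
            )
        b = (self.d18o_min,) + self.boundaries + (self.d18o_max,)
        if any(y <= x for x, y in zip(b, b[1:])):
            raise BaselineError(f"boundaries not strictly increasing: {b}")

    def band(self, d18o: float) -> tuple[str, bool]:
        """Locate a δ18O value; returns (band, out_of_range).

        Values outside [min, max] clamp to the nearest extreme band.
        Interior boundaries belong to the upper band (half-open bands),
        the maximum to Q4.
        """
        if d18o < self.d18o_min:
            return "Q1", True
        if d18o > self.d18o_max:
            return "Q4", True
        i = int(np.searchsorted(self.boundaries, d18o, side="right"))
        return BANDS[i], False


@dataclass(frozen=True)
class SeasonAssignment:
    shell_id: str
    edge_d18o: float
    band: str
    trend_slope: float
    trend: str  # rising | falling | flat
    season: str
    confirmed: bool
    out_of_range: bool


def build_baseline(
    profiles: Iterable[IsotopeProfile],
    filter: str = "all",
    provenance: pd.DataFrame | Mapping[str, str] | None = None,
    site: str | None = None,
    mode: str = "range",
) -> SeasonalBaseline:
    """Pool baseline-role shells into a four-band seasonal δ18O reference.

    ``mode="range"`` (default) splits [min, max] into equal-width quarters;
    ``mode="distribution"`` uses the 25/50/75% quantiles of the pooled
    values instead.  With ``filter="open_coast_only"`` only shells whose
    provenance assignment is open_coast contribute (the sensitivity variant
    that excludes estuarine specimens, whose δ18O carries a freshwater
    overprint on top of temperature).
    """
    if filter not in ("all", "open_coast_only"):
        raise ValueError(f"unknown filter {filter!r}")
    if mode not in ("range", "distribution"):
        raise ValueError(f"unknown mode {mode!r}")
    baseline = [p for p in profiles if p.role == "baseline"]
    if site is not None:
        baseline = [p for p in baseline if p.site == site]
    if filter == "open_coast_only":
        if provenance is None:
            raise BaselineError("open_coast_only filter needs provenance assignments")
        if isinstance(provenance, pd.DataFrame):
            habitat_of = dict(zip(provenance["shell_id"], provenance["habitat"]))
        else:
            habitat_of = dict(provenance)
        baseline = [p for p in baseline if habitat_of.get(p.shell_id) == "open_coast"]
    if not baseline:
        raise BaselineError(
            f"no baseline shells retained (site={site!r}, filter={filter!r})"
        )
    pooled = np.concatenate([np.asarray(p.d18o) for p in baseline])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        raise BaselineError(f"pooled δ18O range is degenerate at {lo}")
    if mode == "range":
        cuts = tuple(lo + k * (hi - lo) / 4 for k in (1, 2, 3))
    else:
        cuts = tuple(float(q) for q in np.quantile(pooled, (0.25, 0.5, 0.75)))
    return SeasonalBaseline(
        site=site if site is not None else baseline[0].site,
        d18o_min=lo,
        d18o_max=hi,
        boundaries=cuts,
        source_shells=tuple(sorted(p.shell_id for p in baseline)),
        filter=filter,
        mode=mode,
    )


def edge_value(profile: IsotopeProfile, edge_window: int = 1) -> float:
    """Mean δ18O of the final ``edge_window`` samples (default: last only)."""
    if edge_window < 1:
        raise ValueError(f"edge_window must be >= 1, got {edge_window}")
    if edge_window > len(profile):
        raise ValueError(
            f"edge_window={edge_window} exceeds profile length {len(profile)}"
        )
    return float(np.mean(profile.d18o[-edge_window:]))


def edge_trend(profile: IsotopeProfile, trend_window: int = 10) -> tuple[str, float]:
    """Direction of δ18O over the final samples before the edge.

    OLS slope of δ18O against sample position over the last
    ``min(trend_window, len(profile))`` samples; the sign gives
    rising / falling, with exact zero (within 1e-12) flat.
    """
    if len(profile) < 2:
        raise ValueError("need >= 2 samples for a trend")
    w = min(trend_window, len(profile))
    y = np.asarray(profile.d18o[-w:])
    x = np.arange(w, dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    if abs(slope) <= FLAT_SLOPE_TOL:
        return "flat", slope
    return ("rising" if slope > 0 else "falling"), slope


def assign_season(
    edge: float,
    trend: str,
    baseline: SeasonalBaseline,
    shell_id: str = "",
    trend_slope: float = float("nan"),
) -> SeasonAssignment:
    """Map (edge band, trend) to a season.

    Q4 (highest δ18O, coldest water) -> winter; Q1 (lowest, warmest) ->
    summer, regardless of trend — but the trend must be consistent with the
    approach to that extreme (rising-or-flat into Q4, falling-or-flat into
    Q1) for ``confirmed=True``.  Q2/Q3: rising δ18O (cooling) -> autumn,
    falling (warming) -> spring; a flat trend falls back on the band's side
    of the annual cycle (Q2 -> spring, Q3 -> autumn) unconfirmed.
    """
    band, out_of_range = baseline.band(edge)
    confirmed = not out_of_range
    if band == "Q4":
        season = "winter"
        confirmed = confirmed and trend in ("rising", "flat")
    elif band == "Q1":
        season = "summer"
        confirmed = confirmed and trend in ("falling", "flat")
    else:
        if trend == "rising":
            season = "autumn"
        elif trend == "falling":
            season = "spring"
        else:  # flat: midpoint-side fallback, never confirmed
            season = "spring" if band == "Q2" else "autumn"
            confirmed = False
    return SeasonAssignment(
        shell_id=shell_id,
        edge_d18o=edge,
        band=band,
        trend_slope=trend_slope,
        trend=trend,
        season=season,
        confirmed=confirmed,
        out_of_range=out_of_range,
    )


class SeasonClassifier(ClassifierMixin, BaseEstimator):
    """Quartile season-of-capture classifier.

    ``fit`` pools the baseline-role profiles into the per-site seasonal
    δ18O reference; ``predict`` locates each shell's edge δ18O in its
    site's bands, using the final-samples trend to split the intermediate
    bands into spring and autumn.

    Parameters
    ----------
    edge_window : int
        Number of final samples averaged as "the edge value".
    trend_window : int
        Number of final samples in the OLS trend (clipped to the profile).
    baseline_filter : {"all", "open_coast_only"}
        Which baseline shells contribute to the pooled range.
    quartile_mode : {"range", "distribution"}
        Equal-width quarters of [min, max] or pooled-value quantiles.

    Attributes
    ----------
    baselines_ : dict mapping site -> SeasonalBaseline
    classes_ : ndarray of the four season labels
    """

    def __init__(
        self,
        edge_window: int = 1,
        trend_window: int = 10,
        baseline_filter: str = "all",
        quartile_mode: str = "range",
    ):
        self.edge_window = edge_window
        self.trend_window = trend_window
        self.baseline_filter = baseline_filter
        self.quartile_mode = quartile_mode

    def fit(
        self,
        X: Sequence[IsotopeProfile],
        y=None,
        provenance: pd.DataFrame | Mapping[str, str] | None = None,
    ) -> "SeasonClassifier":
        profiles = list(X)
        sites = sorted({p.site for p in profiles if p.role == "baseline"})
        if not sites:
            raise BaselineError("no baseline-role profiles to fit on")
        self.baselines_ = {
            s: build_baseline(
                profiles,
                filter=self.baseline_filter,
                provenance=provenance,
                site=s,
                mode=self.quartile_mode,
            )
            for s in sites
        }
        self.classes_ = np.array(SEASONS)
        return self

    def assign(self, profile: IsotopeProfile) -> SeasonAssignment:
        if not hasattr(self, "baselines_"):
            raise RuntimeError("SeasonClassifier is not fitted; call fit() first")
        if profile.site not in self.baselines_:
            raise BaselineError(f"no baseline for site {profile.site!r}")
        edge = edge_value(profile, self.edge_window)
        trend, slope = edge_trend(profile, self.trend_window)
        return assign_season(
            edge,
            trend,
            self.baselines_[profile.site],
            shell_id=profile.shell_id,
            trend_slope=slope,
        )

    def predict(self, X: Sequence[IsotopeProfile]) -> np.ndarray:
        return np.array([self.assign(p).season for p in X])

    def assign_table(self, X: Sequence[IsotopeProfile]) -> pd.DataFrame:
        """One assignment row per shell, in the seasons.csv schema."""
        rows = []
        for p in X:
            a = self.assign(p)
            rows.append(
                {
                    "shell_id": p.shell_id,
                    "site": p.site,
                    "unit": p.unit,
                    "edge_d18o": a.edge_d18o,
                    "band": a.band,
                    "trend_slope": a.trend_slope,
                    "trend": a.trend,
                    "season": a.season,
                    "confirmed": a.confirmed,
                    "out_of_range": a.out_of_range,
                    "baseline_filter": self.baseline_filter,
                }
            )
        return pd.DataFrame(rows)


def season_table(
    assignments: pd.DataFrame, provenance: pd.DataFrame
) -> pd.DataFrame:
    """Cross-tabulate season proportions by site and habitat.

    Both tables must cover the same shell ids; proportions sum to 1 within
    each (site, habitat) row.
    """
    a_ids = set(assignments["shell_id"])
    p_ids = set(provenance["shell_id"])
    if a_ids != p_ids:
        only_a = sorted(a_ids - p_ids)
        only_p = sorted(p_ids - a_ids)
        raise ReconciliationError(
            f"shell id mismatch: only in seasons {only_a}, only in provenance {only_p}"
        )
    merged = assignments.merge(
        provenance[["shell_id", "habitat"]], on="shell_id", validate="1:1"
    )
    counts = (
        merged.groupby(["site", "habitat", "season"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    counts["proportion"] = counts.groupby(["site", "habitat"])["count"].transform(
        lambda c: c / c.sum()
    )
    return counts
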