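"""Harvesting-habitat classification from the shell δ13C–δ18O correlation.

Freshwater input into an estuary depletes both the dissolved inorganic
carbon δ13C and the water δ18O, so carbonate precipitated along an
estuarine salinity gradient couples the two isotopes positively, while
fully marine shells record them (weakly) anticorrelated through the
temperature control on δ18O.  A shell's per-profile Pearson r is therefore
a provenance fingerprint.  Classification compares r against Fisher-z
confidence intervals of modern reference correlations measured in each
habitat; values beyond the outermost bounds extend to the extreme
habitats, values in inter-interval gaps stay unknown.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .profiles import AnalysisConfig, IsotopeProfile, DEFAULT_CALIBRATION

__all__ = [
    "HabitatCalibration",
    "ProvenanceAssignment",
    "HabitatClassifier",
    "pearson_r",
    "fisher_interval",
    "build_calibration",
    "classify_shell",
    "classify_assemblage",
    "DegenerateSeriesError",
    "CalibrationOverlapWarning",
]

UNKNOWN = "unknown"


class DegenerateSeriesError(ValueError):
    """Pearson r undefined: a series is constant."""


class CalibrationOverlapWarning(UserWarning):
    """Reference confidence intervals overlap; classification may be ambiguous."""


@dataclass(frozen=True)
class HabitatCalibration:
    """A reference habitat's modern correlation and its Fisher-z CI."""

    habitat: str
    r_ref: float
    n_ref: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low < self.r_ref < self.ci_high):
            raise ValueError(
                f"{self.habitat}: CI ({self.ci_low}, {self.ci_high}) "
                f"does not bracket r_ref={self.r_ref}"
            )

    def contains(self, r: float) -> bool:
        # closed interval, matching the "ci_low <= r <= ci_high" convention
        return self.ci_low <= r <= self.ci_high


@dataclass(frozen=True)
class ProvenanceAssignment:
    shell_id: str
    r_obs: float
    habitat: str
    rule: str  # within_ci | below_marine_extension | above_estuary_extension |
    #            gap_unknown | ambiguous_overlap | degenerate


def pearson_r(profile: IsotopeProfile) -> float:
    """Pearson product-moment correlation of (δ13C, δ18O) along the profile."""
    if len(profile) < 4:
        raise ValueError(
            f"shell {profile.shell_id}: need >= 4 samples for correlation, "
            f"got {len(profile)}"
        )
    c = np.asarray(profile.d13c)
    o = np.asarray(profile.d18o)
    if np.ptp(c) == 0 or np.ptp(o) == 0:
        raise DegenerateSeriesError(
            f"shell {profile.shell_id}: constant series, correlation undefined"
        )
    return float(stats.pearsonr(c, o).statistic)


def fisher_interval(
    r_ref: float, n_ref: int, level: float = 0.95
) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient.

    z = atanh(r) is approximately normal with standard deviation
    1/sqrt(n - 3); the interval is tanh(z -/+ z_crit / sqrt(n - 3)).
    """
    if n_ref <= 3:
        raise ValueError(f"n_ref must exceed 3, got {n_ref}")
    if not abs(r_ref) < 1:
        raise ValueError(f"|r_ref| must be < 1, got {r_ref}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = math.atanh(r_ref)
    w = stats.norm.ppf(0.5 + level / 2) / math.sqrt(n_ref - 3)
    return math.tanh(z - w), math.tanh(z + w)


def build_calibration(
    refs: Sequence[tuple[str, float, int]] = DEFAULT_CALIBRATION,
    level: float = 0.95,
) -> list[HabitatCalibration]:
    """Attach Fisher-z CIs to reference correlations, sorted by r ascending."""
    if not refs:
        raise ValueError("need at least one reference habitat")
    habitats = [h for h, _, _ in refs]
    if len(set(habitats)) != len(habitats):
        raise ValueError("reference habitats must be distinct")
    cals = []
    for habitat, r_ref, n_ref in refs:
        lo, hi = fisher_interval(r_ref, n_ref, level)
        cals.append(HabitatCalibration(habitat, r_ref, n_ref, lo, hi))
    cals.sort(key=lambda c: (c.r_ref, c.habitat))  # habitat label breaks r ties
    for a, b in zip(cals, cals[1:]):
        if b.ci_low <= a.ci_high:
            warnings.warn(
                f"confidence intervals of {a.habitat} and {b.habitat} overlap; "
                "classification may return ambiguous_overlap",
                CalibrationOverlapWarning,
                stacklevel=2,
            )
    return cals


def classify_shell(
    r_obs: float, calibration: Sequence[HabitatCalibration], shell_id: str = ""
) -> ProvenanceAssignment:
    """Assign a habitat to one observed correlation.

    Deterministic total partition of [-1, 1]: inside exactly one CI ->
    that habitat; below every interval -> the lowest-r habitat (the marine
    extension); above every interval -> the highest-r habitat; in a gap
    between intervals -> unknown; inside two or more overlapping
    intervals -> unknown.
    """
    if not calibration:
        raise ValueError("calibration is empty")
    hits = [c for c in calibration if c.contains(r_obs)]
    if len(hits) == 1:
        return ProvenanceAssignment(shell_id, r_obs, hits[0].habitat, "within_ci")
    if len(hits) > 1:
        return ProvenanceAssignment(shell_id, r_obs, UNKNOWN, "ambiguous_overlap")
    if r_obs < calibration[0].ci_low:
        return ProvenanceAssignment(
            shell_id, r_obs, calibration[0].habitat, "below_marine_extension"
        )
    if r_obs > calibration[-1].ci_high:
        return ProvenanceAssignment(
            shell_id, r_obs, calibration[-1].habitat, "above_estuary_extension"
        )
    return ProvenanceAssignment(shell_id, r_obs, UNKNOWN, "gap_unknown")


class HabitatClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based habitat classifier over δ13C–δ18O correlations.

    Parameters
    ----------
    calibration : sequence of (habitat, r_ref, n_ref)
        Modern reference correlations; defaults to the three-habitat
        open-coast / lower-estuary / upper-estuary calibration.
    ci_level : float
        Confidence level of the Fisher-z reference intervals.

    Attributes
    ----------
    calibrations_ : list of HabitatCalibration
        References with CI bounds attached, sorted by r_ref.
    classes_ : ndarray of str
        Habitat labels plus ``"unknown"``.
    """

    def __init__(
        self,
        calibration: Sequence[tuple[str, float, int]] = DEFAULT_CALIBRATION,
        ci_level: float = 0.95,
    ):
        self.calibration = calibration
        self.ci_level = ci_level

    def fit(self, X=None, y=None) -> "HabitatClassifier":
        """Build the reference intervals (no data needed: the calibration
        is a parameter, not learned)."""
        self.calibrations_ = build_calibration(self.calibration, self.ci_level)
        self.classes_ = np.array([c.habitat for c in self.calibrations_] + [UNKNOWN])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "calibrations_"):
            raise RuntimeError("HabitatClassifier is not fitted; call fit() first")

    def assign(self, r_obs: float, shell_id: str = "") -> ProvenanceAssignment:
        self._check_fitted()
        return classify_shell(r_obs, self.calibrations_, shell_id)

    def predict(self, X) -> np.ndarray:
        """Habitat labels for an array of correlation coefficients or a
        collection of profiles."""
        self._check_fitted()
        out = []
        for x in X:
            if isinstance(x, IsotopeProfile):
                try:
                    r = pearson_r(x)
                except DegenerateSeriesError:
                    out.append(UNKNOWN)
                    continue
            else:
                r = float(x)
            out.append(self.assign(r).habitat)
        return np.array(out)


def classify_assemblage(
    profiles: Iterable[IsotopeProfile],
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every shell and tabulate per-site habitat proportions.

    Returns ``(assignments, proportions)``: one assignment row per shell
    (counts conserved; degenerate shells become unknown), and per-site
    habitat proportions summing to 1.
    """
    config = config or AnalysisConfig()
    clf = HabitatClassifier(config.calibration, config.ci_level).fit()
    rows = []
    for p in profiles:
        try:
            r = pearson_r(p)
            a = clf.assign(r, p.shell_id)
            habitat, rule, r_obs = a.habitat, a.rule, a.r_obs
        except DegenerateSeriesError:
            habitat, rule, r_obs = UNKNOWN, "degenerate", float("nan")
        rows.append(
            {
                "shell_id": p.shell_id,
                "site": p.site,
                "unit": p.unit,
                "n_samples": len(p),
                "r_obs": r_obs,
                "habitat": habitat,
                "rule": rule,
            }
        )
    assignments = pd.DataFrame(
        rows,
        columns=["shell_id", "site", "unit", "n_samples", "r_obs", "habitat", "rule"],
    )
    if assignments.empty:
        proportions = pd.DataFrame(columns=["site", "habitat", "count", "proportion"])
    else:
        counts = (
            assignments.groupby(["site", "habitat"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
        counts["proportion"] = counts.groupby("site")["count"].transform(
            lambda c: c / c.sum()
        )
        proportions = counts
    return assignments, proportions
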