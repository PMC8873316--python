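"""Domain types, CSV schema and configuration shared by all analysis stages.

The unit of analysis is an :class:`IsotopeProfile`: one shell's ordered
sequence of micromilled carbonate samples, each carrying δ13C and δ18O in
‰ VPDB.  Sample index 0 is the ontogenetically oldest sample; the last
sample is the ventral margin (shell edge), deposited at the moment of
death and therefore recording the capture conditions.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "IsotopeSample",
    "IsotopeProfile",
    "AnalysisConfig",
    "SchemaError",
    "ParseError",
    "IntegrityError",
    "ValidationError",
    "ConfigError",
    "DegeneracyWarning",
    "read_profiles",
    "write_profiles",
    "validate_profile",
    "load_config",
]

#: Canonical CSV columns (one row per milled sample).
REQUIRED_COLUMNS = ("shell_id", "site", "unit", "sample_index", "d13c_vpdb", "d18o_vpdb")
OPTIONAL_COLUMNS = ("distance_um", "role")

#: Profiles with at least this many samples are assumed to be baseline
#: (full sub-seasonal) series when no explicit role is given.
ROLE_INFERENCE_THRESHOLD = 20

ISOTOPE_SANITY_BOUND = 20.0  # |δ| ‰ beyond which biogenic calcite is implausible


class SchemaError(ValueError):
    """A required CSV column is missing."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


class IntegrityError(ValueError):
    """Duplicate or inconsistent rows within a shell."""


class ValidationError(ValueError):
    """A profile violates an invariant required downstream."""


class ConfigError(ValueError):
    """Bad configuration file or parameter value."""


class DegeneracyWarning(UserWarning):
    """A constant isotope series: correlation undefined downstream."""


@dataclass(frozen=True)
class IsotopeSample:
    """One micromilled carbonate sample along the growth axis."""

    index: int
    d13c: float
    d18o: float
    distance_um: float | None = None

    def __post_init__(self) -> None:
        for name in ("d13c", "d18o"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
            if abs(v) > ISOTOPE_SANITY_BOUND:
                raise ValidationError(
                    f"|{name}| = {abs(v):.2f}‰ exceeds the {ISOTOPE_SANITY_BOUND}‰ "
                    "sanity bound for biogenic calcite"
                )


@dataclass(frozen=True)
class IsotopeProfile:
    """One shell's ordered isotope series with site/unit metadata.

    ``role`` distinguishes long baseline series (~30 samples, used for the
    seasonal δ18O range and SST reconstruction) from short seasonality
    series (~10 samples, season-of-capture only).
    """

    shell_id: str
    site: str
    unit: str
    samples: tuple[IsotopeSample, ...]
    role: str = "seasonality"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("baseline", "seasonality"):
            raise ValidationError(f"unknown role {self.role!r}")
        idx = [s.index for s in self.samples]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"shell {self.shell_id}: sample indices must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def d13c(self) -> list[float]:
        return [s.d13c for s in self.samples]

    @property
    def d18o(self) -> list[float]:
        return [s.d18o for s in self.samples]

    @property
    def edge_sample(self) -> IsotopeSample:
        """The ventral-margin (last-deposited) sample."""
        return self.samples[-1]


#: Modern reference correlations (habitat, r_ref, n_ref).  The r values are
#: the published modern-mussel calibration; the n values are the calibration
#: sample sizes that reproduce the published 2-decimal CI bounds.
DEFAULT_CALIBRATION: tuple[tuple[str, float, int], ...] = (
    ("open_coast", -0.27, 159),
    ("lower_estuary", 0.13, 88),
    ("upper_estuary", 0.56, 88),
)


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline; one seed governs all randomness."""

    ci_level: float = 0.95
    trend_window: int = 10
    edge_window: int = 1
    calibration: list[tuple[str, float, int]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_CALIBRATION]
    )
    baseline_filter: str = "all"  # all | open_coast_only
    quartile_mode: str = "range"  # range | distribution
    modern_d18o_w: float = 0.9  # ‰ VSMOW
    sea_level_m: float = 0.0  # relative to modern; negative = below
    correction_per_m: float = 0.011  # ‰ per metre of sea level
    sea_level_by_site: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.trend_window < 2:
            raise ConfigError("trend_window must be >= 2")
        if self.edge_window < 1:
            raise ConfigError("edge_window must be >= 1")
        if self.baseline_filter not in ("all", "open_coast_only"):
            raise ConfigError(f"unknown baseline_filter {self.baseline_filter!r}")
        if self.quartile_mode not in ("range", "distribution"):
            raise ConfigError(f"unknown quartile_mode {self.quartile_mode!r}")
        habitats = [h for h, _, _ in self.calibration]
        if len(set(habitats)) != len(habitats):
            raise ConfigError("calibration habitats must be distinct")

    def sea_level_for(self, site: str) -> float:
        return self.sea_level_by_site.get(site, self.sea_level_m)


def read_profiles(path: str | Path) -> list[IsotopeProfile]:
    """Read the canonical per-sample CSV into one profile per shell.

    Rows are grouped by ``shell_id`` and sorted by ``sample_index``; the row
    count is conserved.  Raises :class:`SchemaError`, :class:`ParseError` or
    :class:`IntegrityError` on malformed input.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"shell_id": str, "site": str, "unit": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        raise SchemaError(f"unrecognised column(s): {', '.join(unknown)}")

    for col in ("sample_index", "d13c_vpdb", "d18o_vpdb"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna()]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based, +1 for header
            raise ParseError(
                f"non-numeric value {df.loc[bad[0], col]!r} in column {col!r} "
                f"at file row {row}"
            )
        df[col] = parsed

    dup = df.duplicated(subset=["shell_id", "sample_index"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["shell_id", "sample_index"]]
        raise IntegrityError(
            f"duplicate (shell_id, sample_index) = "
            f"({pair['shell_id']!r}, {int(pair['sample_index'])})"
        )

    profiles: list[IsotopeProfile] = []
    for shell_id, grp in df.groupby("shell_id", sort=True):
        grp = grp.sort_values("sample_index")
        samples = tuple(
            IsotopeSample(
                index=int(r.sample_index),
                d13c=float(r.d13c_vpdb),
                d18o=float(r.d18o_vpdb),
                distance_um=(
                    float(r.distance_um)
                    if "distance_um" in grp.columns and pd.notna(r.distance_um)
                    else None
                ),
            )
            for r in grp.itertuples()
        )
        if "role" in grp.columns and pd.notna(grp["role"].iloc[0]):
            role = str(grp["role"].iloc[0])
        else:
            role = "baseline" if len(samples) >= ROLE_INFERENCE_THRESHOLD else "seasonality"
        profiles.append(
            IsotopeProfile(
                shell_id=str(shell_id),
                site=str(grp["site"].iloc[0]),
                unit=str(grp["unit"].iloc[0]),
                samples=samples,
                role=role,
            )
        )
    return profiles


def write_profiles(profiles: Iterable[IsotopeProfile], path: str | Path) -> None:
    """Write profiles back to the canonical CSV schema."""
    rows = []
    for p in profiles:
        for s in p.samples:
            rows.append(
                {
                    "shell_id": p.shell_id,
                    "site": p.site,
                    "unit": p.unit,
                    "sample_index": s.index,
                    "d13c_vpdb": round(s.d13c, 6),
                    "d18o_vpdb": round(s.d18o, 6),
                    "distance_um": s.distance_um,
                    "role": p.role,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_profile(profile: IsotopeProfile, min_samples: int = 4) -> IsotopeProfile:
    """Check downstream invariants; returns the profile (possibly flagged).

    A constant δ13C or δ18O series leaves the Pearson correlation undefined:
    such profiles get ``degenerate=True`` and a :class:`DegeneracyWarning`
    rather than an error, so the pipeline can still count them (as unknown
    habitat).
    """
    if len(profile) < min_samples:
        raise ValidationError(
            f"shell {profile.shell_id}: {len(profile)} samples < "
            f"min_samples={min_samples}"
        )
    degenerate = len(set(profile.d13c)) == 1 or len(set(profile.d18o)) == 1
    if degenerate and not profile.degenerate:
        warnings.warn(
            f"shell {profile.shell_id}: constant isotope series, "
            "correlation undefined",
            DegeneracyWarning,
            stacklevel=2,
        )
        return dataclasses.replace(profile, degenerate=True)
    return profile


_CONFIG_KEYS = {f.name for f in dataclasses.fields(AnalysisConfig)}


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; absent keys take defaults."""
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "calibration" in raw:
        raw["calibration"] = [
            (str(h), float(r), int(n)) for h, r, n in raw["calibration"]
        ]
    return AnalysisConfig(**raw)
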