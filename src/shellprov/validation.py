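"""Self-validation harnesses: parameter recovery, calibration and end-to-end runs.

These functions exercise the whole package against simulated shells with
known truth and against independent statistical oracles.  They back both
the acceptance test suite and the reproduction script; each returns plain
numbers so results can be reported or asserted.
"""

from __future__ import annotations

import dataclasses
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .paleothermo import compare_sst
from .pipeline import run_pipeline, write_outputs
from .profiles import AnalysisConfig, DEFAULT_CALIBRATION
from .provenance import HabitatClassifier, fisher_interval, pearson_r
from .synthetic import (
    DEFAULT_HABITATS,
    EnvironmentParams,
    paper_shaped_specs,
    simulate_assemblage,
    simulate_shell,
)

__all__ = [
    "reference_ci_bounds",
    "habitat_recovery_rate",
    "season_recovery_rate",
    "anova_type1_rate",
    "fisher_vs_bootstrap",
    "end_to_end_run",
    "sst_recovery_error",
]


def reference_ci_bounds(level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Fisher-z CI bounds for the three modern reference correlations."""
    return {
        habitat: fisher_interval(r, n, level)
        for habitat, r, n in DEFAULT_CALIBRATION
    }


def habitat_recovery_rate(
    n_samples: int,
    n_shells_per_habitat: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of statistical-mode shells assigned their true habitat.

    Each habitat's shells are generated at its reference correlation; the
    sampling noise of r at the given per-shell sample count is the only
    obstacle to recovery.  Returns per-habitat rates plus ``"overall"``.
    """
    env = EnvironmentParams()
    clf = HabitatClassifier().fit()
    ss = np.random.SeedSequence(seed)
    rates: dict[str, float] = {}
    correct_total = 0
    for habitat, hp in DEFAULT_HABITATS.items():
        correct = 0
        for child in ss.spawn(n_shells_per_habitat):
            rng = np.random.default_rng(child)
            doy = float(rng.uniform(1, 365))
            prof, _ = simulate_shell(
                env, hp, doy, n_samples, max(365.0, float(n_samples)), seed=rng
            )
            if clf.assign(pearson_r(prof)).habitat == habitat:
                correct += 1
        rates[habitat] = correct / n_shells_per_habitat
        correct_total += correct
    rates["overall"] = correct_total / (n_shells_per_habitat * len(DEFAULT_HABITATS))
    return rates


def season_recovery_rate(
    noise_sd_d18o: float | None = None, seed: int = 0
) -> float:
    """Fraction of simulated shells whose pipeline season matches the
    quartile truth of their noise-free edge δ18O.

    ``noise_sd_d18o=None`` keeps the default measurement noise; pass 0.0
    for the noise-free contract.
    """
    habitats = DEFAULT_HABITATS
    if noise_sd_d18o is not None:
        habitats = {
            k: dataclasses.replace(v, noise_sd_d18o=noise_sd_d18o)
            for k, v in habitats.items()
        }
    profiles, truth = simulate_assemblage(
        paper_shaped_specs(), seed=seed, habitats=habitats
    )
    seasons = run_pipeline(profiles)["seasons"]
    merged = seasons.merge(truth, on="shell_id", validate="1:1")
    return float((merged.season == merged.quartile_truth_season).mean())


def anova_type1_rate(
    n_sims: int = 1000,
    n_sites: int = 3,
    n_shells: int = 8,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of the site ANOVA under the null.

    All sites draw per-shell mean SSTs from the same normal law
    (17 °C, sd 1 °C); the rejection rate at ``alpha`` should match
    ``alpha`` for a correctly calibrated test.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    sites = [f"s{i}" for i in range(n_sites)]
    for _ in range(n_sims):
        vals = rng.normal(17.0, 1.0, size=(n_sites, n_shells))
        df = pd.DataFrame(
            {
                "shell_id": [f"{s}_{j}" for s in sites for j in range(n_shells)],
                "site": np.repeat(sites, n_shells),
                "t_min_c": vals.ravel(),
                "t_mean_c": vals.ravel(),
                "t_max_c": vals.ravel(),
            }
        )
        out = compare_sst(df, statistic="mean")
        p = float(out.loc[out.test == "anova", "p"].iloc[0])
        rejections += p < alpha
    return rejections / n_sims


def fisher_vs_bootstrap(
    true_r: float = 0.5,
    n: int = 500,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Largest disagreement between the Fisher-z CI and a percentile
    bootstrap CI of r on one large bivariate-normal sample."""
    rng = np.random.default_rng(seed)
    cov = [[1.0, true_r], [true_r, 1.0]]
    x, y = rng.multivariate_normal([0.0, 0.0], cov, size=n).T
    r_hat = float(np.corrcoef(x, y)[0, 1])
    idx = rng.integers(0, n, size=(n_boot, n))
    xs = x[idx] - x[idx].mean(axis=1, keepdims=True)
    ys = y[idx] - y[idx].mean(axis=1, keepdims=True)
    boots = (xs * ys).sum(axis=1) / np.sqrt(
        (xs**2).sum(axis=1) * (ys**2).sum(axis=1)
    )
    b_lo, b_hi = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
    f_lo, f_hi = fisher_interval(r_hat, n, 0.95)
    return {
        "fisher_low": f_lo,
        "fisher_high": f_hi,
        "bootstrap_low": b_lo,
        "bootstrap_high": b_hi,
        "max_bound_gap": max(abs(f_lo - b_lo), abs(f_hi - b_hi)),
    }


def end_to_end_run(
    seed: int = 0, output_dir: str | Path | None = None
) -> dict[str, float]:
    """Simulate the 34-shell three-site assemblage, run every stage and
    write the five output CSVs; returns shell/table counts and site SSTs."""
    profiles, truth = simulate_assemblage(paper_shaped_specs(), seed=seed)
    tables = run_pipeline(profiles)
    if output_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            written = write_outputs(tables, tmp)
    else:
        written = write_outputs(tables, output_dir)
    ids = {p.shell_id for p in profiles}
    conserved = all(
        set(tables[k]["shell_id"]) == ids
        for k in ("provenance", "seasons", "sst_per_shell")
    )
    summary = tables["sst_site_summary"]
    mean_rows = summary[summary.statistic == "mean"]
    return {
        "n_shells": float(len(profiles)),
        "n_output_files": float(len(written)),
        "counts_conserved": float(conserved),
        "sst_site_mean_min_c": float(mean_rows.mean_c.min()),
        "sst_site_mean_max_c": float(mean_rows.mean_c.max()),
    }


def sst_recovery_error(seed: int = 0) -> dict[str, float]:
    """Absolute error of reconstructed site min/mean/max SST against the
    generating 12–22 °C sinusoid, on the baseline shells of a simulated
    assemblage at default measurement noise."""
    env = EnvironmentParams()
    profiles, truth = simulate_assemblage(paper_shaped_specs(), seed=seed)
    tables = run_pipeline(profiles)
    summary = tables["sst_site_summary"]
    true_vals = {
        "min": env.sst_mean - env.sst_amplitude,
        "mean": env.sst_mean,
        "max": env.sst_mean + env.sst_amplitude,
    }
    errors = {
        stat: float(
            np.abs(summary[summary.statistic == stat].mean_c - true_vals[stat]).max()
        )
        for stat in ("min", "mean", "max")
    }
    errors["max_abs_error_c"] = max(errors.values())
    return errors
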