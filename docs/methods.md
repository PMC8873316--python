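# Methods

## Provenance classification

Each shell's habitat of harvest is inferred from the Pearson correlation
r between its δ13C and δ18O series. The mechanism: estuarine freshwater
is depleted in both 13C (soil/respired DIC) and 18O (meteoric water), so
along a salinity gradient the two carbonate isotopes co-vary positively;
in fully marine water δ18O tracks temperature while δ13C does not, giving
a weak negative correlation.

The classifier holds three modern reference correlations — open coast
r = −0.27 (n = 159), lower estuary r = +0.13 (n = 88), upper estuary
r = +0.56 (n = 88) — and brackets each with a Fisher-z confidence
interval: z = atanh(r) is treated as normal with sd 1/√(n − 3), so the
bounds are tanh(z ∓ z_crit/√(n − 3)) with z_crit = 1.960 at the 95%
level. The reference sample sizes are not part of the published
calibration summary; they were recovered by solving for the n whose
interval bounds round to the published two-decimal values
((−0.41, −0.12), (−0.08, 0.33), (0.40, 0.69)) — n = 159 fits the marine
reference (any n in [151, 167] rounds identically) and n = 88 fits both
estuarine references. The defaults reproduce all six printed bounds
exactly and can be overridden in the configuration as
(habitat, r_ref, n_ref) triples.

Decision surface (a total, deterministic partition of [−1, 1]):

- inside exactly one interval → that habitat (intervals are treated as
  closed, matching the `ci_low ≤ r ≤ ci_high` convention);
- below every interval → open coast; above every interval → upper
  estuary (the correlation gradient is monotone in freshwater influence,
  so more-extreme values can only mean more-extreme habitats);
- in a gap between intervals, or inside two overlapping intervals →
  `unknown` (with the rule recorded: `gap_unknown` / `ambiguous_overlap`).

The lower-estuary reference sign deserves a note: published summaries of
the calibration disagree internally (−0.13 vs +0.13); only +0.13 is
consistent with the interval (−0.08, 0.33), so +0.13 is used.

Pearson (not rank) correlation is required: the Fisher-z machinery and
the reference coefficients presuppose it. The Fisher interval is
cross-checked in the tests against a nonparametric percentile bootstrap
(n = 500, 2000 resamples), agreeing to within 0.003–0.006 per bound.

## Season of capture

The baseline is the pooled δ18O of a site's baseline-role shells — the
long (~30-sample) series sub-sampled across a full year. Its [min, max]
range is divided into four **equal-width** bands (Q1 lowest δ18O … Q4
highest). An alternative reading — distribution quartiles of the pooled
values — is available via `quartile_mode="distribution"`; equal-width is
the default because a range "divided into quartiles" most naturally means
a range partition, and because distribution quartiles would entangle the
band boundaries with the (uneven) time the sinusoid spends per δ18O
level.

The edge value is the final sample's δ18O by default (`edge_window = 1`:
the ventral margin is the death surface); a wider trailing mean is
configurable. Band → season:

| band | meaning | season |
|------|---------|--------|
| Q4 | coldest water | winter |
| Q1 | warmest water | summer |
| Q2/Q3, rising δ18O trend | cooling limb | autumn |
| Q2/Q3, falling trend | warming limb | spring |
| Q2/Q3, flat trend | ambiguous | Q2 → spring, Q3 → autumn, `confirmed=False` |

The trend is the OLS slope of δ18O against sample position over the last
`trend_window = 10` samples (clipped to the profile length; |slope| ≤
1e-12 counts as flat). For Q1/Q4 the trend does not reassign the season
but sets the `confirmed` flag: Q4 expects a rising-or-flat approach, Q1
falling-or-flat. Edge values outside the baseline range (possible for
non-baseline shells) clamp to Q1/Q4 with `out_of_range=True`. Interior
band boundaries belong to the upper band; the maximum belongs to Q4.

The `open_coast_only` baseline filter rebuilds the range from shells
classified open-coast, excluding estuarine specimens whose δ18O carries a
freshwater overprint on top of temperature; comparing the two runs shows
exactly which assignments flip.

## Palaeothermometry

Temperature is recovered from the calcite–water fractionation
relationship

    1000 ln α = 2.78e6 / T² − 2.89      (T in Kelvin)
    α = (1000 + δ18O_s) / (1000 + δ18O_w)   (both ‰ VSMOW)

Carbonate measurements arrive on the VPDB scale and are converted with
δ_VSMOW = 1.03091 δ_VPDB + 30.91 (the standard carbonate-scale affine
map). The ambient water value is

    δ18O_w = 0.9 − sea_level_m × 0.011   (‰ VSMOW, sea_level_m ≤ 0)

i.e. the modern local value enriched by 0.011‰ per metre of sea level
below modern — ice sheets sequester isotopically light water, so a lower
sea stand means a heavier ocean. Sea level can be set per site (sites of
different age saw different stands); δ18O_w can also be overridden
directly. All intermediate math is double precision in Kelvin; the
closed-form inverse (used by the simulator) round-trips to < 1e-6 °C
over 0–30 °C × 0–2‰ water. Domain guard: 1000 ln α + 2.89 must be
positive (violated only below ≈ −32‰ VPDB, far outside biogenic calcite).

Per shell, all samples are converted and the minimum / mean / maximum
taken; per site, these per-shell statistics are averaged (± sample,
n−1, sd) over the **baseline shells only** — short edge-targeted series
do not span the year and would bias the extremes toward their capture
season. Single-shell sites report sd = 0 with a flag. Between-site
comparison: one-way fixed-effects ANOVA on the per-shell statistic,
followed by all pairwise Welch (unpooled-variance) t-tests, reported with
both unadjusted and Holm-adjusted p so either multiplicity reading can be
inspected. Sites with fewer than two shells are excluded with a warning.

## Synthetic shells

The simulator emulates the study design: sites of 10–13 shells, of which
four are baseline shells (~30 samples spanning a full year) and the rest
seasonality shells (~10 samples over ~120 days), 34 shells across three
sites in the canonical configuration. The environment is a sinusoid,
SST(d) = 17 + 5 cos(2π(d − 212)/365) °C (12–22 °C, peak late July),
marine water 0.9‰ VSMOW. Sample dates are evenly spaced and end exactly
at the capture day; growth is time-uniform (no winter cessation — the
quartile method itself assumes the edge records the capture season, so
the generator's default honours that assumption; violating it is future
work).

Two habitat modes:

- **statistical** (default): δ18O is the marine thermometer signal plus
  N(0, 0.05‰) noise; δ13C is built to have population correlation
  `target_r` with it (δ13C = μ_c + σ_c(r·z + √(1−r²)·ε), z the
  standardized δ18O). μ_c = 1.0‰, σ_c = 0.4‰ are realistic marine mussel
  calcite values (not part of the published calibration). This mode
  guarantees the classifier-facing structure and is used for recovery
  rates.
- **mechanistic**: a seasonal freshwater mixing fraction
  f(d) = A·clip(½(1 + cos) + N(0, 0.05)), peaking opposite the SST
  maximum, depresses water δ18O by −8‰·f and δ13C by −6‰·f (plausible
  placeholder end-members chosen only to reproduce the sign and order of
  the correlation gradient; A = 0 / 0.15 / 0.45 for open coast / lower /
  upper estuary). The δ13C–δ18O correlation then *emerges* from the
  shared freshwater control, confirming the gradient is reproducible from
  first principles.

Truth records per shell: habitat, capture day-of-year, its meteorological
calendar season (DJF/MAM/JJA/SON), the `quartile_truth_season` — the
season the decision table assigns to the *noise-free* edge δ18O against
the noise-free annual δ18O range — and the generating SST min/mean/max
over the sampled window. Quartile truth, not calendar truth, is the
recovery target: the sinusoid spends unequal time in each δ18O band, so
quartile and calendar season can legitimately differ near band edges;
calendar agreement is reported separately by the truth table.

All randomness flows from one seed through a `numpy` `SeedSequence`
spawn tree; every simulate function is a pure function of (parameters,
seed).

## Validation harness and problem sizes

`shellprov.validation` backs both the acceptance tests and
`scripts/acceptance.py`:

- habitat recovery: 200 shells per habitat, statistical mode, at 200 and
  at 30 samples per shell. At 200 samples the sampling sd of r (~0.07 on
  the z scale) sits well inside the reference bands (measured ≥ 99%
  correct); at 30 samples it genuinely overlaps them (measured ~80%,
  against a ≥ 60% contract) — the residual error is irreducible sampling
  noise of r, not a classifier defect.
- season recovery: the 34-shell assemblage at zero and at default
  measurement noise (measured 100% in both at the tested seeds; the
  noise-free contract is exact).
- ANOVA calibration: 1000 null data sets (3 sites × 8 shells from one
  normal law) through the same `compare_sst` code path as real data;
  rejection rate at α = 0.05 must land in 5% ± 1.5% Monte-Carlo band.
- Fisher vs bootstrap: one n = 500 bivariate-normal sample, 2000
  percentile-bootstrap resamples, bounds compared at ±0.03.
- end-to-end: the full pipeline on the 34-shell assemblage, checking the
  five output tables and shell-count conservation.

These sizes keep the full suite under ~2 minutes on one CPU while leaving
the Monte-Carlo tolerances comfortably resolvable.

## What the simulations do and do not show

Passing recovery tests demonstrates internal consistency: the pipeline
inverts its own generative model. Real shells add effects the generator
omits — growth-rate variation and winter growth cessation (edge may not
record the capture season), time-averaging within each milled sample,
vital effects and diagenesis, tidally driven short-term mixing, and
reference correlations estimated from a different population than the
archaeological one. Conclusions about real assemblages inherit those
caveats; the nine-shell extension rule in particular (extreme r values
assigned to the outer habitats) is a convention, not a mechanism.

## Degenerate inputs and tie-breaks

Constant isotope series → correlation undefined → habitat `unknown`
(rule `degenerate`), warned, still counted. Identical reference r values
→ deterministic order by habitat label, overlap warning. Exactly zero
trend slope → flat, resolved by band side, `confirmed=False`. Profiles
need ≥ 4 samples for correlation (three determine r exactly; one more for
stability). CSV role column optional: absent, profiles with ≥ 20 samples
are treated as baseline.
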