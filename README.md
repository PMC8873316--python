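# shellprov

Provenance, season of capture and palaeotemperature from sequentially
sampled mussel-shell carbonate isotopes.

Archaeological shell middens preserve mollusc shells whose carbonate grew
in isotopic equilibrium with the water the animal lived in. From a series
of micromilled samples along a shell's growth axis (δ13C and δ18O, ‰
VPDB), `shellprov` answers three questions about each shell:

1. **Where was it harvested?** Freshwater entering an estuary depletes
   both the dissolved inorganic carbon δ13C and the water δ18O, so the
   per-shell Pearson correlation r(δ13C, δ18O) grades from weakly negative
   in fully marine habitats to strongly positive up-estuary. Each shell's
   r is compared against Fisher-z 95% confidence intervals of modern
   reference correlations — open coast (r = −0.27), lower estuary
   (r = +0.13), upper estuary (r = +0.56), giving intervals
   (−0.41, −0.12), (−0.08, 0.33) and (0.40, 0.69). Values below −0.41 or
   above 0.69 extend to the extreme habitats; values in the gaps between
   intervals stay `unknown`.
2. **When was it harvested?** Shell-edge carbonate (the ventral margin)
   records the capture conditions. The pooled δ18O range of the fully
   sampled baseline shells at a site is divided into four equal-width
   quartile bands — highest δ18O = coldest water = winter, lowest =
   summer — and the edge value is located within them. The two
   intermediate bands are split by the ordinary-least-squares δ18O trend
   over the last ten samples: rising δ18O (cooling) → autumn, falling
   (warming) → spring.
3. **How warm was the sea?** Calcite–water oxygen-isotope fractionation
   is inverted for temperature:

       1000 ln α = 2.78·10⁶ / T² − 2.89,   α = (1000 + δ18O_s) / (1000 + δ18O_w)

   with T in Kelvin and both δ values on the VSMOW scale
   (δ_VSMOW = 1.03091 δ_VPDB + 30.91). The ambient water δ18O_w starts
   from the modern value (0.9‰ VSMOW) and is corrected for ice-volume by
   +0.011‰ per metre of sea level below modern.

A forward simulator generates shell profiles with known habitat, capture
day and temperature regime, so every stage is validated against ground
truth without any external data.

The three stages are scikit-learn-style estimators — `HabitatClassifier`
(fit/predict), `SeasonClassifier` (fit/predict) and `SSTReconstructor`
(transform) — and compose with sklearn pipelines; plain functions
(`fisher_interval`, `classify_shell`, `assign_season`, `sst_from_d18o`, …)
wrap the same logic.

## Worked example

```python
import shellprov as sp

profiles, truth = sp.simulate_assemblage(sp.paper_shaped_specs(), seed=42)
tables = sp.run_pipeline(profiles)
print(tables["provenance"].head(5).to_string(index=False))
print(tables["sst_site_summary"][["site", "statistic", "mean_c", "sd_c"]]
      .head(3).to_string(index=False))
```

prints

```
shell_id   site unit  n_samples     r_obs       habitat      rule
sim_0001 site_A    1         30 -0.022344 lower_estuary within_ci
sim_0002 site_A    1         30 -0.045635 lower_estuary within_ci
sim_0003 site_A    1         30 -0.162725    open_coast within_ci
sim_0004 site_A    1         30 -0.263567    open_coast within_ci
sim_0005 site_A    1         10 -0.272884    open_coast within_ci
  site statistic    mean_c     sd_c
site_A       min 11.797376 0.173990
site_A      mean 16.957425 0.031781
site_A       max 22.123409 0.111742
```

Each provenance row shows the shell's δ13C–δ18O correlation and the
habitat whose confidence interval captured it (`rule` records which
branch of the classifier fired). The site summary is the mean ± sample
sd, over the site's baseline shells, of the per-shell minimum / mean /
maximum reconstructed temperature — here recovering the simulator's
12–22 °C (mean 17 °C) seasonal regime to within the ~0.2 °C imprint of
measurement noise on the seasonal extremes. The same pipeline runs from
the shell (`run-all` also writes `seasons.csv` and `comparisons.csv`,
the ANOVA + pairwise Welch t-tests between sites):

```sh
shellprov simulate --seed 42 --output sim/
shellprov run-all --input sim/profiles.csv --output out/
```

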