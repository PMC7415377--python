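# phycohealth

Culture health scoring and phycosphere community analysis for outdoor
microalgal reactors.

Open raceway cultures of biofuel algae such as *Chlorella sorokiniana* host
a bacterial community — the phycosphere — whose composition tracks, and may
drive, culture performance: predatory bacteria like *Vampirovibrio
chlorellavorus* crash cultures, while putative mutualists (Rhizobiales,
Burkholderiaceae) associate with healthy growth. `phycohealth` provides the
computational side of linking 16S ASV count tables to reactor performance,
for algal cultivation researchers and microbiome analysts:

- **Health Index (HI).** Observed daytime growth
  `μ_obs = ln(AFDW_e/AFDW_m)/(t_e−t_m)` is compared with the prediction
  `μ_model` of a healthy-growth simulator (cardinal-temperature ×
  tanh-light response with Beer–Lambert self-shading, integrated over the
  sampling interval): `HI = −(μ_obs − μ_model)/μ_obs`, reported negated so
  that 0 is healthy and more negative is sicker. Areal productivity
  (g m⁻² day⁻¹) is computed alongside.
- **Community state typing.** Dirichlet-multinomial mixtures fitted to raw
  ASV counts by EM, with the number of states chosen by a Laplace
  approximation of the model evidence, and day-to-day state-transition
  graphs per reactor run.
- **Covariate differentials.** Penalized multinomial regression of counts
  on culture/weather covariates (BAC treatment, days after inoculation,
  AFDW, dissolved oxygen, productivity, temperature, precipitation, solar
  radiation, wind speed), reporting CLR-centered per-ASV differentials,
  z-score/IQR outlier flags and per-order summaries.
- **Community statistics.** Faith's PD, Jaccard / Bray–Curtis / UniFrac
  distances, PCoA, PERMANOVA, distance-to-centroid dispersion, two-group
  ANCOM (W statistic) and log-ratio/Pearson correlations.
- **Synthetic data.** A seeded generator that emulates the study design
  (baseline and survey reactor runs, growth-and-crash AFDW trajectories,
  mixture-structured counts with planted covariate effects, a pathogen
  taxon, organelle ASVs, a random phylogeny) with a truth manifest, so
  every stage is testable without sequencing data.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import phycohealth as ph

# a full synthetic reactor study with known planted structure
ds = ph.generate_dataset(ph.SyntheticScenario(seed=1))
table = ph.filter_organelles(ds.table, ds.taxonomy)   # drop organelle ASVs

# culture health for one baseline run
sc = ph.SyntheticScenario(seed=1)
series = ds.series["B01"]
records = ph.run_health_series(series, sc.growth_params)
print(records[1].mu_obs, records[1].mu_model, records[1].hi_plot)

# community states and their day-to-day transitions
model = ph.fit_dmm(table.filter_samples(
    [s for s in table.sample_ids if s.startswith("B")]), k=3, seed=1)
print(model.converged, model.neg_log_evidence)

# diversity rises with culture age
pd_series = ph.faith_pd_series(table, ds.tree)
```

Running the example prints (exact values for seed 1):

```
1.47308293683387 1.5483639211290028 -0.05110437600813966
True 31260.25197998771
```

The first line is one day's observed vs. model growth rate (day⁻¹) and the
plotted HI: the noisy run grew ~5 % slower than the healthy model predicts,
so the score is slightly negative. The second line reports the converged
3-state mixture fit and its Laplace score (lower is better across k).

A thin CLI mirrors the library for shell use:

```bash
phycohealth synth --seed 1 --out bundle/
phycohealth metrics --metadata bundle/metadata.tsv --out run1
phycohealth dmm --table bundle/feature_table.tsv --k-range 1:6 --out dmm1
phycohealth beta --table bundle/feature_table.tsv --metric jaccard --out dm.tsv
```

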