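# deprindex

A construction toolkit for **regional socioeconomic deprivation indices**
in the style of the German Index of Socioeconomic Deprivation (GISD), for
epidemiologists and health-reporting analysts who need to link health
outcomes to the socioeconomic situation of administrative regions when
individual-level socioeconomic data are unavailable.

The index summarises nine regional indicators — three each for the
**education**, **employment** and **income** dimensions — into a single
score in [0, 1] per region and year (0 = least, 1 = most deprived), on
every level of a nested administrative hierarchy (municipality → GVB →
district → spatial planning region → NUTS-2).

## Method

For each dimension *d* with harmonized, pooled-z-standardized indicators
*z₁…z₃*, the first principal component of their correlation matrix gives
loadings λᵢ and eigenvalue η = Σλᵢ². Indicator weight shares are

    sᵢ = 100·λᵢ² / Σⱼλⱼ²      (share in the dimension, %)
    gᵢ = sᵢ / 3               (share in the total index, %)

and dimension scores use regression-method factor scoring,
*score = Σᵢ (λᵢ/η)·zᵢ*, with standardization constants frozen from the
2001–2019 pooled fit so that earlier (imputed) years are scored on the
same scale. Scores are min-max normalized to [0, 1] within each year,
summed across the three dimensions (weight ⅓ each), renormalized,
aggregated to coarser levels as population-weighted means, renormalized
per level and year, and finally ranked into yearly quintiles
(1 = least deprived fifth).

Before weighting, the raw panels are harmonized: currency indicators are
deflated and logged; a reporting-procedure level break, school-reform
double-cohort dips and a historically grown East–West level gap are
estimated by fixed-effects regressions and removed; single-year reporting
gaps are carried forward; remaining missing years are predicted from
linear random-intercept models.

The `epi` module provides the standard linkage analyses: direct age
standardization (2013 European Standard Population), rate trajectories by
deprivation group, multilevel Poisson rate ratios across quintiles
(log-population offset, district random intercept) and a linear
deprivation-gradient regression.

## Worked example

Everything is testable offline through the synthetic generator, which
replicates the statistical anatomy of the real indicator panels at a
reduced scale (500 municipalities, 200 GVB, 50 districts):

```python
from deprindex import GISDPipeline, SynthConfig
from deprindex.synthdata import generate_hierarchy, generate_panel

cfg = SynthConfig(seed=1)
hierarchy = generate_hierarchy(cfg)
panel, truth = generate_panel(cfg, hierarchy)

pipe = GISDPipeline(g8_cells=cfg.g8_cells,
                    price_index=cfg.price_index()).fit(panel, hierarchy)
print(pipe.loading_table_[["indicator", "dimension", "loading",
                           "share_dimension", "share_gisd"]]
      .round(3).to_string(index=False))
```

```
                           indicator  dimension  loading  share_dimension  share_gisd
         employees_university_degree  education   -0.746           36.218      12.073
     employees_without_qualification  education    0.763           37.935      12.645
school_leavers_without_qualification  education    0.630           25.847       8.616
                     employment_rate employment   -0.626           22.851       7.617
                   unemployment_rate employment    0.840           41.074      13.691
                          gross_wage employment   -0.787           36.075      12.025
                    household_income     income   -0.916           42.212      14.071
                        debtor_quota     income    0.596           17.891       5.964
                          income_tax     income   -0.890           39.898      13.299
```

Each row is one indicator's correlation with its dimension's first
principal component (sign: negative = higher values mean less
deprivation), its squared-loading share of the dimension weight, and its
share of the total index (a third of the former).

```python
district = pipe.score_panel("district")
print(district[district.year == 2019].head(3)
      .round(3).to_string(index=False))
```

```
region_id  year  score_education  score_employment  score_income  gisd  quintile quintile_group
    01000  2019            0.084             0.165         0.000 0.000         1            low
    01001  2019            0.585             0.400         0.815 0.604         4            mid
    02002  2019            0.584             0.730         0.720 0.687         5           high
```

Per district and year: the three normalized dimension scores, the total
index (0 = least deprived district of that year, 1 = most deprived) and
the yearly quintile with its low/mid/high analysis grouping.

The same pipeline is scriptable from the shell:

```bash
deprindex synth --seed 7 --out bundle/
deprindex build --hierarchy bundle/hierarchy.csv --panel bundle/panel.csv \
                --config bundle/config.yaml --levels district,gvb --out out/
```

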