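# diimlm

Dietary Inflammatory Index (DII) scoring and three-level hierarchical
regression of mental-health outcomes on diet, with empirical-Bayes
shrinkage.

## What problem this solves

Nutritional epidemiology studies often ask whether a pro-inflammatory
diet — summarised by the DII — is associated with depression, anxiety
and stress scores (DASS-42). Estimating that association *adjusted for
the foods and nutrients behind the index* is hard with ordinary
regression: nutrient intakes are exact linear functions of food intakes
through the composition matrix, foods are strongly co-consumed, and the
number of dietary regressors rivals the sample size. The conventional
adjust-for-everything model returns unstable coefficients with very
wide confidence intervals.

`diimlm` implements the hierarchical alternative for exactly this
nesting — foods at level 1, nutrients at level 2, the DII weighting at
level 3:

    y = α + C·c + F·β + ε,   ε ~ N(0, σ²I)
    β = Z·π + δ,             δ ~ N(0, τ²_food·I)
    π = w·γ + θ,             θ ~ N(0, τ²_nutrient·I)

where `F` holds standardized daily food grams, `Z` the standardized
per-100 g composition bridge, `w` the per-nutrient inflammatory effect
scores, and γ is the DII effect (reported per 1 SD of the composite
`F·Z·w`). For Gaussian outcomes this penalized-quasi-likelihood model
is a linear mixed model; the package solves the mixed-model (Henderson)
equations exactly and estimates the variance components τ² by REML
(empirical Bayes), returning shrunken food/nutrient coefficients and
the residual effects δ̂, θ̂. A synthetic cohort generator with known
ground truth stands in for undeposited study data and drives the
calibration tests.

The package also covers the supporting stages: FFQ → daily grams →
nutrient intakes, the ±3 SD daily-energy eligibility filter, DASS-42
subscale scoring, DII computation with quartiles, conventional
simple/multiple OLS comparators, Table-1/2/3-shaped reports, and a
reproducible pipeline (library API, `examples/` scripts, and a thin
`diimlm` CLI).

## Worked example

```python
import diimlm as d

# synthetic cohort at the default study scale (3,550 examined,
# 116 foods, 25 dietary parameters)
cfg = d.SimulationConfig(n_participants=1000, seed=7)
tables, truth = d.generate_cohort(cfg)

# eligibility filter: ±3 SD of daily energy
retained, excluded = d.energy_exclusion(tables.intakes)
print(f"analyzed {len(retained)} of {len(tables.intakes)}"
      f" ({len(excluded)} excluded)")

# DII per participant
dii = d.compute_dii(retained, tables.reference)
print(f"DII mean {dii['dii_overall'].mean():+.3f}"
      f" sd {dii['dii_overall'].std(ddof=1):.3f}")

# hierarchical fit of the stress score
keep = retained.index
spec = d.HierarchicalSpec(
    foods=tables.grams.loc[keep],
    composition=tables.composition,
    effect_scores=tables.reference.set_index("parameter")["effect_score"],
    covariates=tables.covariates.loc[keep],
    outcome_name="stress",
)
fit = d.fit_hierarchical(spec, tables.outcomes.loc[keep, "stress"])
lo, hi = fit.dii_ci
print(f"DII effect on stress: {fit.gamma:.3f} (95% CI {lo:.3f}, {hi:.3f})"
      f"  tau2={fit.tau2['food']:.4f}")
```

Output:

```
analyzed 986 of 1000 (14 excluded)
DII mean +0.023 sd 0.471
DII effect on stress: 4.468 (95% CI 3.474, 5.462)  tau2=0.0020
```

986/1000 analyzed mirrors the single-pass energy rule, recovering
exactly the generator's planted outliers; the DII is centered near 0
with sub-unit spread because the synthetic reference matches the cohort
means; and the hierarchical estimate lands 1.8 SE above the generator's
configured stress effect (3.552 per 1 SD of the composite) on this one
cohort — single-cohort noise, not bias: across replicate cohorts the
95% interval covers the truth at its nominal rate
(`examples/04_calibration_studies.py`).

The same run end-to-end from a shell:

```bash
diimlm simulate-and-run --seed 7 --out results/
```

which writes intakes, exclusions, outcomes, DII scores, all three model
fits (`fits.json`), Table-1/2/3-shaped CSV reports and a manifest with
input hashes and participant counts at every stage.

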