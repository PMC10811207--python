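"""Simple vs multiple vs hierarchical fits on one collinear cohort.

Reproduces the methodological contrast at a single-cohort scale: with
strongly co-consumed foods (intake correlation 0.9), the conventional
adjust-for-everything model is unstable while the hierarchical model
stays sharp. All DII coefficients are shown per 1 SD of each model's
DII regressor so interval widths are comparable.
"""

import diimlm as d
from diimlm import intake

cfg = d.SimulationConfig(
    n_participants=500, n_foods=40, n_nutrients=12,
    intake_correlation=0.9, seed=23,
)
ref = d.generate_reference_table(12, seed=23)
tables, truth = d.generate_cohort(cfg, ref)
retained, _ = d.energy_exclusion(tables.intakes)
keep = retained.index

y = tables.outcomes.loc[keep, "stress"].to_numpy(float)
score = d.compute_dii(retained, ref, quartiles=False)["dii_overall"]
cov = tables.covariates.loc[keep]

simple = d.fit_simple(y, score, outcome_name="stress")
multiple = d.fit_multiple(
    y, dii=score, covariates=cov, nutrients=retained, foods=tables.grams.loc[keep],
    outcome_name="stress",
)
spec = d.HierarchicalSpec(
    foods=tables.grams.loc[keep],
    composition=tables.composition,
    effect_scores=ref.set_index("parameter")["effect_score"],
    covariates=cov,
    outcome_name="stress",
)
hier = d.fit_hierarchical(spec, y)

report = d.compare_models([simple, multiple, hier])
print(report.round(3).to_string(index=False))
print(f"\ntrue effect: {truth.per_outcome['stress'].gamma:.3f} per SD; "
      f"{len(multiple.dropped_columns)} aliased columns dropped in the "
      "multiple model (nutrient intakes are exact combinations of foods)")

# Expect: the multiple model's interval is several times wider than the
# hierarchical one, which is the point of the shrinkage estimator.
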