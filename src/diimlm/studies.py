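"""Simulation studies: calibration and shrinkage properties of the estimators.

Each study generates independent synthetic cohorts, runs the relevant
part of the analysis pipeline on each, and summarises frequentist
performance: Wald-interval coverage of the true DII effect, recovery of
the food-level variance component, and the confidence-interval-width
contrast between the hierarchical and the conventional multiple model
on collinear designs.

Model-recovery studies score the pre-clip continuous outcome, so
calibration statements concern the linear model itself rather than the
mild censoring the bounded DASS scale adds at the extremes.
"""

from __future__ import annotations

import numpy as np

from . import dii as dii_mod
from . import model
from .intake import energy_exclusion
from .simulate import SimulationConfig, generate_cohort, generate_reference_table


def _spawn_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _fit_one(tables, reference, outcome="stress", covariates=True, **spec_kwargs):
    """Exclude energy outliers, then fit the hierarchical model."""
    retained, _ = energy_exclusion(tables.intakes)
    keep = retained.index
    spec = model.HierarchicalSpec(
        foods=tables.grams.loc[keep],
        composition=tables.composition,
        effect_scores=reference.set_index("parameter")["effect_score"],
        covariates=tables.covariates.loc[keep] if covariates else None,
        outcome_name=outcome,
        **spec_kwargs,
    )
    y = tables.outcomes.loc[keep, outcome + "_continuous"].to_numpy()
    return model.fit_hierarchical(spec, y), keep


def coverage_study(
    n_reps: int = 500,
    n_participants: int = 2000,
    seed: int = 0,
    outcome: str = "stress",
    **config_overrides,
) -> dict:
    """Wald 95% CI coverage of the true DII effect over replicate cohorts.

    Cohorts are generated at the generator's default study conditions
    (116 foods, 25 nutrients, planted energy outliers) unless
    overridden; each replicate applies the energy exclusion and fits the
    hierarchical model with REML variance components.
    """
    seeds = _spawn_seeds(seed, 2 * n_reps)
    covered, zs = 0, []
    for r in range(n_reps):
        cfg = SimulationConfig(
            n_participants=n_participants, seed=seeds[r], **config_overrides
        )
        reference = generate_reference_table(cfg.n_nutrients, seed=seeds[n_reps + r])
        tables, truth = generate_cohort(cfg, reference)
        fit, _ = _fit_one(tables, reference, outcome=outcome)
        true_gamma = truth.per_outcome[outcome].gamma
        lo, hi = fit.dii_ci
        covered += lo <= true_gamma <= hi
        zs.append((fit.gamma - true_gamma) / fit.dii_se)
    zs = np.asarray(zs)
    return {
        "n_reps": n_reps,
        "n_participants": n_participants,
        "coverage_pct": 100.0 * covered / n_reps,
        "mean_z": float(zs.mean()),
        "sd_z": float(zs.std(ddof=1)),
    }


def tau2_recovery_study(
    n_reps: int = 100,
    n_participants: int = 2000,
    n_foods: int = 50,
    tau2_food_true: float = 1.0,
    seed: int = 0,
) -> dict:
    """Recovery of a known food-level variance component τ²_food.

    Cohorts carry food-level residual effects δ_j ~ N(0, τ²_food) with a
    small nutrient-level component; both components are REML-estimated
    separately and the distribution of τ̂²_food is summarised.
    """
    seeds = _spawn_seeds(seed, 2 * n_reps)
    estimates = []
    for r in range(n_reps):
        cfg = SimulationConfig(
            n_participants=n_participants,
            n_foods=n_foods,
            n_nutrients=10,
            food_residual_sd=float(np.sqrt(tau2_food_true)),
            nutrient_residual_sd=0.1,
            outlier_energy_fraction=0.0,
            seed=seeds[r],
        )
        reference = generate_reference_table(10, seed=seeds[n_reps + r])
        tables, _ = generate_cohort(cfg, reference)
        fit, _ = _fit_one(
            tables, reference, covariates=False, shared_tau2=False
        )
        estimates.append(fit.tau2["food"])
    estimates = np.asarray(estimates)
    return {
        "n_reps": n_reps,
        "tau2_food_true": tau2_food_true,
        "median": float(np.median(estimates)),
        "q25": float(np.quantile(estimates, 0.25)),
        "q75": float(np.quantile(estimates, 0.75)),
    }


def ci_width_study(
    n_reps: int = 200,
    n_participants: int = 500,
    intake_correlation: float = 0.9,
    seed: int = 0,
    outcome: str = "stress",
) -> dict:
    """How often the hierarchical DII CI is narrower than the multiple model's.

    Collinear designs (compound-symmetric food-intake correlation, 40
    foods, 12 nutrients) at moderate n make the conventional
    adjust-for-everything model unstable; both models are fit to the
    same cohorts and CI widths compared on the per-1-SD regressor scale.
    """
    seeds = _spawn_seeds(seed, 2 * n_reps)
    narrower = 0
    for r in range(n_reps):
        cfg = SimulationConfig(
            n_participants=n_participants,
            n_foods=40,
            n_nutrients=12,
            intake_correlation=intake_correlation,
            outlier_energy_fraction=0.0,
            seed=seeds[r],
        )
        reference = generate_reference_table(12, seed=seeds[n_reps + r])
        tables, _ = generate_cohort(cfg, reference)
        y = tables.outcomes[outcome + "_continuous"].to_numpy()
        score = dii_mod.compute_dii(tables.intakes, reference, quartiles=False)
        mfit = model.fit_multiple(
            y,
            dii=score["dii_overall"],
            covariates=tables.covariates,
            nutrients=tables.intakes,
            foods=tables.grams,
            outcome_name=outcome,
        )
        spec = model.HierarchicalSpec(
            foods=tables.grams,
            composition=tables.composition,
            effect_scores=reference.set_index("parameter")["effect_score"],
            covariates=tables.covariates,
            outcome_name=outcome,
        )
        hfit = model.fit_hierarchical(spec, y)
        narrower += hfit.dii_ci_width_per_sd < mfit.dii_ci_width_per_sd
    return {
        "n_reps": n_reps,
        "n_participants": n_participants,
        "intake_correlation": intake_correlation,
        "fraction_narrower": narrower / n_reps,
    }
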