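"""Synthetic cohort generator.

Emulates, with known ground truth, the statistical structure the
downstream analysis assumes: an FFQ-scale cohort whose food intakes are
log-normal and positively correlated (pro- and anti-inflammatory foods
are consumed together), nutrients nested in foods through a shared
composition matrix, a DII reference table, and DASS-style outcomes
generated from the three-level linear structure

    y = α + C·c + F·β + ε,   β = Z·π + δ,   π = w·γ + θ

where F is the standardized food-gram matrix, Z the standardized
composition bridge, and w the inflammatory effect scores.  γ is
configured per 1 SD of the DII composite F·Z·w, so the hierarchical
estimator's reported coefficient is directly comparable to the
configured truth.  A configurable fraction of participants receive
energy intakes far beyond +3 SD to exercise the eligibility filter;
all generative standardizations use the non-outlier participants, so
the post-exclusion analysis sees exactly the generative scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dass import ITEMS_PER_SUBSCALE, SUBSCALES, load_subscale_key
from .errors import ValidationError
from .params import ENERGY_PARAMETER, parameter_names

OUTCOMES = SUBSCALES  # stress, anxiety, depression

#: Cohort-scale defaults mirror a large employee-cohort study design:
#: ~3,550 examined, 116 FFQ foods, 25 DII parameters, observed outcome
#: means/SDs, and hierarchical DII effects of 3.552/4.264/3.021.
DEFAULT_TRUE_DII_EFFECTS = {"stress": 3.552, "anxiety": 4.264, "depression": 3.021}
DEFAULT_INTERCEPTS = {"stress": 13.57, "anxiety": 6.20, "depression": 8.04}

DEFAULT_COVARIATE_EFFECTS = {
    "gender": 2.5,
    "education": -0.25,
    "smoking": 0.3,
    "childhood_ses": 0.9,
    "ses_status": -0.74,
    "ses_fluctuation": 0.43,
    "liver_disease": 1.9,
    "hypothyroidism": 0.6,
    "cvd": 1.2,
    "diabetes": 0.6,
    "asset": -0.1,
    "social_activity": -0.4,
}

# Marginal covariate distributions (prevalences / level frequencies
# patterned on a large university-employee cohort).
_COVARIATE_LEVELS = {
    "education": [0.005, 0.037, 0.043, 0.187, 0.083, 0.382, 0.209, 0.054],
    "smoking": [0.679, 0.014, 0.052, 0.007, 0.124, 0.075, 0.028, 0.021],
    "childhood_ses": [0.043, 0.173, 0.491, 0.159, 0.134],
    "ses_status": [0.045, 0.264, 0.536, 0.119, 0.036],
    "ses_fluctuation": [0.042, 0.134, 0.225, 0.189, 0.410],
}
_COVARIATE_BINARY = {
    "gender": 0.611,  # 1 = female
    "liver_disease": 0.053,
    "hypothyroidism": 0.115,
    "cvd": 0.069,
    "diabetes": 0.043,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_participants: int = 3550
    n_foods: int = 116
    n_nutrients: int = 25
    true_dii_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_TRUE_DII_EFFECTS)
    )
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    food_residual_sd: float = 0.05  # scale of the food-level deviations delta_j
    nutrient_residual_sd: float = 0.05  # scale of the nutrient-level deviations theta_i
    outcome_noise_sd: float = 8.0
    intake_correlation: float = 0.4
    outlier_energy_fraction: float = 49 / 3550  # mirrors 3,550 examined -> 3,501 kept
    anti_inflammatory_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if min(self.n_participants, self.n_foods, self.n_nutrients) < 1:
            raise ValidationError("n_participants, n_foods, n_nutrients must be >= 1")
        if self.food_residual_sd < 0 or self.nutrient_residual_sd < 0:
            raise ValidationError("residual SDs must be non-negative")
        if self.outcome_noise_sd <= 0:
            raise ValidationError("outcome_noise_sd must be > 0")
        if not 0 <= self.intake_correlation < 1:
            raise ValidationError("intake_correlation must be in [0, 1)")
        if not 0 <= self.outlier_energy_fraction < 1:
            raise ValidationError("outlier_energy_fraction must be in [0, 1)")
        missing = set(OUTCOMES) - set(self.true_dii_effects)
        if missing:
            raise ValidationError(f"true_dii_effects missing outcomes {sorted(missing)}")


@dataclass
class OutcomeTruth:
    """Generative coefficients for one outcome."""

    gamma: float  # DII effect per 1 SD of the composite F·Z·w
    gamma_raw: float  # per raw composite unit
    beta: np.ndarray  # food coefficients (standardized-grams scale)
    pi: np.ndarray  # nutrient coefficients
    delta: np.ndarray  # food-level residual effects
    theta: np.ndarray  # nutrient-level residual effects


@dataclass
class SimulationTruth:
    """Everything the generator knows that the analysis must recover."""

    per_outcome: dict[str, OutcomeTruth]
    Z_std: np.ndarray  # standardized composition bridge (foods × nutrients)
    effect_scores: np.ndarray
    composite: np.ndarray  # per-participant DII composite F·Z·w (raw scale)
    composite_sd: float
    outlier_ids: list
    food_ids: list
    nutrient_names: list

    def to_json(self) -> dict:
        return {
            "per_outcome": {
                k: {
                    "gamma": v.gamma,
                    "gamma_raw": v.gamma_raw,
                    "beta": v.beta.tolist(),
                    "pi": v.pi.tolist(),
                    "delta": v.delta.tolist(),
                    "theta": v.theta.tolist(),
                }
                for k, v in self.per_outcome.items()
            },
            "effect_scores": self.effect_scores.tolist(),
            "composite_sd": self.composite_sd,
            "outlier_ids": list(self.outlier_ids),
            "food_ids": list(self.food_ids),
            "nutrient_names": list(self.nutrient_names),
        }


@dataclass
class CohortTables:
    """The five analysis input tables plus convenience intermediates."""

    ffq: pd.DataFrame  # long: participant_id, food_id, frequency, period, portion_grams
    composition: pd.DataFrame  # foods × nutrients, per 100 g
    reference: pd.DataFrame  # parameter, global_mean, global_sd, effect_score
    covariates: pd.DataFrame  # participants × covariates
    dass_items: pd.DataFrame  # participants × q01..q42
    grams: pd.DataFrame  # participants × foods, grams/day
    intakes: pd.DataFrame  # participants × nutrients, units/day
    outcomes: pd.DataFrame  # clipped DASS totals + *_continuous pre-clip values


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_reference_table(
    n_nutrients: int = 25, seed: int = 0, anti_fraction: float = 0.6
) -> pd.DataFrame:
    """Generate a synthetic DII reference-parameter table.

    Each parameter gets a positive global mean and SD and an overall
    inflammatory effect score in [−1, 1]; ``round(anti_fraction ×
    n_nutrients)`` parameters get negative (anti-inflammatory) scores.
    Values are synthetic stand-ins for the (unpublished) global reference
    statistics, plausible only in scale, not in fact.
    """
    if n_nutrients < 1:
        raise ValidationError("n_nutrients must be >= 1")
    if not 0 <= anti_fraction <= 1:
        raise ValidationError("anti_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = parameter_names(n_nutrients)
    means = np.exp(rng.normal(np.log(50.0), 1.2, size=n_nutrients))
    sds = means * rng.uniform(0.2, 0.6, size=n_nutrients)
    if ENERGY_PARAMETER in names:  # kcal live on their own scale
        k = names.index(ENERGY_PARAMETER)
        means[k] = rng.uniform(1800.0, 2600.0)
        sds[k] = means[k] * rng.uniform(0.2, 0.35)
    magnitudes = rng.uniform(0.05, 0.7, size=n_nutrients)
    signs = np.ones(n_nutrients)
    n_anti = int(round(anti_fraction * n_nutrients))
    signs[rng.choice(n_nutrients, size=n_anti, replace=False)] = -1.0
    return pd.DataFrame(
        {
            "parameter": names,
            "global_mean": means,
            "global_sd": sds,
            "effect_score": magnitudes * signs,
        }
    )


def _generate_grams(rng, n, foods, rho):
    """Correlated log-normal daily grams (compound-symmetry latent normal)."""
    mu = rng.normal(np.log(30.0), 0.7, size=len(foods))
    sd_log = rng.uniform(0.3, 0.7, size=len(foods))
    shared = rng.standard_normal((n, 1))
    idio = rng.standard_normal((n, len(foods)))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * idio
    grams = np.exp(mu + sd_log * z)
    return pd.DataFrame(grams, columns=foods)


def _generate_composition(rng, foods, reference, grams_clean):
    """Non-negative sparse foods × nutrients matrix, per 100 g.

    ~70% of entries are zero (most foods carry few parameters); every
    food carries energy.  Columns are rescaled so the clean cohort's
    mean intake matches the reference global mean, keeping z-scores
    centered.
    """
    params = list(reference["parameter"])
    J, K = len(foods), len(params)
    present = rng.random((J, K)) < 0.3
    present[:, [i for i, p in enumerate(params) if p == ENERGY_PARAMETER]] = True
    for k in range(K):  # every nutrient must occur in at least one food
        if not present[:, k].any():
            present[rng.integers(J), k] = True
    amounts = np.exp(rng.normal(0.0, 0.8, size=(J, K))) * present
    comp = pd.DataFrame(amounts, index=foods, columns=params)
    raw_means = (grams_clean.to_numpy() / 100.0 @ comp.to_numpy()).mean(axis=0)
    scale = reference["global_mean"].to_numpy() / np.where(raw_means > 0, raw_means, 1.0)
    return comp * scale


def _generate_covariates(rng, n):
    cols = {}
    for name, p in _COVARIATE_BINARY.items():
        cols[name] = (rng.random(n) < p).astype(int)
    for name, probs in _COVARIATE_LEVELS.items():
        probs = np.asarray(probs) / np.sum(probs)
        cols[name] = rng.choice(len(probs), size=n, p=probs)
    cols["asset"] = rng.standard_normal(n)
    cols["social_activity"] = rng.standard_normal(n)
    order = list(DEFAULT_COVARIATE_EFFECTS)
    return pd.DataFrame(cols)[order]


def _items_from_totals(rng, totals, key):
    """Distribute integer subscale totals over 14 items coded 0-3."""
    n = len(totals[SUBSCALES[0]])
    items = np.zeros((n, 42), dtype=int)
    for sub in SUBSCALES:
        cols = np.asarray(key[key == sub].index) - 1
        t = np.asarray(totals[sub], dtype=int)
        base = t // ITEMS_PER_SUBSCALE
        extra = t % ITEMS_PER_SUBSCALE
        # rank a random matrix per row to pick which items get the +1
        order = np.argsort(rng.random((n, ITEMS_PER_SUBSCALE)), axis=1)
        vals = base[:, None] + (order < extra[:, None])
        items[:, cols] = vals
    return pd.DataFrame(items, columns=[f"q{i:02d}" for i in range(1, 43)])


def _ffq_from_grams(rng, grams):
    """Emit long-format FFQ records that round-trip to the given grams/day."""
    n, foods = grams.shape
    periods = rng.choice(
        ["day", "week", "month", "year"], size=foods, p=[0.05, 0.5, 0.3, 0.15]
    )
    portions = rng.uniform(30.0, 300.0, size=foods)
    days = pd.Series({"day": 1.0, "week": 7.0, "month": 30.44, "year": 365.25})
    rows = []
    for j, food in enumerate(grams.columns):
        freq = grams[food].to_numpy() * days[periods[j]] / portions[j]
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": grams.index,
                    "food_id": food,
                    "frequency": freq,
                    "period": periods[j],
                    "portion_grams": portions[j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_cohort(
    config: SimulationConfig, reference: pd.DataFrame | None = None
) -> tuple[CohortTables, SimulationTruth]:
    """Generate one synthetic cohort plus its ground truth.

    Deterministic given ``(config, config.seed)``.  When ``reference``
    is omitted a synthetic reference table is generated from a seed
    derived from the config seed.
    """
    cfg = config
    (rng_ref, rng_grams, rng_comp, rng_cov, rng_coef, rng_noise,
     rng_items, rng_ffq, rng_out) = _rngs(cfg.seed, 9)

    if reference is None:
        ref_seed = int(rng_ref.integers(2**31 - 1))
        reference = generate_reference_table(
            cfg.n_nutrients, seed=ref_seed, anti_fraction=cfg.anti_inflammatory_fraction
        )
    if len(reference) != cfg.n_nutrients:
        raise ValidationError(
            f"reference has {len(reference)} rows, config expects {cfg.n_nutrients}"
        )

    n = cfg.n_participants
    participant_ids = [f"p{i + 1:05d}" for i in range(n)]
    food_ids = [f"food_{j + 1:03d}" for j in range(cfg.n_foods)]

    grams = _generate_grams(rng_grams, n, food_ids, cfg.intake_correlation)
    grams.index = pd.Index(participant_ids, name="participant_id")

    # plant upper-tail energy outliers (target z ≈ 8-10 of the clean SD)
    n_out = int(round(cfg.outlier_energy_fraction * n))
    outlier_pos = np.sort(rng_out.choice(n, size=n_out, replace=False)) if n_out else []
    clean_mask = np.ones(n, dtype=bool)
    clean_mask[list(outlier_pos)] = False

    composition = _generate_composition(
        rng_comp, food_ids, reference, grams.iloc[clean_mask]
    )
    e_density = composition[ENERGY_PARAMETER].to_numpy()
    energy = (grams.to_numpy() / 100.0) @ e_density
    if n_out:
        e_mean = energy[clean_mask].mean()
        e_sd = energy[clean_mask].std(ddof=1) if clean_mask.sum() > 1 else 0.0
        targets = e_mean + rng_out.uniform(8.0, 10.0, size=n_out) * max(e_sd, 1e-9)
        pos = list(outlier_pos)
        # escalate until the single-pass ±3 SD rule flags exactly the
        # planted set: raising the planted energies inflates the cohort
        # SD, which pulls every natural tail value back inside the fence
        for _ in range(60):
            factors = targets / energy[pos]
            grams.iloc[pos] = grams.iloc[pos].mul(factors, axis=0)
            energy = (grams.to_numpy() / 100.0) @ e_density
            mean, sd = energy.mean(), energy.std(ddof=1)
            flagged = np.abs(energy - mean) > 3.0 * sd
            if set(np.flatnonzero(flagged)) == set(pos):
                break
            targets = targets * 2.0
        else:  # pragma: no cover - escalation always terminates for k/n < 1/9
            raise ValidationError(
                "could not plant recoverable energy outliers; "
                "outlier_energy_fraction may be too large for this n"
            )

    intakes = pd.DataFrame(
        (grams.to_numpy() / 100.0) @ composition.to_numpy(),
        index=grams.index,
        columns=composition.columns,
    )

    # standardize on the clean participants: the post-exclusion analysis
    # then reproduces the generative scale exactly
    g_clean = grams.iloc[clean_mask]
    mu_f = g_clean.mean(axis=0).to_numpy()
    sd_f = g_clean.std(axis=0, ddof=1).to_numpy()
    F = (grams.to_numpy() - mu_f) / sd_f
    comp_np = composition.to_numpy()
    mu_z = comp_np.mean(axis=0)
    sd_z = comp_np.std(axis=0, ddof=1)
    if (sd_z == 0).any():
        sd_z = np.where(sd_z == 0, 1.0, sd_z)
    Z = (comp_np - mu_z) / sd_z
    w = reference["effect_score"].to_numpy()

    composite = F @ (Z @ w)
    composite_sd = float(np.std(composite[clean_mask], ddof=1))

    covariates = _generate_covariates(rng_cov, n)
    covariates.index = grams.index
    c_effects = np.array(
        [cfg.covariate_effects.get(c, 0.0) for c in covariates.columns]
    )
    cov_part = covariates.to_numpy(float) @ c_effects

    per_outcome = {}
    outcome_cols = {}
    for out in OUTCOMES:
        gamma = float(cfg.true_dii_effects[out])
        gamma_raw = gamma / composite_sd
        delta = rng_coef.normal(0.0, cfg.food_residual_sd, size=cfg.n_foods)
        theta = rng_coef.normal(0.0, cfg.nutrient_residual_sd, size=cfg.n_nutrients)
        pi = w * gamma_raw + theta
        beta = Z @ pi + delta
        per_outcome[out] = OutcomeTruth(gamma, gamma_raw, beta, pi, delta, theta)
        noise = rng_noise.normal(0.0, cfg.outcome_noise_sd, size=n)
        y = cfg.intercepts[out] + cov_part + F @ beta + noise
        outcome_cols[out + "_continuous"] = y
        outcome_cols[out] = np.clip(np.rint(y), 0, 42).astype(int)

    outcomes = pd.DataFrame(outcome_cols, index=grams.index)
    key = load_subscale_key()
    dass_items = _items_from_totals(
        rng_items, {s: outcomes[s].to_numpy() for s in SUBSCALES}, key
    )
    dass_items.index = grams.index

    ffq = _ffq_from_grams(rng_ffq, grams)

    truth = SimulationTruth(
        per_outcome=per_outcome,
        Z_std=Z,
        effect_scores=w,
        composite=composite,
        composite_sd=composite_sd,
        outlier_ids=[participant_ids[i] for i in outlier_pos],
        food_ids=food_ids,
        nutrient_names=list(reference["parameter"]),
    )
    tables = CohortTables(
        ffq=ffq,
        composition=composition,
        reference=reference,
        covariates=covariates,
        dass_items=dass_items,
        grams=grams,
        intakes=intakes,
        outcomes=outcomes,
    )
    return tables, truth


def write_cohort(tables: CohortTables, truth: SimulationTruth, outdir) -> dict:
    """Write the five input CSVs plus truth.json; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ffq": outdir / "ffq.csv",
        "composition": outdir / "composition.csv",
        "reference": outdir / "reference.csv",
        "covariates": outdir / "covariates.csv",
        "dass_items": outdir / "dass_items.csv",
        "truth": outdir / "truth.json",
    }
    tables.ffq.to_csv(paths["ffq"], index=False)
    tables.composition.rename_axis("food_id").to_csv(paths["composition"])
    tables.reference.to_csv(paths["reference"], index=False)
    tables.covariates.reset_index().to_csv(paths["covariates"], index=False)
    tables.dass_items.reset_index().to_csv(paths["dass_items"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json(), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a (YAML-style) mapping."""
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**d)
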