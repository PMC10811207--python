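"""End-to-end pipeline: tables → intakes → exclusion → DASS → DII → fits → reports.

One reproducible run, configured either with paths to the five input
CSVs or with a simulation block, producing per-stage outputs, a
Table-1/2/3-shaped report set, and a manifest recording input hashes,
participant counts at every stage and the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import dass, dii, intake, model, simulate
from .errors import ConfigError
from .params import ENERGY_PARAMETER

log = logging.getLogger("diimlm")

INPUT_TABLES = ("ffq", "composition", "reference", "covariates", "dass_items")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Exactly one of ``input_dir`` (directory holding ffq.csv,
    composition.csv, reference.csv, covariates.csv, dass_items.csv) or
    ``simulation`` (a :class:`~diimlm.simulate.SimulationConfig`) must
    be given.
    """

    out_dir: str = "results"
    input_dir: str | None = None
    simulation: simulate.SimulationConfig | None = None
    dii_method: str = "normal_cdf"
    units_scale: float = 1.0
    energy_filter: bool = True
    shared_tau2: bool = True
    tau2_food: float | str = "estimate"
    tau2_nutrient: float | str = "estimate"
    max_iterations: int = 200
    tolerance: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if (self.input_dir is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of input_dir or a simulation block is required"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(
            simulation=simulate.config_from_dict(sim) if sim is not None else None,
            **raw,
        )
        return cfg


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Share of a count as a percentage, rounded for display parity."""
    if denominator == 0:
        raise ConfigError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def format_p(p: float) -> str:
    """Three-decimal p-value with a '<0.001' floor (display convention)."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig, out_dir: Path):
    if config.simulation is not None:
        tables, truth = simulate.generate_cohort(config.simulation)
        sim_dir = out_dir / "inputs"
        paths = simulate.write_cohort(tables, truth, sim_dir)
        inputs = {
            "ffq": tables.ffq,
            "composition": tables.composition,
            "reference": tables.reference,
            "covariates": tables.covariates.reset_index(),
            "dass_items": tables.dass_items.reset_index(),
        }
        return inputs, {k: _sha256(Path(v)) for k, v in paths.items()}
    indir = Path(config.input_dir)
    paths = {name: indir / f"{name}.csv" for name in INPUT_TABLES}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise ConfigError(f"missing input files: {missing}")
    inputs = {
        "ffq": intake.read_ffq(paths["ffq"]),
        "composition": intake.read_composition(paths["composition"]),
        "reference": dii.read_reference(paths["reference"]),
        "covariates": pd.read_csv(paths["covariates"]),
        "dass_items": pd.read_csv(paths["dass_items"]),
    }
    return inputs, {k: _sha256(p) for k, p in paths.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    manifest: dict = {"seed": config.seed, "stages": {}, "counts": {}}
    stage = "load_inputs"
    try:
        inputs, hashes = _load_inputs(config, out_dir)
        manifest["input_hashes"] = hashes

        stage = "intake"
        intakes = intake.build_intake_table(inputs["ffq"], inputs["composition"])
        examined = len(intakes)
        if config.energy_filter:
            retained, excluded = intake.energy_exclusion(intakes, ENERGY_PARAMETER)
        else:
            retained, excluded = intakes, []
        intake.write_intakes(retained, out_dir / "intakes.csv")
        (out_dir / "excluded.txt").write_text("\n".join(map(str, excluded)) + "\n")
        manifest["counts"] = {
            "examined": examined,
            "excluded": len(excluded),
            "analyzed": len(retained),
            "analyzed_pct": percentage(len(retained), examined, 2),
        }
        log.info("intake: %d examined, %d excluded", examined, len(excluded))

        stage = "dass"
        scores = dass.score_subscales(inputs["dass_items"])
        scores = scores.loc[retained.index]
        dass.write_outcomes(scores, out_dir / "outcomes.csv")

        stage = "dii"
        nutrient_block = retained[intake.nutrient_columns(retained)]
        dii_table = dii.compute_dii(
            nutrient_block,
            inputs["reference"],
            method=config.dii_method,
            units_scale=config.units_scale,
        )
        dii.write_dii(dii_table, out_dir / "dii.csv")

        stage = "fit"
        covariates = inputs["covariates"].set_index("participant_id").loc[retained.index]
        foods = retained[intake.food_columns(retained)]
        foods.columns = [c.removeprefix("food::") for c in foods.columns]
        effect_scores = inputs["reference"].set_index("parameter")["effect_score"]
        fits: dict[str, dict[str, model.ModelFit]] = {}
        comparisons = []
        for outcome in dass.SUBSCALES:
            y = scores[outcome].to_numpy(float)
            simple = model.fit_simple(y, dii_table["dii_overall"], outcome_name=outcome)
            multiple = model.fit_multiple(
                y,
                dii=dii_table["dii_overall"],
                covariates=covariates,
                nutrients=nutrient_block,
                foods=foods,
                outcome_name=outcome,
            )
            spec = model.HierarchicalSpec(
                foods=foods,
                composition=inputs["composition"],
                effect_scores=effect_scores,
                covariates=covariates,
                outcome_name=outcome,
                tau2_food=config.tau2_food,
                tau2_nutrient=config.tau2_nutrient,
                shared_tau2=config.shared_tau2,
                max_iterations=config.max_iterations,
                tolerance=config.tolerance,
            )
            hier = model.fit_hierarchical(spec, y)
            fits[outcome] = {"simple": simple, "multiple": multiple,
                             "hierarchical": hier}
            comparisons.append(model.compare_models([simple, multiple, hier]))

        stage = "report"
        baseline = model.baseline_associations(scores, covariates)
        render_reports(fits, baseline, comparisons, out_dir)
        _write_fits_json(fits, out_dir / "fits.json")
        manifest["stages"] = {s: "ok" for s in
                              ("load_inputs", "intake", "dass", "dii", "fit", "report")}
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {type(exc).__name__}"
        manifest["error"] = {"stage": stage, "type": type(exc).__name__,
                             "message": str(exc)}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _fit_to_dict(f: model.ModelFit) -> dict:
    d = {
        "model": f.model,
        "outcome": f.outcome,
        "n": f.n,
        "params": f.params.to_dict(),
        "se": f.se.to_dict(),
        "ci95": {k: [float(v["lower"]), float(v["upper"])]
                 for k, v in f.ci95.iterrows()},
        "residual_variance": f.residual_variance,
        "dropped_columns": f.dropped_columns,
        "converged": f.converged,
        "n_iterations": f.n_iterations,
        "dii_df": f.dii_df,
        "dii_critical_value": f.dii_critical_value,
    }
    if f.tau2 is not None:
        d["tau2"] = f.tau2
    if f.gamma is not None:
        d["gamma_per_sd"] = f.gamma
        d["gamma_raw"] = f.gamma_raw
    return d


def _write_fits_json(fits, path) -> None:
    payload = {out: {m: _fit_to_dict(f) for m, f in by_model.items()}
               for out, by_model in fits.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def render_reports(fits, baseline: pd.DataFrame, comparisons, out_dir) -> dict:
    """Emit Table-1/2/3-shaped CSV reports.

    Table 1: covariate × outcome association tests.  Table 2: the DII
    coefficient per outcome per model with Wald 95% CI and p.  Table 3:
    covariate coefficients from the hierarchical fits.  An empty
    covariate table omits Table 3 with a logged notice.
    """
    out_dir = Path(out_dir)
    written = {}

    baseline = baseline.assign(p_display=baseline["p_value"].map(
        lambda p: format_p(p) if pd.notna(p) else ""))
    baseline.to_csv(out_dir / "table1.csv", index=False)
    written["table1"] = str(out_dir / "table1.csv")

    rows = []
    for outcome, by_model in fits.items():
        for name, f in by_model.items():
            lo, hi = f.dii_ci
            rows.append({
                "model": name, "outcome": outcome, "exposure": "DII",
                "coefficient": f.dii_coef, "ci_lower": lo, "ci_upper": hi,
                "p_value": format_p(f.dii_p),
            })
    pd.DataFrame(rows).to_csv(out_dir / "table2.csv", index=False)
    written["table2"] = str(out_dir / "table2.csv")

    hier = {o: m.get("hierarchical") for o, m in fits.items()}
    any_cov = any(
        f is not None and len(f.params) > 2 for f in hier.values()
    )
    if any_cov:
        rows = []
        for outcome, f in hier.items():
            if f is None:
                continue
            ci = f.ci95
            for name in f.params.index:
                if name in ("intercept", "dii"):
                    continue
                from scipy import stats as _st
                z = f.params[name] / f.se[name] if f.se[name] > 0 else float("nan")
                rows.append({
                    "variable": name, "outcome": outcome,
                    "coefficient": float(f.params[name]),
                    "ci_lower": float(ci.loc[name, "lower"]),
                    "ci_upper": float(ci.loc[name, "upper"]),
                    "p_value": format_p(float(2 * _st.norm.sf(abs(z)))),
                })
        pd.DataFrame(rows).to_csv(out_dir / "table3.csv", index=False)
        written["table3"] = str(out_dir / "table3.csv")
    else:
        log.info("no covariates in hierarchical fits; table3 omitted")

    comparison = pd.concat(comparisons, ignore_index=True)
    comparison.to_csv(out_dir / "model_comparison.csv", index=False)
    written["model_comparison"] = str(out_dir / "model_comparison.csv")
    return written
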