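"""Conventional and three-level hierarchical regression of DASS outcomes on diet.

Three estimators per outcome:

* ``fit_simple`` — OLS of the outcome on the DII score alone.
* ``fit_multiple`` — OLS adjusting simultaneously for covariates,
  nutrient intakes and food intakes (the conventional "adjust for
  everything" model; aliased columns are dropped deterministically).
* ``fit_hierarchical`` — the three-level model in which food
  coefficients are shrunk toward their nutrient-composition prediction
  and nutrient coefficients toward their inflammatory-score prediction:

      y = α + C·c + F·β + ε,          ε ~ N(0, σ²I)
      β = Z·π + δ,                    δ ~ N(0, τ²_food·I)
      π = w·γ + θ,                    θ ~ N(0, τ²_nutrient·I)

  (F: participants × foods, standardized; Z: foods × nutrients
  standardized composition bridge; w: inflammatory effect scores).
  Marginally this is a Gaussian linear mixed model

      y = X·b + F·δ + (F·Z)·θ + ε,    X = [1, C, (F·Z·w)/s]

  with the DII composite F·Z·w normalized to unit SD (s), so γ is
  reported per 1 SD of the composite.  For a Gaussian outcome with
  identity link, penalized quasi-likelihood coincides with linear
  mixed-model estimation, so the fit solves the mixed-model (Henderson)
  equations exactly; variance components are estimated empirically from
  the data by restricted maximum likelihood, and δ, θ are returned as
  their empirical-Bayes posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, optimize, stats

from .errors import ValidationError

Z975 = 1.959963984540054  # standard-normal 97.5% quantile (Wald CIs)

__all__ = [
    "HierarchicalSpec",
    "ModelFit",
    "fit_simple",
    "fit_multiple",
    "fit_hierarchical",
    "estimate_tau2_eb",
    "baseline_associations",
    "compare_models",
    "standardize_columns",
]


def standardize_columns(X: pd.DataFrame, ddof: int = 1):
    """Column-standardize (mean 0, SD 1); constant columns are rejected."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    bad = sd.index[(sd == 0) | ~np.isfinite(sd)].tolist()
    if bad:
        raise ValidationError(f"cannot standardize constant columns: {bad}")
    return (X - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# Fit container


@dataclass
class ModelFit:
    """Coefficients, Wald intervals and variance components of one fit."""

    model: str
    outcome: str
    n: int
    params: pd.Series
    se: pd.Series
    residual_variance: float
    dii_regressor_sd: float | None = None
    tau2: dict[str, float] | None = None
    gamma: float | None = None  # DII effect per 1 SD of the composite
    gamma_raw: float | None = None  # per raw composite unit
    beta: pd.Series | None = None  # food coefficients, input (grams) units
    beta_std: pd.Series | None = None  # food coefficients, per-SD units
    pi: pd.Series | None = None  # nutrient-level coefficients (bridge scale)
    delta_hat: pd.Series | None = None  # food-level residual effects
    theta_hat: pd.Series | None = None  # nutrient-level residual effects
    dropped_columns: list = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0
    boundary: bool = False
    dii_df: float | None = None  # containment df for the DII coefficient

    @property
    def dii_critical_value(self) -> float:
        """97.5% quantile for the DII interval: Student t with containment
        degrees of freedom when set (hierarchical fit), else normal."""
        if self.dii_df is None:
            return Z975
        return float(stats.t.ppf(0.975, self.dii_df))

    @property
    def ci95(self) -> pd.DataFrame:
        lower = self.params - Z975 * self.se
        upper = self.params + Z975 * self.se
        ci = pd.DataFrame({"lower": lower, "upper": upper})
        if "dii" in self.params.index:
            lo, hi = self.dii_ci
            ci.loc["dii"] = [lo, hi]
        return ci

    # -- DII coefficient accessors -------------------------------------
    @property
    def dii_coef(self) -> float:
        return float(self.params["dii"])

    @property
    def dii_se(self) -> float:
        return float(self.se["dii"])

    @property
    def dii_ci(self) -> tuple[float, float]:
        c = self.dii_critical_value
        return (self.dii_coef - c * self.dii_se, self.dii_coef + c * self.dii_se)

    @property
    def dii_p(self) -> float:
        if self.dii_se == 0:
            return 0.0 if self.dii_coef != 0 else 1.0
        z = self.dii_coef / self.dii_se
        if self.dii_df is None:
            return float(2 * stats.norm.sf(abs(z)))
        return float(2 * stats.t.sf(abs(z), self.dii_df))

    @property
    def dii_coef_per_sd(self) -> float:
        """DII coefficient per 1 SD of this model's DII regressor."""
        if self.dii_regressor_sd is None:
            return self.dii_coef
        return self.dii_coef * self.dii_regressor_sd

    @property
    def dii_se_per_sd(self) -> float:
        if self.dii_regressor_sd is None:
            return self.dii_se
        return self.dii_se * self.dii_regressor_sd

    @property
    def dii_ci_width_per_sd(self) -> float:
        return 2 * self.dii_critical_value * self.dii_se_per_sd


def _wald_fit_from_ols(model_name, outcome_name, res, names, dii_sd, dropped=()):
    params = pd.Series(np.asarray(res.params, float), index=names)
    se = pd.Series(np.asarray(res.bse, float), index=names)
    return ModelFit(
        model=model_name,
        outcome=outcome_name,
        n=int(res.nobs),
        params=params,
        se=se,
        residual_variance=float(res.scale),
        dii_regressor_sd=dii_sd,
        dropped_columns=list(dropped),
    )


# ---------------------------------------------------------------------------
# Conventional models


def fit_simple(outcome, dii, outcome_name: str = "outcome") -> ModelFit:
    """Simple linear regression of the outcome on the DII score."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(dii, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("outcome and DII must be equal-length vectors")
    if y.size < 3:
        raise ValidationError("simple regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("DII score is constant; slope undefined")
    X = np.column_stack([np.ones_like(x), x])
    res = sm.OLS(y, X).fit()
    return _wald_fit_from_ols(
        "simple", outcome_name, res, ["intercept", "dii"], float(np.std(x, ddof=1))
    )


def _sequential_rank_filter(columns: np.ndarray, names: Sequence[str], rtol=1e-10):
    """Keep a maximal independent set of columns, preserving order.

    Modified Gram-Schmidt with re-orthogonalization; a column whose
    residual norm is below ``rtol`` times its own norm is aliased by the
    columns already kept and is dropped.
    """
    n = columns.shape[0]
    Q = np.empty((n, 0))
    kept, dropped = [], []
    for j, name in enumerate(names):
        c = columns[:, j]
        norm0 = np.linalg.norm(c)
        if norm0 == 0:
            dropped.append(name)
            continue
        r = c - Q @ (Q.T @ c)
        r = r - Q @ (Q.T @ r)  # second pass for numerical safety
        if np.linalg.norm(r) <= rtol * norm0:
            dropped.append(name)
        else:
            kept.append(j)
            Q = np.column_stack([Q, r / np.linalg.norm(r)])
    return kept, dropped


def fit_multiple(
    outcome,
    dii=None,
    covariates: pd.DataFrame | None = None,
    nutrients: pd.DataFrame | None = None,
    foods: pd.DataFrame | None = None,
    outcome_name: str = "outcome",
) -> ModelFit:
    """Conventional multiple regression: OLS on [covariates, DII, nutrients, foods].

    Exactly collinear columns are dropped deterministically in reverse
    priority order (foods drop before nutrients before DII before
    covariates), so the DII coefficient always remains estimable.
    """
    y = np.asarray(outcome, dtype=float)
    blocks: list[tuple[str, np.ndarray]] = [("intercept", np.ones((y.size, 1)))]

    def add_block(df, prefix=""):
        if df is None:
            return
        frame = pd.DataFrame(df)
        for col in frame.columns:
            blocks.append((f"{prefix}{col}", frame[col].to_numpy(float).reshape(-1, 1)))

    add_block(covariates)
    if dii is not None:
        blocks.append(("dii", np.asarray(dii, float).reshape(-1, 1)))
    add_block(nutrients, "nutrient::")
    add_block(foods, "food::")

    names = [name for name, _ in blocks]
    X = np.hstack([col for _, col in blocks])
    if X.shape[0] != y.size:
        raise ValidationError("design blocks and outcome have mismatched lengths")

    kept, dropped = _sequential_rank_filter(X, names)
    Xk = X[:, kept]
    kept_names = [names[j] for j in kept]
    if y.size <= Xk.shape[1]:
        raise ValidationError(
            f"n={y.size} <= p={Xk.shape[1]} after dropping aliased columns; "
            "consider the hierarchical model, which remains identified"
        )
    res = sm.OLS(y, Xk).fit()
    dii_sd = float(np.std(np.asarray(dii, float), ddof=1)) if dii is not None else None
    return _wald_fit_from_ols("multiple", outcome_name, res, kept_names, dii_sd, dropped)


# ---------------------------------------------------------------------------
# Hierarchical model


@dataclass
class HierarchicalSpec:
    """Design for the three-level (foods / nutrients / DII) model.

    ``foods`` holds raw daily grams (standardized internally), the
    ``composition`` bridge holds per-100 g amounts (columns standardized
    over foods), ``effect_scores`` the per-nutrient inflammatory weights.
    ``tau2_food`` / ``tau2_nutrient`` are either the string
    ``"estimate"`` (REML, the default) or fixed non-negative values;
    with ``shared_tau2`` a single common τ² is estimated for both
    levels.  ``sigma2`` may likewise be fixed (mainly for exact oracle
    comparisons).
    """

    foods: pd.DataFrame
    composition: pd.DataFrame
    effect_scores: pd.Series
    covariates: pd.DataFrame | None = None
    outcome_name: str = "outcome"
    tau2_food: float | str = "estimate"
    tau2_nutrient: float | str = "estimate"
    shared_tau2: bool = True
    sigma2: float | str = "estimate"
    max_iterations: int = 200
    tolerance: float = 1e-8

    def __post_init__(self):
        foods = pd.DataFrame(self.foods)
        comp = pd.DataFrame(self.composition)
        w = pd.Series(self.effect_scores)
        if list(foods.columns) != list(comp.index):
            if set(foods.columns) != set(comp.index):
                raise ValidationError("food design columns must match composition rows")
            comp = comp.loc[list(foods.columns)]
        if list(comp.columns) != list(w.index):
            if set(comp.columns) != set(w.index):
                raise ValidationError("composition columns must match effect-score index")
            w = w.loc[list(comp.columns)]
        for name, value in (("tau2_food", self.tau2_food),
                            ("tau2_nutrient", self.tau2_nutrient)):
            if value != "estimate" and (not np.isfinite(value) or value < 0):
                raise ValidationError(f"{name} must be 'estimate' or a value >= 0")
        self.foods, self.composition, self.effect_scores = foods, comp, w

    def build(self):
        """Return (F, Z, w, C, X, x_sd, names) with standardization applied."""
        F, _, self.food_sd = standardize_columns(self.foods)
        Z, _, _ = standardize_columns(self.composition)
        F = F.to_numpy(float)
        Z = Z.to_numpy(float)
        w = self.effect_scores.to_numpy(float)
        x = F @ (Z @ w)
        x_sd = float(np.std(x, ddof=1))
        if x_sd == 0:
            raise ValidationError("DII composite F·Z·w is constant")
        cols = [("intercept", np.ones(len(F)))]
        if self.covariates is not None:
            C = pd.DataFrame(self.covariates)
            cols += [(str(c), C[c].to_numpy(float)) for c in C.columns]
        cols.append(("dii", x / x_sd))
        X = np.column_stack([v for _, v in cols])
        names = [name for name, _ in cols]
        return F, Z, w, X, x_sd, names


class _MarginalModel:
    """Gram-matrix workspace for the marginal covariance V = σ²(I + U Λ Uᵀ).

    U = [F, FZ] collects both levels' random-effect designs; all REML
    evaluations reduce to q×q linear algebra (q = n_foods + n_nutrients)
    through the Woodbury identity, which is the Henderson mixed-model
    solve in disguise.
    """

    def __init__(self, X, U, y, groups):
        self.X, self.U, self.y = X, U, y
        self.groups = np.asarray(groups)
        self.n, self.p = X.shape
        self.q = U.shape[1]
        self.A = U.T @ U
        self.B = U.T @ X
        self.uy = U.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _lam_vector(self, lam_food, lam_nutrient):
        lam = np.where(self.groups == 0, lam_food, lam_nutrient)
        return np.asarray(lam, float)

    def solve(self, lam_food, lam_nutrient):
        """GLS at fixed variance ratios λ = τ²/σ²; returns profile pieces."""
        lam = self._lam_vector(lam_food, lam_nutrient)
        d = np.sqrt(lam)
        K = self.A * np.outer(d, d)
        K[np.diag_indices_from(K)] += 1.0
        cho = linalg.cho_factor(K, lower=True)

        def cross(Pu, Qu, PtQ):  # PᵀW⁻¹Q with W = I + UΛUᵀ
            return PtQ - (d[:, None] * Pu).T @ linalg.cho_solve(cho, d[:, None] * Qu)

        XtWiX = cross(self.B, self.B, self.XtX)
        XtWiy = cross(self.B, self.uy[:, None], self.Xty[:, None]).ravel()
        ytWiy = cross(self.uy[:, None], self.uy[:, None],
                      np.array([[self.yty]])).item()
        try:
            cho_x = linalg.cho_factor(XtWiX)
            b = linalg.cho_solve(cho_x, XtWiy)
            XtWiX_inv = linalg.cho_solve(cho_x, np.eye(self.p))
        except linalg.LinAlgError:
            XtWiX_inv = np.linalg.pinv(XtWiX)
            b = XtWiX_inv @ XtWiy
        rss = max(ytWiy - XtWiy @ b, 1e-300)
        logdetK = 2.0 * np.sum(np.log(np.diag(cho[0])))
        sign, logdetXtWiX = np.linalg.slogdet(XtWiX)
        return {
            "b": b,
            "rss": rss,
            "XtWiX_inv": XtWiX_inv,
            "logdetK": logdetK,
            "logdetXtWiX": logdetXtWiX,
            "cho": cho,
            "d": d,
            "lam": lam,
        }

    def reml_neg2ll(self, lam_food, lam_nutrient):
        """−2 × restricted log-likelihood, profiled over b and σ² (up to a constant)."""
        s = self.solve(lam_food, lam_nutrient)
        df = self.n - self.p
        sigma2 = s["rss"] / df
        return df * np.log(sigma2) + s["logdetK"] + s["logdetXtWiX"], sigma2, s

    def posterior_means(self, s, b):
        """Empirical-Bayes posterior means of the stacked random effects."""
        u_r = self.uy - self.B @ b
        t = u_r - self.A @ (s["d"] * linalg.cho_solve(s["cho"], s["d"] * u_r))
        return s["lam"] * t


_LOG_LAM_BOUNDS = (-30.0, 16.0)
_STARTS = (-6.0, -2.0, 0.0, 2.0)


def _reml_optimize(mm: _MarginalModel, shared: bool, tol: float, maxiter: int):
    """Minimize the restricted −2 log-likelihood over log variance ratios."""

    def objective(log_lams):
        if shared:
            lf = ln = np.exp(log_lams[0])
        else:
            lf, ln = np.exp(log_lams)
        return mm.reml_neg2ll(lf, ln)[0]

    k = 1 if shared else 2
    best = None
    n_iter = 0
    success = False
    for s0 in _STARTS:
        res = optimize.minimize(
            objective,
            x0=np.full(k, s0),
            method="Nelder-Mead",
            options={"xatol": max(tol, 1e-9), "fatol": max(tol, 1e-10),
                     "maxiter": maxiter * 10},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        success = success or res.success
    log_lams = np.clip(best.x, *_LOG_LAM_BOUNDS)
    if shared:
        lams = (float(np.exp(log_lams[0])),) * 2
    else:
        lams = tuple(float(np.exp(v)) for v in log_lams)
    boundary = bool(np.any(log_lams <= _LOG_LAM_BOUNDS[0] + 1e-6))
    return lams, success, n_iter, boundary


def fit_hierarchical(spec: HierarchicalSpec, outcome) -> ModelFit:
    """Fit the three-level foods/nutrients/DII model.

    Returns the DII effect γ (per 1 SD of the composite F·Z·w) with
    Wald interval, the shrunken food and nutrient coefficients, the
    posterior-mean residual effects (δ̂ at the food level, θ̂ at the
    nutrient level), the variance components and convergence metadata.
    """
    y = np.asarray(outcome, dtype=float)
    F, Z, w, X, x_sd, names = spec.build()
    kept, dropped = _sequential_rank_filter(X, names)
    if "dii" not in [names[j] for j in kept]:
        raise ValidationError("DII composite aliased by covariates; cannot fit")
    X = X[:, kept]
    names = [names[j] for j in kept]
    n, p = X.shape
    if y.size != n:
        raise ValidationError("outcome length does not match design")
    if n < p + 2:
        raise ValidationError(f"n={n} too small for {p} fixed effects")
    J, I = Z.shape
    U = np.hstack([F, F @ Z])
    groups = np.concatenate([np.zeros(J, int), np.ones(I, int)])
    mm = _MarginalModel(X, U, y, groups)

    est_f = spec.tau2_food == "estimate"
    est_n = spec.tau2_nutrient == "estimate"
    converged, n_iter, boundary = True, 0, False

    if est_f and est_n:
        (lam_f, lam_n), converged, n_iter, boundary = _reml_optimize(
            mm, spec.shared_tau2, spec.tolerance, spec.max_iterations
        )
        _, sigma2, sol = mm.reml_neg2ll(lam_f, lam_n)
        tau2_f, tau2_n = lam_f * sigma2, lam_n * sigma2
        if boundary:
            tau2_f = 0.0 if lam_f <= np.exp(_LOG_LAM_BOUNDS[0] + 1e-6) else tau2_f
            tau2_n = 0.0 if lam_n <= np.exp(_LOG_LAM_BOUNDS[0] + 1e-6) else tau2_n
    elif not est_f and not est_n:
        tau2_f, tau2_n = float(spec.tau2_food), float(spec.tau2_nutrient)
        if spec.sigma2 != "estimate":
            sigma2 = float(spec.sigma2)
            sol = mm.solve(tau2_f / sigma2, tau2_n / sigma2)
        else:
            # fixed τ², free σ²: fixed-point on the profiled residual variance
            sigma2 = float(np.var(y, ddof=1))
            for n_iter in range(1, spec.max_iterations + 1):
                sol = mm.solve(tau2_f / sigma2, tau2_n / sigma2)
                new = sol["rss"] / (n - p)
                if abs(new - sigma2) <= spec.tolerance * max(sigma2, 1e-12):
                    sigma2 = new
                    break
                sigma2 = new
            else:
                converged = False
            sol = mm.solve(tau2_f / sigma2, tau2_n / sigma2)
    else:
        raise ValidationError(
            "tau2_food and tau2_nutrient must both be fixed or both 'estimate'"
        )

    b = sol["b"]
    cov_b = sigma2 * sol["XtWiX_inv"]
    se = np.sqrt(np.clip(np.diag(cov_b), 0, None))
    u_hat = mm.posterior_means(sol, b)
    delta_hat = u_hat[:J]
    theta_hat = u_hat[J:]

    gamma_std = float(b[names.index("dii")])
    gamma_raw = gamma_std / x_sd
    pi = w * gamma_raw + theta_hat
    beta_std = Z @ pi + delta_hat
    food_index = spec.foods.columns
    nutrient_index = spec.composition.columns

    return ModelFit(
        model="hierarchical",
        outcome=spec.outcome_name,
        n=n,
        params=pd.Series(b, index=names),
        se=pd.Series(se, index=names),
        residual_variance=float(sigma2),
        dii_regressor_sd=1.0,  # composite pre-normalized to unit SD
        tau2={"food": float(tau2_f), "nutrient": float(tau2_n)},
        gamma=gamma_std,
        gamma_raw=gamma_raw,
        beta=pd.Series(beta_std / spec.food_sd.to_numpy(float), index=food_index),
        beta_std=pd.Series(beta_std, index=food_index),
        pi=pd.Series(pi, index=nutrient_index),
        delta_hat=pd.Series(delta_hat, index=food_index),
        theta_hat=pd.Series(theta_hat, index=nutrient_index),
        dropped_columns=dropped,
        # containment df: the composite lies in the span of the nutrient-
        # level random design, whose I units carry its information
        dii_df=float(I - 1) if I >= 2 else (float(J - 1) if J >= 2 else None),
        converged=bool(converged),
        n_iterations=int(n_iter),
        boundary=boundary,
    )


def estimate_tau2_eb(spec: HierarchicalSpec, outcome):
    """Empirical-Bayes (REML) variance components (τ²_food, τ²_nutrient, σ²)."""
    spec = HierarchicalSpec(
        foods=spec.foods,
        composition=spec.composition,
        effect_scores=spec.effect_scores,
        covariates=spec.covariates,
        outcome_name=spec.outcome_name,
        tau2_food="estimate",
        tau2_nutrient="estimate",
        shared_tau2=spec.shared_tau2,
        max_iterations=spec.max_iterations,
        tolerance=spec.tolerance,
    )
    fit = fit_hierarchical(spec, outcome)
    return fit.tau2["food"], fit.tau2["nutrient"], fit.residual_variance


# ---------------------------------------------------------------------------
# Baseline (Table-1 style) associations and model comparison


def infer_covariate_types(covariates: pd.DataFrame, max_levels: int = 10) -> dict:
    """binary / categorical / continuous, by number of distinct values."""
    types = {}
    for col in covariates.columns:
        nunique = covariates[col].nunique(dropna=True)
        if nunique <= 2:
            types[col] = "binary"
        elif nunique <= max_levels:
            types[col] = "categorical"
        else:
            types[col] = "continuous"
    return types


def baseline_associations(
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    types: dict | None = None,
) -> pd.DataFrame:
    """Per covariate × outcome association tests (Table-1 shape).

    Binary covariates get an independent two-sample t-test with group
    mean ± SD; multi-category covariates a one-way ANOVA; continuous
    covariates a simple linear regression slope ± SE.  Groups with
    fewer than 2 members yield undefined (NaN) statistics, not errors.
    """
    if types is None:
        types = infer_covariate_types(covariates)
    rows = []
    for cov, kind in types.items():
        x = covariates[cov]
        for out in outcomes.columns:
            y = outcomes[out].astype(float)
            row = {"covariate": cov, "type": kind, "outcome": out,
                   "statistic": np.nan, "p_value": np.nan, "detail": ""}
            if kind in ("binary", "categorical"):
                groups = [y[x == lvl].to_numpy() for lvl in sorted(x.dropna().unique())]
                row["detail"] = "; ".join(
                    f"{lvl}: {g.mean():.2f} ± {g.std(ddof=1):.2f}" if g.size >= 2
                    else f"{lvl}: undefined (n={g.size})"
                    for lvl, g in zip(sorted(x.dropna().unique()), groups)
                )
                usable = [g for g in groups if g.size >= 2]
                if len(usable) == len(groups) and len(groups) >= 2:
                    if kind == "binary":
                        if groups[0].std() == 0 and groups[1].std() == 0:
                            # zero-variance groups: no evidence either way
                            equal = groups[0].mean() == groups[1].mean()
                            t, pval = (0.0, 1.0) if equal else (np.inf, 0.0)
                        else:
                            t, pval = stats.ttest_ind(groups[0], groups[1])
                        row["statistic"], row["p_value"] = float(t), float(pval)
                    else:
                        f, pval = stats.f_oneway(*groups)
                        row["statistic"], row["p_value"] = float(f), float(pval)
            else:
                X = sm.add_constant(x.to_numpy(float))
                res = sm.OLS(y.to_numpy(), X).fit()
                slope, se_ = res.params[1], res.bse[1]
                row["statistic"] = float(slope / se_) if se_ > 0 else np.nan
                row["p_value"] = float(2 * stats.norm.sf(abs(row["statistic"])))
                row["detail"] = f"slope {slope:.3f} ± {se_:.3f}"
            rows.append(row)
    return pd.DataFrame(rows)


def compare_models(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Side-by-side DII coefficients of the simple/multiple/hierarchical fits.

    All coefficients are placed on the per-1-SD-of-the-model's-DII-
    regressor scale so confidence-interval widths are comparable; the
    ``hierarchical_narrower`` column records whether the hierarchical CI
    is narrower than the conventional multiple model's — the central
    qualitative claim shrinkage is meant to deliver.
    """
    fits = list(fits)
    outcomes = {f.outcome for f in fits}
    ns = {f.n for f in fits}
    if len(outcomes) != 1 or len(ns) != 1:
        raise ValidationError("fits must share one outcome and participant set")
    rows = []
    for f in fits:
        coef, se_ = f.dii_coef_per_sd, f.dii_se_per_sd
        crit = f.dii_critical_value
        rows.append({
            "model": f.model,
            "outcome": f.outcome,
            "dii_coef_per_sd": coef,
            "se": se_,
            "ci_lower": coef - crit * se_,
            "ci_upper": coef + crit * se_,
            "ci_width": 2 * crit * se_,
            "p_value": f.dii_p,
        })
    report = pd.DataFrame(rows).set_index("model")
    if {"hierarchical", "multiple"} <= set(report.index):
        report["hierarchical_narrower"] = bool(
            report.loc["hierarchical", "ci_width"] < report.loc["multiple", "ci_width"]
        )
    return report.reset_index()
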