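"""Dietary Inflammatory Index (DII) engine.

The DII summarises the inflammatory potential of a diet.  For each
dietary parameter k with reference global mean m_k, global SD s_k and
overall inflammatory effect score w_k (positive = pro-inflammatory,
negative = anti-inflammatory):

    z_k  = (intake_k − m_k) / s_k
    cp_k = 2·P(z_k) − 1                (centered percentile, in [−1, 1])
    parameter score_k = cp_k · w_k
    overall DII = Σ_k parameter score_k

P is either the standard-normal CDF (``normal_cdf``, the original
construction) or a within-cohort empirical percentile (``empirical``).
The overall score can additionally be categorised into cohort-relative
quartiles.  The index is subset-flexible: omitting a parameter is the
same as setting its effect score to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

REFERENCE_COLUMNS = ("parameter", "global_mean", "global_sd", "effect_score")


def validate_reference(reference: pd.DataFrame) -> pd.DataFrame:
    """Validate a DII reference-parameter table (returns it unchanged)."""
    missing = set(REFERENCE_COLUMNS) - set(reference.columns)
    if missing:
        raise ValidationError(f"reference table missing columns {sorted(missing)}")
    if reference["parameter"].duplicated().any():
        raise ValidationError("duplicate parameter names in reference table")
    if (reference["global_sd"] <= 0).any():
        bad = reference.loc[reference["global_sd"] <= 0, "parameter"].tolist()
        raise ValidationError(f"global_sd must be > 0 (violated by {bad})")
    return reference


def z_score(intake, mean, sd):
    """Standardise intake against the global reference: (intake − mean)/sd."""
    sd = np.asarray(sd, dtype=float)
    if (sd <= 0).any():
        raise ValidationError("global SD must be strictly positive")
    return (np.asarray(intake, dtype=float) - np.asarray(mean, dtype=float)) / sd


def centered_percentile(z, method: str = "normal_cdf"):
    """Map z-scores to [−1, 1]: percentile scaled by 2 and shifted by −1.

    ``normal_cdf`` uses 2·Φ(z) − 1 per value; ``empirical`` ranks the
    given cohort vector (mid-rank percentile (rank − 0.5)/n, so the
    cohort mean is 0 absent ties) and needs at least 2 values.
    """
    z = np.asarray(z, dtype=float)
    if method == "normal_cdf":
        return 2.0 * stats.norm.cdf(z) - 1.0
    if method == "empirical":
        if z.size < 2:
            raise ValidationError("empirical percentiles need a cohort of >= 2")
        ranks = stats.rankdata(z, method="average")
        return 2.0 * (ranks - 0.5) / z.size - 1.0
    raise ValidationError(f"unknown percentile method '{method}'")


def parameter_score(cp, effect_score):
    """Weight a centered percentile by the parameter's inflammatory effect score."""
    cp = np.asarray(cp, dtype=float)
    if (np.abs(cp) > 1 + 1e-12).any():
        raise ValidationError("centered percentile outside [-1, 1]")
    return cp * np.asarray(effect_score, dtype=float)


def overall_dii(parameter_scores):
    """Sum parameter-specific scores into the overall DII."""
    scores = np.atleast_2d(np.asarray(parameter_scores, dtype=float))
    if scores.shape[-1] == 0:
        raise ValidationError("overall DII needs at least one parameter score")
    out = scores.sum(axis=-1)
    return out if out.size > 1 else float(out[0])


def dii_quartiles(overall) -> np.ndarray:
    """Cohort-relative quartile (1-4) of the overall DII.

    Rank-based: quartile = ceil(4·rank/n) with min-ranks, so tied values
    share the lower quartile and counts differ by at most one otherwise.
    """
    values = np.asarray(overall, dtype=float)
    if values.size < 4:
        raise ValidationError("quartiles need at least 4 participants")
    ranks = stats.rankdata(values, method="min")
    return np.ceil(4.0 * ranks / values.size).astype(int)


def compute_dii(
    intakes: pd.DataFrame,
    reference: pd.DataFrame,
    method: str = "normal_cdf",
    units_scale: float = 1.0,
    quartiles: bool = True,
) -> pd.DataFrame:
    """Score a cohort's nutrient intakes against a DII reference table.

    Parameters
    ----------
    intakes
        Participants × parameters daily intakes; must contain a column
        for every reference parameter (extra columns are ignored).
    reference
        Table with ``parameter, global_mean, global_sd, effect_score``.
    method
        ``normal_cdf`` (default) or ``empirical`` percentile transform.
    units_scale
        Scalar applied to intakes before standardisation, for reference
        tables expressed on a different units basis (default 1.0).

    Returns
    -------
    DataFrame indexed like ``intakes`` with per-parameter columns
    ``z_<p>``, ``cp_<p>``, ``score_<p>`` plus ``dii_overall`` and,
    optionally, ``dii_quartile``.
    """
    validate_reference(reference)
    missing = set(reference["parameter"]) - set(intakes.columns)
    if missing:
        raise ValidationError(f"intake table lacks parameters {sorted(missing)}")

    blocks = {}
    score_cols = []
    for row in reference.itertuples(index=False):
        x = intakes[row.parameter].to_numpy(dtype=float) * units_scale
        z = z_score(x, row.global_mean, row.global_sd)
        cp = centered_percentile(z, method=method)
        blocks[f"z_{row.parameter}"] = z
        blocks[f"cp_{row.parameter}"] = cp
        blocks[f"score_{row.parameter}"] = parameter_score(cp, row.effect_score)
        score_cols.append(f"score_{row.parameter}")

    out = pd.DataFrame(blocks, index=intakes.index)
    out["dii_overall"] = out[score_cols].to_numpy().sum(axis=1)
    if quartiles and len(out) >= 4:
        out["dii_quartile"] = dii_quartiles(out["dii_overall"])
    return out


def read_reference(path) -> pd.DataFrame:
    return validate_reference(pd.read_csv(path))


def write_dii(dii: pd.DataFrame, path) -> None:
    dii.rename_axis("participant_id").reset_index().to_csv(path, index=False)
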