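"""FFQ → daily intakes.

Converts food-frequency-questionnaire records (frequency per reference
period × portion size) into daily grams per food, aggregates nutrient
intakes through a food-composition matrix expressed per 100 g, and
applies the cohort's ±3 SD daily-energy eligibility filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError, MissingFoodError, ValidationError
from .params import ENERGY_PARAMETER

#: Days per reference period used to convert frequencies to a daily rate.
PERIOD_DAYS = {"day": 1.0, "week": 7.0, "month": 30.44, "year": 365.25}


def daily_grams(frequency, period, portion_grams):
    """Convert (frequency per period, portion in grams) to grams/day.

    Vectorised: accepts scalars or aligned array-likes.  Periods are
    ``day`` (1), ``week`` (7), ``month`` (30.44) or ``year`` (365.25).
    """
    scalar = (
        np.ndim(frequency) == 0 and np.ndim(period) == 0
        and np.ndim(portion_grams) == 0
    )
    freq = np.atleast_1d(np.asarray(frequency, dtype=float))
    portion = np.atleast_1d(np.asarray(portion_grams, dtype=float))
    periods = np.atleast_1d(np.asarray(period, dtype=object))
    if (freq < 0).any() or (portion < 0).any():
        raise ValidationError("frequency and portion must be non-negative")
    unknown = set(np.unique(periods)) - set(PERIOD_DAYS)
    if unknown:
        raise FormatError(f"unknown period label(s): {sorted(unknown)}")
    days = np.vectorize(PERIOD_DAYS.get, otypes=[float])(periods)
    out = freq * portion / days
    return out.item() if scalar else out


def grams_table(ffq: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format FFQ records into a participants × foods grams/day table.

    ``ffq`` columns: participant_id, food_id, frequency, period,
    portion_grams.  (participant, food) pairs must be unique; foods a
    participant did not report count as 0 g/day.
    """
    required = {"participant_id", "food_id", "frequency", "period", "portion_grams"}
    if not required <= set(ffq.columns):
        raise FormatError(f"ffq table needs columns {sorted(required)}")
    if ffq.duplicated(["participant_id", "food_id"]).any():
        raise ValidationError("duplicate (participant, food) FFQ records")
    ffq = ffq.assign(
        grams_per_day=daily_grams(ffq["frequency"], ffq["period"], ffq["portion_grams"])
    )
    wide = ffq.pivot(index="participant_id", columns="food_id", values="grams_per_day")
    return wide.fillna(0.0).sort_index()


def nutrient_intakes(grams: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-food daily grams into per-nutrient daily intakes.

    ``composition`` is foods × nutrients, amounts per 100 g of food, so
    intake(nutrient) = Σ_foods grams/100 × composition.  Every food
    column in ``grams`` must appear in the composition matrix.
    """
    missing = set(grams.columns) - set(composition.index)
    if missing:
        raise MissingFoodError(missing)
    comp = composition.loc[list(grams.columns)]
    intakes = (grams.to_numpy() / 100.0) @ comp.to_numpy()
    return pd.DataFrame(intakes, index=grams.index, columns=comp.columns)


def build_intake_table(ffq: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    """FFQ records → combined table of food grams/day and nutrient intakes.

    Food columns are prefixed ``food::``; nutrient columns keep their
    composition names.  The energy column doubles as the eligibility
    variable.
    """
    grams = grams_table(ffq)
    nutrients = nutrient_intakes(grams, composition)
    foods = grams.add_prefix("food::")
    return pd.concat([foods, nutrients], axis=1)


def food_columns(intakes: pd.DataFrame) -> list[str]:
    return [c for c in intakes.columns if str(c).startswith("food::")]


def nutrient_columns(intakes: pd.DataFrame) -> list[str]:
    return [c for c in intakes.columns if not str(c).startswith("food::")]


def energy_exclusion(intakes: pd.DataFrame, energy_col: str = ENERGY_PARAMETER):
    """Apply the ±3 SD daily-energy eligibility filter.

    The mean and sample SD (ddof=1) of the energy column are computed
    once over the full table; participants with |energy − mean| > 3·SD
    are excluded in a single pass.  Returns ``(retained, excluded_ids)``.
    A zero-SD cohort excludes no one.
    """
    if energy_col not in intakes.columns:
        raise ValidationError(f"energy column '{energy_col}' not found")
    if len(intakes) < 2:
        raise ValidationError("energy filter needs at least 2 participants")
    energy = intakes[energy_col].astype(float)
    mean, sd = energy.mean(), energy.std(ddof=1)
    if sd == 0:
        mask = pd.Series(False, index=intakes.index)
    else:
        mask = (energy - mean).abs() > 3.0 * sd
    excluded = list(intakes.index[mask])
    return intakes.loc[~mask], excluded


def read_composition(path) -> pd.DataFrame:
    """Read a composition.csv (first column = food id, rest nutrients per 100 g)."""
    comp = pd.read_csv(path, index_col=0)
    if (comp.to_numpy() < 0).any():
        raise ValidationError("composition amounts must be non-negative")
    return comp


def read_ffq(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_intakes(intakes: pd.DataFrame, path) -> None:
    intakes.rename_axis("participant_id").reset_index().to_csv(path, index=False)


def read_intakes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")
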