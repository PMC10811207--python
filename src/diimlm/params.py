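"""Registry of the dietary parameters available for DII calculation.

The full DII construction draws on 45 food parameters; dish-based FFQ
studies typically resolve a subset.  This registry lists the 25
parameters that a semi-quantitative FFQ pipeline can usually compute
(energy, macronutrients, micronutrients, fatty-acid classes), in the
units conventional for food-composition tables (per day after intake
aggregation).
"""

from __future__ import annotations

#: 25 dietary parameters, with conventional units in the name suffix.
DEFAULT_PARAMETERS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "total_fat_g",
    "vitamin_b12_ug",
    "vitamin_b6_ug",
    "niacin_mg",
    "thiamin_mg",
    "riboflavin_mg",
    "folic_acid_ug",
    "vitamin_c_mg",
    "vitamin_d_ug",
    "fiber_g",
    "caffeine_g",
    "cholesterol_mg",
    "magnesium_mg",
    "vitamin_a_re",
    "vitamin_e_mg",
    "zinc_mg",
    "selenium_ug",
    "mufa_g",
    "pufa_g",
    "iron_mg",
    "beta_carotene_ug",
    "carbohydrate_g",
    "saturated_fat_g",
)

#: Name of the parameter used for the kcal-based eligibility filter.
ENERGY_PARAMETER = "energy_kcal"


def parameter_names(n: int) -> list[str]:
    """Return ``n`` parameter names.

    The first ``min(n, 25)`` come from :data:`DEFAULT_PARAMETERS`;
    any surplus is filled with generic ``parameter_26``, ... labels.
    """
    if n < 1:
        raise ValueError("need at least one dietary parameter")
    names = list(DEFAULT_PARAMETERS[:n])
    names += [f"parameter_{i + 1}" for i in range(len(names), n)]
    return names
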