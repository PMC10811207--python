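"""DII engine: z-scores, centered percentiles, weighting, overall score, quartiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diimlm as d
from diimlm import dii
from diimlm.errors import ValidationError


class TestZScore:
    @pytest.mark.parametrize(
        "intake,mean,sd,expected",
        [(5.0, 5.0, 2.0, 0.0), (2.0, 1.0, 0.5, 2.0), (0.0, 10.0, 4.0, -2.5)],
    )
    def test_closed_form(self, intake, mean, sd, expected):
        assert d.z_score(intake, mean, sd) == pytest.approx(expected)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValidationError):
            d.z_score(1.0, 0.0, 0.0)


class TestCenteredPercentile:
    def test_normal_cdf_values(self):
        assert d.centered_percentile(0.0) == pytest.approx(0.0)
        # 2·Φ(1) − 1, standard normal CDF
        assert d.centered_percentile(1.0) == pytest.approx(0.6826894921370859)
        assert d.centered_percentile(50.0) == pytest.approx(1.0)
        assert d.centered_percentile(-50.0) == pytest.approx(-1.0)

    def test_empirical_mean_near_zero(self, rng):
        z = rng.standard_normal(501)
        cp = d.centered_percentile(z, method="empirical")
        assert abs(cp.mean()) < 2 / len(z)
        assert np.abs(cp).max() <= 1.0

    def test_empirical_needs_cohort(self):
        with pytest.raises(ValidationError):
            d.centered_percentile(np.array([1.0]), method="empirical")


class TestParameterScoreAndOverall:
    @pytest.mark.parametrize(
        "cp,w,expected", [(0.0, 0.9, 0.0), (0.5, -0.4, -0.2), (-1.0, 0.3, -0.3)]
    )
    def test_product(self, cp, w, expected):
        assert d.parameter_score(cp, w) == pytest.approx(expected)

    def test_overall_sum(self):
        assert d.overall_dii([0.0, 0.0]) == 0.0
        assert d.overall_dii([0.2, -0.5, 0.1]) == pytest.approx(-0.2)

    def test_overall_empty_rejected(self):
        with pytest.raises(ValidationError):
            d.overall_dii([])


class TestQuartiles:
    def test_evenly_spaced(self):
        assert d.dii_quartiles(np.arange(1, 9)).tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_all_ties_lower_quartile(self):
        assert d.dii_quartiles(np.full(8, 1.5)).tolist() == [1] * 8

    def test_uniform_balanced(self, rng):
        q = d.dii_quartiles(rng.uniform(size=1000))
        assert np.bincount(q)[1:].tolist() == [250, 250, 250, 250]

    def test_too_few(self):
        with pytest.raises(ValidationError):
            d.dii_quartiles([1.0, 2.0, 3.0])


class TestCohortScoring:
    def test_mean_intake_scores_zero(self, small_reference):
        """A participant eating exactly the global mean of every
        parameter contributes nothing to the DII."""
        intakes = pd.DataFrame(
            [small_reference["global_mean"].to_numpy()],
            columns=small_reference["parameter"],
        )
        out = dii.compute_dii(intakes, small_reference, quartiles=False)
        score_cols = [c for c in out.columns if c.startswith("score_")]
        assert np.abs(out[score_cols].to_numpy()).max() == 0.0
        assert out["dii_overall"].iloc[0] == 0.0

    def test_overall_bounded_by_effect_scores(self, small_cohort, small_reference):
        tables, _ = small_cohort
        out = dii.compute_dii(tables.intakes, small_reference)
        bound = small_reference["effect_score"].abs().sum()
        assert out["dii_overall"].abs().max() <= bound + 1e-12
        cp_cols = [c for c in out.columns if c.startswith("cp_")]
        assert np.abs(out[cp_cols].to_numpy()).max() <= 1.0

    def test_monotone_in_pro_inflammatory_intake(self, small_reference):
        """Raising the intake of a positively weighted parameter strictly
        raises the overall DII (normal CDF transform); mirrored for a
        negative weight."""
        ref = small_reference
        pro = ref.loc[ref["effect_score"] > 0, "parameter"].iloc[0]
        anti = ref.loc[ref["effect_score"] < 0, "parameter"].iloc[0]
        base = pd.DataFrame(
            [ref["global_mean"].to_numpy()], columns=ref["parameter"]
        )
        for param, direction in ((pro, 1), (anti, -1)):
            bumped = base.copy()
            bumped[param] += ref.set_index("parameter").loc[param, "global_sd"]
            lo = dii.compute_dii(base, ref, quartiles=False)["dii_overall"].iloc[0]
            hi = dii.compute_dii(bumped, ref, quartiles=False)["dii_overall"].iloc[0]
            assert direction * (hi - lo) > 0

    def test_subset_flexibility(self, small_cohort, small_reference):
        """Scoring a parameter subset equals full scoring with the
        excluded parameters' effect scores zeroed."""
        tables, _ = small_cohort
        subset = small_reference.iloc[:6]
        zeroed = small_reference.copy()
        zeroed.loc[6:, "effect_score"] = 0.0
        a = dii.compute_dii(tables.intakes, subset, quartiles=False)["dii_overall"]
        b = dii.compute_dii(tables.intakes, zeroed, quartiles=False)["dii_overall"]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_translation_invariance(self, small_cohort, small_reference):
        """Shifting an intake and its global mean together changes nothing."""
        tables, _ = small_cohort
        ref2 = small_reference.copy()
        param = ref2["parameter"].iloc[3]
        shift = 123.4
        ref2.loc[ref2["parameter"] == param, "global_mean"] += shift
        intakes2 = tables.intakes.copy()
        intakes2[param] += shift
        a = dii.compute_dii(tables.intakes, small_reference, quartiles=False)
        b = dii.compute_dii(intakes2, ref2, quartiles=False)
        assert np.allclose(
            a["dii_overall"].to_numpy(), b["dii_overall"].to_numpy(), atol=1e-12
        )

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 10.0, allow_nan=False))
    def test_units_scale_matches_rescaled_reference(self, scale, small_reference):
        intakes = pd.DataFrame(
            [small_reference["global_mean"].to_numpy() * 1.7],
            columns=small_reference["parameter"],
        )
        scaled_ref = small_reference.copy()
        scaled_ref["global_mean"] *= scale
        scaled_ref["global_sd"] *= scale
        a = dii.compute_dii(intakes, scaled_ref, units_scale=scale, quartiles=False)
        b = dii.compute_dii(
            intakes.mul(scale), scaled_ref, units_scale=1.0, quartiles=False
        )
        assert a["dii_overall"].iloc[0] == pytest.approx(b["dii_overall"].iloc[0])

    def test_missing_parameter_column_rejected(self, small_reference):
        intakes = pd.DataFrame({"energy_kcal": [2000.0]})
        with pytest.raises(ValidationError):
            dii.compute_dii(intakes, small_reference)
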