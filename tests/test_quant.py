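"""Semi-quantification, imputation, recovery, linearity and CV filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmrm.quant import (
    cv_percent,
    impute_missing,
    linearity_lod,
    recovery,
    retained_class_counts,
    semi_quantify,
    to_matrix,
    validation_filter,
)
from lipidmrm.rules import default_is_map
from lipidmrm.simulate import simulate_spike_design


def _tiny_tables(area_ratio=1.0, weight_mg=100.0):
    areas = pd.DataFrame(
        {
            "sample": ["s1", "s1"],
            "transition_id": ["PE 16:0_18:1", "IS 15:0-18:1(d7) PE"],
            "area": [1000.0 * area_ratio, 1000.0],
        }
    )
    areas.loc[areas["transition_id"].str.startswith("IS"), "lipid_class"] = "PE"
    areas["lipid_class"] = areas["lipid_class"].fillna("PE")
    samples = pd.DataFrame({"sample": ["s1"], "weight_mg": [weight_mg]})
    return areas, samples


IS_MAP = {"PE": ("IS 15:0-18:1(d7) PE", 150.0)}


class TestSemiQuantify:
    def test_direct_formula(self):
        areas, samples = _tiny_tables(area_ratio=1.0, weight_mg=100.0)
        conc = semi_quantify(areas, samples, IS_MAP)
        # ratio 1 x 150 ug / 0.1 g = 1500 ug/g
        assert conc["conc_ug_g"].iloc[0] == pytest.approx(1500.0)

    def test_doubling_weight_halves_concentration(self):
        a1, s1 = _tiny_tables(weight_mg=100.0)
        a2, s2 = _tiny_tables(weight_mg=200.0)
        c1 = semi_quantify(a1, s1, IS_MAP)["conc_ug_g"].iloc[0]
        c2 = semi_quantify(a2, s2, IS_MAP)["conc_ug_g"].iloc[0]
        assert c2 == pytest.approx(c1 / 2)

    def test_forward_simulation_inverts_exactly(self, maturation_run):
        """quantify(simulate(...)) reproduces the planted concentrations."""
        _, areas, samples, truth = maturation_run
        conc = semi_quantify(areas, samples, default_is_map())
        wide = to_matrix(conc)
        expected = truth["conc"]
        obs = wide.loc[expected.index, expected.columns]
        both = obs.notna() & expected.notna()
        assert both.to_numpy().any()
        assert np.allclose(
            obs.to_numpy()[both.to_numpy()],
            expected.to_numpy()[both.to_numpy()],
            rtol=1e-12,
        )
        # masked entries stay missing on both sides
        pd.testing.assert_frame_equal(obs.isna(), expected.isna())

    def test_missing_is_area_names_sample_and_class(self):
        areas, samples = _tiny_tables()
        areas = areas[~areas["transition_id"].str.startswith("IS")]
        with pytest.raises((ValueError, KeyError), match="PE"):
            semi_quantify(areas, samples, IS_MAP)

    def test_zero_weight_rejected(self):
        areas, samples = _tiny_tables(weight_mg=0.0)
        with pytest.raises(ValueError, match="weight"):
            semi_quantify(areas, samples, IS_MAP)


class TestImputation:
    def _matrix(self):
        return pd.DataFrame(
            {
                "a": [10.0, np.nan, 14.0, np.nan],
                "b": [1.0, 2.0, 3.0, 4.0],
            },
            index=list("wxyz"),
        )

    def test_draws_fall_below_half_minimum(self):
        out = impute_missing(self._matrix(), seed=3)
        filled = out.loc[["x", "z"], "a"]
        assert ((filled > 0) & (filled < 5.0)).all()

    def test_complete_table_unchanged(self):
        m = self._matrix()[["b"]]
        pd.testing.assert_frame_equal(impute_missing(m, seed=1), m)

    def test_seed_determinism(self):
        m = self._matrix()
        pd.testing.assert_frame_equal(
            impute_missing(m, seed=42), impute_missing(m, seed=42)
        )

    def test_all_missing_compound_rejected(self):
        m = self._matrix()
        m["a"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            impute_missing(m)


class TestCV:
    def test_constant_values(self):
        assert cv_percent([5, 5, 5]) == 0.0

    def test_hand_computed(self):
        assert cv_percent([8, 10, 12]) == pytest.approx(20.0)

    @given(st.floats(0.01, 1e4))
    @settings(max_examples=30, derandomize=True)
    def test_scale_invariance(self, k):
        assert cv_percent([8 * k, 10 * k, 12 * k]) == pytest.approx(20.0, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cv_percent([5.0])
        with pytest.raises(ValueError):
            cv_percent([-1.0, 1.0])


class TestRecovery:
    def test_perfect_measurement_is_100(self):
        df = simulate_spike_design({"PE": 100.0}, noise_cv=0.0)
        assert recovery(df)["PE"] == pytest.approx(100.0)

    def test_uniform_bias(self):
        df = simulate_spike_design({"PI": 80.0}, noise_cv=0.0)
        assert recovery(df)["PI"] == pytest.approx(80.0)

    def test_mean_of_levels(self):
        rows = []
        for level, rec in [(0.1, 0.7), (0.5, 0.8), (1.0, 0.9)]:
            for r in range(5):
                rows.append(("PG", level, r, level, level * rec))
        df = pd.DataFrame(
            rows, columns=["lipid_class", "level", "replicate", "expected", "measured"]
        )
        assert recovery(df)["PG"] == pytest.approx(80.0)

    def test_missing_level_lists_found(self):
        df = simulate_spike_design({"PE": 100.0})
        df = df[df["level"] != 0.5]
        with pytest.raises(ValueError, match=r"0\.5.*found.*0\.1"):
            recovery(df)


class TestLinearityLod:
    def test_perfect_series_spans_full_range(self):
        conc = np.array([0.1, 0.5, 1, 5, 10, 50, 100])
        res = linearity_lod(conc, 20 * conc + 1, noise_sd=0.5)
        assert res.linear_range == (0.1, 100.0)
        assert res.loq == 0.1
        assert res.lod == pytest.approx(3.3 * 0.5 / 20)

    def test_saturating_top_point_excluded(self):
        conc = np.array([0.1, 0.5, 1, 5, 10, 50, 100])
        resp = 20 * conc + 1
        resp[-1] = resp[-2] * 1.05  # detector saturation
        res = linearity_lod(conc, resp, noise_sd=0.5)
        assert res.linear_range == (0.1, 50.0)
        assert res.loq == 0.1

    def test_zero_noise_sentinel(self):
        conc = np.array([1.0, 2, 3, 4, 5])
        res = linearity_lod(conc, 2 * conc, noise_sd=0.0)
        assert res.lod == 0.0
        assert "lod-below-lowest-level" in res.flags

    def test_hopeless_series_flagged_empty(self):
        rng = np.random.default_rng(0)
        conc = np.arange(1.0, 9.0)
        res = linearity_lod(conc, rng.permutation(conc), noise_sd=1.0)
        assert res.linear_range is None
        assert "no-linear-range" in res.flags


class TestValidationFilter:
    def _records(self):
        return pd.DataFrame(
            {
                "transition_id": ["a", "b", "c", "d"],
                "lipid_class": ["PE", "PE", "CER", "CER"],
                "repeatability_cv": [10.0, 20.0, 19.0, 21.0],
                "kmd_flag": ["pass", "pass", "diagonal_violation", "pass"],
            }
        )

    def test_threshold_is_inclusive_and_conjunctive(self):
        out = validation_filter(self._records())
        assert out.set_index("transition_id")["retained"].to_dict() == {
            "a": True,   # clean
            "b": True,   # CV == 20.0 exactly: retained
            "c": False,  # CV fine but grid violation
            "d": False,  # CV above threshold
        }

    def test_tightening_threshold_is_monotone(self):
        rec = self._records()
        loose = validation_filter(rec, repeatability_max=20)["retained"]
        for thr in (15, 10, 5, 1):
            tight = validation_filter(rec, repeatability_max=thr)["retained"]
            assert not (tight & ~loose).any()
            loose = tight

    def test_class_count_layout(self):
        counts = retained_class_counts(validation_filter(self._records()))
        assert counts.loc["PE", "validated"] == 2
        assert counts.loc["CER", "detected"] == 2
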