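import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cardioscreen.activity import (
    activity_indexes,
    bioactive_map,
    dual_scores,
    normalize_areas,
    rank_compounds,
)
from cardioscreen.synth import AssaySimConfig, generate_fraction_assay


def _matrix(values, fractions=None, compounds=None):
    values = np.asarray(values, dtype=float)
    m, p = values.shape
    return pd.DataFrame(values,
                        index=fractions or [f"F{i+1}" for i in range(m)],
                        columns=compounds or [f"C{j+1}" for j in range(p)])


class TestNormalize:
    def test_single_fraction_all_ones(self):
        norm = normalize_areas(_matrix([[3.0, 7.0, 0.5]]))
        assert (norm.values == 1.0).all()

    def test_three_to_one_split(self):
        norm = normalize_areas(_matrix([[3.0], [1.0]]))
        assert norm["C1"].tolist() == [0.75, 0.25]

    def test_random_matrix_columns_sum_to_one(self, rng):
        norm = normalize_areas(_matrix(rng.lognormal(size=(6, 30))))
        assert np.allclose(norm.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_dropped_with_warning(self):
        m = _matrix([[1.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="zero total area"):
            norm = normalize_areas(m)
        assert list(norm.columns) == ["C1"]

    def test_all_zero_matrix_raises_and_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_areas(_matrix([[0.0], [0.0]]))
        with pytest.raises(ValueError):
            normalize_areas(_matrix([[-1.0], [2.0]]))


class TestActivityIndexes:
    def test_constant_recovery_gives_constant_ai(self, rng):
        norm = normalize_areas(_matrix(rng.lognormal(size=(5, 12))))
        r = pd.Series(37.5, index=norm.index)
        scores = activity_indexes(norm, r)
        assert np.allclose(scores["AI"], 37.5, atol=1e-9)

    def test_compound_wholly_in_one_fraction_gets_that_recovery(self):
        m = _matrix([[5.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        r = pd.Series([80.0, 20.0, -10.0], index=m.index)
        scores = activity_indexes(normalize_areas(m), r)
        assert scores.loc["C1", "AI"] == pytest.approx(80.0)

    def test_positive_flag_and_rank_permutation(self, rng):
        norm = normalize_areas(_matrix(rng.lognormal(size=(4, 9))))
        r = pd.Series([50.0, 10.0, -5.0, -40.0], index=norm.index)
        scores = activity_indexes(norm, r)
        assert sorted(scores["rank"]) == list(range(1, 10))
        assert ((scores["AI"] > 0) == scores["positive"]).all()

    def test_missing_fraction_in_recovery_raises(self):
        norm = normalize_areas(_matrix([[1.0], [1.0]]))
        with pytest.raises(ValueError, match="missing fractions"):
            activity_indexes(norm, pd.Series({"F1": 10.0}))

    @given(arrays(np.float64, (5, 8),
                  elements=st.floats(0.01, 1e6)),
           arrays(np.float64, 5, elements=st.floats(-100, 150)))
    @settings(derandomize=True, max_examples=40)
    def test_ai_bounded_by_recovery_range(self, areas, r_vals):
        norm = normalize_areas(_matrix(areas))
        r = pd.Series(r_vals, index=norm.index)
        ai = activity_indexes(norm, r)["AI"]
        assert (ai >= r_vals.min() - 1e-9).all()
        assert (ai <= r_vals.max() + 1e-9).all()

    @given(arrays(np.float64, (4, 6), elements=st.floats(0.01, 1e4)),
           st.floats(0.001, 1000.0))
    @settings(derandomize=True, max_examples=40)
    def test_ai_invariant_to_compound_rescaling(self, areas, scale):
        r = pd.Series([60.0, 30.0, 0.0, -20.0],
                      index=[f"F{i+1}" for i in range(4)])
        base = activity_indexes(normalize_areas(_matrix(areas)), r)["AI"]
        scaled = areas.copy()
        scaled[:, 2] *= scale
        rescored = activity_indexes(normalize_areas(_matrix(scaled)), r)["AI"]
        assert np.allclose(base, rescored, rtol=1e-9)

    def test_weighted_total_identity_on_random_matrix(self, rng):
        # sum_j AI_j * (share of total area in compound j) equals
        # sum_i R_i * (share of total area in fraction i) -- both reduce to
        # the grand area-weighted recovery when normalisation is undone
        areas = _matrix(rng.lognormal(size=(6, 10)))
        r = pd.Series(rng.normal(20, 40, size=6), index=areas.index)
        norm = normalize_areas(areas)
        ai = activity_indexes(norm, r)["AI"]
        # oracle identity computed directly from raw areas
        lhs = float((areas.mul(r, axis=0).sum(axis=0) / areas.sum(axis=0)
                     * areas.sum(axis=0)).sum()) / float(areas.values.sum())
        rhs = float(areas.sum(axis=1).mul(r).sum()) / float(areas.values.sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)
        weighted_ai = float((ai * areas.sum(axis=0)).sum()) / float(areas.values.sum())
        assert weighted_ai == pytest.approx(rhs, rel=1e-9)


class TestRanking:
    def test_ties_broken_by_compound_id(self):
        scores = pd.DataFrame({"AI": [10.0, 10.0], "rank": [1, 2],
                               "positive": [True, True]}, index=["Cb", "Ca"])
        assert rank_compounds(scores) == ["Ca", "Cb"]

    def test_strictly_decreasing_identity_permutation(self):
        scores = pd.DataFrame({"AI": [30.0, 20.0, 10.0]},
                              index=["C1", "C2", "C3"])
        assert rank_compounds(scores) == ["C1", "C2", "C3"]

    def test_input_order_invariance(self, rng):
        norm = normalize_areas(_matrix(rng.lognormal(size=(3, 7))))
        r = pd.Series([50.0, 0.0, -30.0], index=norm.index)
        a = activity_indexes(norm, r)
        b = activity_indexes(norm[sorted(norm.columns, reverse=True)], r)
        assert a["rank"].sort_index().equals(b["rank"].sort_index())

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_compounds(pd.DataFrame(columns=["AI"]))


class TestBioactiveMap:
    def test_column_sums_equal_ai(self, rng):
        norm = normalize_areas(_matrix(rng.lognormal(size=(5, 8))))
        r = pd.Series(rng.normal(0, 50, size=5), index=norm.index)
        bmap = bioactive_map(norm, r)
        ai = activity_indexes(norm, r)["AI"]
        assert np.allclose(bmap.sum(axis=0), ai, atol=1e-12)

    def test_zero_recovery_row_is_zero(self):
        norm = normalize_areas(_matrix([[1.0, 2.0], [1.0, 2.0]]))
        r = pd.Series([0.0, 40.0], index=norm.index)
        assert (bioactive_map(norm, r).loc["F1"] == 0.0).all()

    def test_single_cell_equals_recovery(self):
        bmap = bioactive_map(normalize_areas(_matrix([[7.0]])),
                             pd.Series({"F1": 55.0}))
        assert bmap.iloc[0, 0] == pytest.approx(55.0)


class TestDualScores:
    def test_identical_coefficients_put_points_on_diagonal(self, rng):
        norm = normalize_areas(_matrix(rng.lognormal(size=(4, 6))))
        r = pd.Series([60.0, 20.0, -10.0, 5.0], index=norm.index)
        z = activity_indexes(norm, r)
        c = activity_indexes(norm, r)
        dual = dual_scores(z, c)
        assert np.allclose(dual["cell_AI"], dual["zebrafish_AI"])

    def test_planted_dual_active_lands_upper_right(self):
        areas, recovery, placement = generate_fraction_assay(AssaySimConfig(seed=8))
        norm = normalize_areas(areas)
        protection = pd.Series(
            np.clip(recovery.values, 0, None), index=recovery.index)
        dual = dual_scores(activity_indexes(norm, recovery),
                           activity_indexes(norm, protection))
        active = next(iter(placement))
        assert dual.loc[active, "cell_AI"] > 0
        assert dual.loc[active, "zebrafish_AI"] > 0
        assert dual.loc[active, "zebrafish_AI"] >= dual["zebrafish_AI"].max() - 1e-9

    def test_unmatched_reported_and_empty_intersection_raises(self):
        z = pd.DataFrame({"AI": [1.0, 2.0]}, index=["C1", "C2"])
        c = pd.Series({"C2": 3.0, "C9": 4.0})
        dual = dual_scores(z, c)
        assert dual.attrs["unmatched"] == ["C1", "C9"]
        with pytest.raises(ValueError):
            dual_scores(z, pd.Series({"X": 1.0}))


class TestParameterRecoverySmoke:
    def test_planted_active_ranks_first_in_typical_run(self):
        areas, recovery, placement = generate_fraction_assay(AssaySimConfig(seed=0))
        scores = activity_indexes(normalize_areas(areas), recovery)
        active = next(iter(placement))
        assert scores.loc[active, "rank"] == 1
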