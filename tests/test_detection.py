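"""Complete-case filter, timepoint ANOVA, delta categorisation, dedup,
specificity subtraction and the composed pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats

from rrbsdmf.detection import (
    CATEGORY_ORDER,
    MethMatrix,
    PipelineConfig,
    anova_timepoints,
    categorize_deltas,
    category_counts,
    complete_case_filter,
    dedupe_combine,
    run_dmf_pipeline,
    significance_filter,
    subtract_control_dmfs,
    timepoint_means,
)

TPS = ("0h", "24h", "48h")


def make_matrix(arr, participants, groups, fragment_ids=None):
    """arr shape (fragments, timepoints, participants)."""
    arr = np.asarray(arr, dtype=float)
    cols = pd.MultiIndex.from_tuples(
        [(p, t) for p in participants for t in TPS]
    )
    flat = np.concatenate(
        [arr[:, :, i] for i in range(arr.shape[2])], axis=1
    )
    ids = fragment_ids or [f"chr1:{i * 100}-{i * 100 + 50}" for i in range(arr.shape[0])]
    return MethMatrix(pd.DataFrame(flat, index=ids, columns=cols), groups, TPS)


def case_matrix(arr, n=None):
    n = n or np.asarray(arr).shape[2]
    parts = [f"P{i}" for i in range(n)]
    return make_matrix(arr, parts, {p: "case" for p in parts})


class TestCompleteCase:
    def test_fragment_with_one_missing_cell_removed(self):
        arr = np.full((3, 3, 5), 0.5)
        m = case_matrix(arr)
        vals = m.values.copy()
        vals.iloc[1, 4] = np.nan
        m = MethMatrix(vals, m.groups, TPS)
        out = complete_case_filter(m, "case")
        assert list(out.values.index) == [m.values.index[0], m.values.index[2]]

    def test_no_missing_leaves_matrix_unchanged(self):
        m = case_matrix(np.full((4, 3, 5), 0.3))
        out = complete_case_filter(m, "case")
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(17)
        arr = rng.random((200, 3, 4))
        mask = rng.random((200, 3, 4)) < 0.1
        arr[mask] = np.nan
        m = case_matrix(arr)
        out = complete_case_filter(m, "case")
        oracle = [
            m.values.index[i]
            for i in range(200)
            if not np.isnan(arr[i]).any()
        ]
        assert list(out.values.index) == oracle

    def test_empty_group_is_an_error(self):
        m = case_matrix(np.full((2, 3, 3), 0.5))
        with pytest.raises(ValueError, match="control"):
            complete_case_filter(m, "control")


class TestAnova:
    def test_no_variation_gives_f_zero_p_one(self):
        m = case_matrix(np.full((2, 3, 2), 0.1))
        out = anova_timepoints(m)
        assert (out["f_statistic"] == 0).all()
        assert (out["p_value"] == 1).all()

    def test_matches_hand_computed_closed_form(self):
        # groups (0.2,0.3), (0.4,0.5), (0.6,0.7): MS_b=0.08, MS_w=0.005,
        # F=16 with df (2, 3)
        arr = np.array([[[0.2, 0.3], [0.4, 0.5], [0.6, 0.7]]])
        out = anova_timepoints(case_matrix(arr))
        assert out["f_statistic"].iloc[0] == pytest.approx(16.0)
        # independent F-tail via the regularised incomplete beta function
        d1, d2, F = 2, 3, 16.0
        p_beta = special.betainc(d2 / 2, d1 / 2, d2 / (d2 + d1 * F))
        assert out["p_value"].iloc[0] == pytest.approx(p_beta, rel=1e-12)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        arr = rng.random((50, 3, 5))
        out = anova_timepoints(case_matrix(arr))
        for i in range(50):
            f, p = stats.f_oneway(arr[i, 0], arr[i, 1], arr[i, 2])
            assert out["f_statistic"].iloc[i] == pytest.approx(f)
            assert out["p_value"].iloc[i] == pytest.approx(p)

    def test_zero_within_variance_unequal_means_sentinel(self):
        arr = np.array([[[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]]])
        with pytest.warns(RuntimeWarning, match="zero within-timepoint"):
            out = anova_timepoints(case_matrix(arr))
        assert out["p_value"].iloc[0] == 0.0

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError, match="participants"):
            anova_timepoints(case_matrix(np.full((1, 3, 1), 0.5)))

    def test_invariant_to_participant_relabelling(self):
        rng = np.random.default_rng(3)
        arr = rng.random((20, 3, 5))
        base = anova_timepoints(case_matrix(arr))
        shuffled = arr.copy()
        for t in range(3):  # permute participants within each timepoint
            shuffled[:, t, :] = shuffled[:, t, rng.permutation(5)]
        out = anova_timepoints(case_matrix(shuffled))
        np.testing.assert_allclose(
            out["f_statistic"], base["f_statistic"], rtol=1e-10
        )

    def test_type_one_error_calibrated_on_unimodal_null(self):
        # smoke-scale calibration; the full 10^4-fragment check runs in the
        # acceptance suite
        rng = np.random.default_rng(2024)
        arr = rng.beta(2, 2, size=(2000, 3, 5))
        out = anova_timepoints(case_matrix(arr))
        rate = (out["p_value"] < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)


class TestSignificance:
    def test_threshold_is_strict(self):
        df = pd.DataFrame({"p_value": [0.01, 0.05, 0.049]})
        out = significance_filter(df, alpha=0.05)
        assert list(out["p_value"]) == [0.01, 0.049]

    def test_alpha_one_retains_everything(self):
        df = pd.DataFrame({"p_value": [0.2, 0.9, 0.999]})
        assert len(significance_filter(df, alpha=1.0)) == 3

    def test_invalid_alpha_rejected(self):
        df = pd.DataFrame({"p_value": [0.5]})
        for alpha in (0.0, -1, 1.5):
            with pytest.raises(ValueError):
                significance_filter(df, alpha=alpha)

    def test_bh_correction_is_more_conservative(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"p_value": rng.uniform(0, 0.2, 100)})
        raw = significance_filter(df, 0.05)
        bh = significance_filter(df, 0.05, fdr=True)
        assert set(bh.index) <= set(raw.index)


def mean_frame(rows):
    return pd.DataFrame(
        rows, columns=["mean_0h", "mean_24h", "mean_48h"],
        index=[f"f{i}" for i in range(len(rows))],
    )


class TestCategorize:
    def test_strictness_at_exactly_ten_points(self):
        # complement-pathway promoter worked example: means 28/38/20
        df = mean_frame([[28.0, 38.0, 20.0]])
        strict = categorize_deltas(df, 10.0, strict=True)
        assert strict.iloc[0][["delta_early", "delta_late", "delta_gradual"]].tolist() == [
            pytest.approx(10.0),
            pytest.approx(-18.0),
            pytest.approx(-8.0),
        ]
        assert not strict.iloc[0]["cat_early"]  # |10| is not > 10
        assert strict.iloc[0]["cat_late"]
        lax = categorize_deltas(df, 10.0, strict=False)
        assert lax.iloc[0]["cat_early"] and lax.iloc[0]["cat_late"]
        assert not lax.iloc[0]["cat_gradual"]

    def test_flat_record_dropped(self):
        assert categorize_deltas(mean_frame([[50.0, 50.0, 50.0]])).empty

    def test_delta_identity_holds_exactly(self):
        rng = np.random.default_rng(9)
        df = mean_frame(rng.uniform(0, 100, (200, 3)))
        out = categorize_deltas(df, threshold=0.0, strict=False)
        np.testing.assert_array_equal(
            out["delta_gradual"].to_numpy(),
            (out["delta_early"] + out["delta_late"]).to_numpy(),
        )

    @given(
        t1=st.floats(min_value=0, max_value=40),
        t2=st.floats(min_value=0, max_value=40),
    )
    def test_raising_threshold_never_adds_categories(self, t1, t2):
        lo, hi = sorted((t1, t2))
        rng = np.random.default_rng(4)
        df = mean_frame(rng.uniform(0, 100, (50, 3)))
        a = categorize_deltas(df, lo)
        b = categorize_deltas(df, hi)
        for cat in CATEGORY_ORDER:
            sub = b.index.intersection(a.index)
            assert (~b.loc[sub, f"cat_{cat}"] | a.loc[sub, f"cat_{cat}"]).all()
        assert set(b.index) <= set(a.index)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            categorize_deltas(mean_frame([[0, 50, 100]]), threshold=-1)


class TestDedupeAndSubtract:
    def _records(self, flags):
        df = pd.DataFrame(
            flags, columns=[f"cat_{c}" for c in CATEGORY_ORDER],
            index=[f"f{i}" for i in range(len(flags))],
        )
        return df

    def test_earliest_category_wins(self):
        df = self._records([[True, False, True], [False, True, False]])
        out = dedupe_combine(df)
        assert list(out["assigned_category"]) == ["early", "late"]

    def test_total_equals_set_union_oracle(self):
        rng = np.random.default_rng(12)
        flags = rng.random((300, 3)) < 0.3
        flags = flags[flags.any(axis=1)]
        out = dedupe_combine(self._records(flags))
        union = set()
        for j in range(3):
            union |= {i for i in range(len(flags)) if flags[i, j]}
        assert len(out) == len(union)
        counts = category_counts(out)
        assert counts["combined"] == len(union)

    def test_empty_category_set_rejected(self):
        with pytest.raises(ValueError, match="empty category"):
            dedupe_combine(self._records([[False, False, False]]))

    def test_specificity_is_set_difference(self):
        case = pd.DataFrame(index=["A", "B", "C"])
        flagged, specific, removed = subtract_control_dmfs(case, ["B"])
        assert list(specific.index) == ["A", "C"]
        assert removed == 1
        assert flagged.loc["B", "specific"] == False  # noqa: E712

    def test_empty_control_set_keeps_everything(self):
        case = pd.DataFrame(index=["A", "B"])
        _, specific, removed = subtract_control_dmfs(case, [])
        assert list(specific.index) == ["A", "B"] and removed == 0

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(23)
        universe = [f"frag{i}" for i in range(500)]
        case_ids = sorted(rng.choice(universe, 200, replace=False))
        control_ids = set(rng.choice(universe, 150, replace=False))
        case = pd.DataFrame(index=case_ids)
        _, specific, removed = subtract_control_dmfs(case, control_ids)
        brute = [f for f in case_ids if f not in control_ids]
        assert list(specific.index) == brute
        assert removed == 200 - len(brute)


class TestPipeline:
    def test_shared_effects_are_flagged_non_specific(self):
        # planted jump present in cases AND controls -> removed by subtraction
        rng = np.random.default_rng(6)
        parts = [f"P{i}" for i in range(5)] + ["C0", "C1"]
        groups = {p: ("case" if p.startswith("P") else "control") for p in parts}
        base = rng.uniform(0.3, 0.5, size=(30, 1, 1))
        arr = base + rng.normal(0, 0.01, size=(30, 3, 7))
        arr[:5, 1:, :] += 0.3  # shared early jump in fragments 0-4, all samples
        m = make_matrix(np.clip(arr, 0, 1), parts, groups)
        res = run_dmf_pipeline(m)
        shared = set(m.values.index[:5])
        assert shared <= set(res.case.index)
        assert not (shared & set(res.specific.index))
        assert (~res.case.loc[sorted(shared), "specific"]).all()

    def test_case_only_effects_are_specific(self):
        rng = np.random.default_rng(60)
        parts = [f"P{i}" for i in range(5)] + ["C0", "C1"]
        groups = {p: ("case" if p.startswith("P") else "control") for p in parts}
        arr = 0.4 + rng.normal(0, 0.01, size=(30, 3, 7))
        arr[:5, 1:, :5] += 0.3  # cases only
        m = make_matrix(np.clip(arr, 0, 1), parts, groups)
        res = run_dmf_pipeline(m)
        assert set(m.values.index[:5]) <= set(res.specific.index)

    def test_stage_counts_are_monotone_non_increasing(self, small_matrix):
        res = run_dmf_pipeline(small_matrix)
        for col in ("case", "control"):
            seq = res.stage_counts[col].dropna()
            main = [
                seq["input"], seq["complete_case"], seq["significant"], seq["combined"],
            ]
            if col == "case":
                main.append(seq["specific"])
            assert all(a >= b for a, b in zip(main, main[1:]))

    def test_null_permutation_keeps_counts_similar(self):
        rng = np.random.default_rng(77)
        parts = [f"P{i}" for i in range(5)] + ["C0", "C1"]
        groups = {p: ("case" if p.startswith("P") else "control") for p in parts}
        arr = rng.beta(2, 2, size=(400, 3, 7))
        m = make_matrix(arr, parts, groups)
        res = run_dmf_pipeline(m)
        perm = arr[:, rng.permutation(3), :]
        res_p = run_dmf_pipeline(make_matrix(perm, parts, groups))
        a = res.stage_counts.loc["significant", "case"]
        b = res_p.stage_counts.loc["significant", "case"]
        # both are Binomial(400, ~0.05) draws; allow a wide stochastic band
        assert abs(a - b) < 30

    def test_timepoint_means_reported_in_percent(self):
        arr = np.full((1, 3, 2), 0.25)
        arr[0, 1, :] = 0.75
        means = timepoint_means(case_matrix(arr))
        assert means.iloc[0].tolist() == [25.0, 75.0, 25.0]

    def test_matrix_rejects_out_of_range_values(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            case_matrix(np.full((1, 3, 2), 1.5))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PipelineConfig(alpha=0)
        with pytest.raises(ValueError):
            PipelineConfig(delta_threshold=-5)
        with pytest.raises(ValueError):
            PipelineConfig(control_comparison="nope")
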