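"""Differential-intensity workflow: filtering, imputation, SAM/S0 test,
phospho classification, condition-specific detection."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicetope import diff_intensity as di
from splicetope import synthetic_data as syn


def _matrix(values, n_per_group=None, meta=None):
    df = pd.DataFrame(values)
    n = df.shape[1] // 2 if n_per_group is None else n_per_group
    cols = [f"control_{i+1}" for i in range(n)] + [f"treated_{i+1}" for i in range(df.shape[1] - n)]
    df.columns = cols
    df.index = [f"f{i+1}" for i in range(len(df))]
    groups = pd.Series([c.rsplit("_", 1)[0] for c in cols], index=cols)
    if meta is not None:
        meta = pd.DataFrame(meta, index=df.index)
    return di.IntensityMatrix(df.astype(float), groups, meta)


class TestValidityFilter:
    def test_three_of_four_valid_in_one_group_is_kept(self):
        row = [1.0, 2.0, 3.0, np.nan, np.nan, np.nan, np.nan, np.nan]
        mat = _matrix([row], n_per_group=4)
        assert len(di.filter_valid_fraction(mat, 0.75).values) == 1

    def test_half_valid_in_both_groups_is_dropped(self):
        row = [1.0, 2.0, np.nan, np.nan, 1.0, 2.0, np.nan, np.nan]
        mat = _matrix([row], n_per_group=4)
        with pytest.warns(UserWarning):
            out = di.filter_valid_fraction(mat, 0.75)
        assert len(out.values) == 0

    def test_full_validity_requirement_drops_any_missing(self):
        row = [1.0, 2.0, np.nan, 4.0, 5.0, np.nan]
        mat = _matrix([row], n_per_group=3)
        with pytest.warns(UserWarning):
            assert len(di.filter_valid_fraction(mat, 1.0).values) == 0

    def test_order_preserved(self, rng):
        mat = _matrix(rng.normal(size=(10, 6)))
        out = di.filter_valid_fraction(mat, 0.75)
        assert list(out.values.index) == list(mat.values.index)


class TestPhosphositeFilter:
    def _mat(self, probs, reverse=None, contaminant=None):
        n = len(probs)
        meta = {
            "protein_id": [f"P{i}" for i in range(n)],
            "localization_prob": probs,
            "reverse": reverse or [False] * n,
            "contaminant": contaminant or [False] * n,
        }
        return _matrix(np.ones((n, 4)), meta=meta)

    def test_localization_bound_is_inclusive(self):
        mat = self._mat([0.75, 0.74, 0.99])
        out = di.filter_phosphosites(mat)
        assert list(out.values.index) == ["f1", "f3"]

    def test_reverse_flag_dominates_probability(self):
        mat = self._mat([0.99, 0.99], reverse=[True, False])
        assert list(di.filter_phosphosites(mat).values.index) == ["f2"]

    def test_missing_metadata_is_contract_error(self):
        mat = _matrix(np.ones((2, 4)))
        with pytest.raises(ValueError):
            di.filter_phosphosites(mat)


class TestImputation:
    def test_complete_matrix_returned_unchanged(self, rng):
        mat = _matrix(rng.normal(25, 1, size=(50, 6)))
        out = di.impute_downshifted_normal(mat, seed=1)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_imputed_draws_match_downshifted_normal(self, rng):
        n = 20000
        vals = rng.normal(25, 1, size=(n, 4))
        vals[: n // 2, 0] = np.nan
        mat = _matrix(vals, n_per_group=2)
        obs = mat.values["control_1"].dropna()
        mu, sd = obs.mean(), obs.std(ddof=1)
        out = di.impute_downshifted_normal(mat, width=0.3, downshift=2.4, seed=5)
        drawn = out.values["control_1"].iloc[: n // 2]
        ks = stats.kstest(drawn, "norm", args=(mu - 2.4 * sd, 0.3 * sd))
        assert ks.pvalue > 0.01

    def test_same_seed_gives_identical_values(self, rng):
        vals = rng.normal(25, 1, size=(100, 4))
        vals[:30, 1] = np.nan
        mat = _matrix(vals, n_per_group=2)
        a = di.impute_downshifted_normal(mat, seed=9)
        b = di.impute_downshifted_normal(mat, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_sample_with_single_observation_is_an_error(self):
        vals = np.full((3, 4), np.nan)
        vals[0, 0] = 25.0
        vals[:, 1:] = 25.0
        mat = _matrix(vals, n_per_group=2)
        with pytest.raises(ValueError, match="control_1"):
            di.impute_downshifted_normal(mat, seed=1)


class TestMedianNormalize:
    def test_definition_and_idempotence(self):
        mat = _matrix([[1.0, 5, 7, 2], [2.0, 6, 8, 3], [3.0, 7, 9, 4]], n_per_group=2)
        out = di.median_normalize(mat)
        assert list(out.values["control_1"]) == [-1.0, 0.0, 1.0]
        again = di.median_normalize(out)
        pd.testing.assert_frame_equal(again.values, out.values)

    def test_all_medians_zero_after_normalisation(self, rng):
        mat = _matrix(rng.normal(20, 3, size=(101, 6)))
        out = di.median_normalize(mat)
        assert np.allclose(out.values.median(axis=0), 0.0)


class TestSamTest:
    def test_identical_groups_zero_variance_gives_no_hits(self):
        base = np.tile(np.arange(10, 20, dtype=float)[:, None], (1, 6))
        mat = _matrix(base)
        res = di.sam_test(mat, s0=0.35, n_permutations=100, seed=1)
        assert (res["d"] == 0).all()
        assert not res["significant"].any()

    def test_s0_zero_equals_classical_pooled_t(self, rng):
        mat = _matrix(rng.normal(25, 2, size=(1000, 6)))
        res = di.sam_test(mat, s0=0.0, n_permutations=100, seed=1)
        t = stats.ttest_ind(
            mat.values[mat.samples("treated")],
            mat.values[mat.samples("control")],
            axis=1,
        ).statistic
        assert np.abs(res["d"].to_numpy() - t).max() < 1e-9

    def test_lowering_s0_never_flips_d_sign(self, rng):
        mat = _matrix(rng.normal(25, 2, size=(500, 6)))
        d_hi = di.sam_test(mat, s0=0.5, n_permutations=100, seed=1)["d"]
        d_lo = di.sam_test(mat, s0=0.0, n_permutations=100, seed=1)["d"]
        assert (np.sign(d_hi) == np.sign(d_lo)).all()

    def test_q_values_monotone_in_abs_d(self, rng):
        mat = _matrix(rng.normal(25, 2, size=(500, 6)))
        res = di.sam_test(mat, s0=0.1, n_permutations=250, seed=1)
        res = res.sort_values("d", key=np.abs, ascending=False)
        assert (np.diff(res["q_value"]) >= -1e-12).all()

    def test_planted_effects_recovered_with_sensitivity_and_fdr(self):
        sens, fdr = [], []
        for s in range(5):
            truths = syn.make_intensity_truths(2000, 0.1, 2.0, seed=300 + s)
            mat = syn.simulate_intensity_matrix(2000, 3, truths, noise_sd=0.5, seed=300 + s)
            res = di.sam_test(mat, s0=0.35, fdr_threshold=0.05, n_permutations=250, seed=s)
            nonnull = {t.feature_id for t in truths if not t.is_null}
            flagged = set(res.index[res["significant"]])
            sens.append(len(flagged & nonnull) / len(nonnull))
            fdr.append(len(flagged - nonnull) / max(1, len(flagged)))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.10

    def test_small_group_is_contract_error(self):
        vals = np.ones((3, 3))
        df = pd.DataFrame(vals, columns=["control_1", "control_2", "treated_1"])
        groups = pd.Series(
            {"control_1": "control", "control_2": "control", "treated_1": "treated"}
        )
        with pytest.raises(ValueError):
            di.IntensityMatrix(df, groups)


class TestPhosphoClassification:
    def _results(self, rows):
        df = pd.DataFrame(rows)
        df.index = [f"site{i}" for i in range(len(df))]
        return df

    def test_classes_follow_site_directions(self):
        res = self._results(
            [
                {"log2fc": 1.2, "significant": True},   # protA up
                {"log2fc": 0.9, "significant": True},   # protA up
                {"log2fc": 1.2, "significant": True},   # protB up
                {"log2fc": -0.8, "significant": True},  # protB down
                {"log2fc": 0.3, "significant": True},   # protC below FC cut
                {"log2fc": -2.0, "significant": False}, # protD not significant
            ]
        )
        proteins = pd.Series(
            ["A", "A", "B", "B", "C", "D"], index=res.index
        )
        out = di.classify_protein_phospho(res, proteins)
        assert out.loc["A", "class"] == "hyper"
        assert out.loc["B", "class"] == "biphasic"
        assert out.loc["C", "class"] == "unchanged"
        assert out.loc["D", "class"] == "unchanged"

    def test_classes_partition_all_proteins(self, rng):
        n = 200
        res = self._results(
            [
                {"log2fc": float(rng.normal(0, 1)), "significant": bool(rng.random() < 0.5)}
                for _ in range(n)
            ]
        )
        proteins = pd.Series(rng.integers(0, 50, size=n).astype(str), index=res.index)
        out = di.classify_protein_phospho(res, proteins)
        assert len(out) == proteins.nunique()
        assert set(out["class"]) <= {"hyper", "hypo", "biphasic", "unchanged"}
        biph = out["class"] == "biphasic"
        assert ((out.loc[biph, "n_sites_up"] >= 1) & (out.loc[biph, "n_sites_down"] >= 1)).all()


class TestConditionSpecific:
    def test_planted_treated_only_features_recovered_exactly(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(25, 1, size=(30, 6))
        treated_only = {0, 3, 7}
        for i in treated_only:
            vals[i, :3] = np.nan
            vals[i, 3:] = 28.0 + rng.normal(0, 0.1, size=3)
        raw = _matrix(vals.copy())
        imputed = di.impute_downshifted_normal(raw, width=0.3, downshift=2.4, seed=2)
        out = di.detect_condition_specific(raw, imputed, p_threshold=0.05)
        assert set(out["feature"]) == {f"f{i+1}" for i in treated_only}
        assert (out["direction"] == "treated-only").all()

    def test_features_valid_in_both_groups_are_never_reported(self, rng):
        vals = rng.normal(25, 1, size=(20, 6))
        raw = _matrix(vals)
        out = di.detect_condition_specific(raw, raw, p_threshold=1.0)
        assert out.empty
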