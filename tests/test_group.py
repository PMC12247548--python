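import numpy as np
import pytest
from scipy import stats

from cardiocohere import (ConditionContrast, bonferroni, cluster_correct,
                          contrast_table, paired_t)
from cardiocohere.coherence import CoherenceRecord


class TestPairedT:
    def test_symmetric_differences_give_zero(self):
        t, df, p, d = paired_t([1, -1, 2, -2])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        t, df, p, d = paired_t([2, 4, 6])
        assert t == pytest.approx(4 / (2 / np.sqrt(3)), abs=1e-4)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert df == 2
        assert d == pytest.approx(2.0, abs=1e-12)

    def test_df_is_n_minus_one(self, rng):
        t, df, p, d = paired_t(rng.normal(size=29))
        assert df == 28

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            diffs = rng.normal(0.2, 1.0, rng.integers(3, 40))
            t, df, p, d = paired_t(diffs)
            t_ref, p_ref = stats.ttest_rel(diffs, np.zeros_like(diffs))
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 1.0, 1.0])

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 3"):
            paired_t([1.0, 2.0])


class TestBonferroni:
    def test_hypothesis_family_of_five(self):
        assert bonferroni(5) == pytest.approx(0.01, abs=1e-15)

    def test_exploratory_family_of_55(self):
        a = bonferroni(55)
        assert np.trunc(a * 1e4) / 1e4 == pytest.approx(0.0009)
        assert a == pytest.approx(0.05 / 55)

    def test_family_of_one(self):
        assert bonferroni(1) == 0.05


def _records(values_by_subject_condition, target="amygdala_R-dmPFC",
             measure="bivariate_z"):
    recs = []
    for subject, conds in values_by_subject_condition.items():
        for cond, value in conds.items():
            recs.append(CoherenceRecord(subject, cond, target, measure, value))
    return recs


class TestContrastTable:
    def test_directional_effect_detected(self, rng):
        recs = []
        for s in range(29):
            sub = f"sub-{s:02d}"
            recs += _records({sub: {
                "control": 0.5 + rng.normal(0, 0.15),
                "suspense": -0.5 + rng.normal(0, 0.15)}})
        out = contrast_table(recs)
        assert len(out) == 1
        r = out[0]
        assert r.t < 0
        assert r.family == "exploratory"
        assert r.significant_corrected
        assert r.df == 28

    def test_hypothesis_family_assignment(self, rng):
        recs = []
        for s in range(10):
            sub = f"sub-{s:02d}"
            for target in ("amygdala_R", "vmPFC", "amygdala_R-dmPFC"):
                recs += _records(
                    {sub: {"control": rng.normal(), "suspense": rng.normal()}},
                    target=target)
        out = {r.target: r for r in contrast_table(recs)}
        assert out["amygdala_R"].family == "hypothesis"
        assert out["vmPFC"].family == "exploratory"
        assert out["amygdala_R-dmPFC"].family == "exploratory"
        # exploratory alpha uses the full roi+edge target count
        assert out["vmPFC"].alpha_corrected == pytest.approx(0.05 / 3)

    def test_listwise_exclusion_of_incomplete_subjects(self, rng):
        recs = []
        for s in range(8):
            sub = f"sub-{s:02d}"
            conds = {"control": rng.normal(), "suspense": rng.normal()}
            if s == 7:
                conds.pop("suspense")
            recs += _records({sub: conds})
        out = contrast_table(recs)
        assert out[0].n_subjects == 7

    def test_zero_variance_target_excluded(self, rng):
        recs = []
        for s in range(6):
            sub = f"sub-{s:02d}"
            recs += _records({sub: {"control": 1.0, "suspense": 1.0}},
                             target="flat")
            recs += _records({sub: {"control": rng.normal(),
                                    "suspense": rng.normal()}}, target="ok")
        out = contrast_table(recs)
        assert [r.target for r in out] == ["ok"]

    def test_too_few_subjects_rejected(self, rng):
        recs = []
        for s in range(2):
            recs += _records({f"sub-{s}": {"control": rng.normal(),
                                           "suspense": rng.normal()}})
        with pytest.raises(ValueError, match="fewer than 3"):
            contrast_table(recs)


class TestConditionContrast:
    def test_fit_and_summary(self, rng):
        recs = []
        for s in range(12):
            sub = f"sub-{s:02d}"
            for target in ("dmPFC", "amygdala_R-dmPFC"):
                recs += _records({sub: {"control": rng.normal(0.3, 0.2),
                                        "suspense": rng.normal(-0.3, 0.2)}},
                                 target=target)
        res = ConditionContrast(recs).fit()
        text = res.summary()
        assert "suspense - control" in text
        assert "amygdala_R-dmPFC" in text
        mat = res.d_matrix()
        assert mat.loc["dmPFC", "dmPFC"] == pytest.approx(
            [r.cohens_d for r in res.results if r.target == "dmPFC"][0])

    def test_from_dataframe(self, rng):
        import pandas as pd
        rows = []
        for s in range(6):
            for cond in ("control", "suspense"):
                rows.append({"subject": f"s{s}", "condition": cond,
                             "target": "PAG", "measure": "bivariate_z",
                             "value": rng.normal()})
        res = ConditionContrast.from_dataframe(pd.DataFrame(rows)).fit()
        assert len(res.results) == 1


class TestClusterCorrect:
    @staticmethod
    def _null_maps(rng, n=10, shape=(8, 8, 8)):
        return rng.normal(size=(n,) + shape)

    def test_deterministic_given_seed(self, rng):
        diffs = self._null_maps(rng)
        out1 = cluster_correct(diffs, n_perms=500, seed=42)
        out2 = cluster_correct(diffs, n_perms=500, seed=42)
        assert out1[1] == out2[1]
        np.testing.assert_array_equal(out1[2], out2[2])

    def test_sign_symmetry(self, rng):
        diffs = self._null_maps(rng) + 0.8
        clusters_pos, thr_pos, _ = cluster_correct(diffs, n_perms=500, seed=1)
        clusters_neg, thr_neg, _ = cluster_correct(-diffs, n_perms=500, seed=1)
        assert sorted(c.extent for c in clusters_pos) == \
            sorted(c.extent for c in clusters_neg)

    def test_threshold_monotone_in_alpha(self, rng):
        diffs = self._null_maps(rng, n=9)
        thr = {}
        for alpha in (0.01, 0.05, 0.2):
            _, thr[alpha], _ = cluster_correct(diffs, alpha=alpha,
                                               n_perms=600, seed=5)
        assert thr[0.01] >= thr[0.05] >= thr[0.2]

    def test_threshold_monotone_in_voxel_p(self, rng):
        diffs = self._null_maps(rng, n=9)
        thr = {}
        for vp in (0.01, 0.001):
            _, thr[vp], _ = cluster_correct(diffs, voxel_p=vp, n_perms=600,
                                            seed=5)
        assert thr[0.001] <= thr[0.01]

    def test_strong_blob_recovered(self, rng):
        shape = (10, 10, 10)
        diffs = rng.normal(size=(12,) + shape)
        blob = np.zeros(shape, bool)
        blob[3:7, 3:7, 3:7] = True
        diffs[:, blob] += 3.0
        clusters, thr, _ = cluster_correct(diffs, n_perms=800, seed=9,
                                           affine=np.diag([2.5, 2.5, 2.5, 1]))
        assert clusters, "expected the injected blob to survive"
        top = clusters[0]
        peak_vox = np.array(top.peak_world_mm) / 2.5
        assert blob[tuple(np.round(peak_vox).astype(int))]
        assert top.corrected_p <= 0.05

    def test_preconditions(self, rng):
        with pytest.raises(ValueError, match="8 subjects"):
            cluster_correct(self._null_maps(rng, n=5), n_perms=500)
        with pytest.raises(ValueError, match="500"):
            cluster_correct(self._null_maps(rng, n=10), n_perms=100)
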