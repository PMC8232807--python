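"""Paired tests, Bonferroni, DiffFeatureRatio, histograms and PCA views."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mriharm.evaluate import (
    bonferroni_adjust,
    diff_feature_ratio,
    evaluate_feature_table,
    friedman_test,
    image_histogram,
    pca_components,
    wilcoxon_signed_rank,
)


def wilcoxon_exact_oracle(d):
    """Two-sided signed-rank p by full enumeration of all sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    stat_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= stat_obs - 1e-12:
            count += 1
    return count / 2.0**n


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_six_positive_differences_exact_tail(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = x - np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        assert wilcoxon_signed_rank(x, y) == pytest.approx(2.0 / 64.0, abs=1e-12)

    def test_matches_full_enumeration_at_n8(self, rng):
        """Exact p equals the brute-force enumeration over all 2^8 patterns."""
        for _ in range(20):
            d = rng.normal(0.3, 1.0, 8)
            d = np.where(d == 0, 0.1, d)
            # ensure untied |d| so the exact path is exercised
            if np.unique(np.abs(d)).size < 8:
                continue
            p_pkg = wilcoxon_signed_rank(d, np.zeros(8))
            p_oracle = wilcoxon_exact_oracle(d)
            assert p_pkg == pytest.approx(p_oracle, abs=1e-12)

    def test_too_few_nonzero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3, 4], [0, 1, 2, 3])


class TestFriedman:
    def test_identical_blocks_give_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert friedman_test([g, g, g]) == 1.0

    def test_strictly_ordered_blocks_statistic(self):
        """k=3 strictly ordered groups, n=10 -> chi2 statistic 2n = 20."""
        n = 10
        base = np.arange(n, dtype=float)
        groups = [base, base + 1.0, base + 2.0]
        p = friedman_test(groups)
        assert p == pytest.approx(float(stats.chi2.sf(20.0, df=2)), rel=1e-10)

    def test_two_groups_redirected_to_wilcoxon(self):
        with pytest.raises(ValueError, match="Wilcoxon"):
            friedman_test([[1, 2, 3, 4, 5], [2, 3, 4, 5, 6]])

    def test_agrees_with_permutation_oracle(self, rng):
        """Chi-square approximation vs exhaustive within-block permutations."""
        n, k = 6, 3
        data = rng.normal(0, 1, (n, k)) + np.array([0.0, 0.8, 1.6])
        groups = [data[:, j] for j in range(k)]
        p_pkg = friedman_test(groups)

        def statistic(d):
            ranks = np.array([stats.rankdata(row) for row in d])
            rj = ranks.sum(axis=0)
            return 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3 * n * (k + 1)

        s_obs = statistic(data)
        perms = list(itertools.permutations(range(k)))
        count = total = 0
        for combo in itertools.product(perms, repeat=n):
            d = np.array([data[i, list(combo[i])] for i in range(n)])
            total += 1
            if statistic(d) >= s_obs - 1e-12:
                count += 1
        assert p_pkg == pytest.approx(count / total, abs=0.02)


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01], 92), [0.92])
        np.testing.assert_allclose(bonferroni_adjust([0.5], 92), [1.0])
        np.testing.assert_allclose(bonferroni_adjust([0.3, 0.7], 1), [0.3, 0.7])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], 10)


class TestDiffFeatureRatio:
    def _report(self, pvals):
        return pd.DataFrame({"p_adjusted": pvals, "p_raw": pvals})

    def test_end_points_and_fraction(self):
        assert diff_feature_ratio(self._report([1.0] * 92)) == 0.0
        assert diff_feature_ratio(self._report([0.0] * 92)) == 1.0
        p = [0.001] * 23 + [0.9] * 69
        assert diff_feature_ratio(self._report(p)) == pytest.approx(23 / 92)

    def test_monotone_in_alpha(self, rng):
        p = rng.uniform(0, 1, 200)
        rep = self._report(p)
        ratios = [diff_feature_ratio(rep, alpha=a) for a in (0.01, 0.05, 0.2, 0.8)]
        assert all(a <= b for a, b in zip(ratios, ratios[1:]))


class TestImageHistogram:
    def test_counts_conserved_and_constant_region(self, small_brain_study):
        vol, rois, brain_mask = small_brain_study[0]
        counts, edges = image_histogram(vol, brain_mask)
        assert counts.sum() == brain_mask.sum()
        assert len(counts) == 512
        from mriharm.core import ImageVolume

        const = ImageVolume(np.full((6, 6, 3), 5.0), (1, 1, 1))
        c2, _ = image_histogram(const, np.ones((6, 6, 3), bool))
        assert (c2 > 0).sum() == 1

    def test_brain_histogram_brightest_mode_is_wm(self, small_brain_study):
        """T1 convention: the highest-intensity dominant mode sits at WM."""
        vol, rois, brain_mask = small_brain_study[0]
        counts, edges = image_histogram(vol, brain_mask)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # smooth lightly and find the brightest substantial mode
        k = np.ones(9) / 9.0
        sm = np.convolve(counts, k, mode="same")
        peaks = [
            i
            for i in range(1, 511)
            if sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1] and sm[i] > 0.2 * sm.max()
        ]
        wm_mean = 200.0  # ground-truth WM class mean of the generator
        assert abs(centers[peaks[-1]] - wm_mean) < 0.15 * wm_mean


class TestPCA:
    def test_rank_one_data(self, rng):
        base = rng.normal(size=50)
        X = np.outer(base, [1.0, 2.0, 3.0, 4.0])
        X += rng.normal(scale=1e-6, size=X.shape)
        df = pd.DataFrame(X, columns=["a", "b", "c", "d"])
        scores, evr = pca_components(df, k=3, feature_names=list(df.columns))
        assert evr[0] > 0.999

    def test_explained_variance_contract(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        scores, evr = pca_components(df, k=3, feature_names=list(df.columns))
        assert scores.shape == (40, 3)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1.0 + 1e-9

    def test_constant_columns_dropped_with_warning(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        df["const"] = 1.0
        with pytest.warns(UserWarning, match="const"):
            pca_components(df, k=2, feature_names=["a", "b", "c", "const"])


def test_evaluate_feature_table_pairs_and_families(rng):
    """End-to-end report on a synthetic table with one shifted feature."""
    rows = []
    for subj in range(10):
        for roi in range(6):
            for setting in ("A", "B"):
                shift = 1.0 if setting == "B" else 0.0
                rows.append(
                    {
                        "subject_id": f"s{subj}",
                        "roi_id": f"r{roi}",
                        "setting_id": setting,
                        "tissue_class": "WM",
                        "f_shifted": rng.normal(shift, 0.1),
                        "f_null": rng.normal(0.0, 1.0),
                    }
                )
    table = pd.DataFrame(rows)
    report = evaluate_feature_table(
        table, feature_names=["f_shifted", "f_null"], alpha=0.05
    )
    assert set(report["test"]) == {"wilcoxon"}
    by_feat = report.set_index("feature")
    assert by_feat.loc["f_shifted", "significant"]
    assert not by_feat.loc["f_null", "significant"]
    # Bonferroni family is the feature count
    assert by_feat.loc["f_null", "p_adjusted"] == pytest.approx(
        min(1.0, 2 * by_feat.loc["f_null", "p_raw"])
    )


def test_tube_classes_identifiable_after_harmonization():
    """Harmonization merges the per-setting subclusters while keeping the
    nine tube classes identifiable: after per-class ComBat the classes are
    perfectly linearly separable in standardized feature space, and the
    leading principal component aligns with the tube classes."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.model_selection import cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    from mriharm.features import FEATURE_NAMES
    from mriharm.pipeline import PipelineConfig, run_pipeline

    accs = {}
    feats_by_condition = {}
    for combat in ("none", "parametric"):
        cfg = PipelineConfig(
            study="homogeneous_phantom", n_subjects=1, n_slices=8, matrix=224,
            seed=3, combat=combat,
        )
        feats = run_pipeline(cfg)["features"]
        clf = make_pipeline(StandardScaler(), LinearDiscriminantAnalysis())
        accs[combat] = cross_val_score(
            clf, feats[FEATURE_NAMES].to_numpy(), feats["tissue_class"], cv=4
        ).mean()
        feats_by_condition[combat] = feats

    # biological (tube) information is fully recoverable after harmonization,
    # and harmonization improves identifiability by merging setting subclusters
    assert accs["parametric"] >= 0.95
    assert accs["parametric"] >= accs["none"]

    feats = feats_by_condition["parametric"]
    scores, evr = pca_components(feats, k=3)
    y = pd.factorize(feats["tissue_class"])[0]
    pc1 = scores[:, 0]
    within = np.mean([pc1[y == k].var() for k in np.unique(y)])
    assert 1.0 - within / pc1.var() > 0.5  # PC1 is mostly between-class
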