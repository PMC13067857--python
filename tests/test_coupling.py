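"""Reinforcing/compensatory classification and the matched permutation test."""

import numpy as np
import pandas as pd
import pytest

from ribofuse import coupling as cp
from ribofuse.simulate import simulate_fold_changes

SQRT2 = np.sqrt(2.0)


def oracle_classify(m, r, sd_mult=2.0, ratio_bound=0.5):
    """Literal, loop-based re-statement of the classification rule."""
    u = [(a + b) / SQRT2 for a, b in zip(m, r)]
    v = [(a - b) / SQRT2 for a, b in zip(m, r)]
    def sd(xs):
        mu = sum(xs) / len(xs)
        return (sum((x - mu) ** 2 for x in xs) / (len(xs) - 1)) ** 0.5
    s_u, s_v = sd(u), sd(v)
    labels = []
    for a, b, ui, vi in zip(m, r, u, v):
        if a == 0 or b == 0:
            labels.append("none")
            continue
        ratio_ok = abs(np.log10(abs(a / b))) < ratio_bound
        if np.sign(a) == np.sign(b) and abs(ui) > sd_mult * s_u and ratio_ok:
            labels.append("reinforcing")
        elif np.sign(a) != np.sign(b) and abs(vi) > sd_mult * s_v and ratio_ok:
            labels.append("compensatory")
        else:
            labels.append("none")
    return labels


def cloud_plus(extra):
    """Small background cloud at (+-0.1, +-0.1) plus one extra gene."""
    pts = [(0.1, 0.1), (-0.1, -0.1), (0.1, -0.1), (-0.1, 0.1), (0.08, 0.12), (-0.12, -0.09)]
    pts.append(extra)
    m = pd.Series([p[0] for p in pts])
    r = pd.Series([p[1] for p in pts])
    return m, r


class TestClassifyInteractions:
    def test_strong_same_sign_gene_is_reinforcing(self):
        m, r = cloud_plus((3.0, 3.0))
        fc = cp.classify_interactions(cp.FoldChangeTable(m, r))
        assert fc.classes.iloc[-1] == "reinforcing"
        assert list(fc.classes) == oracle_classify(m, r)

    def test_strong_opposite_sign_gene_is_compensatory(self):
        m, r = cloud_plus((3.0, -3.0))
        fc = cp.classify_interactions(cp.FoldChangeTable(m, r))
        assert fc.classes.iloc[-1] == "compensatory"
        assert list(fc.classes) == oracle_classify(m, r)

    def test_ratio_filter_overrides_projection(self):
        # |log10(|3 / 0.05|)| = log10(60) ~ 1.78 >= 0.5, so never classified
        m, r = cloud_plus((3.0, 0.05))
        fc = cp.classify_interactions(cp.FoldChangeTable(m, r))
        assert fc.classes.iloc[-1] == "none"

    def test_zero_fold_change_is_none(self):
        m, r = cloud_plus((3.0, 0.0))
        fc = cp.classify_interactions(cp.FoldChangeTable(m, r))
        assert fc.classes.iloc[-1] == "none"

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(4)
        m = pd.Series(rng.normal(0, 1, 100))
        r = pd.Series(rng.normal(0, 1, 100))
        fc = cp.classify_interactions(cp.FoldChangeTable(m, r))
        assert list(fc.classes) == oracle_classify(list(m), list(r))

    def test_negating_both_preserves_labels(self):
        m, r, _ = simulate_fold_changes(200, 10, 10, seed=0)
        a = cp.classify_interactions(cp.FoldChangeTable(pd.Series(m), pd.Series(r)))
        b = cp.classify_interactions(cp.FoldChangeTable(pd.Series(-m), pd.Series(-r)))
        assert (a.classes == b.classes).all()

    def test_negating_rpf_swaps_categories(self):
        m, r, _ = simulate_fold_changes(200, 10, 10, seed=0)
        a = cp.classify_interactions(cp.FoldChangeTable(pd.Series(m), pd.Series(r)))
        b = cp.classify_interactions(cp.FoldChangeTable(pd.Series(m), pd.Series(-r)))
        swapped = a.classes.map(
            {"reinforcing": "compensatory", "compensatory": "reinforcing", "none": "none"}
        )
        assert (b.classes == swapped).all()

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            cp.classify_interactions(
                cp.FoldChangeTable(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))
            )


class TestBreedLog2FC:
    def _tpm(self):
        cols = [f"liver_{b}_{r}_RNA" for b in "AB" for r in (1, 2, 3)]
        samples = pd.DataFrame(
            [(c, "liver", c.split("_")[1], int(c.split("_")[2]), "RNA") for c in cols],
            columns=["sample_id", "tissue", "breed", "replicate", "modality"],
        )
        vals = pd.DataFrame(
            [[3.0] * 3 + [1.0] * 3, [5.0] * 6], columns=cols, index=["g1", "g2"]
        )
        return vals, samples

    def test_hand_values_and_antisymmetry(self):
        vals, samples = self._tpm()
        fc = cp.breed_log2fc(vals, samples, "liver", "RNA", ("A", "B"))
        assert fc["g1"] == pytest.approx(1.0)  # log2(4/2)
        assert fc["g2"] == pytest.approx(0.0)
        rev = cp.breed_log2fc(vals, samples, "liver", "RNA", ("B", "A"))
        np.testing.assert_allclose(fc, -rev)

    def test_missing_breed_errors(self):
        vals, samples = self._tpm()
        with pytest.raises(ValueError, match="no samples"):
            cp.breed_log2fc(vals, samples, "liver", "RNA", ("A", "C"))


class TestMatchedPermutation:
    def test_moments_matched_exactly(self):
        rng = np.random.default_rng(1)
        m = rng.normal(0, 1, 300)
        r = 0.6 * m + rng.normal(0, 0.8, 300)
        mu_r, sigma_r = r.mean(), r.std(ddof=1)
        rho = np.corrcoef(m, r)[0, 1]
        for perm_seed in range(5):
            p = r[cp._derangement(300, np.random.default_rng(perm_seed))]
            r_star = cp.match_moments(p, m, mu_r, sigma_r, rho)
            assert abs(r_star.mean() - mu_r) < 1e-9
            assert abs(r_star.std(ddof=1) - sigma_r) < 1e-9
            assert abs(np.corrcoef(m, r_star)[0, 1] - rho) < 1e-9

    def test_derangement_has_no_fixed_points(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 5, 50):
            for _ in range(20):
                perm = cp._derangement(n, rng)
                assert not np.any(perm == np.arange(n))
                assert sorted(perm) == list(range(n))

    def test_p_value_bounds(self):
        m, r, _ = simulate_fold_changes(300, 20, 20, seed=2)
        res = cp.matched_permutation(m, r, B=99, seed=0)
        for cat in ("reinforcing", "compensatory"):
            assert 1 / 100 <= res.p[cat] <= 1.0

    def test_strong_planting_gives_minimal_p(self):
        m, r, _ = simulate_fold_changes(1000, 60, 60, effect=2.0, sd=0.5, seed=3)
        res = cp.matched_permutation(m, r, B=199, seed=1)
        assert res.p["reinforcing"] == pytest.approx(1 / 200)
        assert res.p["compensatory"] == pytest.approx(1 / 200)

    def test_degenerate_correlation_errors(self):
        m = np.arange(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            cp.matched_permutation(m, 2 * m, B=10, seed=0)

    def test_null_calibration(self):
        """Type-I error of the permutation test at alpha=0.01 stays within
        3 binomial SEs under bivariate-normal null data."""
        alpha, n_datasets, B = 0.01, 120, 150
        rejections = trials = 0
        for ds in range(n_datasets):
            m, r, _ = simulate_fold_changes(250, 0, 0, sd=0.5, correlation=0.6, seed=1000 + ds)
            res = cp.matched_permutation(m, r, B=B, seed=ds, alpha=alpha)
            for cat in ("reinforcing", "compensatory"):
                trials += 1
                rejections += res.p[cat] < alpha
        rate = rejections / trials
        se = np.sqrt(alpha * (1 - alpha) / trials)
        assert rate <= alpha + 3 * se


class TestPlantedRecovery:
    def test_classifier_recovers_planted_labels(self):
        """At effect 2 over a 0.5-sd background, at least 90% of planted
        genes receive their planted label."""
        m, r, labels = simulate_fold_changes(2000, 100, 100, effect=2.0, sd=0.5, seed=5)
        fc = cp.classify_interactions(cp.FoldChangeTable(pd.Series(m), pd.Series(r)))
        got = fc.classes.to_numpy()
        for cls in ("reinforcing", "compensatory"):
            planted = labels == cls
            assert (got[planted] == cls).mean() >= 0.9


class TestProteinIntegration:
    def test_reinforcing_genes_show_larger_protein_shifts(self, small_dataset):
        """Protein follows translational output, and buffering attenuates the
        RPF response, so reinforcing genes shift protein more than
        compensatory genes."""
        expr, truth, cfg = (
            small_dataset["expr"],
            small_dataset["truth"],
            small_dataset["config"],
        )
        prot = expr.protein  # already log2 scale
        samples = expr.protein_samples.set_index("sample_id")
        tissue = cfg.tissues[0]
        cols_a = samples.index[(samples["tissue"] == tissue) & (samples["breed"] == "A")]
        cols_b = samples.index[(samples["tissue"] == tissue) & (samples["breed"] == "B")]
        protein_fc = prot[cols_a].mean(axis=1) - prot[cols_b].mean(axis=1)
        classes = pd.Series(truth.gene_class).replace("background", "none")
        m = pd.Series(
            {g: truth.class_sign.get(g, 0) * cfg.interaction_effect for g in classes.index}
        )
        table = cp.protein_divergence_by_class(protein_fc, classes, m)
        assert (
            table.loc["reinforcing", "mean_abs_fc"] > table.loc["compensatory", "mean_abs_fc"]
        )

    def test_breed_relabeling_flips_direction_not_magnitude(self):
        m, r, labels = simulate_fold_changes(200, 20, 20, seed=9)
        classes = pd.Series(labels).replace("background", "none")
        pfc = pd.Series(r)
        a = cp.protein_divergence_by_class(pfc, classes, pd.Series(m))
        b = cp.protein_divergence_by_class(-pfc, classes, pd.Series(-m))
        np.testing.assert_allclose(a["mean_abs_fc"], b["mean_abs_fc"])
        assert a.loc["reinforcing", "n_up"] == b.loc["reinforcing", "n_down"]

    def test_zero_protein_fcs_give_zero_difference(self):
        m, r, labels = simulate_fold_changes(200, 20, 20, seed=10)
        classes = pd.Series(labels).replace("background", "none")
        table = cp.protein_divergence_by_class(pd.Series(np.zeros(len(m))), classes, pd.Series(m))
        assert table["mean_abs_fc"].fillna(0).eq(0).all()


class TestRatioGroups:
    @pytest.mark.parametrize(
        "ratio, group", [(2.0, ">1.5"), (0.5, "<1/1.5"), (1.0, "other")]
    )
    def test_group_assignment(self, ratio, group):
        protein = pd.Series([ratio], index=["g"])
        mrna = pd.Series([1.0], index=["g"])
        te = pd.Series([1.0], index=["g"])
        labels, _ = cp.te_fc_by_ratio_group(protein, mrna, te)
        assert labels["g"] == group

    def test_zero_mrna_fc_is_excluded(self):
        labels, _ = cp.te_fc_by_ratio_group(
            pd.Series([1.0], index=["g"]), pd.Series([0.0], index=["g"]),
            pd.Series([1.0], index=["g"]),
        )
        assert "g" not in labels.index
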