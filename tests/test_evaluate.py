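import numpy as np
import pytest

from vcore.encoder import AttentionRecord
from vcore.evaluate import (
    AgreementTable,
    abmil_heat_rasters,
    attention_rollout,
    classification_metrics,
    mcnemar_test,
    overlay_heatmaps,
    quadratic_weighted_kappa,
)


def _make_record(rng, n, f, a=2, uniform=False):
    """Random (or uniform) row-stochastic attention record."""

    def rows(shape):
        if uniform:
            return np.full(shape, 1.0 / shape[-1])
        x = rng.random(shape) + 0.1
        return x / x.sum(axis=-1, keepdims=True)

    return AttentionRecord(
        alpha_time=rows((a, n, f, f + 1)),
        alpha_space=rows((a, f, n, n + 1)),
        alpha_cls=rows((a, 1 + n * f)),
        n_spatial=n,
        depth=f,
    )


class TestRollout:
    def test_uniform_attention_gives_uniform_rollout(self, rng):
        rec = _make_record(rng, n=4, f=2, uniform=True)
        roll = attention_rollout([rec], residual_alpha=0.0)
        np.testing.assert_allclose(roll.cumulative, 1.0 / 8, atol=1e-12)

    def test_single_block_equals_hand_product(self, rng):
        """W[i,j,p,q] = S[i,j,p] * T[p,j,q], literal equation at alpha=0."""
        n, f = 2, 2
        rec = _make_record(rng, n=n, f=f, a=1)
        roll = attention_rollout([rec], residual_alpha=0.0)
        s = rec.alpha_space[0][..., 1:]
        s = (s / s.sum(-1, keepdims=True)).transpose(1, 0, 2)  # S[i, j, p]
        t = rec.alpha_time[0][..., 1:]
        t = t / t.sum(-1, keepdims=True)  # T[p, j, q]
        w = roll.w(0)
        for i in range(n):
            for j in range(f):
                for p in range(n):
                    for q in range(f):
                        assert w[i, j, p, q] == pytest.approx(
                            s[i, j, p] * t[p, j, q], abs=1e-12
                        )

    @pytest.mark.parametrize("n_blocks", [1, 2, 3])
    @pytest.mark.parametrize("alpha", [0.0, 0.5])
    def test_conservation(self, rng, n_blocks, alpha):
        recs = [_make_record(rng, n=4, f=3) for _ in range(n_blocks)]
        roll = attention_rollout(recs, residual_alpha=alpha)
        np.testing.assert_allclose(roll.cumulative.sum(axis=1), 1.0, atol=1e-6)
        for b in roll.per_block:
            np.testing.assert_allclose(b.sum(axis=1), 1.0, atol=1e-6)

    def test_mismatched_records_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_rollout(
                [_make_record(rng, 4, 2), _make_record(rng, 4, 3)]
            )
        with pytest.raises(ValueError):
            attention_rollout([])

    def test_cls_heat_shape(self, rng):
        roll = attention_rollout([_make_record(rng, n=4, f=4)])
        assert roll.cls_heat.shape == (4, 2, 2)
        assert roll.cls_heat.sum() == pytest.approx(1.0)


class TestOverlay:
    def test_uniform_weights_give_uniform_heat(self):
        sections = [np.full((32, 32, 3), 255, dtype=np.uint8)] * 2
        out = overlay_heatmaps(sections, np.full((4, 4), 0.5))
        assert len(out) == 2
        assert np.ptp(out[0]) < 1e-9  # constant blend everywhere

    def test_single_hot_patch_footprint(self):
        heats = abmil_heat_rasters(
            (64, 64), origins=[(0, 0), (32, 32)], weights=np.array([0.0, 1.0]),
            patch_size=32, n_sections=3,
        )
        assert len(heats) == 3
        assert heats[0][:32, :32].max() == 0.0
        assert heats[0][32:, 32:].min() == 1.0

    def test_unknown_origin_rejected(self):
        with pytest.raises(ValueError):
            abmil_heat_rasters((64, 64), [(50, 50)], np.array([1.0]),
                               patch_size=32, n_sections=1)

    def test_depth_resolved_rollout_heat(self, rng):
        sections = [np.zeros((16, 16, 3)) for _ in range(4)]
        heat = rng.random((4, 2, 2))
        out = overlay_heatmaps(sections, list(heat))
        assert len(out) == 4


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[y]
        m = classification_metrics(y, probs)
        for key in ("macro_auc", "weighted_precision", "weighted_recall",
                    "weighted_f1"):
            assert m[key] == pytest.approx(1.0)

    def test_separable_scores_give_unit_auc(self):
        y = np.array([0, 0, 1, 1])
        p_a = np.array([0.9, 0.8, 0.4, 0.1])
        probs = np.stack([p_a, 1 - p_a], axis=1)
        assert classification_metrics(y, probs)["macro_auc"] == pytest.approx(1.0)

    def test_binary_confusion_arithmetic(self):
        """TP=3, FP=1, FN=1, TN=5 gives precision=recall=F1=0.75."""
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        probs = np.stack([1.0 - pred, pred.astype(float)], axis=1)
        m = classification_metrics(y, probs)
        conf = m["confusion"]
        assert conf[1, 1] == 3 and conf[0, 1] == 1 and conf[1, 0] == 1
        from sklearn.metrics import precision_score

        assert precision_score(y, pred) == pytest.approx(0.75)
        # weighted metrics cross-checked against the hand-counted table
        prec1, rec1 = 3 / 4, 3 / 4
        prec0, rec0 = 5 / 6, 5 / 6
        assert m["weighted_precision"] == pytest.approx(
            (4 * prec1 + 6 * prec0) / 10
        )
        assert m["weighted_recall"] == pytest.approx((4 * rec1 + 6 * rec0) / 10)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1, 1])
        probs = np.full((4, 3), 1 / 3)
        probs[:2, 0] = 0.5
        probs[2:, 1] = 0.5
        probs /= probs.sum(1, keepdims=True)
        with pytest.warns(UserWarning, match="absent"):
            m = classification_metrics(y, probs)
        assert np.isfinite(m["macro_auc"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.zeros(4, dtype=int), np.ones((4, 2)) / 2)


class TestKappa:
    def test_perfect_agreement(self):
        assert quadratic_weighted_kappa(np.diag([3, 4, 5])) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        row = np.array([2.0, 3.0])
        col = np.array([4.0, 1.0])
        table = np.outer(row, col) / 5.0
        assert quadratic_weighted_kappa(table) == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_against_cell_enumeration(self):
        o = np.array([[2.0, 1.0], [1.0, 2.0]])
        # brute force over the 4 cells
        k = 2
        w = np.array([[(i - j) ** 2 / (k - 1) ** 2 for j in range(k)]
                      for i in range(k)])
        e = np.outer(o.sum(1), o.sum(0)) / o.sum()
        expected = 1 - (w * o).sum() / (w * e).sum()
        assert quadratic_weighted_kappa(o) == pytest.approx(expected)
        assert expected == pytest.approx(1 - 2 / 3)  # hand arithmetic

    def test_transpose_and_relabel_invariance(self, rng):
        o = rng.integers(0, 10, size=(4, 4)).astype(float)
        o += np.diag([5, 5, 5, 5])
        k1 = quadratic_weighted_kappa(o)
        assert quadratic_weighted_kappa(o.T) == pytest.approx(k1)
        assert quadratic_weighted_kappa(o[::-1, ::-1]) == pytest.approx(k1)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        r1 = rng.integers(0, 4, size=200)
        r2 = np.clip(r1 + rng.integers(-1, 2, size=200), 0, 3)
        table = np.zeros((4, 4))
        np.add.at(table, (r1, r2), 1)
        assert quadratic_weighted_kappa(table) == pytest.approx(
            cohen_kappa_score(r1, r2, weights="quadratic")
        )

    def test_degenerate_marginal_signaled(self):
        with pytest.raises(ValueError, match="undefined|concentrated"):
            quadratic_weighted_kappa(np.array([[4.0, 0.0], [0.0, 0.0]]))


class TestMcNemar:
    def test_symmetric_discordance_not_significant(self):
        a = np.r_[np.ones(5), np.zeros(5), np.ones(10)].astype(bool)
        b = np.r_[np.zeros(5), np.ones(5), np.ones(10)].astype(bool)
        res = mcnemar_test(a, b)
        assert res["b"] == 5 and res["c"] == 5
        assert res["p_value"] > 0.99

    def test_chi2_branch_statistic(self):
        a = np.r_[np.ones(10), np.zeros(2), np.ones(5)].astype(bool)
        b = np.r_[np.zeros(10), np.ones(2), np.ones(5)].astype(bool)
        res = mcnemar_test(a, b, force_chi2=True)
        assert res["statistic"] == pytest.approx(49 / 12)

    def test_exact_small_sample(self):
        a = np.array([1, 1, 1, 1], dtype=bool)
        b = np.array([0, 0, 0, 1], dtype=bool)
        res = mcnemar_test(a, b)
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(0.25)  # 2 * (1/2)^3

    def test_degenerate_case(self):
        a = np.ones(6, dtype=bool)
        res = mcnemar_test(a, a)
        assert res["degenerate"] and res["p_value"] == 1.0

    def test_branches_agree_near_threshold(self):
        """Balanced b=13, c=12 at the b+c=25 switch point: exact and
        chi-square p-values agree within 0.02."""
        a = np.r_[np.ones(13), np.zeros(12)].astype(bool)
        b = np.r_[np.zeros(13), np.ones(12)].astype(bool)
        p_chi = mcnemar_test(a, b)["p_value"]  # b+c=25 -> chi2 branch
        from scipy.stats import binomtest

        p_exact = binomtest(13, 25, 0.5).pvalue
        assert abs(p_chi - p_exact) < 0.02

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        a = np.r_[np.ones(30), np.zeros(10), np.ones(20)].astype(bool)
        b = np.r_[np.zeros(30), np.ones(10), np.ones(20)].astype(bool)
        res = mcnemar_test(a, b)
        sm = sm_mcnemar(np.array([[20, 30], [10, 0]]), exact=False,
                        correction=True)
        assert res["statistic"] == pytest.approx(sm.statistic)
        assert res["p_value"] == pytest.approx(sm.pvalue)


def test_agreement_table_validation():
    with pytest.raises(ValueError):
        AgreementTable(np.ones((2, 3)))
    with pytest.raises(ValueError):
        AgreementTable(np.array([[1.0, -1.0], [0.0, 1.0]]))
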