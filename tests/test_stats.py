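"""Normality gate, group tests, BH, volcano rule, and ROC/Youden."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from evpanel.exceptions import ConfigurationError, InsufficientDataError
from evpanel.matrix import ExpressionMatrix, GROUP_BASELINE, GROUP_HC
from evpanel.stats import (
    adjust_bh,
    empirical_auc,
    normality_gate,
    roc_with_youden,
    three_group_test,
    two_group_test,
    volcano_classify,
    DifferentialResult,
)


def _two_group_matrix(a: np.ndarray, b: np.ndarray, proteins=None):
    """Stack two (n x p) group blocks into an HC / PT_BE matrix."""
    p = a.shape[1]
    proteins = proteins or [f"P{j:02d}" for j in range(p)]
    vals = pd.DataFrame(np.vstack([a, b]),
                        index=[f"s{i}" for i in range(len(a) + len(b))],
                        columns=proteins)
    groups = [GROUP_HC] * len(a) + [GROUP_BASELINE] * len(b)
    return ExpressionMatrix(
        values=vals,
        sample_group=pd.Series(groups, index=vals.index),
        subject_id=pd.Series(vals.index, index=vals.index),
    )


class TestNormalityGate:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(0).normal(size=100)
        assert normality_gate(x) is True

    def test_exponential_sample_fails(self):
        x = np.random.default_rng(0).exponential(size=100)
        assert normality_gate(x) is False

    def test_constant_vector_is_not_gaussian(self):
        assert normality_gate(np.ones(10)) is False

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0])


class TestAdjustBH:
    def test_stepup_worked_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.04])[0] == pytest.approx(0.04)

    def test_all_equal_stay_equal(self):
        q = adjust_bh([0.2] * 5)
        assert np.allclose(q, 0.2)

    def test_out_of_range_rejected(self):
        from evpanel.exceptions import DataIntegrityError
        with pytest.raises(DataIntegrityError):
            adjust_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_sorted_q_nondecreasing_and_bounded(self, p):
        q = adjust_bh(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestTwoGroupTest:
    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(30, 3))
        b = a + np.array([2.0, 0.0, 0.0]) + rng.normal(0, 0.1, size=(30, 3))
        res = {r.protein_id: r for r in two_group_test(_two_group_matrix(a, b),
                                                       GROUP_HC, GROUP_BASELINE)}
        hit = res["P00"]
        assert hit.q_bh < 0.05 and hit.direction == "up"
        assert hit.delta_npx == pytest.approx(2.0, abs=0.15)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rates = []
        for _ in range(10):
            a = rng.normal(size=(25, 40))
            b = rng.normal(size=(25, 40))
            res = two_group_test(_two_group_matrix(a, b), GROUP_HC, GROUP_BASELINE)
            rates.append(np.mean([r.p_raw < 0.05 for r in res]))
        assert np.mean(rates) < 0.12

    def test_swapped_groups_negate_delta(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(15, 4))
        b = rng.normal(0.5, 1, size=(15, 4))
        m = _two_group_matrix(a, b)
        fwd = two_group_test(m, GROUP_HC, GROUP_BASELINE)
        rev = two_group_test(m, GROUP_BASELINE, GROUP_HC)
        for f, r in zip(fwd, rev):
            assert f.delta_npx == pytest.approx(-r.delta_npx)
            assert f.p_raw == pytest.approx(r.p_raw, rel=1e-6)

    def test_degenerate_protein_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(10, 2))
        b = rng.normal(size=(10, 2))
        b[:, 1] = np.nan
        with pytest.warns(UserWarning, match="P01"):
            res = two_group_test(_two_group_matrix(a, b), GROUP_HC, GROUP_BASELINE)
        assert [r.protein_id for r in res] == ["P00"]

    def test_empty_group_is_configuration_error(self):
        rng = np.random.default_rng(5)
        m = _two_group_matrix(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        with pytest.raises(ConfigurationError):
            two_group_test(m, GROUP_HC, "PT_FU")


class TestThreeGroupTest:
    def _three_group(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(rng.normal(size=(30, 5)),
                            index=[f"s{i}" for i in range(30)],
                            columns=[f"P{j}" for j in range(5)])
        groups = ["HC"] * 10 + ["PT_BE"] * 10 + ["PT_FU"] * 10
        vals.iloc[10:20, 0] += shift
        subj = [f"h{i}" for i in range(10)] + [f"p{i}" for i in range(10)] * 2
        return ExpressionMatrix(values=vals,
                                sample_group=pd.Series(groups, index=vals.index),
                                subject_id=pd.Series(subj, index=vals.index))

    def test_shifted_group_detected(self):
        res = {r.protein_id: r for r in three_group_test(self._three_group(shift=3.0))}
        assert res["P0"].q_bh < 0.05

    def test_null_roughly_uniform(self):
        rates = []
        for seed in range(10):
            res = three_group_test(self._three_group(seed=seed))
            rates.append(np.mean([r.p_raw < 0.05 for r in res]))
        assert np.mean(rates) < 0.2

    def test_two_groups_rejected(self):
        rng = np.random.default_rng(0)
        m = _two_group_matrix(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)))
        with pytest.raises(ConfigurationError):
            three_group_test(m)


class TestVolcano:
    @pytest.mark.parametrize(
        "q,delta,expected",
        [
            (0.01, 1.5, "up"),
            (0.01, 1.0, "ns"),  # strict > on the fold-change bound
            (0.06, 3.0, "ns"),
            (0.01, -1.2, "down"),
            (0.049, 1.001, "up"),
        ],
    )
    def test_rule(self, q, delta, expected):
        r = DifferentialResult(protein_id="P", delta_npx=delta, statistic=0.0,
                               p_raw=q, q_bh=q)
        assert volcano_classify([r])[0].direction == expected

    def test_log2_unit_threshold_is_twofold_linear(self):
        # the 1-NPX volcano bound corresponds to exactly a 2x linear change
        assert 2.0 ** 1.0 == 2.0


class TestRoc:
    def test_bruteforce_example(self):
        r = roc_with_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 2 < r.youden_threshold <= 3
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_perfect_separation(self):
        r = roc_with_youden([0, 0, 0, 5, 5, 5], [0, 0, 0, 1, 1, 1])
        assert (r.auc, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        r = roc_with_youden(rng.normal(size=2000), rng.integers(0, 2, 2000))
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=50)
        y = (s + rng.normal(0, 1, 50) > 0).astype(int)
        a1 = roc_with_youden(s, y).auc
        a2 = roc_with_youden(np.exp(3 * s), y).auc
        assert a1 == pytest.approx(a2)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=60)
        y = (s + rng.normal(0, 2, 60) > 0).astype(int)
        r = roc_with_youden(s, y)
        assert r.auc_ci_low <= r.auc <= r.auc_ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_with_youden([1, 2, 3], [1, 1, 1])

    @pytest.mark.parametrize("seed", range(3))
    def test_fast_auc_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=80)
        s[rng.random(80) < 0.3] = 0.0  # inject ties
        y = rng.integers(0, 2, 80)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert empirical_auc(y, s) == pytest.approx(roc_auc_score(y, s))
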