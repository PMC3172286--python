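"""Welch t-test, Benjamini-Hochberg FDR, and per-timepoint DE calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from marrownet.diffexpr import bh_fdr, call_differential, welch_t
from tests.conftest import matrix_from_log2


def textbook_welch(a, b):
    """Independent implementation straight from the formulas: unequal
    variance t with Welch-Satterthwaite degrees of freedom."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * tdist.sf(abs(t), df)


class TestWelchT:
    def test_identical_groups_give_p_one(self):
        t, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_degenerate_variance_conventions(self):
        _, p_equal = welch_t([5, 5, 5], [5, 5, 5])
        assert p_equal == 1.0
        _, p_diff = welch_t([0, 0, 0], [1, 1, 1])
        assert p_diff == 0.0

    def test_matches_textbook_formula(self):
        a, b = [10, 11, 12, 13], [8, 8.5, 9, 9.5]
        t, p = welch_t(a, b)
        t_ref, p_ref = textbook_welch(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            welch_t([1.0], [1, 2, 3])


class TestBhFdr:
    def test_step_up_by_hand(self):
        q = bh_fdr(np.array([0.005, 0.02, 0.04]))
        assert np.allclose(q, [0.015, 0.03, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr(np.ones(5)), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p_list, rnd):
        p = np.array(p_list)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), bruteforce_bh(p), atol=1e-12)


def bruteforce_bh(p):
    """Literal step-up definition: at sorted position i (1-based),
    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(pos, m + 1)), 1.0
        )
    return np.array(q)


class TestCallDifferential:
    def test_planted_twofold_gene_fold_change(self):
        rng = np.random.default_rng(5)
        n_rep = 4
        log2 = np.full((10, 5 * n_rep), 8.0) + rng.normal(0, 0.1, (10, 5 * n_rep))
        log2[0, n_rep:] += 1.0  # up 2-fold at every post-baseline timepoint
        matrix = matrix_from_log2(log2, [f"G{i}" for i in range(10)], n_rep)
        result = call_differential(matrix)
        lfc = result.table.loc[result.table.gene == "G0", "log2_fold_change"]
        assert np.all(np.abs(lfc - 1.0) < 0.2)
        assert result.significant_any["G0"]

    def test_constant_gene_not_significant(self):
        log2 = np.vstack([np.full(20, 8.0), np.random.default_rng(0).normal(8, 1, 20)])
        matrix = matrix_from_log2(log2, ["FLAT", "NOISY"], 4)
        result = call_differential(matrix)
        assert not result.significant_any["FLAT"]
        flat_rows = result.table[result.table.gene == "FLAT"]
        assert (flat_rows.p_value == 1.0).all()

    def test_single_baseline_replicate_rejected(self):
        # 1 baseline chip and 2 chips at each later timepoint
        log2 = np.random.default_rng(1).normal(8, 1, (5, 9))
        import pandas as pd
        from marrownet.io import ExpressionMatrix
        cols = ["t0_r1"] + [f"t{t}_r{r}" for t in (3, 7, 11, 21) for r in (1, 2)]
        values = pd.DataFrame(2.0 ** log2, index=[f"G{i}" for i in range(5)], columns=cols)
        samples = pd.DataFrame(
            {
                "timepoint_days": [0] + [t for t in (3, 7, 11, 21) for _ in (1, 2)],
                "replicate": [1] + [r for _ in (3, 7, 11, 21) for r in (1, 2)],
                "group": ["baseline"] + ["irradiated"] * 8,
            },
            index=pd.Index(cols, name="sample_id"),
        )
        with pytest.raises(ValueError, match="baseline"):
            call_differential(ExpressionMatrix(values, samples))

    def test_pooled_baseline_uses_all_sham_chips(self):
        # sham chips hybridized alongside each timepoint, marked baseline in
        # the sidecar; pooling makes the t-test well-posed
        import pandas as pd
        from marrownet.io import ExpressionMatrix
        rng = np.random.default_rng(2)
        cols, tps, groups = [], [], []
        for t in (0, 3, 7, 11, 21):
            cols += [f"s{t}", f"a{t}", f"b{t}"]
            tps += [t, t, t]
            groups += ["baseline", "irradiated", "irradiated"] if t else ["baseline"] * 3
        values = pd.DataFrame(2.0 ** rng.normal(8, 0.5, (4, len(cols))),
                              index=[f"G{i}" for i in range(4)], columns=cols)
        samples = pd.DataFrame({"timepoint_days": tps,
                                "replicate": [1, 2, 3] * 5,
                                "group": groups},
                               index=pd.Index(cols, name="sample_id"))
        matrix = ExpressionMatrix(values, samples)
        result = call_differential(matrix, baseline_pooled=True)
        assert set(result.table.timepoint_days) == {3, 7, 11, 21}

    def test_equal_var_flag_matches_student_t(self):
        from scipy.stats import ttest_ind
        rng = np.random.default_rng(3)
        log2 = rng.normal(8, 0.5, (6, 20))
        matrix = matrix_from_log2(log2, [f"G{i}" for i in range(6)], 4)
        result = call_differential(matrix, equal_var=True)
        row = result.table[(result.table.gene == "G0") & (result.table.timepoint_days == 3)]
        expected = ttest_ind(log2[0, 4:8], log2[0, :4], equal_var=True).pvalue
        assert row.p_value.iloc[0] == pytest.approx(expected)

    def test_recall_improves_with_effect_size(self):
        """Monotonicity: larger planted effects never reduce recall."""
        from marrownet.simulate import SimConfig, simulate_timecourse
        recalls = []
        for effect in (0.25, 1.0):
            rec = []
            for seed in range(3):
                cfg = SimConfig(n_genes=200, n_de=40, n_modules=0, effect_log2=effect,
                                seed=seed)
                matrix, truth = simulate_timecourse(cfg)
                called = set(call_differential(matrix).significant_genes())
                rec.append(len(called & truth.de_genes) / len(truth.de_genes))
            recalls.append(np.mean(rec))
        assert recalls[1] >= recalls[0]
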