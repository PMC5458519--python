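import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from splicemod import differential as de
from splicemod.formats_io import AnnotationModel, Transcript


# ---------------------------------------------------------------------------
# variance-prior estimation
# ---------------------------------------------------------------------------


def _variance_fixture():
    """30 pooled variances on df=10; expected hyper-parameters frozen from an
    independent empirical-Bayes reference fit on the identical numbers."""
    rng = np.random.default_rng(20260927)
    return rng.chisquare(10, 30) / 10 * np.exp(rng.normal(0, 0.5, 30))


def _matrix_fixture():
    """40 events x 12 samples with heterogeneous per-event variance; the
    expected moderated statistics are frozen from the same reference fit."""
    rng = np.random.default_rng(777)
    sd = 0.05 * np.sqrt(rng.chisquare(3, 40) / 3)
    m = rng.normal(0.5, sd[:, None], (40, 12))
    m[:8, 6:] += 0.1
    return m


class TestEstimatePrior:
    def test_matches_reference_moment_fit(self):
        prior = de.estimate_prior(_variance_fixture(), 10)
        assert prior.s0_sq == pytest.approx(0.787509662554, rel=1e-9)
        assert prior.d0 == pytest.approx(12.0899220851, rel=1e-8)

    def test_posterior_variances_match_reference(self):
        s2 = _variance_fixture()
        prior = de.estimate_prior(s2, 10)
        post = (prior.d0 * prior.s0_sq + 10 * s2) / (prior.d0 + 10)
        expected = [0.538015283303, 0.566002958077, 0.818154730891, 0.529969768284, 0.685949221855]
        np.testing.assert_allclose(post[:5], expected, rtol=1e-9)

    def test_identical_variances_give_infinite_prior_df(self):
        prior = de.estimate_prior([2.0] * 10, 10)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(2.0)

    def test_near_identical_variances_large_finite_or_infinite(self):
        prior = de.estimate_prior([1.0, 1.0 + 1e-9], 10)
        assert prior.d0 > 100 or math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(1.0, rel=1e-3)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError):
            de.estimate_prior([0.0, 0.0, 0.0], 10)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(0)
        df, d0, s0 = 10, 4.0, 2.0
        s2 = s0 * (rng.chisquare(df, 2000) / df) / (rng.chisquare(d0, 2000) / d0)
        prior = de.estimate_prior(s2, df)
        assert prior.d0 == pytest.approx(d0, rel=0.10)
        assert prior.s0_sq == pytest.approx(s0, rel=0.05)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def _as_frame(m):
    cols = [f"s{i}" for i in range(m.shape[1])]
    return pd.DataFrame(m, columns=cols), {c: ("a" if i < 6 else "b") for i, c in enumerate(cols)}


class TestModeratedT:
    def test_matches_reference_implementation(self):
        mat, labels = _as_frame(_matrix_fixture())
        res = de.moderated_t_test(mat, labels, group_order=("a", "b"))
        prior = res.attrs["prior"]
        assert prior.d0 == pytest.approx(2.4578679229, rel=1e-8)
        assert prior.s0_sq == pytest.approx(0.000747165023368, rel=1e-9)
        t_exp = [5.05201251824, 7.438929972, 1.56391202158, 3.1124095481,
                 11.7459221899, 5.58743539507, 4.83207266359, 11.9453574228]
        p_exp = [0.000252675018124, 6.31056135693e-06, 0.14287447755,
                 0.00862673086393, 4.19449248589e-08, 0.000103153583696,
                 0.000369272676682, 3.45546922574e-08]
        s2_exp = [0.00154462825687, 0.000714339750546, 0.00181136735309,
                  0.00406766833693, 0.000232944996569, 0.000489130364865,
                  0.00132987119828, 0.000265650571183]
        np.testing.assert_allclose(res["t_mod"][:8], t_exp, rtol=1e-8)
        np.testing.assert_allclose(res["p"][:8], p_exp, rtol=1e-7)
        np.testing.assert_allclose(res["s2_post"][:8], s2_exp, rtol=1e-8)
        assert res["df_total"].iloc[0] == pytest.approx(12.4578679229, rel=1e-8)

    def test_identical_groups_give_zero_t_and_p_one(self):
        m = np.tile(np.array([0.5, 0.5, 0.5, 0.6, 0.6, 0.6] * 2), (3, 1))
        mat, labels = _as_frame(m)
        res = de.moderated_t_test(mat, labels)
        assert np.allclose(res["t_mod"], 0)
        assert np.allclose(res["p"], 1)

    def test_zero_prior_df_reduces_to_pooled_t(self):
        rng = np.random.default_rng(123)
        m = rng.normal(0, 1, (50, 12))
        mat, labels = _as_frame(m)
        res = de.moderated_t_test(mat, labels, prior=de.ShrinkagePrior(0.0, 1.0),
                                  group_order=("a", "b"))
        for i in range(50):
            t_ref, p_ref = stats.ttest_ind(m[i, 6:], m[i, :6], equal_var=True)
            assert res["t_mod"].iloc[i] == pytest.approx(t_ref, abs=1e-10)
            assert res["p"].iloc[i] == pytest.approx(p_ref, abs=1e-10)

    def test_infinite_prior_limit(self):
        rng = np.random.default_rng(5)
        m = rng.normal(0.5, 0.1, (20, 12))
        mat, labels = _as_frame(m)
        s0 = 0.01
        res = de.moderated_t_test(mat, labels, prior=de.ShrinkagePrior(math.inf, s0),
                                  group_order=("a", "b"))
        delta = m[:, 6:].mean(axis=1) - m[:, :6].mean(axis=1)
        expected = delta / np.sqrt(s0 * (1 / 6 + 1 / 6))
        np.testing.assert_allclose(res["t_mod"], expected, rtol=1e-12)

    def test_sign_consistency_and_untestable_handling(self):
        m = np.full((2, 12), np.nan)
        m[0] = np.linspace(0.2, 0.9, 12)
        m[1, :2] = [0.5, 0.6]  # group a has 2 values, group b none
        mat, labels = _as_frame(m)
        res = de.moderated_t_test(mat, labels, prior=de.ShrinkagePrior(4.0, 0.01))
        assert np.sign(res["t_mod"].iloc[0]) == np.sign(res["delta_psi"].iloc[0])
        assert not res["testable"].iloc[1]
        assert math.isnan(res["p"].iloc[1])

    def test_one_group_absent_errors(self):
        mat, _ = _as_frame(np.zeros((2, 12)))
        with pytest.raises(ValueError, match="two groups"):
            de.moderated_t_test(mat, {c: "a" for c in mat.columns})


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------


class TestBH:
    def test_single_p(self):
        assert de.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_check(self):
        np.testing.assert_allclose(
            de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_collapse(self):
        np.testing.assert_allclose(de.bh_adjust([0.05] * 7), [0.05] * 7)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.random(200)
        q = de.bh_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        perm = rng.permutation(50)
        q = de.bh_adjust(p)
        assert np.allclose(de.bh_adjust(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------


@pytest.fixture
def index(toy_annotation):
    return de.AnnotationIndex.build(toy_annotation)


class TestClassification:
    def test_annotated_intron_is_canonical(self, index):
        assert de.classify_junction(("chrT", 201, 400, "+"), index) == "canonical"

    def test_skip_of_one_exon_is_es(self, index):
        # merges intron1 (201,400) and intron2 (501,800) across exon (401,500)
        assert de.classify_junction(("chrT", 201, 800, "+"), index) == "ES"

    def test_minus_strand_skip_is_es(self, index):
        assert de.classify_junction(("chrT", 1201, 1800, "-"), index) == "ES"

    def test_novel_acceptor_is_alt3(self, index):
        assert de.classify_junction(("chrT", 201, 450, "+"), index) == "alt3"

    def test_novel_donor_is_alt5(self, index):
        assert de.classify_junction(("chrT", 250, 400, "+"), index) == "alt5"

    def test_unanchored_is_other(self, index):
        assert de.classify_junction(("chrT", 10, 50, "+"), index) == "other"

    def test_boundary_event_at_annotated_acceptor_is_ir(self, index):
        assert de.classify_event(("boundary", ("chrT", 400, "+")), index) == "IR"
        assert de.classify_event(("boundary", ("chrT", 999, "+")), index) == "other"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


class TestSummaries:
    def _frame(self, cats, qs):
        n = len(cats)
        return pd.DataFrame(
            {
                "category": cats,
                "q": qs,
                "mean_1": np.full(n, 0.2),
                "mean_2": np.full(n, 0.5),
            }
        )

    def test_empty_significant_set(self):
        out = de.summarize_events(self._frame(["IR"], [0.5]))
        assert out.empty

    def test_fractions_sum_to_one_and_counts(self):
        df = self._frame(["IR"] * 80 + ["ES"] * 20, [0.01] * 100)
        out = de.summarize_events(df).set_index("category")
        assert out.loc["IR", "count"] == 80
        assert out.loc["ES", "fraction"] == pytest.approx(0.2)
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_log2fc_uses_pseudocount(self):
        df = self._frame(["IR"], [0.0])
        out = de.summarize_events(df, epsilon=0.01)
        assert out["log2fc_median"].iloc[0] == pytest.approx(np.log2(0.51 / 0.21))
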