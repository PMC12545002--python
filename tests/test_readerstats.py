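"""Reader-study statistics against definitional and library oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ceustic import (
    TrendTable,
    ValidationError,
    auc_delong,
    cochran_armitage,
    cohen_kappa,
    delong_compare,
    diagnostic_metrics,
    fleiss_kappa,
    icc_absolute,
    make_ratings,
    mcnemar,
    reader_study_report,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def icc_a1_bruteforce(x: np.ndarray) -> float:
    """ICC(A,1) from raw definitional sums of squares (no shortcuts)."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = ssc = sse = 0.0
    for i in range(n):
        ssr += k * (x[i].mean() - grand) ** 2
    for j in range(k):
        ssc += n * (x[:, j].mean() - grand) ** 2
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def fleiss_bruteforce(x: np.ndarray) -> float:
    """Fleiss' kappa by exhaustive per-case agreement computation."""
    n, k = x.shape
    cats = sorted(set(x.ravel().tolist()))
    counts = [[int(np.sum(x[i] == c)) for c in cats] for i in range(n)]
    p_j = [sum(row[j] for row in counts) / (n * k) for j in range(len(cats))]
    p_i = [(sum(c * c for c in row) - k) / (k * (k - 1)) for row in counts]
    p_bar = sum(p_i) / n
    p_e = sum(p * p for p in p_j)
    return (p_bar - p_e) / (1 - p_e)


def cochran_armitage_bruteforce(counts: np.ndarray, scores: np.ndarray) -> float:
    """z by direct summation of T and Var(T)."""
    n_k = counts.sum(axis=0)
    n_total = counts.sum()
    p_bar = counts[1].sum() / n_total
    t = sum(s * (counts[1, j] - n_k[j] * p_bar) for j, s in enumerate(scores))
    var = p_bar * (1 - p_bar) * (
        sum(n_k[j] * scores[j] ** 2 for j in range(len(scores)))
        - sum(n_k[j] * scores[j] for j in range(len(scores))) ** 2 / n_total
    )
    return t / math.sqrt(var)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class TestIcc:
    def test_perfect_agreement(self):
        x = np.tile(np.arange(1.0, 7.0)[:, None], (1, 3))
        assert icc_absolute(x).icc == pytest.approx(1.0)

    def test_null_case_large_noise_matrix(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((500, 4))
        assert abs(icc_absolute(x).icc) < 0.1

    def test_fixture_matches_bruteforce_anova(self):
        x = np.array([[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
                     dtype=float)
        assert icc_absolute(x).icc == pytest.approx(icc_a1_bruteforce(x), abs=1e-10)

    def test_random_matrices_match_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(3, 11)
            k = rng.integers(2, 6)
            x = rng.integers(0, 6, size=(n, k)).astype(float)
            if np.ptp(x.mean(axis=1)) < 1e-12:
                continue
            assert icc_absolute(x).icc == pytest.approx(icc_a1_bruteforce(x), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=(8, 4)).astype(float)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(8), 4),
            "raters": np.tile(np.arange(4), 8),
            "scores": x.ravel(),
        })
        tab = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        mine_1 = icc_absolute(x, form="single")
        mine_k = icc_absolute(x, form="average")
        ref_1 = tab[tab["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ref_k = tab[tab["Type"].isin(["ICC2k", "ICC(A,k)"])].iloc[0]
        assert mine_1.icc == pytest.approx(float(ref_1["ICC"]), abs=1e-9)
        assert mine_k.icc == pytest.approx(float(ref_k["ICC"]), abs=1e-9)
        assert mine_1.p == pytest.approx(float(ref_1["pval"]), abs=1e-9)
        ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
        assert mine_1.ci95 == pytest.approx(tuple(ref_1[ci_col]), abs=0.01)

    def test_zero_between_case_variance_flagged(self):
        x = np.tile([[1.0, 2.0, 3.0]], (5, 1))
        res = icc_absolute(x)
        assert res.degenerate and res.icc == 0.0


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

class TestKappa:
    def test_unanimous_raters_kappa_one(self):
        x = np.repeat(np.array([[0], [1], [0], [1], [1], [0]]), 4, axis=1)
        assert fleiss_kappa(x).kappa == pytest.approx(1.0)

    def test_chance_level_large_sample(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, size=(2000, 4))
        assert abs(fleiss_kappa(x).kappa) < 0.05

    def test_fixture_matches_definitional_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, size=(10, 4))
        assert fleiss_kappa(x).kappa == pytest.approx(fleiss_bruteforce(x), abs=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, size=(30, 5))
        agg, _ = sm.aggregate_raters(x)
        assert fleiss_kappa(x).kappa == pytest.approx(sm.fleiss_kappa(agg), abs=1e-12)

    def test_single_category_degenerate(self):
        res = fleiss_kappa(np.zeros((5, 3), dtype=int))
        assert res.degenerate

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_relabeling_and_rater_permutation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, size=(12, 4))
        base = fleiss_kappa(x).kappa
        relabeled = (2 - x)  # bijective category relabeling
        permuted = x[:, rng.permutation(4)]
        if not math.isnan(base):
            assert fleiss_kappa(relabeled).kappa == pytest.approx(base, abs=1e-12)
            assert fleiss_kappa(permuted).kappa == pytest.approx(base, abs=1e-12)

    def test_cohen_kappa_perfect_and_chance(self):
        a = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        assert cohen_kappa(a, a).kappa == pytest.approx(1.0)
        assert abs(cohen_kappa(a, 1 - a).kappa) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

class TestMcNemar:
    @staticmethod
    def _vectors(b, c, both=5):
        first = np.r_[np.ones(b), np.zeros(c), np.ones(both), np.zeros(both)]
        second = np.r_[np.zeros(b), np.ones(c), np.ones(both), np.zeros(both)]
        return first, second

    def test_symmetric_discordance(self):
        res = mcnemar(*self._vectors(5, 5), method="asymptotic")
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        res = mcnemar(*self._vectors(10, 2), method="asymptotic")
        assert res.statistic == pytest.approx(16.0 / 3.0)
        assert (res.b, res.c) == (10, 2)

    def test_minimal_discordance_exact(self):
        res = mcnemar(*self._vectors(1, 0), method="exact")
        assert res.p == pytest.approx(1.0)

    def test_zero_discordance_flagged(self):
        res = mcnemar(*self._vectors(0, 0))
        assert res.degenerate and res.p == 1.0

    def test_auto_switches_to_exact_for_few_discordant(self):
        assert mcnemar(*self._vectors(3, 2)).method == "exact"
        assert mcnemar(*self._vectors(20, 10)).method == "asymptotic"


# ---------------------------------------------------------------------------
# Cochran-Armitage
# ---------------------------------------------------------------------------

class TestCochranArmitage:
    def test_no_trend_gives_zero(self):
        table = TrendTable(np.array([[10, 20, 30, 40], [1, 2, 3, 4]]))
        assert cochran_armitage(table).z == pytest.approx(0.0, abs=1e-12)

    def test_score_reversal_negates_z(self):
        counts = np.array([[20, 15, 10, 5], [1, 2, 4, 8]])
        z_fwd = cochran_armitage(TrendTable(counts)).z
        z_rev = cochran_armitage(TrendTable(counts, scores=[4, 3, 2, 1])).z
        assert z_rev == pytest.approx(-z_fwd, abs=1e-12)

    def test_fixture_matches_definitional_oracle(self):
        counts = np.array([[20, 15, 10, 5], [1, 2, 4, 8]])
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        z = cochran_armitage(TrendTable(counts, scores=scores)).z
        assert z == pytest.approx(cochran_armitage_bruteforce(counts, scores), abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_score_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=(2, 4))
        counts[0, 0] += 1
        counts[1, -1] += 1
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        base = cochran_armitage(TrendTable(counts, scores=scores))
        trans = cochran_armitage(TrendTable(counts, scores=a * scores + b))
        if not base.degenerate:
            assert trans.z == pytest.approx(base.z, abs=1e-9)

    def test_single_class_degenerate(self):
        res = cochran_armitage(TrendTable(np.array([[5, 5, 5, 5], [0, 0, 0, 0]])))
        assert res.degenerate


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

class TestRoc:
    def test_perfect_calls(self):
        truth = np.array([1, 1, 0, 0, 1, 0])
        m = diagnostic_metrics(truth, truth)
        for e in (m.sensitivity, m.specificity, m.ppv, m.npv, m.auc):
            assert e.value == pytest.approx(1.0)
        assert m.youden == pytest.approx(1.0)

    def test_hand_computed_confusion(self):
        truth = np.r_[np.ones(10), np.zeros(50)].astype(int)
        calls = np.r_[np.ones(5), np.zeros(5), np.ones(10), np.zeros(40)].astype(int)
        m = diagnostic_metrics(calls, truth)
        assert m.sensitivity.value == pytest.approx(0.5)
        assert m.specificity.value == pytest.approx(0.8)
        assert m.ppv.value == pytest.approx(1 / 3)
        assert m.npv.value == pytest.approx(8 / 9)
        assert m.youden == pytest.approx(0.3)

    def test_printed_operating_point_identity(self):
        # Se 0.20, Sp 0.65 pools to AUC (0.20 + 0.65)/2 = 0.425, i.e. the
        # published 0.43 after rounding
        assert (0.20 + 0.65) / 2 == pytest.approx(0.425)
        tab = make_ratings(620, 4, 11 / 62, sens=0.20, spec=0.65, seed=0)
        calls, truth = tab.pooled_calls()
        m = diagnostic_metrics(calls, truth)
        assert m.auc.value == pytest.approx(
            (m.sensitivity.value + m.specificity.value) / 2, abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_binary_auc_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 2, 40)
        if truth.sum() in (0, 40):
            return
        calls = rng.integers(0, 2, 40)
        m = diagnostic_metrics(calls, truth)
        assert m.auc.value == pytest.approx(
            (m.sensitivity.value + m.specificity.value) / 2, abs=1e-12
        )

    def test_truth_as_scores_gives_auc_one(self):
        truth = np.array([1, 0, 1, 0, 0, 1])
        assert auc_delong(truth.astype(float), truth).value == pytest.approx(1.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValidationError):
            diagnostic_metrics(np.array([1, 0]), np.array([1, 1]))

    def test_delong_identical_scores_p_one(self):
        truth = np.array([1, 1, 0, 0, 1, 0])
        s = np.array([0.9, 0.8, 0.2, 0.4, 0.7, 0.1])
        res = delong_compare(s, s, truth)
        assert res.p == 1.0 and res.degenerate

    def test_delong_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(42)
        truth = np.r_[np.ones(200), np.zeros(200)].astype(int)
        sa = rng.normal(truth * 0.8, 1.0)
        sb = rng.normal(truth * 0.5, 1.0)
        res = delong_compare(sa, sb, truth)
        idx_p = np.flatnonzero(truth == 1)
        idx_n = np.flatnonzero(truth == 0)
        boots = []
        for _ in range(2000):
            bi = np.r_[rng.choice(idx_p, idx_p.size), rng.choice(idx_n, idx_n.size)]
            r2 = delong_compare(sa[bi], sb[bi], truth[bi])
            boots.append(r2.auc_a - r2.auc_b)
        assert res.var_diff == pytest.approx(np.var(boots, ddof=1), rel=0.15)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

class TestReport:
    def test_perfect_raters_all_statistics_one(self):
        sessions = {
            "junior": {
                "unassisted": make_ratings(62, 4, 11 / 62, 1.0, 1.0, seed=1),
                "assisted": make_ratings(62, 4, 11 / 62, 1.0, 1.0, seed=1),
            }
        }
        rep = reader_study_report(sessions)
        for sess in rep["groups"]["junior"].values():
            assert sess["pooled"]["auc"]["value"] == pytest.approx(1.0)
            assert sess["icc"]["value"] == pytest.approx(1.0)
            assert sess["fleiss_kappa"]["value"] == pytest.approx(1.0)
        within = [c for c in rep["comparisons"] if c["kind"] == "within-group"][0]
        assert within["mcnemar_correctness"]["b"] == 0
        assert within["mcnemar_correctness"]["c"] == 0
        assert within["mcnemar_correctness"]["p"] == 1.0

    def test_case_id_mismatch_rejected(self):
        a = make_ratings(10, 2, 0.3, 0.9, 0.9, seed=0)
        b = make_ratings(12, 2, 0.3, 0.9, 0.9, seed=0)
        with pytest.raises(ValidationError, match="case-id mismatch"):
            reader_study_report({"g": {"s1": a, "s2": b}})

    def test_csv_round_trip(self, tmp_path):
        tab = make_ratings(20, 3, 0.3, 0.8, 0.7, seed=4, session_label="junior_unassisted")
        path = tab.to_csv(tmp_path / "junior_unassisted.csv")
        back = type(tab).from_csv(path)
        assert np.array_equal(back.ratings, tab.ratings)
        assert np.array_equal(back.truth, tab.truth)
        assert back.case_ids == tab.case_ids
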