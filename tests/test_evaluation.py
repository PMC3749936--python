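"""Gene-list association battery and group summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from _oracles import (
    auc_pair_counting,
    ecdf_percentile,
    logistic_irls,
    mwu_u_enumeration,
)
from rvistools.errors import DegenerateStatisticsError, InputError
from rvistools.evaluation import (
    GeneListAnnotation,
    evaluate_list,
    group_summary,
    logistic_association,
    mann_whitney,
    resolve_list,
    roc_auc_delong,
    score_correlation,
)
from rvistools.rvis_core import ScoreTable, percentile_rank


def make_scores(values, prefix="g"):
    return pd.Series(
        values, index=[f"{prefix}{i}" for i in range(len(values))], dtype=float
    )


def make_list(scores, member_idx):
    members = frozenset(scores.index[i] for i in member_idx)
    background = frozenset(scores.index) - members
    return GeneListAnnotation("toy", members, background)


def make_score_table(values):
    s = make_scores(values)
    pct = percentile_rank(s)
    df = pd.DataFrame(
        {
            "x_total": 10,
            "y_common_functional": 1,
            "rvis": s,
            "percentile": pct,
            "covered_sites": 1000,
        }
    )
    df.index.name = "gene"
    return ScoreTable(table=df, meta={})


class TestLogistic:
    def test_members_at_bottom_give_negative_beta(self):
        rng = np.random.default_rng(1)
        scores = make_scores(np.sort(rng.normal(size=1000)))
        gl = make_list(scores, range(50))  # the 50 lowest-scored genes
        beta, ci, p, sep = logistic_association(scores, gl)
        assert beta < 0
        if not sep:  # separation is possible by construction here
            assert ci[0] <= beta <= ci[1]
            assert p < 0.01

    def test_tiny_fixture_matches_irls_oracle(self):
        scores = make_scores([-1.2, -0.7, -0.1, 0.3, 0.8, 1.5])
        gl = make_list(scores, [0, 1, 3])
        beta, _, _, sep = logistic_association(scores, gl)
        x = np.array([-1.2, -0.7, 0.3, -0.1, 0.8, 1.5])
        y = np.array([1, 1, 1, 0, 0, 0])
        oracle = logistic_irls(x, y)
        assert not sep
        assert beta == pytest.approx(oracle[1], rel=1e-6)

    def test_perfect_separation_flagged_not_fatal(self):
        scores = make_scores([-3, -2.5, -2, 2, 2.5, 3, 3.5, 4])
        gl = make_list(scores, [0, 1, 2])
        *_, sep = logistic_association(scores, gl)
        assert sep

    def test_too_few_genes_rejected(self):
        scores = make_scores([-1, 0, 1])
        with pytest.raises(InputError):
            logistic_association(scores, make_list(scores, [0]))


class TestRocAucDelong:
    def test_perfect_separation_gives_auc_one(self):
        scores = make_scores([-5, -4, -3, 1, 2, 3])
        auc, ci = roc_auc_delong(scores, make_list(scores, [0, 1, 2]))
        assert auc == 1.0
        assert ci[1] == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(2)
        scores = make_scores(rng.normal(size=4000))
        gl = make_list(scores, rng.choice(4000, size=2000, replace=False))
        auc, _ = roc_auc_delong(scores, gl)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_ties_match_pair_counting_oracle(self):
        values = [-1.0, -0.5, 0.0, 0.0, 2.0, -0.5, 0.0, 1.0, 1.5, 2.0]
        scores = make_scores(values)
        gl = make_list(scores, [0, 1, 2, 3, 4])
        auc, _ = roc_auc_delong(scores, gl)
        m = [values[i] for i in (0, 1, 2, 3, 4)]
        b = [values[i] for i in (5, 6, 7, 8, 9)]
        assert auc == pytest.approx(auc_pair_counting(m, b), abs=1e-12)

    def test_direction_flip_complements_auc(self):
        rng = np.random.default_rng(3)
        scores = make_scores(rng.normal(size=60))
        gl = make_list(scores, range(12))
        a_low, _ = roc_auc_delong(scores, gl, lower_predicts_member=True)
        a_high, _ = roc_auc_delong(scores, gl, lower_predicts_member=False)
        assert a_low + a_high == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        scores = make_scores([1, 2, 3])
        with pytest.raises(DegenerateStatisticsError):
            roc_auc_delong(
                scores, GeneListAnnotation("all", frozenset(scores.index), frozenset())
            )

    def test_ci_coverage_under_normal_shift(self):
        """DeLong CIs cover the analytic AUC Phi(delta/sqrt(2)) ~95% of
        the time over repeated sampling."""
        delta = 1.0
        true_auc = norm.cdf(delta / np.sqrt(2))
        rng = np.random.default_rng(7)
        hits = 0
        reps = 300
        for _ in range(reps):
            m = rng.normal(-delta, 1, size=40)  # members score lower
            b = rng.normal(0, 1, size=60)
            scores = make_scores(np.concatenate([m, b]))
            gl = make_list(scores, range(40))
            _, (lo, hi) = roc_auc_delong(scores, gl)
            hits += lo <= true_auc <= hi
        assert 0.88 <= hits / reps <= 0.99


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        scores = make_scores([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        gl = make_list(scores, [0, 1, 2])
        u, p = mann_whitney(scores, gl)
        assert u == pytest.approx(4.5)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_u_matches_enumeration_oracle(self):
        values = [-2.0, -1.0, 0.5, 3.0, -1.5, 0.0, 1.0, 2.0]
        scores = make_scores(values)
        gl = make_list(scores, [0, 1, 2, 3])
        u, _ = mann_whitney(scores, gl)
        assert u == mwu_u_enumeration(values[:4], values[4:])

    def test_auc_u_identity(self, small_scores):
        """U/(n1*n2) equals the DeLong AUC point estimate (low = member)."""
        scores = small_scores.scores()
        rng = np.random.default_rng(4)
        members = rng.choice(scores.index, size=30, replace=False)
        gl, _ = resolve_list(scores, members)
        auc, _ = roc_auc_delong(scores, gl)
        u, _ = mann_whitney(scores, gl)
        n1, n2 = len(gl.members), len(gl.background)
        # U counts member > background; lower-predicts flips the complement
        assert 1.0 - u / (n1 * n2) == pytest.approx(auc, abs=1e-9)


class TestScoreCorrelation:
    def test_self_and_negation(self, small_scores):
        same = score_correlation(small_scores, small_scores)
        assert same.r == pytest.approx(1.0)
        neg_table = small_scores.table.copy()
        neg_table["rvis"] = -neg_table["rvis"]
        neg = score_correlation(small_scores, ScoreTable(table=neg_table))
        assert neg.r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, small_sim):
        from conftest import score_simulation
        from rvistools import io as rio
        from rvistools.rvis_core import compute_rvis

        a = score_simulation(small_sim)
        b = compute_rvis(
            rio.records_from_frame(small_sim.variants),
            small_sim.exons,
            small_sim.coverage_profile(),
            rho=1.0,
        )
        res = score_correlation(a, b)
        x = a.scores().to_numpy()
        y = b.scores().loc[a.scores().index].to_numpy()
        oracle = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert res.r == pytest.approx(oracle, abs=1e-12)
        assert res.ci95[0] <= res.r <= res.ci95[1]

    def test_empty_intersection_rejected(self):
        a = make_score_table([1, 2, 3, 4])
        b = make_score_table([1, 2, 3, 4])
        b.table.index = pd.Index([f"x{i}" for i in range(4)], name="gene")
        with pytest.raises(InputError):
            score_correlation(a, b)


class TestGroupSummary:
    def test_single_gene_list(self):
        st = make_score_table([-2.0, -1.0, 0.0, 1.0])
        gs = group_summary(st, ["g1"])
        assert gs.mean_score == pytest.approx(-1.0)
        assert gs.n_members_scored == 1

    def test_all_genes_give_quarter_bins(self):
        st = make_score_table(np.linspace(-3, 3, 100))
        gs = group_summary(st, list(st.table.index))
        assert gs.bin_proportions == pytest.approx((0.25, 0.25, 0.25, 0.25))

    def test_percentile_of_mean_matches_ecdf_oracle(self):
        rng = np.random.default_rng(9)
        st = make_score_table(rng.normal(size=100))
        members = [f"g{i}" for i in rng.choice(100, size=10, replace=False)]
        gs = group_summary(st, members)
        mean_s = st.table.loc[members, "rvis"].mean()
        assert gs.percentile_of_mean == pytest.approx(
            ecdf_percentile(st.table["rvis"], mean_s), abs=1e-12
        )

    def test_unscored_list_errors_with_symbols(self):
        st = make_score_table([1, 2, 3])
        with pytest.raises(InputError, match="NOPE"):
            group_summary(st, ["NOPE"])


class TestBattery:
    def test_null_membership_p_values_roughly_uniform(self):
        """Type-I control: random membership gives uniform-ish p over
        200 simulations (full 1000-rep check lives in the acceptance
        suite)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(12)
        p_log, p_mwu = [], []
        scores = make_scores(rng.normal(size=200))
        for _ in range(200):
            members = rng.choice(scores.index, size=20, replace=False)
            res = evaluate_list(scores, members)
            p_log.append(res.p_logistic)
            p_mwu.append(res.p_mwu)
        assert kstest(p_log, "uniform").pvalue > 1e-3
        assert kstest(p_mwu, "uniform").pvalue > 1e-3

    def test_invariant_to_symbol_relabeling(self):
        rng = np.random.default_rng(13)
        values = rng.normal(size=50)
        a = make_scores(values, prefix="a")
        b = make_scores(values, prefix="zz")
        res_a = evaluate_list(a, list(a.index[:10]))
        res_b = evaluate_list(b, list(b.index[:10]))
        assert res_a.auc == res_b.auc
        assert res_a.p_mwu == res_b.p_mwu
        assert res_a.beta == pytest.approx(res_b.beta)

    def test_resolve_list_reports_unresolved(self, caplog):
        scores = make_scores([1, 2, 3, 4])
        gl, unresolved = resolve_list(scores, ["g0", "g1", "MISSING"])
        assert unresolved == ["MISSING"]
        assert gl.members == frozenset({"g0", "g1"})
        assert gl.background == frozenset({"g2", "g3"})
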