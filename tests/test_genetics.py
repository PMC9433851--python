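"""SNP QC, polygenic scoring, extreme groups, and the Bayesian model."""

import numpy as np
import pandas as pd
import pytest

from hcdn.errors import ValidationError
from hcdn.genetics import (BayesianModelSpec, PrsModel, PrsScores,
                           compute_prs, fit_bayesian_logistic,
                           select_extremes, snp_qc)


def _model(rows):
    t = pd.DataFrame(rows).set_index("snp_id")
    return PrsModel(table=t)


class TestSnpQc:
    def test_low_maf_excluded_with_reason(self):
        m = snp_qc(_model([
            {"snp_id": "rs1", "beta": 0.1, "maf": 0.005, "info": 0.9},
            {"snp_id": "rs2", "beta": 0.1, "maf": 0.30, "info": 0.9},
        ]))
        assert not m.table.loc["rs1", "qc_pass"]
        assert m.table.loc["rs1", "qc_reasons"] == "maf"
        assert m.table.loc["rs2", "qc_pass"]
        assert m.exclusion_counts["maf"] == 1

    def test_boundary_values_retained(self):
        # thresholds are strict inequalities: maf == 0.01, info == 0.8 pass
        m = snp_qc(_model([
            {"snp_id": "rs1", "beta": 0.1, "maf": 0.01, "info": 0.9},
            {"snp_id": "rs2", "beta": 0.1, "maf": 0.30, "info": 0.8},
        ]))
        assert m.table["qc_pass"].all()

    def test_hand_written_table_matches_manual_filter(self):
        rows = []
        for i in range(10):
            rows.append({"snp_id": f"rs{i}", "beta": 0.05 * i,
                         "maf": 0.25, "info": 0.95,
                         "effect_allele": "A", "other_allele": "G"})
        rows[2]["maf"] = 0.002                       # fails maf
        rows[5]["info"] = 0.5                        # fails info
        rows[7]["other_allele"] = "T"                # A/T strand-ambiguous
        m = snp_qc(_model(rows))
        surviving = set(m.passing_snps)
        assert surviving == {f"rs{i}" for i in range(10)} - {"rs2", "rs5", "rs7"}
        assert m.exclusion_counts == {"maf": 1, "info": 1, "duplicate": 0,
                                      "ambiguous": 1}

    def test_duplicate_ids_excluded(self):
        m = snp_qc(_model([
            {"snp_id": "rs1", "beta": 0.1, "maf": 0.2, "info": 0.9},
            {"snp_id": "rs1", "beta": 0.2, "maf": 0.2, "info": 0.9},
            {"snp_id": "rs2", "beta": 0.1, "maf": 0.2, "info": 0.9},
        ]))
        assert m.exclusion_counts["duplicate"] == 2
        assert list(m.passing_snps) == ["rs2"]

    def test_missing_qc_columns_rejected(self):
        with pytest.raises(ValidationError, match="info"):
            PrsModel(table=pd.DataFrame(
                {"beta": [0.1], "maf": [0.2]},
                index=pd.Index(["rs1"], name="snp_id")))


def _scored_model(n_snps, seed=0):
    rng = np.random.default_rng(seed)
    return snp_qc(_model([
        {"snp_id": f"rs{i}", "beta": rng.normal(), "maf": 0.3, "info": 0.95}
        for i in range(n_snps)]))


class TestComputePrs:
    def test_all_zero_genotypes_score_zero(self):
        m = _scored_model(4)
        g = pd.DataFrame(0, index=pd.Index(["a", "b"], name="participant_id"),
                         columns=[f"rs{i}" for i in range(4)])
        assert (compute_prs(g, m).scores == 0).all()

    def test_single_snp_direct_product(self):
        m = snp_qc(_model([{"snp_id": "rs1", "beta": 0.5, "maf": 0.3,
                            "info": 0.9}]))
        g = pd.DataFrame({"rs1": [2]},
                         index=pd.Index(["a"], name="participant_id"))
        assert compute_prs(g, m).scores.iloc[0] == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        m = _scored_model(50, seed=1)
        g = pd.DataFrame(rng.integers(0, 3, size=(20, 50)),
                         index=pd.Index([f"p{i}" for i in range(20)],
                                        name="participant_id"),
                         columns=[f"rs{i}" for i in range(50)])
        scores = compute_prs(g, m).scores
        beta = m.table["beta"]
        for i in range(20):
            acc = 0.0
            for snp in g.columns:
                acc += g.iloc[i][snp] * beta[snp]
            assert abs(scores.iloc[i] - acc) < 1e-12

    def test_prs_linear_in_effect_sizes(self):
        rng = np.random.default_rng(2)
        m = _scored_model(10, seed=2)
        g = pd.DataFrame(rng.integers(0, 3, size=(8, 10)),
                         index=pd.Index([f"p{i}" for i in range(8)],
                                        name="participant_id"),
                         columns=[f"rs{i}" for i in range(10)])
        doubled = PrsModel(table=m.table.assign(beta=2 * m.table["beta"]))
        assert np.allclose(compute_prs(g, doubled).scores,
                           2 * compute_prs(g, m).scores)

    def test_bad_dosage_rejected(self):
        m = _scored_model(2)
        g = pd.DataFrame({"rs0": [0, 3], "rs1": [1, 1]},
                         index=pd.Index(["a", "b"], name="participant_id"))
        with pytest.raises(ValidationError, match="dosages"):
            compute_prs(g, m)

    def test_missing_snp_column_rejected(self):
        m = _scored_model(3)
        g = pd.DataFrame({"rs0": [0], "rs1": [1]},
                         index=pd.Index(["a"], name="participant_id"))
        with pytest.raises(ValidationError, match="lacks"):
            compute_prs(g, m)


def _scores(values):
    idx = pd.Index([f"p{i:03d}" for i in range(len(values))],
                   name="participant_id")
    return PrsScores(scores=pd.Series(values, index=idx, name="prs"))


class TestSelectExtremes:
    def test_top_and_bottom_five_percent_of_hundred(self):
        out = select_extremes(_scores(np.arange(1.0, 101.0)), q=0.05)
        assert len(out) == 10
        assert set(out.index[out == 0]) == {f"p{i:03d}" for i in range(5)}
        assert set(out.index[out == 1]) == {f"p{i:03d}" for i in range(95, 100)}

    def test_all_tied_scores_rejected(self):
        with pytest.raises(ValidationError, match="tied"):
            select_extremes(_scores(np.full(100, 3.0)), q=0.05)

    def test_boundary_ties_follow_stable_sort_oracle(self):
        vals = np.r_[np.zeros(10), np.ones(80), np.full(10, 2.0)]
        out = select_extremes(_scores(vals), q=0.1)
        # oracle: stable sort by (score, id), slice the ends
        df = _scores(vals).scores.reset_index()
        order = df.sort_values(["prs", "participant_id"],
                               kind="stable")["participant_id"]
        assert list(out.index[out == 0]) == list(order[:10])
        assert list(out.index[out == 1]) == list(order[-10:])

    def test_invariant_to_monotone_transformation(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=200)
        a = select_extremes(_scores(vals), q=0.05)
        b = select_extremes(_scores(np.exp(vals)), q=0.05)
        assert a.equals(b)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValidationError, match="too small"):
            select_extremes(_scores(np.arange(5.0)), q=0.05)


QUICK = BayesianModelSpec(n_steps=400, n_burn=200, thin=2, seed=0)


def _regression_data(n, m=5, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"p{i}" for i in range(n)], name="participant_id")
    pred = pd.DataFrame(rng.normal(size=(n, m)), index=idx,
                        columns=[f"mode_{j + 1}" for j in range(m)])
    eta = pred.to_numpy() @ (beta if beta is not None else np.zeros(m))
    y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-eta))), index=idx)
    sex = pd.Series(rng.integers(0, 2, n), index=idx)
    age = pd.Series(rng.normal(55, 7.5, n), index=idx)
    return pred, y, sex, age


class TestBayesianLogistic:
    def test_deterministic_given_seed(self):
        pred, y, sex, age = _regression_data(300, seed=4)
        a = fit_bayesian_logistic(pred, y, sex, age, QUICK)
        b = fit_bayesian_logistic(pred, y, sex, age, QUICK)
        assert np.array_equal(a.draws, b.draws)

    def test_strong_effect_recovered_and_flagged(self):
        beta = np.array([1.2, 0.0, 0.0, 0.0, 0.0])
        pred, y, sex, age = _regression_data(1500, seed=5, beta=beta)
        s = fit_bayesian_logistic(pred, y, sex, age,
                                  BayesianModelSpec(seed=1))
        assert s.flags["beta_mode_1"]
        assert 0.8 < s.summary.loc["beta_mode_1", "mean"] < 1.6
        assert (s.exclusion_prob >= 0.5).all()
        assert (s.exclusion_prob <= 1.0).all()

    def test_linear_family_runs_on_continuous_outcome(self):
        pred, _, sex, age = _regression_data(300, seed=6)
        y = pd.Series(np.random.default_rng(6).normal(size=300)
                      + pred["mode_1"], index=pred.index)
        spec = BayesianModelSpec(n_steps=400, n_burn=200, thin=2,
                                 family="linear", seed=2)
        s = fit_bayesian_logistic(pred, y, sex, age, spec)
        assert s.summary.loc["beta_mode_1", "mean"] > 0.2

    def test_bad_sex_coding_rejected(self):
        pred, y, sex, age = _regression_data(100, seed=7)
        with pytest.raises(ValidationError, match="sex"):
            fit_bayesian_logistic(pred, y, sex + 1, age, QUICK)
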