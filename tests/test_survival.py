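"""Cox univariate weighting, scoring, median split and log-rank validation."""

import math

import numpy as np
import pandas as pd
import pytest

import apasig as ap
from apasig.survival import SignatureResults, cox_univariate, score_cohort


def clinical(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": ids, "time": times, "event": events})


def grid_search_beta(x, time, event, lo=-3, hi=3, steps=200001):
    """Independent oracle: maximize the Breslow partial likelihood on a grid."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    betas = np.linspace(lo, hi, steps)
    best, best_ll = None, -np.inf
    ev_times = np.unique(time[event == 1])
    for b in betas:
        ll = 0.0
        for t in ev_times:
            at_risk = time >= t
            dead = (time == t) & (event == 1)
            d = dead.sum()
            ll += b * x[dead].sum() - d * math.log(np.exp(b * x[at_risk]).sum())
        if ll > best_ll:
            best_ll, best = ll, b
    return best


class TestCoxUnivariate:
    def test_three_patient_worked_example(self):
        """All-event toy: the partial likelihood maximum has 2 e^{2 beta} = 1."""
        res = cox_univariate([1, 0, 1], [1, 2, 3], [1, 1, 1])
        assert res.beta == pytest.approx(-0.5 * math.log(2), abs=1e-6)
        assert res.beta == pytest.approx(grid_search_beta([1, 0, 1], [1, 2, 3], [1, 1, 1]),
                                         abs=1e-4)

    def test_matches_grid_oracle_with_censoring_and_ties(self, rng):
        x = rng.standard_normal(12)
        time = np.round(rng.exponential(10, 12), 0) + 1  # forces ties
        event = (rng.uniform(size=12) < 0.7).astype(int)
        event[:2] = 1
        res = cox_univariate(x, time, event)
        assert res.beta == pytest.approx(grid_search_beta(x, time, event), abs=1e-4)

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        x = rng.standard_normal(80)
        t = rng.exponential(10, 80) * np.exp(-0.5 * x)
        c = rng.uniform(0, 20, 80)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        res = cox_univariate(x, time, event)
        cph = CoxPHFitter().fit(pd.DataFrame({"x": x, "T": time, "E": event}),
                                "T", "E")
        assert res.beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert res.z == pytest.approx(
            float(cph.params_["x"] / cph.standard_errors_["x"]), abs=1e-3)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 0, 1])

    def test_separation_capped_with_warning(self):
        x = [0, 0, 0, 1, 1, 1]
        time = [1, 2, 3, 10, 11, 12]
        event = [1, 1, 1, 1, 1, 1]
        with pytest.warns(UserWarning, match="separation"):
            res = cox_univariate(x, time, event)
        assert abs(res.beta) == 20.0

    def test_null_z_is_standard_normal(self, rng):
        zs = []
        for _ in range(500):
            x = rng.standard_normal(200)
            t = rng.exponential(1, 200)
            c = rng.uniform(0, 2, 200)
            zs.append(cox_univariate(x, np.minimum(t, c), (t <= c).astype(int)).z)
        assert abs(np.mean(zs)) < 0.1
        assert 0.9 < np.std(zs) < 1.1


class TestSignature:
    def test_weighted_sum_worked_example(self):
        model = SignatureResults(pd.Series({"A": 2.0, "B": -1.0}))
        eri = pd.DataFrame({"s1": [0.5, 1.0], "s2": [1.0, 1.0]}, index=["A", "B"])
        sv = score_cohort(model, eri, cutoff=0.0)
        assert sv.scores["s1"] == pytest.approx(0.0)
        assert sv.scores["s2"] == pytest.approx(1.0)

    def test_training_sign_recovers_hazard_link(self, rng):
        # single APA whose high ERI shortens survival -> positive weight
        n = 120
        x = rng.standard_normal(n)
        t = rng.exponential(10, n) * np.exp(-0.8 * x)
        c = rng.uniform(0, 25, n)
        cl = clinical(np.minimum(t, c), (t <= c).astype(int))
        eri = pd.DataFrame([x], index=["A1"], columns=cl["sample_id"])
        res = ap.PrognosticSignature(eri, cl, ["A1"]).fit()
        assert res.weights["A1"] > 0

    def test_serialization_round_trip(self, tmp_path, rng):
        w = pd.Series(rng.standard_normal(5), index=[f"A{i}" for i in range(5)])
        model = SignatureResults(w, {"dataset": "train", "horizon": 60.0})
        path = tmp_path / "sig.tsv"
        model.to_tsv(path)
        back = SignatureResults.from_tsv(path)
        assert np.allclose(back.weights.to_numpy(), w.to_numpy())
        assert list(back.weights.index) == list(w.index)
        assert back.metadata["dataset"] == "train"

    def test_missing_apa_policy(self, rng):
        model = SignatureResults(pd.Series({"A": 1.0, "B": 1.0}))
        eri = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["A"])
        with pytest.raises(KeyError):
            score_cohort(model, eri)
        with pytest.warns(UserWarning, match="renormalized"):
            sv = score_cohort(model, eri, missing="subset", cutoff=0.0)
        assert sv.scores["s1"] == pytest.approx(2.0)  # renormalized by 2/1

    def test_median_split_balance_and_tie_rule(self, rng):
        model = SignatureResults(pd.Series({"A": 1.0}))
        for n in (7, 8, 31):
            eri = pd.DataFrame([rng.standard_normal(n)], index=["A"],
                               columns=[f"s{i}" for i in range(n)])
            sv = score_cohort(model, eri)
            counts = sv.risk_class.value_counts()
            assert abs(counts.get("high", 0) - counts.get("low", 0)) <= 1
            # lower-or-equal goes to low risk
            assert (sv.scores[sv.risk_class == "low"] <= sv.cutoff + 1e-12).all()

    def test_degenerate_splits(self):
        model = SignatureResults(pd.Series({"A": 0.0}))
        eri = pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"], columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="degenerate"):
            sv = score_cohort(model, eri)
        assert sv.degenerate
        one = pd.DataFrame([[1.0]], index=["A"], columns=["a"])
        with pytest.raises(ValueError, match="at least 2"):
            score_cohort(SignatureResults(pd.Series({"A": 1.0})), one)

    def test_score_additive_in_disjoint_signatures(self, rng):
        eri = pd.DataFrame(rng.standard_normal((4, 6)),
                           index=list("ABCD"), columns=[f"s{i}" for i in range(6)])
        w1 = pd.Series({"A": 1.0, "B": -2.0})
        w2 = pd.Series({"C": 0.5, "D": 3.0})
        s1 = score_cohort(SignatureResults(w1), eri, cutoff=0.0).scores
        s2 = score_cohort(SignatureResults(w2), eri, cutoff=0.0).scores
        s12 = score_cohort(SignatureResults(pd.concat([w1, w2])), eri, cutoff=0.0).scores
        assert np.allclose(s12, s1 + s2)

    def test_refit_scores_are_idempotent(self, rng):
        n = 60
        x = rng.standard_normal((3, n))
        t = rng.exponential(10, n)
        cl = clinical(t, np.ones(n, dtype=int))
        eri = pd.DataFrame(x, index=["A", "B", "C"], columns=cl["sample_id"])
        res = ap.PrognosticSignature(eri, cl, ["A", "B", "C"]).fit()
        sv1 = res.score(eri, cutoff=0.0)
        sv2 = res.score(eri, cutoff=0.0)
        assert np.allclose(sv1.scores, sv2.scores)


class TestLogrank:
    def test_duplicated_cohort_no_difference(self):
        cl = clinical([5, 8, 12, 20, 5, 8, 12, 20], [1, 0, 1, 1, 1, 0, 1, 1])
        labels = pd.Series(["low"] * 4 + ["high"] * 4, index=cl["sample_id"])
        res = ap.logrank_compare(labels, cl)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_four_event_toy_matches_hand_computation(self):
        # group A events at 1,2; group B events at 3,4
        # risk tables: t=1 (4 at risk, 2 in A), t=2 (3 at risk, 1 in A)
        # O_A = 2, E_A = 2/4 + 1/3, V = 1/4 + 2/9 -> chi2 = (O-E)^2 / V
        cl = clinical([1, 2, 3, 4], [1, 1, 1, 1])
        labels = pd.Series(["A", "A", "B", "B"], index=cl["sample_id"])
        res = ap.logrank_compare(labels, cl)
        o_minus_e = 2 - (2 / 4 + 1 / 3)
        var = (2 * 2 * 1 * (4 - 1)) / (4 ** 2 * 3) + (1 * 2 * 1 * (3 - 1)) / (3 ** 2 * 2)
        assert res.statistic == pytest.approx(o_minus_e ** 2 / var, rel=1e-6)

    def test_km_curves_returned_per_class(self):
        cl = clinical([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        labels = pd.Series(["A", "A", "A", "B", "B", "B"], index=cl["sample_id"])
        res = ap.logrank_compare(labels, cl)
        assert set(res.km_curves["class"]) == {"A", "B"}
        assert ((res.km_curves["survival"] >= 0) & (res.km_curves["survival"] <= 1)).all()

    def test_single_class_rejected(self):
        cl = clinical([1, 2], [1, 1])
        labels = pd.Series(["A", "A"], index=cl["sample_id"])
        with pytest.raises(ValueError, match="2 classes"):
            ap.logrank_compare(labels, cl)

    def test_zero_events_rejected(self):
        cl = clinical([1, 2], [0, 0])
        labels = pd.Series(["A", "B"], index=cl["sample_id"])
        with pytest.raises(ValueError, match="events"):
            ap.logrank_compare(labels, cl)

    def test_null_pvalues_uniform(self, rng):
        """Random class labels: log-rank p should be uniform on (0, 1)."""
        from scipy import stats as sps

        ps = []
        for _ in range(500):
            n = 200
            t = rng.exponential(10, n)
            c = rng.uniform(0, 25, n)
            cl = clinical(np.minimum(t, c), (t <= c).astype(int))
            labels = pd.Series(np.where(rng.uniform(size=n) < 0.5, "A", "B"),
                               index=cl["sample_id"])
            if labels.nunique() < 2:
                continue
            ps.append(ap.logrank_compare(labels, cl).pvalue)
        assert sps.kstest(ps, "uniform").pvalue > 0.01
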