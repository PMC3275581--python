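"""Mechanism correlation, miRNA enrichment, gene-set overlap statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import apasig as ap
from apasig.mechanism import relevance_labels, spearman
from apasig.probesets import pairs_to_frame

from conftest import planted_groups


class TestSpearman:
    def test_equals_pearson_on_ranks(self, rng):
        x = rng.standard_normal(40)
        y = 0.3 * x + rng.standard_normal(40)
        rho, _ = spearman(x, y)
        pearson_on_ranks = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(pearson_on_ranks)

    def test_exact_permutation_close_to_approximation(self, rng):
        for _ in range(5):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10)
            _, p_exact = spearman(x, y)  # n=10 -> exact path
            p_approx = float(sps.spearmanr(x, y).pvalue)
            assert p_exact == pytest.approx(p_approx, abs=0.02)

    def test_identical_ranks_rho_one(self):
        x = [1.0, 2.0, 5.0, 9.0, 11.0]
        rho, p = spearman(x, [2 * v for v in x])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(5))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestMechanismCorrelation:
    @pytest.mark.parametrize("truth,expected", [
        (ap.SimulationTruth.synthesis(), "synthesis"),
        (ap.SimulationTruth.degradation(), "degradation"),
    ])
    def test_recovers_planted_mechanism(self, truth, expected):
        u = ap.generate_universe(150, 0.1, seed=31)
        pairs, _ = ap.build_all(u.transcripts, u.probes)
        defs = pairs_to_frame(pairs)
        c = ap.generate_cohort(u, truth, 80, 1.0, seed=7)
        expr = ap.summarize(c.intensity, defs, "median_log")
        eri = ap.compute_eri(expr, pairs)
        res = ap.mechanism_correlation(expr, eri, pairs, planted_groups(c))
        assert res.verdict == expected
        assert res.pvalue < 0.01

    def test_uses_five_prime_most_site_only(self, small_universe, small_pairs,
                                            synthesis_cohort, synthesis_eri):
        expr, eri = synthesis_eri
        pairs, _ = small_pairs
        res = ap.mechanism_correlation(expr, eri, pairs, planted_groups(synthesis_cohort))
        assert res.frame["transcript_id"].is_unique
        by_tr = {}
        for p in pairs:
            by_tr.setdefault(p.transcript_id, []).append(p.position)
        for row in res.frame.itertuples():
            assert row.apa_id.endswith(str(min(by_tr[row.transcript_id])))

    def test_too_few_transcripts_rejected(self, synthesis_cohort, synthesis_eri,
                                          small_pairs):
        expr, eri = synthesis_eri
        pairs, _ = small_pairs
        with pytest.raises(ValueError, match="3 transcripts"):
            ap.mechanism_correlation(expr, eri, pairs[:1], planted_groups(synthesis_cohort))


def sites_frame(assignments):
    """assignments: list of (apa_id, family)."""
    return pd.DataFrame({"apa_id": [a for a, _ in assignments],
                         "mirna_family": [f for _, f in assignments],
                         "n_sites": 1})


class TestMirnaRelevance:
    def test_exact_small_example(self):
        deltas = pd.Series({"a": 0.5, "b": 0.6, "c": 0.1, "d": 0.2})
        sites = sites_frame([("a", "miR-1"), ("b", "miR-1")])
        u, p, direction = ap.mirna_relevance_test(deltas, sites)
        assert p == pytest.approx(1 / 3)
        assert direction == "relevant_more_shortened"

    def test_relevance_labels_pure_function_of_sites(self, rng):
        ids = [f"A{i}" for i in range(20)]
        sites = sites_frame([(ids[i], "miR-1") for i in (1, 4, 7)])
        base = relevance_labels(ids, sites)
        shuffled = sites.sample(frac=1, random_state=3).reset_index(drop=True)
        assert base.equals(relevance_labels(ids, shuffled))

    def test_all_one_side_rejected(self):
        deltas = pd.Series({"a": 0.5, "b": 0.6})
        with pytest.raises(ValueError):
            ap.mirna_relevance_test(deltas, sites_frame([("a", "m"), ("b", "m")]))


class TestPerMirna:
    def make_deltas(self, rng, n=400, sd=0.15):
        return pd.Series(rng.normal(0, sd, n), index=[f"A{i}" for i in range(n)])

    def test_min_relevant_skip_rule(self, rng):
        deltas = self.make_deltas(rng)
        assignments = [(f"A{i}", "miR-small") for i in range(4)]
        assignments += [(f"A{i}", "miR-big") for i in range(10, 30)]
        res = ap.per_mirna_tests(deltas, sites_frame(assignments), min_relevant=5)
        small = res[res["mirna_family"] == "miR-small"].iloc[0]
        assert small["skipped"] and np.isnan(small["qvalue"])
        assert not res[res["mirna_family"] == "miR-big"].iloc[0]["skipped"]

    def test_planted_family_recovered(self, rng):
        deltas = self.make_deltas(rng, n=1000)
        assignments = []
        for fam in range(10):
            ids = rng.choice(1000, size=60, replace=False)
            assignments += [(f"A{i}", f"miR-{fam:02d}") for i in ids]
        planted_ids = [a for a, f in assignments if f == "miR-00"]
        deltas.loc[planted_ids] += 0.5 * 0.15
        res = ap.per_mirna_tests(deltas, sites_frame(assignments), fdr=0.10)
        assert res.set_index("mirna_family").loc["miR-00", "significant"]

    def test_comparison_set_is_per_mirna(self, rng):
        deltas = self.make_deltas(rng, n=50)
        assignments = [(f"A{i}", "miR-a") for i in range(10)]
        assignments += [(f"A{i}", "miR-b") for i in range(5, 15)]
        res = ap.per_mirna_tests(deltas, sites_frame(assignments), min_relevant=5)
        assert len(res) == 2  # overlapping relevant sets are both testable

    def test_no_testable_family_rejected(self, rng):
        deltas = self.make_deltas(rng, n=20)
        with pytest.raises(ValueError, match="min_relevant|relevant"):
            ap.per_mirna_tests(deltas, sites_frame([("A1", "m")]), min_relevant=5)


class TestGeneSetOverlap:
    def test_expected_and_exact_tail(self):
        universe = [f"g{i}" for i in range(100)]
        a = universe[:10]
        b = universe[5:15]  # overlap 5
        obs, exp, p = ap.gene_set_overlap(a, b, universe)
        assert obs == 5
        assert exp == pytest.approx(1.0)
        tail = sum(math.comb(10, k) * math.comb(90, 10 - k) for k in range(5, 11))
        assert p == pytest.approx(tail / math.comb(100, 10))

    def test_saturated_overlap_degenerate(self):
        u = ["a", "b", "c"]
        obs, exp, p = ap.gene_set_overlap(u, u, u)
        assert obs == 3 and p == 1.0

    def test_disjoint_sets_no_enrichment(self):
        universe = [f"g{i}" for i in range(40)]
        obs, exp, p = ap.gene_set_overlap(universe[:5], universe[30:], universe)
        assert obs == 0
        assert p > 0.5

    def test_matches_scipy_fisher(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 80))
            na, nb = int(rng.integers(1, n)), int(rng.integers(1, n))
            ids = [f"g{i}" for i in range(n)]
            a = set(rng.choice(ids, na, replace=False))
            b = set(rng.choice(ids, nb, replace=False))
            obs, _, p = ap.gene_set_overlap(a, b, ids)
            table = [[obs, len(a) - obs], [len(b) - obs, n - len(a) - len(b) + obs]]
            assert p == pytest.approx(sps.fisher_exact(table, alternative="greater")[1])

    def test_subset_validation(self):
        with pytest.raises(ValueError):
            ap.gene_set_overlap(["x"], ["a"], ["a", "b"])
        with pytest.raises(ValueError):
            ap.gene_set_overlap([], [], [])
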