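"""Preranked GSEA: running-sum oracle, permutation null, filtering."""

import itertools

import numpy as np
import pandas as pd
import pytest

import coexnet as cx
from _oracles import naive_enrichment_score
from conftest import planted_cohort, planted_module


def make_profile(genes, scores, query="Q"):
    s = pd.Series(np.asarray(scores, float), index=genes)
    s = s.sort_values(ascending=False, kind="stable")
    return cx.RankedProfile(query=query, scores=s)


@pytest.fixture(scope="module")
def ten_gene_profile():
    return make_profile([f"G{i}" for i in range(10)], np.arange(10.0, 0.0, -1.0))


class TestRankProfile:
    def test_identical_gene_ranks_first_with_score_one(self):
        rng = np.random.default_rng(0)
        base = rng.gamma(2.0, 30.0, size=(5, 20))
        base[1] = base[0]  # G1 identical to the query G0
        m = cx.ExpressionMatrix(
            values=pd.DataFrame(base, index=[f"G{i}" for i in range(5)],
                                columns=[f"s{j}" for j in range(20)]),
            unit="TPM",
        )
        prof = cx.rank_profile([m], "G0")
        assert prof.genes[0] == "G1"
        assert prof.scores.iloc[0] == pytest.approx(1.0)

    def test_score_is_mean_of_per_cohort_correlations(self):
        rng = np.random.default_rng(1)
        cohorts = []
        for seed in (1, 2):
            data = np.random.default_rng(seed).gamma(2.0, 30.0, size=(6, 25))
            cohorts.append(cx.ExpressionMatrix(
                values=pd.DataFrame(data, index=[f"G{i}" for i in range(6)],
                                    columns=[f"c{seed}s{j}" for j in range(25)]),
                unit="TPM", cohort_id=f"c{seed}",
            ))
        prof = cx.rank_profile(cohorts, "G0")
        # independent recomputation of the averaged correlation for G3
        rs = []
        for m in cohorts:
            X = np.log2(m.values.to_numpy() + 1)
            rs.append(np.corrcoef(X[0], X[3])[0, 1])
        assert prof.scores["G3"] == pytest.approx(np.mean(rs), abs=1e-12)

    def test_query_excluded_from_entries(self):
        cohort = planted_cohort(seed=3, n_samples=50)
        prof = cx.rank_profile([cohort], "MOD0")
        assert "MOD0" not in prof.genes

    def test_module_co_members_occupy_top_ranks(self, module_genes):
        hits = 0
        for seed in range(5):
            prof = cx.rank_profile([planted_cohort(seed=seed)], "MOD0")
            top = set(prof.genes[:7])
            hits += top == set(module_genes) - {"MOD0"}
        assert hits >= 4

    def test_missing_query_names_cohort(self):
        cohort = planted_cohort(seed=1, n_samples=20)
        with pytest.raises(KeyError, match="SIM"):
            cx.rank_profile([cohort], "ABSENT")

    def test_mean_expression_mode(self):
        cohort = planted_cohort(seed=1, n_samples=30)
        prof = cx.rank_profile([cohort], "MOD0", profile_mode="mean_expression")
        X = np.log2(cohort.values.to_numpy() + 1)
        means = pd.Series(X.mean(axis=1), index=cohort.genes).drop("MOD0")
        assert prof.scores.idxmax() == means.idxmax()


class TestEnrichmentScore:
    def test_singleton_top_gene_gives_es_one(self, ten_gene_profile):
        out = cx.enrichment_score(ten_gene_profile, {"G0"}, weight_p=1)
        assert out.es == pytest.approx(1.0)
        assert out.leading_edge == ["G0"]

    def test_matches_step_by_step_oracle_top_set(self, ten_gene_profile):
        out = cx.enrichment_score(ten_gene_profile, {"G0", "G1", "G2"})
        scores = ten_gene_profile.scores.to_numpy()
        hit = np.array([g in {"G0", "G1", "G2"} for g in ten_gene_profile.genes])
        es, running = naive_enrichment_score(scores, hit)
        assert out.es == pytest.approx(es, abs=1e-12)
        np.testing.assert_allclose(out.running_sum, running, atol=1e-12)

    def test_bottom_set_has_negative_es(self, ten_gene_profile):
        out = cx.enrichment_score(ten_gene_profile, {"G7", "G8", "G9"})
        assert out.es < 0

    def test_all_subsets_match_oracle(self, ten_gene_profile):
        genes = ten_gene_profile.genes
        scores = ten_gene_profile.scores.to_numpy()
        for subset in itertools.combinations(genes, 3):
            out = cx.enrichment_score(ten_gene_profile, set(subset))
            hit = np.array([g in set(subset) for g in genes])
            es, _ = naive_enrichment_score(scores, hit)
            assert out.es == pytest.approx(es, abs=1e-12)

    def test_empty_intersection_rejected(self, ten_gene_profile):
        with pytest.raises(ValueError, match="no overlap"):
            cx.enrichment_score(ten_gene_profile, {"NOPE"})

    def test_whole_universe_rejected(self, ten_gene_profile):
        with pytest.raises(ValueError, match="universe"):
            cx.enrichment_score(ten_gene_profile, set(ten_gene_profile.genes))

    def test_complement_sign_flip_at_weight_zero(self, ten_gene_profile):
        """With p=0 the running sum of a set is the negative of its
        complement's, so the ES signs are opposite."""
        subset = {"G0", "G3", "G5"}
        complement = set(ten_gene_profile.genes) - subset
        a = cx.enrichment_score(ten_gene_profile, subset, weight_p=0)
        b = cx.enrichment_score(ten_gene_profile, complement, weight_p=0)
        assert a.es * b.es < 0

    def test_promoting_a_hit_never_decreases_positive_es_unweighted(self):
        """Enumeration on 10-gene lists: with equal hit weights (p=0) the
        running sum is pointwise monotone under promoting a hit, so a
        positive ES never decreases.  (With score weighting, promotion
        changes the hit weights and the property does not hold.)"""
        genes = [f"G{i}" for i in range(10)]
        scores = np.arange(10.0, 0.0, -1.0)
        prof = make_profile(genes, scores)
        for positions in itertools.combinations(range(10), 3):
            subset = {genes[i] for i in positions}
            es = cx.enrichment_score(prof, subset, weight_p=0).es
            if es <= 0:
                continue
            for i in positions:
                for up in range(i):
                    if up in positions:
                        continue
                    moved = (set(positions) - {i}) | {up}
                    es_moved = cx.enrichment_score(
                        prof, {genes[j] for j in moved}, weight_p=0
                    ).es
                    assert es_moved >= es - 1e-12

    def test_fast_path_matches_full_path(self, rng):
        """The O(k) permutation kernel agrees with the full running sum."""
        from coexnet.enrichment import _es_from_positions

        n = 80
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        prof = make_profile([f"G{i}" for i in range(n)], scores)
        abs_w = np.abs(prof.scores.to_numpy())
        for _ in range(50):
            k = int(rng.integers(2, 20))
            pos = np.sort(rng.choice(n, size=k, replace=False))
            subset = {prof.genes[i] for i in pos}
            full = cx.enrichment_score(prof, subset).es
            fast = _es_from_positions(abs_w, pos, n)
            assert fast == pytest.approx(full, abs=1e-12)


class TestNesAndFdr:
    @pytest.fixture(scope="class")
    def planted_run(self):
        cohort = planted_cohort(seed=4)
        prof = cx.rank_profile([cohort], "MOD0")
        coll = cx.generate_gene_sets(
            [planted_module()], n_random_sets=15, set_size=10,
            universe=prof.genes, seed=4,
        )
        return prof, coll

    def test_seeded_determinism(self, planted_run):
        prof, coll = planted_run
        a = cx.nes_and_fdr(prof, coll, n_permutations=200, seed=11)
        b = cx.nes_and_fdr(prof, coll, n_permutations=200, seed=11)
        assert [(r.name, r.nes, r.fdr_q) for r in a] == [
            (r.name, r.nes, r.fdr_q) for r in b
        ]

    def test_planted_module_set_tops_ranking(self, planted_run):
        prof, coll = planted_run
        res = cx.nes_and_fdr(prof, coll, n_permutations=500, seed=11)
        assert res[0].name == "MODULE_M1"
        assert res[0].nes >= 1.4
        assert res[0].fdr_q <= 0.05

    def test_too_few_permutations_rejected(self, planted_run):
        prof, coll = planted_run
        with pytest.raises(ValueError, match="100"):
            cx.nes_and_fdr(prof, coll, n_permutations=50, seed=1)

    def test_all_sets_get_q_values(self, planted_run):
        prof, coll = planted_run
        res = cx.nes_and_fdr(prof, coll, n_permutations=200, seed=3)
        assert len(res) == len(coll)
        assert all(0.0 <= r.fdr_q <= 1.0 for r in res)
        assert all(0.0 <= r.nominal_p <= 1.0 for r in res)


class TestFilterResults:
    def fake(self, name, nes, q):
        return cx.EnrichmentResult(
            name=name, es=np.sign(nes), nes=nes, nominal_p=0.01, fdr_q=q,
            n_hits_in_universe=5,
        )

    def test_permissive_cutoffs_keep_everything(self):
        res = [self.fake("a", 0.5, 0.9), self.fake("b", -2.0, 0.5)]
        assert len(cx.filter_results(res, nes_cutoff=0, fdr_cutoff=1)) == 2

    def test_infinite_cutoff_empties(self):
        res = [self.fake("a", 3.0, 0.0)]
        assert cx.filter_results(res, nes_cutoff=np.inf, fdr_cutoff=1) == []

    def test_exact_threshold_recount(self):
        res = [
            self.fake("pass_hi", 2.0, 0.01),
            self.fake("pass_neg", -1.5, 0.04),
            self.fake("fail_nes", 1.2, 0.01),
            self.fake("fail_q", 1.9, 0.2),
        ]
        kept = cx.filter_results(res, nes_cutoff=1.4, fdr_cutoff=0.05)
        assert [r.name for r in kept] == ["pass_hi", "pass_neg"]

    def test_results_frame_columns(self):
        frame = cx.results_to_frame([self.fake("a", 1.0, 0.1)])
        assert list(frame.columns) == [
            "set", "ES", "NES", "nominal_p", "fdr_q", "n_hits", "leading_edge"
        ]


class TestRnkRoundTrip:
    def test_profile_rnk_round_trip(self, tmp_path, ten_gene_profile):
        path = tmp_path / "profile.rnk"
        ten_gene_profile.to_rnk(path)
        back = cx.RankedProfile.from_rnk(path, query="Q")
        assert back.genes == ten_gene_profile.genes
        np.testing.assert_allclose(
            back.scores.to_numpy(), ten_gene_profile.scores.to_numpy()
        )
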