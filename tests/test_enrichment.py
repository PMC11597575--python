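"""Logistic enrichment: signed score, IRLS vs oracles, Firth, rankings."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

import coldseq as cs
from coldseq.containers import ConfigError, GOAnnotation, GOTerm
from coldseq.enrichment import fit_logistic_enrichment


def brute_force_logit(x, y):
    """Independent ML oracle: dense grid + Nelder-Mead/BFGS polish."""
    X = np.column_stack([np.ones_like(x), x])

    def nll(b):
        eta = np.clip(X @ b, -500, 500)
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    grid = np.linspace(-5, 5, 41)
    best, best_v = None, np.inf
    for b0 in grid:
        for b1 in grid:
            v = nll(np.array([b0, b1]))
            if v < best_v:
                best, best_v = np.array([b0, b1]), v
    r = minimize(nll, best, method="Nelder-Mead",
                 options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    r = minimize(nll, r.x, method="BFGS", options={"gtol": 1e-12})
    return r.x


def random_logit_fixture(rng, n_max=50):
    """Non-separated random fixture (redraws until the plain fit is stable)."""
    while True:
        n = int(rng.integers(15, n_max + 1))
        x = rng.normal(0, 2, n)
        b0, b1 = rng.normal(0, 0.8, 2)
        y = rng.binomial(1, expit(b0 + b1 * x)).astype(float)
        if y.sum() < 2 or y.sum() > n - 2:
            continue
        rec = fit_logistic_enrichment(x, {i for i in range(n) if y[i]},
                                      gene_ids=list(range(n)))
        if rec.fit_method == "irls" and rec.converged and abs(rec.beta1) < 10:
            return x, y, rec


class TestSignedScore:
    @pytest.mark.parametrize("logfc,fdr,expect", [
        (2.0, 0.01, 2.0),
        (-1.3, 0.001, -3.0),
        (5.0, 1.0, 0.0),
        (0.0, 0.001, 0.0),
    ])
    def test_values(self, logfc, fdr, expect):
        assert cs.signed_score(logfc, fdr) == pytest.approx(expect)

    def test_floor_keeps_score_finite(self):
        assert cs.signed_score(1.0, 0.0) == pytest.approx(300.0)

    def test_out_of_range_fdr_rejected(self):
        with pytest.raises(ConfigError):
            cs.signed_score(1.0, 1.5)


class TestLogisticFit:
    def test_matches_statsmodels_logit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2, 400)
        y = rng.binomial(1, expit(-1.0 + 0.5 * x)).astype(float)
        rec = fit_logistic_enrichment(x, {i for i in range(400) if y[i]},
                                      gene_ids=list(range(400)))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert rec.beta0 == pytest.approx(ref.params[0], abs=1e-8)
        assert rec.beta1 == pytest.approx(ref.params[1], abs=1e-8)
        assert rec.se1 == pytest.approx(ref.bse[1], rel=1e-6)

    def test_matches_brute_force_on_small_fixtures(self):
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(25):
            x, y, rec = random_logit_fixture(rng)
            oracle = brute_force_logit(x, y)
            worst = max(worst, abs(rec.beta0 - oracle[0]), abs(rec.beta1 - oracle[1]))
        assert worst < 1e-6

    def test_separation_triggers_finite_firth(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 60)
        rec = fit_logistic_enrichment(x, {i for i in range(60) if x[i] > 0},
                                      gene_ids=list(range(60)))
        assert rec.fit_method == "firth"
        assert np.isfinite(rec.score) and rec.score > 0
        assert 0 < rec.p_enrich <= 1

    def test_antisymmetry_under_score_negation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 2, 200)
        y = rng.binomial(1, expit(0.3 * x - 0.5)).astype(float)
        members = {i for i in range(200) if y[i]}
        a = fit_logistic_enrichment(x, members, gene_ids=list(range(200)))
        b = fit_logistic_enrichment(-x, members, gene_ids=list(range(200)))
        assert b.beta1 == pytest.approx(-a.beta1, abs=1e-8)
        assert b.p_enrich == pytest.approx(a.p_enrich, rel=1e-8)
        assert b.score == pytest.approx(-a.score, abs=1e-8)

    def test_null_rejection_rate(self):
        # balanced random membership independent of x
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(0, 2, 1000)
            y = rng.permutation(np.repeat([0.0, 1.0], 500))
            rec = fit_logistic_enrichment(x, {i for i in range(1000) if y[i]},
                                          gene_ids=list(range(1000)))
            hits += rec.p_enrich < 0.05
        assert abs(hits / n_rep - 0.05) <= 0.02 + 1e-12

    def test_degenerate_membership_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ConfigError):
            fit_logistic_enrichment(x, set(), gene_ids=list(range(10)))
        with pytest.raises(ConfigError):
            fit_logistic_enrichment(x, set(range(10)), gene_ids=list(range(10)))


@pytest.fixture(scope="module")
def planted_run(small_sim):
    _, cm, truth = small_sim
    de = cs.nb_exact_test(cm, "22C", "0C")
    ann, truth2 = cs.generate_go_annotation(
        truth, n_terms=80, size_range=(20, 100), planted_fraction=0.05,
        planted_strength=1.5, seed=31, condition="0C", planted_direction="up",
    )
    return de, ann, truth2


class TestEnrichAll:
    def test_empty_annotation_gives_empty_table(self, de_0c):
        res = cs.enrich_all(de_0c, GOAnnotation([]))
        assert res.frame.empty

    def test_whole_universe_term_skipped(self, de_0c):
        whole = GOTerm("GO:all", frozenset(de_0c.frame.index))
        tiny = GOTerm("GO:tiny", frozenset(de_0c.frame.index[:2]))
        ok = GOTerm("GO:ok", frozenset(de_0c.frame.index[:40]))
        res = cs.enrich_all(de_0c, GOAnnotation([whole, tiny, ok]))
        assert [t for t, _ in res.skipped] == ["GO:all", "GO:tiny"]
        assert list(res.frame["term_id"]) == ["GO:ok"]

    def test_planted_term_outscores_null_terms(self, planted_run):
        de, ann, truth2 = planted_run
        res = cs.enrich_all(de, ann)
        f = res.frame.set_index("term_id")
        planted = truth2.terms["term_id"].tolist()
        null_scores = f.drop(index=planted)["score"]
        for t in planted:
            assert f.at[t, "score"] > np.quantile(null_scores, 0.95)

    def test_score_definition_holds(self, planted_run):
        de, ann, _ = planted_run
        f = cs.enrich_all(de, ann).frame
        assert np.allclose(np.abs(f["score"]), -np.log10(f["p_enrich"]))
        nz = f["beta1"] != 0
        assert (np.sign(f.loc[nz, "score"]) == np.sign(f.loc[nz, "beta1"])).all()

    def test_monotone_in_planted_strength(self, small_sim):
        _, cm, truth = small_sim
        de = cs.nb_exact_test(cm, "22C", "0C")
        medians = []
        for strength in (0.5, 1.5):
            scores = []
            for seed in range(4):
                ann, truth2 = cs.generate_go_annotation(
                    truth, n_terms=10, size_range=(30, 80), planted_fraction=0.3,
                    planted_strength=strength, seed=100 + seed, condition="0C",
                    planted_direction="up",
                )
                f = cs.enrich_all(de, ann).frame.set_index("term_id")
                scores.extend(f.loc[truth2.terms["term_id"], "score"])
            medians.append(np.median(scores))
        assert medians[1] >= medians[0]


class TestHeatmapAndTopBP:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["term_id", "name", "namespace", "score"])

    def test_single_condition_matrix_equals_scores(self):
        t = self._table([("GO:1", "", "BP", 2.0), ("GO:2", "", "BP", -1.0)])
        mat = cs.enrichment_heatmap_matrix({"0C": t})
        assert mat.loc["GO:1", "0C"] == 2.0
        assert mat.loc["GO:2", "0C"] == -1.0

    def test_absent_term_filled_with_zero(self):
        a = self._table([("GO:1", "", "BP", 2.0)])
        b = self._table([("GO:2", "", "BP", 3.0)])
        mat = cs.enrichment_heatmap_matrix({"a": a, "b": b})
        assert mat.loc["GO:1", "b"] == 0.0
        assert mat.loc["GO:2", "a"] == 0.0

    def test_namespace_filter(self):
        t = self._table([("GO:1", "", "BP", 2.0), ("GO:2", "", "CC", 5.0)])
        mat = cs.enrichment_heatmap_matrix({"a": t}, namespace="BP")
        assert list(mat.index) == ["GO:1"]

    def test_planted_terms_share_sign_across_nested_conditions(self):
        cfg = cs.SimConfig(n_genes=1500, conditions=("c", "t1", "t2"),
                           de_fraction_per_condition=0.25, nested_effects=True,
                           lib_size_mean=8e5, seed=41)
        cm, truth = cs.generate_counts(cfg)
        ann, truth2 = cs.generate_go_annotation(
            truth, n_terms=20, size_range=(30, 80), planted_fraction=0.2,
            planted_strength=2.0, seed=42, condition="t2", planted_direction="up",
        )
        tables = {t: cs.enrich_all(cs.nb_exact_test(cm, "c", t), ann) for t in ("t1", "t2")}
        mat = cs.enrichment_heatmap_matrix(tables)
        planted = truth2.terms["term_id"]
        assert (mat.loc[planted].to_numpy() > 0).all()

    def test_top_bp_ordering_and_flags(self):
        t = self._table([
            ("GO:b", "", "BP", 3.0), ("GO:a", "", "BP", 3.0), ("GO:c", "", "BP", 1.0),
            ("GO:d", "", "BP", -2.0), ("GO:e", "", "CC", 9.0),
        ])
        ids, complete = cs.top_bp(t, k=3, direction="induced")
        assert ids == ["GO:a", "GO:b", "GO:c"]
        assert complete
        ids, complete = cs.top_bp(t, k=3, direction="repressed")
        assert ids == ["GO:d"] and not complete

    def test_top_bp_agrees_with_full_sort_oracle(self):
        rng = np.random.default_rng(9)
        rows = [(f"GO:{i}", "", "BP", s) for i, s in enumerate(rng.normal(0, 2, 60))]
        t = self._table(rows)
        ids, _ = cs.top_bp(t, k=5, direction="induced")
        expect = t[t["score"] > 0].sort_values(
            ["score", "term_id"], ascending=[False, True])["term_id"].head(5).tolist()
        assert ids == expect

    def test_all_negative_induced_is_empty_with_flag(self):
        t = self._table([("GO:1", "", "BP", -1.0)])
        ids, complete = cs.top_bp(t, k=5, direction="induced")
        assert ids == [] and not complete
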