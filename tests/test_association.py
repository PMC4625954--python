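"""Predictive R2, cluster-wise expression, region correlations, enrichment."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cgimeth import (compare_cluster_expression, cross_condition_concordance,
                     predictive_r2, tf_enrichment)


def test_noiseless_linear_relation_scores_near_one():
    rng = np.random.default_rng(0)
    X = rng.random((100, 1))
    y = 3.0 - 2.0 * X[:, 0]
    res = predictive_r2(y, X, model="ols_mean", cv_repeats=5, seed=1)
    assert res.score >= 0.99
    lasso = predictive_r2(y, np.hstack([X, rng.random((100, 5))]),
                          model="lasso_full", cv_repeats=3, seed=1)
    assert lasso.score >= 0.98


def test_null_predictors_score_near_zero():
    rng = np.random.default_rng(3)
    scores = []
    for _ in range(20):
        X = rng.random((80, 15))
        y = rng.normal(size=80)
        scores.append(predictive_r2(y, X, model="lasso_full",
                                    cv_repeats=5, seed=7).score)
    assert np.mean(scores) <= 0.05


def test_affine_invariance_of_score():
    rng = np.random.default_rng(5)
    X = rng.random((60, 8))
    y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(0, 0.1, 60)
    a = predictive_r2(y, X, model="lasso_full", cv_repeats=4, seed=9).score
    b = predictive_r2(5.0 * y - 7.0, X, model="lasso_full", cv_repeats=4, seed=9).score
    assert a == pytest.approx(b, abs=1e-9)


def test_score_reproducible_under_seed():
    rng = np.random.default_rng(8)
    X = rng.random((40, 6))
    y = X[:, 1] + rng.normal(0, 0.3, 40)
    s1 = predictive_r2(y, X, model="ridge_full", cv_repeats=3, seed=4).score
    s2 = predictive_r2(y, X, model="ridge_full", cv_repeats=3, seed=4).score
    assert s1 == s2


def test_constant_expression_flagged_zero():
    X = np.random.default_rng(0).random((30, 4))
    res = predictive_r2(np.full(30, 2.0), X, cv_repeats=2, seed=0)
    assert res.score == 0.0 and res.flagged


def test_too_few_samples_rejected():
    with pytest.raises(ValueError):
        predictive_r2(np.arange(5.0), np.arange(5.0)[:, None], cv_repeats=1)
    with pytest.raises(ValueError):
        predictive_r2(np.arange(20.0), np.arange(19.0)[:, None], cv_repeats=1)


def test_sparse_effect_favors_lasso_over_mean():
    """Two effect probes among 25, neighbors canceling in the mean."""
    rng = np.random.default_rng(11)
    wins = 0
    n_genes = 20
    for g in range(n_genes):
        X = rng.uniform(0.2, 0.8, size=(100, 25))
        y = 5.0 - 2.0 * X[:, 3] - 2.0 * X[:, 17] + rng.normal(0, 0.25, 100)
        full = predictive_r2(y, X, model="lasso_full", cv_repeats=3, seed=g).score
        mean = predictive_r2(y, X.mean(axis=1, keepdims=True),
                             model="ols_mean", cv_repeats=3, seed=g).score
        wins += full > mean
    assert wins >= 0.9 * n_genes


def test_compare_cluster_expression_planted_repression(small_cohort):
    c = small_cohort
    labels = {}
    for g, a in c.truth.archetype_per_cgi.items():
        labels[g] = {"cluster1": 1, "cluster2": 2,
                     "cluster3up": 3, "cluster3down": 3}[a]
    sub = {g: ("3up" if c.truth.archetype_per_cgi[g] == "cluster3up" else
               "3down" if c.truth.archetype_per_cgi[g] == "cluster3down" else "none")
           for g in labels}
    dists, pmat = compare_cluster_expression(c.expr_cancer, c.manifest.genes,
                                             labels, sub)
    assert np.median(dists["cluster3up"]) < np.median(dists["cluster1"])
    assert pmat.loc["cluster3up", "cluster1"] < 0.05
    assert "ref" in dists and len(dists["ref"]) == len(c.expr_cancer)


def test_identical_groups_give_high_p():
    expr = pd.DataFrame({"s1": np.arange(10.0), "s2": np.arange(10.0)},
                        index=[f"G{i}" for i in range(10)])
    ann = pd.DataFrame({"gene_id": expr.index, "chrom": "chr1",
                        "tss": 0, "strand": "+",
                        "cgi_ids": [f"C{i % 2}" for i in range(10)]})
    # two interleaved groups drawn from the same values
    labels = {"C0": 1, "C1": 2}
    _, pmat = compare_cluster_expression(expr, ann, labels)
    assert pmat.loc["cluster1", "cluster2"] > 0.5


def test_concordance_identity_and_scale_shift():
    a = pd.Series(np.random.default_rng(0).random(50),
                  index=[f"G{i}" for i in range(50)])
    r2, _ = cross_condition_concordance(a, a)
    assert r2 == pytest.approx(1.0)
    r2b, _ = cross_condition_concordance(a, 2.0 * a + 1.0)
    assert r2b == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cross_condition_concordance(a.iloc[:2], a.iloc[:2])


def test_concordance_independent_scores_near_zero():
    rng = np.random.default_rng(1)
    idx = [f"G{i}" for i in range(500)]
    vals = []
    for rep in range(20):
        a = pd.Series(rng.random(500), index=idx)
        b = pd.Series(rng.random(500), index=idx)
        vals.append(cross_condition_concordance(a, b)[0])
    assert np.mean(vals) <= 0.02


def test_tf_enrichment_matches_hypergeometric_tail():
    universe = [f"G{i}" for i in range(2374)]
    tfs = set(universe[:100])
    top = universe[:10] + universe[200:240]  # 10 TFs among 50 picked
    out = tf_enrichment(top, tfs, universe)
    expected_p = stats.hypergeom.sf(10 - 1, 2374, 100, 50)
    assert out["p_value"] == pytest.approx(expected_p, rel=1e-9)
    assert out["table"][0][0] == 10


def test_tf_enrichment_degenerate_full_list():
    universe = [f"G{i}" for i in range(50)]
    out = tf_enrichment(universe[:10], set(universe), universe)
    assert out["p_value"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        tf_enrichment([], set(), [])


def test_closest_tss_rule_for_multi_cgi_genes():
    """Genes linked to several CGI+SS are scored on the island whose
    midpoint is nearest their TSS."""
    from cgimeth import SimConfig, build_profiles, generate_manifest
    from cgimeth.association import closest_profile

    cfg = SimConfig(n_cgi=30, multi_cgi_fraction=0.5, seed=17)
    manifest = generate_manifest(cfg)
    # profiles without the 20-probe filter so every CGI is available
    beta = pd.DataFrame(0.5, index=manifest.probes["probe_id"],
                        columns=["S0", "S1"])
    profiles = build_profiles(beta, manifest.probes,
                              islands=manifest.islands, min_probes=1)
    by_cgi = {p.cgi_id: p for p in profiles}
    multi = manifest.genes[manifest.genes["cgi_ids"].str.contains(";")]
    assert len(multi) > 0
    for _, gene in multi.iterrows():
        linked = gene["cgi_ids"].split(";")
        chosen = closest_profile(linked, by_cgi, int(gene["tss"]))
        dists = {c: abs(sum(by_cgi[c].island) / 2 - gene["tss"])
                 for c in linked if c in by_cgi}
        assert chosen.cgi_id == min(sorted(dists), key=lambda c: dists[c])
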