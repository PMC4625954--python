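"""Generator contracts: manifest geometry, planted structure, determinism."""
import numpy as np
import pandas as pd
import pytest

from cgimeth import SimConfig, generate_manifest, simulate_cohort, simulate_methylation
from cgimeth.synthetic import (CohortTruth, _label_region, cancer_sample_ids,
                               oriented_region, simulate_survival_table)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(archetype_fractions=(0.5, 0.5, 0.1, 0.1))
    with pytest.raises(ValueError):
        SimConfig(cimp_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_cgi=0)
    with pytest.raises(ValueError):
        SimConfig(effect_region="promoter")


def test_manifest_probe_geometry(small_cohort):
    """Positions strictly increase per CGI and region labels match distance
    from the island boundary."""
    m = small_cohort.manifest
    bounds = m.islands.set_index("cgi_id")
    for cgi_id, grp in m.probes.groupby("cgi_id"):
        pos = grp["pos"].to_numpy()
        assert (np.diff(pos) > 0).all()
        start, end = bounds.loc[cgi_id, ["start", "end"]]
        for p, region in zip(pos, grp["region"]):
            assert region == _label_region(p, start, end)


def test_manifest_exercises_probe_filter():
    cfg = SimConfig(n_cgi=60, probes_per_cgi_range=(10, 40), seed=3)
    m = generate_manifest(cfg)
    counts = m.probes["cgi_id"].value_counts()
    assert (counts < 20).any() and (counts >= 20).any()


def test_manifest_deterministic_under_seed():
    cfg = SimConfig(n_cgi=25, seed=9)
    m1, m2 = generate_manifest(cfg), generate_manifest(cfg)
    pd.testing.assert_frame_equal(m1.probes, m2.probes)
    pd.testing.assert_frame_equal(m1.genes, m2.genes)


def test_unknown_condition_rejected(small_config):
    m = generate_manifest(small_config)
    with pytest.raises(ValueError):
        simulate_methylation(m, small_config, "metastasis")


def test_betas_in_unit_interval(small_cohort):
    for beta in (small_cohort.beta_normal, small_cohort.beta_cancer):
        v = beta.to_numpy()
        assert ((v >= 0) & (v <= 1)).all()


def test_cimp_count_matches_fraction(small_cohort, small_config):
    expected = round(small_config.cimp_fraction * small_config.n_samples_cancer)
    assert len(small_cohort.truth.cimp_samples) == expected


def test_cimp_hypermethylation_planted(small_cohort):
    """Every island probe of a 3up CGI is higher in CIMP than non-CIMP tumors."""
    c = small_cohort
    up = [g for g, a in c.truth.archetype_per_cgi.items() if a == "cluster3up"]
    assert up, "fixture must contain 3up loci"
    cimp = sorted(c.truth.cimp_samples)
    non = [s for s in c.beta_cancer.columns if s not in c.truth.cimp_samples]
    probes = c.manifest.probes
    for g in up:
        isl = probes[(probes["cgi_id"] == g) & (probes["region"] == "island")]
        sub = c.beta_cancer.loc[isl["probe_id"]]
        assert (sub[cimp].mean(axis=1) > sub[non].mean(axis=1)).all()


def test_cluster1_island_below_shelf_in_normal(small_cohort):
    c = small_cohort
    probes = c.manifest.probes
    for g, a in c.truth.archetype_per_cgi.items():
        if a != "cluster1":
            continue
        grp = probes[probes["cgi_id"] == g]
        isl = grp.loc[grp["region"] == "island", "probe_id"]
        shelf = grp.loc[grp["region"].str.endswith("shelf"), "probe_id"]
        if len(isl) and len(shelf):
            assert (c.beta_normal.loc[isl].mean().mean()
                    < c.beta_normal.loc[shelf].mean().mean())


def test_low_baseline_for_3up_genes(small_cohort):
    """Genes linked to 3up loci are lowly expressed already in normal tissue."""
    c = small_cohort
    ann = c.manifest.genes.set_index("gene_id")
    up, c1 = [], []
    for gene_id in ann.index:
        cgi = ann.loc[gene_id, "cgi_ids"].split(";")[0]
        arche = c.truth.archetype_per_cgi[cgi]
        mean = c.expr_normal.loc[gene_id].mean()
        (up if arche == "cluster3up" else c1 if arche == "cluster1" else []).append(mean)
    assert np.mean(up) < np.mean(c1)


def test_effect_probes_belong_to_linked_cgi(small_cohort):
    c = small_cohort
    ann = c.manifest.genes.set_index("gene_id")
    probes = c.manifest.probes.set_index("probe_id")
    for gene_id, (probe_ids, weights) in c.truth.regulated_genes.items():
        assert len(probe_ids) == len(weights)
        assert all(w > 0 for w in weights)
        linked = set(ann.loc[gene_id, "cgi_ids"].split(";"))
        assert set(probes.loc[probe_ids, "cgi_id"]) <= linked


def test_single_probe_effect_correlation_limit():
    """One effect probe and vanishing noise: beta-expression correlation -> -1."""
    cfg = SimConfig(n_samples_normal=60, n_cgi=30, n_regulated_genes=2,
                    effect_probes_per_gene=1, expression_noise_sd=1e-6,
                    cnv_effect_size=0.0, seed=5)
    c = simulate_cohort(cfg)
    for gene_id, (probe_ids, _) in c.truth.regulated_genes.items():
        r = np.corrcoef(c.beta_normal.loc[probe_ids[0]],
                        c.expr_normal.loc[gene_id])[0, 1]
        assert r < -0.999


def test_seg_segments_partition_chromosomes(small_cohort):
    """Every TSS is covered by exactly one segment per sample."""
    seg = small_cohort.seg
    genes = small_cohort.manifest.genes
    for sample, grp in seg.groupby("sample"):
        for _, gene in genes.iterrows():
            segs = grp[grp["chrom"] == gene["chrom"]]
            hits = ((segs["start"] <= gene["tss"]) & (gene["tss"] < segs["end"])).sum()
            assert hits == 1
        break  # one sample suffices; construction is identical across samples


def test_survival_times_positive_and_censoring(small_cohort):
    clin = small_cohort.clinical
    assert (clin["time"] > 0).all()
    assert set(clin["event"].unique()) <= {0, 1}
    censored = clin[clin["event"] == 0]
    assert np.allclose(censored["time"], 5 * 365.25)


def test_equal_hazards_give_one_distribution():
    """With all hazard ratios 1 the strata share a survival law (KS test)."""
    from scipy.stats import ks_2samp
    rng = np.random.default_rng(0)
    strata = pd.Series(["low"] * 300 + ["intermediate"] * 300 + ["high"] * 300,
                       index=[f"P{i}" for i in range(900)])
    clin = simulate_survival_table(strata, {"low": 1.0, "intermediate": 1.0,
                                            "high": 1.0}, 0.18, np.inf, rng)
    t = clin.join(strata.rename("s"))
    p = ks_2samp(t.loc[t["s"] == "low", "time"],
                 t.loc[t["s"] == "intermediate", "time"]).pvalue
    assert p > 0.01


def test_oriented_region_reflects_on_minus_strand():
    assert oriented_region("S_shore", "+") == "S_shore"
    assert oriented_region("S_shore", "-") == "N_shore"
    assert oriented_region("N_shelf", "-") == "S_shelf"
    assert oriented_region("island", "-") == "island"


def test_cohort_bitwise_reproducible(small_config):
    c1 = simulate_cohort(small_config)
    c2 = simulate_cohort(small_config)
    pd.testing.assert_frame_equal(c1.beta_cancer, c2.beta_cancer)
    pd.testing.assert_frame_equal(c1.expr_normal, c2.expr_normal)
    pd.testing.assert_frame_equal(c1.seg, c2.seg)
    pd.testing.assert_frame_equal(c1.clinical, c2.clinical)
    assert c1.truth.to_json() == c2.truth.to_json()


def test_truth_json_roundtrip(small_cohort):
    text = small_cohort.truth.to_json()
    again = CohortTruth.from_json(text)
    assert again.to_json() == text
    assert again.cimp_samples == small_cohort.truth.cimp_samples
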