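"""Patient stratification, Kaplan-Meier/log-rank, and the Cox model."""
import numpy as np
import pandas as pd
import pytest

from cgimeth import cox_multivariate, km_logrank, stratify_patients
from cgimeth.synthetic import simulate_survival_table

from _oracles import cox_binary_mle


def _clin(time, event, **covs):
    n = len(time)
    base = {"time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int)}
    base.update(covs)
    return pd.DataFrame(base, index=[f"P{i}" for i in range(n)])


# --- stratification ---------------------------------------------------------

def test_stratify_recovers_cimp_membership(small_cohort, small_profiles):
    c = small_cohort
    sub = {g: ("3up" if a == "cluster3up" else "none")
           for g, a in c.truth.archetype_per_cgi.items()}
    res = stratify_patients(small_profiles, sub, list(c.beta_cancer.columns))
    high = set(res.strata[res.strata == "high"].index)
    cimp = c.truth.cimp_samples
    assert len(cimp & high) / len(cimp) >= 0.9
    assert set(res.strata.unique()) == {"low", "intermediate", "high"}


def test_stratify_order_invariant(small_cohort, small_profiles):
    c = small_cohort
    sub = {g: ("3up" if a == "cluster3up" else "none")
           for g, a in c.truth.archetype_per_cgi.items()}
    samples = list(c.beta_cancer.columns)
    a = stratify_patients(small_profiles, sub, samples).strata
    b = stratify_patients(small_profiles, sub, samples[::-1]).strata
    assert (a.loc[samples] == b.loc[samples]).all()


def test_stratify_requires_3up_and_samples(small_profiles):
    with pytest.raises(ValueError):
        stratify_patients(small_profiles, {}, ["a", "b", "c"])
    sub = {small_profiles[0].cgi_id: "3up"}
    with pytest.raises(ValueError):
        stratify_patients(small_profiles, sub, small_profiles[0].samples[:2])


def test_stratify_flags_degenerate_identical_samples(small_profiles):
    p = small_profiles[0]
    clone = type(p)(cgi_id=p.cgi_id, probe_ids=p.probe_ids,
                    positions=p.positions, regions=p.regions,
                    betas=pd.DataFrame(0.5, index=p.betas.index,
                                       columns=p.betas.columns),
                    island=p.island)
    res = stratify_patients([clone], {p.cgi_id: "3up"}, p.samples)
    assert res.degenerate


# --- Kaplan-Meier / log-rank ------------------------------------------------

def test_km_equals_empirical_survival_without_censoring():
    times = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.9])
    strata = pd.Series(["low"] * 8, index=[f"P{i}" for i in range(8)])
    out = km_logrank(strata, _clin(times, np.ones(8)))
    curve = out["curves"]["low"].set_index("time")["survival"]
    for t in times:
        assert curve.loc[t] == pytest.approx(np.mean(times > t))


def test_logrank_extreme_separation():
    rng = np.random.default_rng(0)
    t_a = rng.uniform(1, 10, 50)
    t_b = rng.uniform(20, 30, 50)
    strata = pd.Series(["low"] * 50 + ["high"] * 50,
                       index=[f"P{i}" for i in range(100)])
    out = km_logrank(strata, _clin(np.r_[t_a, t_b], np.ones(100)))
    assert out["logrank_p"] < 1e-4


def test_logrank_null_is_calibrated():
    """Equal hazards: log-rank p approximately uniform over repeats."""
    from scipy.stats import kstest
    rng = np.random.default_rng(12)
    ps = []
    for _ in range(100):
        t = rng.exponential(5.0, 60)
        strata = pd.Series(rng.choice(["low", "high"], 60),
                           index=[f"P{i}" for i in range(60)])
        ps.append(km_logrank(strata, _clin(t, np.ones(60)))["logrank_p"])
    assert kstest(ps, "uniform").pvalue > 0.01


def test_single_stratum_skips_test_and_flags_no_events():
    strata = pd.Series(["low"] * 5, index=[f"P{i}" for i in range(5)])
    out = km_logrank(strata, _clin(np.arange(1.0, 6.0), np.zeros(5)))
    assert "logrank_p" not in out
    assert out["flags"] == ["stratum low: no events"]


def test_window_recensors_late_events():
    strata = pd.Series(["low", "low", "high", "high"], index=list("abcd"))
    clin = pd.DataFrame({"time": [400.0, 3000.0, 500.0, 2500.0],
                         "event": [1, 1, 1, 1]}, index=list("abcd"))
    out = km_logrank(strata, clin, window_years=5.0)
    merged = pd.concat(out["curves"].values())
    assert merged["time"].max() <= 5 * 365.25


# --- Cox --------------------------------------------------------------------

def test_cox_binary_covariate_matches_partial_likelihood_oracle():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 2, 120)
    t = rng.exponential(1.0 / (0.2 * np.exp(np.log(2.5) * x)))
    t += rng.uniform(0, 1e-6, len(t))  # break ties
    strata = pd.Series(np.where(x == 1, "high", "low"),
                       index=[f"P{i}" for i in range(120)])
    clin = _clin(t, np.ones(120))
    fit = cox_multivariate(strata, clin).set_index("covariate")
    oracle = cox_binary_mle(t, np.ones(120, dtype=int), x)
    assert fit.loc["stratum_high", "coef"] == pytest.approx(oracle, abs=1e-6)


def test_cox_recovers_planted_hazard_ratio():
    rng = np.random.default_rng(21)
    strata = pd.Series(rng.choice(["low", "intermediate", "high"], 2000,
                                  p=[0.35, 0.35, 0.3]),
                       index=[f"P{i}" for i in range(2000)])
    clin = simulate_survival_table(strata, {"low": 1.0, "intermediate": 3.44,
                                            "high": 1.92}, 0.18, 5.0, rng)
    out = cox_multivariate(strata, clin).set_index("covariate")
    row = out.loc["stratum_intermediate"]
    assert row["HR_lower95"] <= 3.44 <= row["HR_upper95"]
    null_row = out.loc["node"]  # covariate with no planted effect
    assert null_row["HR_lower95"] <= 1.0 <= null_row["HR_upper95"]


def test_cox_flags_zero_event_level():
    """A factor level with no events mirrors the degenerate HR cell."""
    rng = np.random.default_rng(3)
    n = 120
    strata = pd.Series(["low"] * n, index=[f"P{i}" for i in range(n)])
    er = rng.integers(0, 2, n)
    her2 = np.zeros(n, dtype=int)
    her2[:10] = 1
    er[:10] = 0
    t = rng.exponential(5.0, n)
    event = np.ones(n, dtype=int)
    event[:10] = 0  # the -/+ level never has an event
    clin = _clin(t, event, ER=er, HER2=her2,
                 node=rng.integers(0, 2, n),
                 age=rng.normal(60, 10, n),
                 tumor_size=rng.normal(25, 5, n))
    out = cox_multivariate(strata, clin).set_index("covariate")
    row = out.loc["ER_HER2_-/+"]
    assert bool(row["degenerate"])
    assert row["HR_upper95"] == np.inf


def test_cox_rejects_collinear_design():
    rng = np.random.default_rng(5)
    n = 60
    strata = pd.Series(["low"] * 30 + ["high"] * 30,
                       index=[f"P{i}" for i in range(n)])
    age = rng.normal(60, 10, n)
    clin = _clin(rng.exponential(5.0, n), np.ones(n), age=age,
                 tumor_size=2.0 * age)  # perfectly collinear
    with pytest.raises(ValueError, match="singular"):
        cox_multivariate(strata, clin)
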