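"""CIMP-style patient stratification and survival analysis.

Cancer samples are represented by the vector of their per-CGI+SS mean beta
values over the cluster-3up loci, Ward-clustered (Euclidean: the vectors are
positionless means) and cut into three strata relabeled low / intermediate /
high by ascending grand mean methylation.  Prognostic value is assessed by
Kaplan-Meier curves with a k-group log-rank test and a multivariate Cox
proportional hazards model (Efron tie handling) with the clinical design:
stratum (reference low), combined (ER, HER2) factor (reference -/-), lymph
node (reference negative), age and tumor size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage

from .profiles import CGISSProfile

STRATA = ("low", "intermediate", "high")


@dataclass
class StratificationResult:
    table: pd.DataFrame        # sample x (per-3up-CGI means, stratum)
    strata: pd.Series          # sample -> low/intermediate/high
    degenerate: bool = False   # all samples identical: split is arbitrary


def stratify_patients(profiles: list[CGISSProfile], sublabels: dict[str, str],
                      samples: list[str], k: int = 3) -> StratificationResult:
    """Cluster cancer samples by their mean methylation over 3up CGI+SS."""
    up = [p for p in profiles if sublabels.get(p.cgi_id) == "3up"]
    if not up:
        raise ValueError("no CGI+SS labeled 3up")
    if len(samples) < k:
        raise ValueError(f"need >= {k} samples, got {len(samples)}")
    mat = pd.DataFrame({p.cgi_id: p.betas[samples].mean(axis=0) for p in up},
                       index=samples)
    degenerate = bool(np.allclose(mat.to_numpy().std(axis=0), 0.0))
    Z = linkage(mat.to_numpy(), method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    grand = mat.mean(axis=1).to_numpy()
    order = np.argsort([grand[raw == u].mean() for u in np.unique(raw)],
                       kind="stable")
    names = list(STRATA) if k == 3 else [f"stratum{i + 1}" for i in range(k)]
    mapping = {u: names[r] for r, u in zip(np.argsort(order), np.unique(raw))}
    strata = pd.Series([mapping[u] for u in raw], index=samples, name="stratum")
    table = mat.copy()
    table["stratum"] = strata
    return StratificationResult(table=table, strata=strata, degenerate=degenerate)


def km_logrank(strata: pd.Series, clinical: pd.DataFrame,
               window_years: float | None = None) -> dict:
    """Kaplan-Meier estimates per stratum and the k-group log-rank test.

    ``clinical`` must carry ``time`` (days) and ``event`` columns indexed by
    sample.  An optional administrative window re-censors events beyond
    ``window_years``.  Strata with no events are flagged; with a single
    stratum the test is skipped.
    """
    common = strata.index.intersection(clinical.index)
    df = clinical.loc[common, ["time", "event"]].copy()
    df["stratum"] = strata.loc[common]
    if window_years is not None:
        limit = window_years * 365.25
        beyond = df["time"] > limit
        df.loc[beyond, "time"] = limit
        df.loc[beyond, "event"] = 0
    curves = {}
    flags = []
    for name, grp in df.groupby("stratum", sort=False):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"], label=str(name))
        sf = kmf.survival_function_
        curves[str(name)] = pd.DataFrame({
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(),
        })
        if grp["event"].sum() == 0:
            flags.append(f"stratum {name}: no events")
    out = {"curves": curves, "flags": flags, "n": int(len(df))}
    if df["stratum"].nunique() >= 2:
        res = multivariate_logrank_test(df["time"], df["stratum"], df["event"])
        out["logrank_statistic"] = float(res.test_statistic)
        out["logrank_p"] = float(res.p_value)
    return out


_DEGENERATE_HR_CUTOFF = 50.0  # |log HR| beyond this marks a non-converged level


def cox_multivariate(strata: pd.Series, clinical: pd.DataFrame,
                     window_years: float | None = None) -> pd.DataFrame:
    """Multivariate Cox fit: hazard ratios, 95% Wald CIs and p-values.

    Design: stratum dummies (reference "low"), combined (ER, HER2) factor
    dummies (reference -/-), lymph node, age, tumor size.  Factor levels with
    no events cannot be estimated (the partial likelihood drives their
    coefficient to -inf); such rows are flagged ``degenerate`` with an
    infinite CI rather than raising.
    """
    common = strata.index.intersection(clinical.index)
    df = clinical.loc[common].copy()
    df["stratum"] = strata.loc[common]
    if window_years is not None:
        limit = window_years * 365.25
        beyond = df["time"] > limit
        df.loc[beyond, "time"] = limit
        df.loc[beyond, "event"] = 0

    design = pd.DataFrame(index=df.index)
    for s in STRATA[1:]:  # "low" is the reference level
        if (df["stratum"] == s).any():
            design[f"stratum_{s}"] = (df["stratum"] == s).astype(float)
    if {"ER", "HER2"} <= set(df.columns):
        er = df["ER"].astype(int)
        her2 = df["HER2"].astype(int)
        for e, h, name in ((1, 0, "+/-"), (0, 1, "-/+"), (1, 1, "+/+")):
            design[f"ER_HER2_{name}"] = ((er == e) & (her2 == h)).astype(float)
    if "node" in df.columns:
        design["node"] = df["node"].astype(float)
    for cov in ("age", "tumor_size"):
        if cov in df.columns:
            design[cov] = df[cov].astype(float)

    constant = [c for c in design.columns if design[c].nunique() <= 1]
    design = design.drop(columns=constant)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(f"singular design matrix (rank {rank} < "
                         f"{design.shape[1]} columns): {list(design.columns)}")

    # binary levels whose carriers have no events cannot be estimated: the
    # partial likelihood drives their coefficient to -inf
    zero_event = [c for c in design.columns
                  if set(design[c].unique()) <= {0.0, 1.0}
                  and df.loc[design[c] == 1.0, "event"].sum() == 0]

    fit_df = design.copy()
    fit_df["time"] = df["time"]
    fit_df["event"] = df["event"].astype(int)
    cph = CoxPHFitter()
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        cph.fit(fit_df, duration_col="time", event_col="event",
                show_progress=False)
    summ = cph.summary
    out = pd.DataFrame({
        "covariate": summ.index,
        "coef": summ["coef"].to_numpy(),
        "HR": summ["exp(coef)"].to_numpy(),
        "HR_lower95": summ["exp(coef) lower 95%"].to_numpy(),
        "HR_upper95": summ["exp(coef) upper 95%"].to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)
    out["degenerate"] = (np.abs(out["coef"]) > _DEGENERATE_HR_CUTOFF
                         ) | out["covariate"].isin(zero_event)
    out.loc[out["degenerate"], ["HR_lower95", "HR_upper95"]] = [0.0, np.inf]
    for c in constant:
        out.loc[len(out)] = [c, np.nan, np.nan, np.nan, np.nan, np.nan, True]
    return out
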