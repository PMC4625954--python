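"""Methylation-expression association.

The central quantity is the predictive goodness of fit R^2: the squared
Pearson correlation between held-out observations and cross-validated
predictions (3-fold CV averaged over repeats), which measures out-of-sample
explanatory power and is invariant to the scale of expression.  Models:

- ``ols_mean``   : univariate least squares on the CGI+SS-wide mean beta.
- ``lasso_full`` : lasso on all probe betas, penalty chosen by nested 3-fold
                   CV on a 50-point log-spaced path (lambda_max down to
                   lambda_max * 1e-4).
- ``ridge_full`` : ridge on all probe betas, same nested selection.
- ``ols_cnv``    : univariate least squares on the gene-level copy-number
                   log ratio.
- ``lasso_combined``: lasso on [probe betas | copy-number], all columns
                   standardized jointly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression, Ridge, lasso_path
from sklearn.model_selection import KFold

from .profiles import CGISSProfile
from .synthetic import oriented_region

MODELS = ("ols_mean", "lasso_full", "ridge_full", "ols_cnv", "lasso_combined")
MIN_SAMPLES = 12
N_ALPHAS = 50
ALPHA_EPS = 1e-4


@dataclass
class R2Result:
    score: float
    n_repeats: int
    n_anticorrelated: int = 0   # repeats where predictions anti-correlated
    n_constant: int = 0         # repeats with constant predictions (contribute 0)
    flagged: bool = False


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _lasso_path_alphas(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    yc = y - y.mean()
    alpha_max = np.max(np.abs(X.T @ yc)) / len(y)
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.geomspace(alpha_max, alpha_max * ALPHA_EPS, N_ALPHAS)


def _ridge_path_predict(Xa: np.ndarray, ya: np.ndarray, Xb: np.ndarray,
                        alphas: np.ndarray) -> np.ndarray:
    """Out-of-fold ridge predictions for every alpha via one SVD."""
    ym = ya.mean()
    U, s, Vt = np.linalg.svd(Xa, full_matrices=False)
    Uty = U.T @ (ya - ym)
    # coefs(alpha) = V diag(s/(s^2+alpha)) U^T y_c
    shrink = s[:, None] / (s[:, None] ** 2 + alphas[None, :])
    coefs = Vt.T @ (shrink * Uty[:, None])          # p x n_alphas
    return Xb @ coefs + ym                           # n_test x n_alphas


def _fit_penalized(X_tr: np.ndarray, y_tr: np.ndarray, kind: str,
                   inner_seed: int):
    """Choose the penalty on an inner 3-fold grid minimizing MSE, then refit.

    Lasso uses the coordinate-descent regularization path (warm starts);
    ridge evaluates the whole grid from a single SVD per inner fold.
    """
    if kind == "lasso":
        alphas = _lasso_path_alphas(X_tr, y_tr)
    else:
        alphas = np.geomspace(1e3, 1e-3, N_ALPHAS)
    inner = KFold(n_splits=3, shuffle=True, random_state=inner_seed)
    sse = np.zeros(len(alphas))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, te in inner.split(X_tr):
            Xa, Xb = _standardize(X_tr[tr], X_tr[te])
            ya = y_tr[tr]
            if kind == "lasso":
                ym = ya.mean()
                # check_input=False skips sklearn's per-alpha validation,
                # which dominates runtime at this problem size; inputs are
                # fresh float64 arrays in the required layout
                _, coefs, _ = lasso_path(np.asfortranarray(Xa), ya - ym,
                                         alphas=alphas, max_iter=2000,
                                         tol=1e-3, check_input=False)
                preds = Xb @ coefs + ym
            else:
                preds = _ridge_path_predict(Xa, ya, Xb, alphas)
            sse += np.sum((preds - y_tr[te][:, None]) ** 2, axis=0)
    best = float(alphas[int(np.argmin(sse))])
    if kind == "lasso":
        return Lasso(alpha=best, max_iter=5000, tol=1e-3)
    return Ridge(alpha=best)


def _fit_predict(X_tr, y_tr, X_te, model: str, inner_seed: int) -> np.ndarray:
    if model in ("ols_mean", "ols_cnv"):
        est = LinearRegression()
        Xa, Xb = X_tr, X_te
    elif model in ("lasso_full", "lasso_combined"):
        Xa, Xb = _standardize(X_tr, X_te)
        est = _fit_penalized(X_tr, y_tr, "lasso", inner_seed)
    elif model == "ridge_full":
        Xa, Xb = _standardize(X_tr, X_te)
        est = _fit_penalized(X_tr, y_tr, "ridge", inner_seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    return est.fit(Xa, y_tr).predict(Xb)


def predictive_r2(y: np.ndarray, X: np.ndarray, model: str = "lasso_full",
                  cv_folds: int = 3, cv_repeats: int = 100, seed: int = 0
                  ) -> R2Result:
    """Cross-validated predictive R^2 of one gene under one model.

    Each repeat draws a fresh random fold split; the per-repeat score is the
    squared Pearson correlation between the pooled out-of-fold predictions
    and the observations.  Constant predictions contribute 0; repeats whose
    predictions anti-correlate with the observations are squared as-is but
    counted, since a squared correlation cannot distinguish them.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != len(X):
        raise ValueError("sample mismatch between expression and predictors")
    if len(y) < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {len(y)}")
    if np.ptp(y) == 0:
        return R2Result(score=0.0, n_repeats=cv_repeats, flagged=True)
    rng = np.random.default_rng(seed)
    total, n_anti, n_const = 0.0, 0, 0
    for _ in range(cv_repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=rep_seed)
        pred = np.empty_like(y)
        for fold, (tr, te) in enumerate(kf.split(X)):
            pred[te] = _fit_predict(X[tr], y[tr], X[te], model,
                                    inner_seed=rep_seed + fold + 1)
        if np.ptp(pred) == 0:
            n_const += 1
            continue
        r = float(np.corrcoef(pred, y)[0, 1])
        if not np.isfinite(r):
            n_const += 1
            continue
        if r < 0:
            n_anti += 1
        total += r * r
    return R2Result(score=total / cv_repeats, n_repeats=cv_repeats,
                    n_anticorrelated=n_anti, n_constant=n_const,
                    flagged=n_const == cv_repeats)


# ---------------------------------------------------------------------------
# cohort-level scoring

def closest_profile(cgi_ids: list[str], profiles: dict[str, CGISSProfile],
                    tss: int) -> CGISSProfile | None:
    """Among a gene's linked CGI+SS, the one whose island midpoint is closest
    to the TSS (ties by cgi_id)."""
    cands = [profiles[c] for c in cgi_ids if c in profiles]
    cands = [p for p in cands if p.island is not None]
    if not cands:
        return None
    return min(cands, key=lambda p: (abs((p.island[0] + p.island[1]) / 2 - tss),
                                     p.cgi_id))


def score_all_genes(profiles: list[CGISSProfile], expression: pd.DataFrame,
                    annotation: pd.DataFrame, condition: str = "",
                    models: tuple[str, ...] = ("ols_mean", "lasso_full"),
                    gene_cnv: pd.DataFrame | None = None,
                    cv_folds: int = 3, cv_repeats: int = 100, seed: int = 0
                    ) -> tuple[pd.DataFrame, dict]:
    """One predictive score per gene with a >=20-probe CGI+SS.

    Returns a per-gene table of R^2 scores (one column per model, plus the
    chosen cgi_id) and a summary dict with the paired Wilcoxon signed-rank
    comparison of the full-profile vs mean-methylation scores across genes.
    """
    by_cgi = {p.cgi_id: p for p in profiles}
    if profiles:
        shared = [s for s in profiles[0].samples if s in expression.columns]
    else:
        shared = []
    if profiles and not shared:
        raise ValueError("no samples shared between beta and expression matrices")
    rows = []
    rng = np.random.default_rng(seed)
    for _, gene in annotation.iterrows():
        gene_id = gene["gene_id"]
        if gene_id not in expression.index:
            continue
        prof = closest_profile(str(gene["cgi_ids"]).split(";"), by_cgi,
                               int(gene["tss"]))
        if prof is None:
            continue
        y = expression.loc[gene_id, shared].to_numpy(dtype=float)
        B = prof.betas[shared].to_numpy(dtype=float).T  # samples x probes
        gene_seed = int(rng.integers(0, 2**31 - 1))
        row: dict = {"gene_id": gene_id, "condition": condition,
                     "cgi_id": prof.cgi_id, "n_probes": prof.n_probes}
        for model in models:
            if model == "ols_mean":
                Xm = B.mean(axis=1, keepdims=True)
            elif model in ("ols_cnv", "lasso_combined"):
                if gene_cnv is None or gene_id not in gene_cnv.index:
                    row[f"r2_{model}"] = np.nan
                    continue
                c = gene_cnv.loc[gene_id, shared].to_numpy(dtype=float)[:, None]
                Xm = c if model == "ols_cnv" else np.hstack([B, c])
            else:
                Xm = B
            res = predictive_r2(y, Xm, model=model, cv_folds=cv_folds,
                                cv_repeats=cv_repeats, seed=gene_seed)
            row[f"r2_{model}"] = res.score
            row[f"flag_{model}"] = res.flagged
        rows.append(row)
    scores = pd.DataFrame(rows)
    summary: dict = {"n_genes": len(scores)}
    if {"r2_ols_mean", "r2_lasso_full"} <= set(scores.columns) and len(scores) >= 10:
        diff = scores["r2_lasso_full"] - scores["r2_ols_mean"]
        if np.any(diff != 0):
            stat, p = stats.wilcoxon(scores["r2_lasso_full"], scores["r2_ols_mean"])
            summary["wilcoxon_full_vs_mean"] = {"statistic": float(stat),
                                                "p_value": float(p)}
    return scores, summary


def compare_cluster_expression(expression: pd.DataFrame, annotation: pd.DataFrame,
                               labels: dict[str, int],
                               sublabels: dict[str, str] | None = None
                               ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Expression distributions per CGI+SS cluster plus pairwise tests.

    Each gene contributes its mean expression across samples to the group of
    its (first linked) CGI+SS; "ref" is the genome-wide set.  Groups are
    compared by two-sided Mann-Whitney; groups with fewer than 2 genes are
    skipped (p = NaN).
    """
    gene_means = expression.mean(axis=1)
    groups: dict[str, list[float]] = {}
    for _, gene in annotation.iterrows():
        gene_id = gene["gene_id"]
        if gene_id not in gene_means.index:
            continue
        cgi = str(gene["cgi_ids"]).split(";")[0]
        if cgi not in labels:
            continue
        key = f"cluster{labels[cgi]}"
        groups.setdefault(key, []).append(float(gene_means[gene_id]))
        if sublabels and sublabels.get(cgi) in ("3up", "3down"):
            groups.setdefault(f"cluster{sublabels[cgi]}", []).append(
                float(gene_means[gene_id]))
    dists = {k: np.asarray(v) for k, v in sorted(groups.items())}
    dists["ref"] = gene_means.to_numpy(dtype=float)
    names = list(dists)
    pmat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if len(dists[a]) < 2 or len(dists[b]) < 2:
                continue
            p = stats.mannwhitneyu(dists[a], dists[b],
                                   alternative="two-sided").pvalue
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return dists, pmat


def region_correlations(top_genes: list[str], profiles: list[CGISSProfile],
                        expression: pd.DataFrame, annotation: pd.DataFrame,
                        scores: pd.DataFrame | None = None,
                        orient_by_strand: bool = True
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probewise beta-expression Pearson correlations pooled by region.

    For each top gene, correlations are computed across samples for every
    probe of its selected CGI+SS, then pooled by (optionally strand-oriented)
    region label.  Returns the per-probe table and a per-region summary with
    median and quartiles; constant-beta probes are excluded and counted.
    """
    if not top_genes:
        raise ValueError("top-gene list is empty")
    by_cgi = {p.cgi_id: p for p in profiles}
    chosen = (dict(zip(scores["gene_id"], scores["cgi_id"]))
              if scores is not None else {})
    ann = annotation.set_index("gene_id")
    rows = []
    n_constant = 0
    for gene_id in top_genes:
        if gene_id not in ann.index or gene_id not in expression.index:
            continue
        gene = ann.loc[gene_id]
        cgi_id = chosen.get(gene_id)
        prof = (by_cgi.get(cgi_id) if cgi_id
                else closest_profile(str(gene["cgi_ids"]).split(";"), by_cgi,
                                     int(gene["tss"])))
        if prof is None:
            continue
        shared = [s for s in prof.samples if s in expression.columns]
        y = expression.loc[gene_id, shared].to_numpy(dtype=float)
        B = prof.betas[shared].to_numpy(dtype=float)
        for probe_id, region, b in zip(prof.probe_ids, prof.regions, B):
            if np.ptp(b) == 0 or np.ptp(y) == 0:
                n_constant += 1
                continue
            r = float(np.corrcoef(b, y)[0, 1])
            label = oriented_region(region, gene["strand"]) if orient_by_strand else region
            rows.append({"gene_id": gene_id, "probe_id": probe_id,
                         "region": label, "correlation": r})
    table = pd.DataFrame(rows)
    summary = (table.groupby("region")["correlation"]
               .agg(median="median",
                    q1=lambda v: v.quantile(0.25),
                    q3=lambda v: v.quantile(0.75),
                    n="size")
               .reset_index())
    summary.attrs["n_constant_excluded"] = n_constant
    return table, summary


def cross_condition_concordance(scores_a: pd.Series, scores_b: pd.Series
                                ) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation of per-gene scores between two conditions."""
    common = scores_a.index.intersection(scores_b.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared genes")
    a = scores_a.loc[common].to_numpy(dtype=float)
    b = scores_b.loc[common].to_numpy(dtype=float)
    r = float(np.corrcoef(a, b)[0, 1])
    scatter = pd.DataFrame({"gene_id": common, "score_a": a, "score_b": b})
    return r * r, scatter


def tf_enrichment(top_genes: list[str], tf_list: set[str] | list[str],
                  universe: list[str]) -> dict:
    """One-sided Fisher exact test for transcription-factor over-representation."""
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    top = set(top_genes) & uni
    tfs = set(tf_list) & uni
    a = len(top & tfs)
    b = len(top - tfs)
    c = len(tfs - top)
    d = len(uni - top - tfs)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return {"table": [[a, b], [c, d]], "odds_ratio": float(odds),
            "p_value": float(p), "n_top": len(top), "n_tf": len(tfs),
            "n_universe": len(uni)}
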