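"""Gene-level copy number from SEG segments, and its predictive power.

Each gene's copy-number score in a sample is the segmented log2 ratio of the
segment containing its TSS.  SEG intervals are treated as 0-based half-open;
a TSS falling in a gap between segments is assigned the nearest segment
within 1Mb, else left missing (flagged).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

GAP_TOLERANCE_BP = 1_000_000


def gene_level_cnv(seg: pd.DataFrame, annotation: pd.DataFrame
                   ) -> pd.DataFrame:
    """Gene x sample table of segment means at each gene's TSS.

    Raises if two segments of one sample overlap a TSS; output column order
    follows the order samples first appear in the SEG table.
    """
    samples = list(dict.fromkeys(seg["sample"]))
    out = pd.DataFrame(np.nan, index=annotation["gene_id"].to_numpy(),
                       columns=samples)
    genes_by_chrom = {c: g for c, g in annotation.groupby("chrom")}
    for (sample, chrom), segs in seg.groupby(["sample", "chrom"], sort=False):
        if chrom not in genes_by_chrom:
            continue
        segs = segs.sort_values("start", kind="stable")
        starts = segs["start"].to_numpy()
        ends = segs["end"].to_numpy()
        means = segs["seg_mean"].to_numpy(dtype=float)
        if np.any(ends[:-1] > starts[1:]):
            bad = np.where(ends[:-1] > starts[1:])[0][0]
            raise ValueError(
                f"overlapping segments for {sample}/{chrom} near position "
                f"{starts[bad + 1]}")
        genes = genes_by_chrom[chrom]
        tss = genes["tss"].to_numpy()
        idx = np.searchsorted(starts, tss, side="right") - 1
        for g, t, i in zip(genes["gene_id"], tss, idx):
            if i >= 0 and starts[i] <= t < ends[i]:
                out.loc[g, sample] = means[i]
            else:  # gap: nearest segment within tolerance
                d_prev = t - ends[i] + 1 if i >= 0 else np.inf
                d_next = starts[i + 1] - t if i + 1 < len(starts) else np.inf
                d = min(d_prev, d_next)
                if d <= GAP_TOLERANCE_BP:
                    out.loc[g, sample] = means[i if d_prev <= d_next else i + 1]
    out.attrs["n_missing"] = int(out.isna().sum().sum())
    return out


def cnv_expression_scores(scores: pd.DataFrame) -> dict:
    """Independence and combined-model summaries from a per-gene score table.

    Expects columns ``r2_lasso_full``, ``r2_ols_cnv`` and optionally
    ``r2_lasso_combined`` (as produced by ``score_all_genes`` with the CNV
    models requested).  Returns the squared Pearson correlation between the
    methylation-only and CNV-only scores, and paired Wilcoxon tests of the
    combined model against each marginal.
    """
    need = {"r2_lasso_full", "r2_ols_cnv"}
    if not need <= set(scores.columns):
        raise ValueError(f"score table must contain columns {sorted(need)}")
    sub = scores.dropna(subset=sorted(need))
    meth = sub["r2_lasso_full"].to_numpy(dtype=float)
    cnv = sub["r2_ols_cnv"].to_numpy(dtype=float)
    r = float(np.corrcoef(meth, cnv)[0, 1]) if len(sub) >= 3 else np.nan
    out: dict = {"independence_r2": r * r if np.isfinite(r) else np.nan,
                 "n_genes": int(len(sub))}
    if "r2_lasso_combined" in scores.columns:
        both = scores.dropna(subset=["r2_lasso_combined", *sorted(need)])
        comb = both["r2_lasso_combined"].to_numpy(dtype=float)
        for name, marginal in (("meth", both["r2_lasso_full"]),
                               ("cnv", both["r2_ols_cnv"])):
            m = marginal.to_numpy(dtype=float)
            if len(both) >= 10 and np.any(comb != m):
                stat, p = stats.wilcoxon(comb, m)
                out[f"wilcoxon_combined_vs_{name}"] = {
                    "statistic": float(stat), "p_value": float(p)}
        out["frac_combined_ge_max_marginal"] = float(np.mean(
            comb >= np.maximum(both["r2_lasso_full"], both["r2_ols_cnv"]) - 0.02))
    return out
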