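"""End-to-end orchestration: simulate -> profiles -> clustering -> subclusters
-> association (with CNV) -> survival, with deterministic seeding and a run
manifest recording parameters, per-stage seeds and output hashes."""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, clustering, cnv as cnv_mod, survival as surv_mod
from .config import RunConfig
from .dtw import dissimilarity_matrix
from .io import write_table
from .profiles import build_profiles, mean_signature, standardize_axis
from .synthetic import simulate_cohort, write_cohort

log = logging.getLogger("cgimeth")

_STAGE_SEEDS = ("cluster_normal", "cluster_cancer", "associate_normal",
                "associate_cancer", "survival")


def _stage_seed(master: int, stage: str) -> int:
    child = np.random.SeedSequence(master).spawn(len(_STAGE_SEEDS))
    return int(np.random.default_rng(
        child[_STAGE_SEEDS.index(stage)]).integers(0, 2**31 - 1))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _island_means(profiles, signatures) -> np.ndarray:
    out = []
    for p, s in zip(profiles, signatures):
        mask = np.array([r == "island" for r in p.regions])
        out.append(float(np.mean(s.Y[mask])) if mask.any() else float(np.mean(s.Y)))
    return np.asarray(out)


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; returns the run manifest (also written
    to ``<out_dir>/run_manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_record = config.to_dict()
    cfg_record["out_dir"] = "."  # keep the manifest location-independent
    manifest: dict = {"config": cfg_record, "outputs": {}, "stages": []}

    if not config.simulate:
        raise NotImplementedError(
            "run_all currently starts from the synthetic generator; run the "
            "individual CLI stages to analyze externally supplied files")
    sim = config.sim
    if sim.seed != config.seed:
        sim = type(sim).from_dict({**sim.to_dict(), "seed": config.seed})
    log.info("simulate: n_cgi=%d samples=%d+%d seed=%d", sim.n_cgi,
             sim.n_samples_normal, sim.n_samples_cancer, sim.seed)
    cohort = simulate_cohort(sim)
    paths = write_cohort(cohort, out / "sim")
    manifest["outputs"].update({f"sim/{k}": _sha256(v) for k, v in paths.items()})
    manifest["stages"].append("simulate")

    if not config.run_profiles:
        _finish(manifest, out)
        return manifest
    profs = {}
    for cond, beta in (("normal", cohort.beta_normal), ("cancer", cohort.beta_cancer)):
        profs[cond] = build_profiles(beta, cohort.manifest.probes,
                                     annotation=cohort.manifest.genes,
                                     islands=cohort.manifest.islands,
                                     min_probes=config.min_probes)
        rows = [{"cgi_id": p.cgi_id, "n_probes": p.n_probes} for p in profs[cond]]
        p = write_table(pd.DataFrame(rows), out / f"profiles_{cond}.tsv")
        manifest["outputs"][f"profiles_{cond}.tsv"] = _sha256(p)
    log.info("profiles: retained %d (normal) / %d (cancer) CGI+SS",
             len(profs["normal"]), len(profs["cancer"]))
    manifest["stages"].append("profiles")

    assignments = {}
    if config.run_cluster:
        for cond, k_policy in (("normal", config.k_normal), ("cancer", config.k_cancer)):
            pl = profs[cond]
            sigs = [mean_signature(p, condition=cond) for p in pl]
            D = dissimilarity_matrix(sigs)
            ids = [p.cgi_id for p in pl]
            seed = _stage_seed(config.seed, f"cluster_{cond}")
            if k_policy == "auto":
                stab = clustering.bootstrap_stability(
                    D, range(2, 7), n_repeats=config.bootstrap_repeats,
                    subsample=config.bootstrap_subsample, seed=seed)
                k = stab.selected_k
                p = write_table(pd.DataFrame(
                    {"k": list(stab.scores), "stability": list(stab.scores.values())}),
                    out / f"stability_{cond}.tsv")
                manifest["outputs"][f"stability_{cond}.tsv"] = _sha256(p)
            else:
                k = int(k_policy)
            assignment = clustering.ward_cluster(
                D, k, cgi_ids=ids, island_means=_island_means(pl, sigs),
                condition=cond)
            assignments[cond] = assignment
            p = write_table(pd.DataFrame(D, index=ids, columns=ids),
                            out / f"dissimilarity_{cond}.tsv", index=True)
            manifest["outputs"][f"dissimilarity_{cond}.tsv"] = _sha256(p)
            p = write_table(pd.DataFrame(
                {"cgi_id": ids, "cluster": [assignment.labels[g] for g in ids]}),
                out / f"labels_{cond}.tsv")
            manifest["outputs"][f"labels_{cond}.tsv"] = _sha256(p)
            # condensed profiles: the 10 medoids per cluster on the
            # standardized CGI+SS axis
            medoids = clustering.medoid_profiles(D, assignment, ids)
            by_id = dict(zip(ids, zip(pl, sigs)))
            rows = []
            for cluster, members in medoids.items():
                for g in members:
                    prof, sig = by_id[g]
                    if prof.island is None:
                        continue
                    strand = (prof.linked_genes[0][2]
                              if prof.linked_genes else "+")
                    std = standardize_axis(sig, prof.island, strand)
                    rows.extend({"cluster": cluster, "cgi_id": g,
                                 "coord": x, "mean_beta": y}
                                for x, y in zip(std.X, std.Y))
            p = write_table(pd.DataFrame(rows),
                            out / f"condensed_profiles_{cond}.tsv")
            manifest["outputs"][f"condensed_profiles_{cond}.tsv"] = _sha256(p)
            log.info("cluster %s: k=%s sizes=%s", cond, k,
                     pd.Series(list(assignment.labels.values())).value_counts().to_dict())
        sub, table = clustering.derive_cancer_subclusters(
            assignments["normal"], assignments["cancer"])
        p = write_table(pd.DataFrame(
            {"cgi_id": sorted(sub), "sublabel": [sub[g] for g in sorted(sub)]}),
            out / "sublabels.tsv")
        manifest["outputs"]["sublabels.tsv"] = _sha256(p)
        p = write_table(table, out / "concordance_normal_cancer.tsv", index=True)
        manifest["outputs"]["concordance_normal_cancer.tsv"] = _sha256(p)
        manifest["stages"].append("cluster")

    if config.run_associate:
        models = list(config.models)
        gene_cnv = cohort.gene_cnv if config.run_cnv else None
        if config.run_cnv:
            for m in ("ols_cnv", "lasso_combined"):
                if m not in models:
                    models.append(m)
            p = write_table(cohort.gene_cnv, out / "gene_cnv.tsv", index=True)
            manifest["outputs"]["gene_cnv.tsv"] = _sha256(p)
        score_tables = {}
        for cond, expr in (("normal", cohort.expr_normal), ("cancer", cohort.expr_cancer)):
            scores, summary = association.score_all_genes(
                profs[cond], expr, cohort.manifest.genes, condition=cond,
                models=tuple(m for m in models if cond == "cancer" or
                             m not in ("ols_cnv", "lasso_combined")),
                gene_cnv=gene_cnv if cond == "cancer" else None,
                cv_folds=config.cv_folds, cv_repeats=config.cv_repeats,
                seed=_stage_seed(config.seed, f"associate_{cond}"))
            score_tables[cond] = scores
            p = write_table(scores, out / f"scores_{cond}.tsv")
            manifest["outputs"][f"scores_{cond}.tsv"] = _sha256(p)
            top = scores.nlargest(config.top_n, "r2_lasso_full")["gene_id"].tolist()
            _, region_summary = association.region_correlations(
                top, profs[cond], expr, cohort.manifest.genes, scores=scores)
            p = write_table(region_summary, out / f"region_correlations_{cond}.tsv")
            manifest["outputs"][f"region_correlations_{cond}.tsv"] = _sha256(p)
            manifest[f"associate_{cond}"] = _jsonable(summary)
        r2, _ = association.cross_condition_concordance(
            score_tables["normal"].set_index("gene_id")["r2_lasso_full"],
            score_tables["cancer"].set_index("gene_id")["r2_lasso_full"])
        manifest["cross_condition_r2"] = r2
        if config.run_cnv:
            manifest["cnv_summary"] = _jsonable(
                cnv_mod.cnv_expression_scores(score_tables["cancer"]))
        manifest["stages"].append("associate")

    if config.run_survival:
        if not config.run_cluster:
            raise RuntimeError("survival stage needs sublabels from the "
                               "cluster stage; enable run_cluster")
        strat = surv_mod.stratify_patients(
            profs["cancer"], assignments["cancer"].sublabels,
            list(cohort.beta_cancer.columns))
        p = write_table(strat.table, out / "strata.tsv", index=True)
        manifest["outputs"]["strata.tsv"] = _sha256(p)
        km = surv_mod.km_logrank(strat.strata, cohort.clinical,
                                 window_years=config.window_years)
        km_rows = [c.assign(stratum=name) for name, c in km["curves"].items()]
        p = write_table(pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv")
        manifest["outputs"]["km_curves.tsv"] = _sha256(p)
        cox = surv_mod.cox_multivariate(strat.strata, cohort.clinical,
                                        window_years=config.window_years)
        p = write_table(cox, out / "cox_summary.tsv")
        manifest["outputs"]["cox_summary.tsv"] = _sha256(p)
        manifest["survival"] = {"logrank_p": km.get("logrank_p"),
                                "flags": km["flags"]}
        manifest["stages"].append("survival")

    _finish(manifest, out)
    return manifest


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=float))


def _finish(manifest: dict, out: Path) -> None:
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=float))
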