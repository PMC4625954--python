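"""Synthetic cohort generator.

Emulates the statistical structure the analysis pipeline assumes in real
promoter-methylation cohorts: per-CGI+SS spatial methylation archetypes
(hypo-methylated island with hemi-methylated shores and hyper-methylated
shelves; fully hyper-methylated; cancer-specific hemi-methylated),
beta-distributed probe noise, a CIMP subgroup of cancer samples with
coordinated hypermethylation of a designated CGI set, genes whose expression
depends linearly on a sparse subset of shore/shelf probes, gene-dosage CNV
effects, and group-dependent survival hazards.  Every quantity the recovery
tests need is recorded in a :class:`CohortTruth`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ARCHETYPES, REGIONS, SimConfig

_FLOAT_FMT = "%.10g"

# stream names -> fixed spawn index so every stage draws from an independent,
# reproducible child of the master seed
_STREAMS = ("manifest", "archetype", "cimp", "meth_normal", "meth_cancer",
            "genes", "expr_normal", "expr_cancer", "cnv", "clinical")


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass
class Manifest:
    """Probe manifest, island intervals and gene annotation of one cohort."""

    probes: pd.DataFrame   # probe_id, chrom, pos, cgi_id, region
    islands: pd.DataFrame  # cgi_id, chrom, start, end (0-based half-open)
    genes: pd.DataFrame    # gene_id, chrom, tss, strand, cgi_ids (';'-joined)

    def probes_of(self, cgi_id: str) -> pd.DataFrame:
        return self.probes[self.probes["cgi_id"] == cgi_id]


@dataclass
class CohortTruth:
    """Planted parameters against which recovery is tested."""

    archetype_per_cgi: dict[str, str] = field(default_factory=dict)
    cimp_samples: set[str] = field(default_factory=set)
    # gene_id -> (effect probe ids, weights)
    regulated_genes: dict[str, tuple[list[str], list[float]]] = field(default_factory=dict)
    # gene -> dosage-sensitivity multiplier (genes absent are CNV-buffered)
    cnv_sensitivity: dict[str, float] = field(default_factory=dict)
    planted_hr: dict[str, float] = field(default_factory=dict)
    planted_strata: dict[str, str] = field(default_factory=dict)
    cimp_score: dict[str, float] = field(default_factory=dict)  # cancer sample -> mean 3up beta
    baselines: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "archetype_per_cgi": self.archetype_per_cgi,
            "cimp_samples": sorted(self.cimp_samples),
            "regulated_genes": {g: {"probes": p, "weights": w}
                                for g, (p, w) in self.regulated_genes.items()},
            "cnv_sensitivity": self.cnv_sensitivity,
            "planted_hr": self.planted_hr,
            "planted_strata": self.planted_strata,
            "cimp_score": self.cimp_score,
            "baselines": self.baselines,
        }, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        d = json.loads(text)
        return cls(
            archetype_per_cgi=d["archetype_per_cgi"],
            cimp_samples=set(d["cimp_samples"]),
            regulated_genes={g: (v["probes"], v["weights"])
                             for g, v in d["regulated_genes"].items()},
            cnv_sensitivity=d.get("cnv_sensitivity", {}),
            planted_hr=d["planted_hr"],
            planted_strata=d["planted_strata"],
            cimp_score=d["cimp_score"],
            baselines=d["baselines"],
        )


# ---------------------------------------------------------------------------
# manifest

_REGION_WEIGHTS = {"island": 0.45, "N_shore": 0.175, "S_shore": 0.175,
                   "N_shelf": 0.10, "S_shelf": 0.10}
_CGI_SPACING = 100_000  # bp between successive island starts on one chromosome
_N_CHROMS = 5


def generate_manifest(config: SimConfig) -> Manifest:
    """Place islands, probes (island + shores <=2kb + shelves 2-4kb) and genes.

    Probe counts are drawn from ``probes_per_cgi_range`` so that, with the
    default (10, 40) range, some CGI+SS fall below the 20-probe filter.
    Positions are uniform within each region; one gene per CGI with its TSS at
    the island edge matching its strand.
    """
    config.validate()
    rng = _rng(config, "manifest")
    probe_rows, island_rows, gene_rows = [], [], []
    pid = 0
    for i in range(config.n_cgi):
        cgi_id = f"CGI{i:04d}"
        chrom = f"chr{i % _N_CHROMS + 1}"
        start = 50_000 + (i // _N_CHROMS) * _CGI_SPACING
        width = int(rng.integers(600, 1401))
        end = start + width
        lo, hi = config.probes_per_cgi_range
        n_probes = int(rng.integers(lo, hi + 1))
        # every region tier gets probes first (up to 2 each) so profiles span
        # island, shores and shelves; the rest follow the density weights
        order = ["island", "N_shore", "S_shore", "N_shelf", "S_shelf"]
        guaranteed = [order[j % 5] for j in range(min(n_probes, 10))]
        extra = rng.choice(list(_REGION_WEIGHTS), size=max(0, n_probes - 10),
                           p=list(_REGION_WEIGHTS.values()))
        regions = np.concatenate([guaranteed, extra])
        positions = []
        for region in regions:
            if region == "island":
                span = (start, end)
            elif region == "N_shore":
                span = (start - 2000, start)
            elif region == "N_shelf":
                span = (start - 4000, start - 2000)
            elif region == "S_shore":
                span = (end, end + 2000)
            else:  # S_shelf
                span = (end + 2000, end + 4000)
            positions.append(int(rng.integers(span[0], span[1])))
        order = np.argsort(positions, kind="stable")
        seen: set[int] = set()
        for idx in order:
            pos = positions[idx]
            while pos in seen:  # enforce strictly increasing coordinates
                pos += 1
            seen.add(pos)
            probe_rows.append((f"cg{pid:06d}", chrom, pos, cgi_id,
                               _label_region(pos, start, end)))
            pid += 1
        island_rows.append((cgi_id, chrom, start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start - 100 if strand == "+" else end + 100
        gene_rows.append((f"G{i:04d}", chrom, tss, strand, cgi_id))

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand", "cgi_ids"])
    if config.multi_cgi_fraction > 0:
        n_multi = int(round(config.multi_cgi_fraction * len(genes)))
        picks = rng.choice(len(genes), size=n_multi, replace=False)
        for j in np.sort(picks):
            other = (j + 1) % len(genes)
            genes.loc[j, "cgi_ids"] = f"{genes.loc[j, 'cgi_ids']};CGI{other:04d}"

    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos", "cgi_id", "region"])
    islands = pd.DataFrame(island_rows, columns=["cgi_id", "chrom", "start", "end"])
    return Manifest(probes=probes, islands=islands, genes=genes)


def _label_region(pos: int, start: int, end: int) -> str:
    if start <= pos < end:
        return "island"
    d = start - pos if pos < start else pos - end + 1
    side = "N" if pos < start else "S"
    return f"{side}_shore" if d <= 2000 else f"{side}_shelf"


# ---------------------------------------------------------------------------
# methylation

def _island_distance_kb(manifest: Manifest) -> pd.Series:
    """Distance (kb) of each probe from its island, 0 inside the island."""
    bounds = manifest.islands.set_index("cgi_id")
    start = manifest.probes["cgi_id"].map(bounds["start"]).to_numpy()
    end = manifest.probes["cgi_id"].map(bounds["end"]).to_numpy()
    pos = manifest.probes["pos"].to_numpy()
    d = np.where(pos < start, start - pos, np.where(pos >= end, pos - end + 1, 0))
    return pd.Series(d / 1000.0, index=manifest.probes["probe_id"].to_numpy())


def _ramp(d_kb: np.ndarray, island_level: float, shelf_level: float) -> np.ndarray:
    """Island plateau blending linearly through the shores into the shelf
    plateau (shores span 0-2kb from the island edge, shelves beyond)."""
    t = np.clip(d_kb / 2.0, 0.0, 1.0)
    return island_level + (shelf_level - island_level) * t


# Archetype levels (island, shelf).  Flank plateaus deliberately differ
# between archetypes: hemi-methylated cancer-specific signatures sit at
# intermediate levels across the whole CGI+SS, not just the island, and the
# fully hyper-methylated class is uniformly high -- which is also what makes
# the shapes distinguishable under a free-boundary alignment distance.
_LEVELS = {
    "cluster1": (0.10, 0.80),       # hypo island, hemi shores, hyper shelves
    "cluster2": (0.92, 0.85),       # fully hyper-methylated
    "cimp_3up": (0.60, 0.55),       # hemi-methylated (CIMP tumors only)
    "cancer_3down": (0.50, 0.73),   # partially demethylated in all tumors
}


def archetype_mean_curve(archetype: str, d_kb: np.ndarray, condition: str,
                         cimp_member: bool = False) -> np.ndarray:
    """Mean beta along a CGI+SS for one archetype, condition and sample class."""
    if archetype == "cluster1":
        return _ramp(d_kb, *_LEVELS["cluster1"])
    if archetype == "cluster2":
        return _ramp(d_kb, *_LEVELS["cluster2"])
    if archetype == "cluster3up":
        if condition == "cancer" and cimp_member:
            return _ramp(d_kb, *_LEVELS["cimp_3up"])
        return _ramp(d_kb, *_LEVELS["cluster1"])
    if archetype == "cluster3down":
        if condition == "cancer":
            return _ramp(d_kb, *_LEVELS["cancer_3down"])
        return _ramp(d_kb, *_LEVELS["cluster2"])
    raise ValueError(f"unknown archetype {archetype!r}")


def _assign_archetypes(manifest: Manifest, config: SimConfig) -> dict[str, str]:
    rng = _rng(config, "archetype")
    cgis = manifest.islands["cgi_id"].tolist()
    labels = rng.choice(ARCHETYPES, size=len(cgis), p=list(config.archetype_fractions))
    return dict(zip(cgis, labels))


def _cimp_members(config: SimConfig) -> set[str]:
    rng = _rng(config, "cimp")
    samples = cancer_sample_ids(config)
    n_cimp = int(round(config.cimp_fraction * config.n_samples_cancer))
    return set(rng.choice(samples, size=n_cimp, replace=False))


def normal_sample_ids(config: SimConfig) -> list[str]:
    return [f"N{i:04d}" for i in range(config.n_samples_normal)]


def cancer_sample_ids(config: SimConfig) -> list[str]:
    return [f"C{i:04d}" for i in range(config.n_samples_cancer)]


def simulate_methylation(manifest: Manifest, config: SimConfig, condition: str,
                         truth: CohortTruth | None = None
                         ) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw the probe x sample beta matrix for one condition.

    Betas are Beta-distributed around the archetype mean curve with shape
    parameters ``(mean*c, (1-mean)*c)`` where ``c`` is
    ``beta_noise_concentration``; 3up loci are shifted toward hemi-methylation
    only in CIMP-member cancer samples, so the population mean is intermediate
    while per-sample values are bimodal.
    """
    if condition not in ("normal", "cancer"):
        raise ValueError(f"unknown condition {condition!r}")
    truth = truth if truth is not None else CohortTruth()
    if not truth.archetype_per_cgi:
        truth.archetype_per_cgi = _assign_archetypes(manifest, config)
    if not truth.cimp_samples and condition == "cancer":
        truth.cimp_samples = _cimp_members(config)
    samples = normal_sample_ids(config) if condition == "normal" else cancer_sample_ids(config)
    rng = _rng(config, f"meth_{condition}")
    d_kb = _island_distance_kb(manifest)
    c = config.beta_noise_concentration

    # coordinated per-tumor drift at the CIMP target (3up) loci: the CIMP
    # phenotype is a continuum, so every cancer sample shares one small
    # offset across all 3up CGI+SS on top of its class curve
    drift = (rng.normal(0.0, config.cimp_drift_sd, size=len(samples))
             if condition == "cancer" else np.zeros(len(samples)))

    means = np.empty((len(manifest.probes), len(samples)))
    cimp_mask = np.array([s in truth.cimp_samples for s in samples])
    probes = manifest.probes
    for cgi_id, idx in probes.groupby("cgi_id", sort=False).indices.items():
        arche = truth.archetype_per_cgi[cgi_id]
        d = d_kb.to_numpy()[idx]
        base = archetype_mean_curve(arche, d, condition, cimp_member=False)
        means[np.ix_(idx, np.arange(len(samples)))] = base[:, None]
        if condition == "cancer" and arche == "cluster3up":
            if cimp_mask.any():
                shifted = archetype_mean_curve(arche, d, condition, cimp_member=True)
                means[np.ix_(idx, np.where(cimp_mask)[0])] = shifted[:, None]
            means[idx, :] = means[idx, :] + drift[None, :]

    means = np.clip(means, 0.02, 0.98)
    betas = rng.beta(means * c, (1.0 - means) * c)
    beta_df = pd.DataFrame(betas, index=probes["probe_id"].to_numpy(), columns=samples)

    if condition == "cancer":
        up_cgis = [g for g, a in truth.archetype_per_cgi.items() if a == "cluster3up"]
        if up_cgis:
            per_cgi = [beta_df.loc[probes.loc[probes["cgi_id"] == g, "probe_id"]].mean(axis=0)
                       for g in up_cgis]
            score = pd.concat(per_cgi, axis=1).mean(axis=1)
            truth.cimp_score = {s: float(v) for s, v in score.items()}
    return beta_df, truth


# ---------------------------------------------------------------------------
# expression

def oriented_region(label: str, strand: str) -> str:
    """Region label relative to the gene: S_* is 3' of a plus-strand gene."""
    if strand == "+" or label == "island":
        return label
    side, part = label.split("_")
    return f"{'N' if side == 'S' else 'S'}_{part}"


BASELINE_MEAN = 8.0
BASELINE_SD = 1.0
LOW_BASELINE_MEAN = 4.5
LOW_BASELINE_SD = 0.5


def _assign_gene_effects(manifest: Manifest, truth: CohortTruth, config: SimConfig) -> None:
    """Pick regulated genes, their sparse effect probes/weights, and baselines.

    Runs once per cohort (idempotent): regulated genes are drawn from
    cluster1-archetype CGIs with enough probes in the strand-oriented effect
    region; genes linked to 3up CGIs get a low baseline in both conditions.
    """
    if truth.regulated_genes or truth.baselines:
        return
    rng = _rng(config, "genes")
    probes = manifest.probes
    counts = probes["cgi_id"].value_counts()
    candidates = []
    for _, gene in manifest.genes.iterrows():
        cgi_id = gene["cgi_ids"].split(";")[0]
        if truth.archetype_per_cgi.get(cgi_id) != "cluster1":
            continue
        if counts.get(cgi_id, 0) < 20:  # plant effects where the analysis looks
            continue
        cgi_probes = probes[probes["cgi_id"] == cgi_id]
        oriented = cgi_probes["region"].map(lambda r: oriented_region(r, gene["strand"]))
        eligible = cgi_probes.loc[oriented == config.effect_region, "probe_id"].tolist()
        if len(eligible) >= config.effect_probes_per_gene:
            candidates.append((gene["gene_id"], eligible))
    if len(candidates) < config.n_regulated_genes:
        raise ValueError(
            f"only {len(candidates)} genes have >= {config.effect_probes_per_gene} "
            f"probes in oriented {config.effect_region}; lower n_regulated_genes")
    picks = rng.choice(len(candidates), size=config.n_regulated_genes, replace=False)
    for j in np.sort(picks):
        gene_id, eligible = candidates[j]
        k = config.effect_probes_per_gene
        probe_ids = [eligible[i] for i in np.sort(rng.choice(len(eligible), size=k, replace=False))]
        weights = rng.uniform(0.5, 1.5, size=k)
        truth.regulated_genes[gene_id] = (probe_ids, [float(w) for w in weights])

    up_cgis = {g for g, a in truth.archetype_per_cgi.items() if a == "cluster3up"}
    for _, gene in manifest.genes.iterrows():
        cgi_id = gene["cgi_ids"].split(";")[0]
        if cgi_id in up_cgis:
            b = rng.normal(LOW_BASELINE_MEAN, LOW_BASELINE_SD)
        else:
            b = rng.normal(BASELINE_MEAN, BASELINE_SD)
        truth.baselines[gene["gene_id"]] = float(b)

    # dosage sensitivity: only a fraction of genes respond to copy number,
    # the rest are buffered; drawn independently of the methylation effects
    for gene_id in manifest.genes["gene_id"]:
        if rng.random() < config.cnv_sensitive_fraction:
            truth.cnv_sensitivity[gene_id] = float(rng.uniform(0.5, 1.5))


def simulate_expression(beta: pd.DataFrame, truth: CohortTruth, config: SimConfig,
                        manifest: Manifest, condition: str,
                        gene_cnv: pd.DataFrame | None = None) -> pd.DataFrame:
    """Gene x sample expression (log2 scale).

    Regulated genes: ``baseline - effect_size * sum_j w_j beta_j`` over their
    effect probes plus an optional gene-dosage CNV term and Gaussian noise;
    unregulated genes omit the methylation term.
    """
    _assign_gene_effects(manifest, truth, config)
    samples = list(beta.columns)
    if gene_cnv is not None and list(gene_cnv.columns) != samples:
        raise ValueError("gene_cnv samples do not match beta matrix samples")
    rng = _rng(config, f"expr_{condition}")
    rows = []
    gene_ids = manifest.genes["gene_id"].tolist()
    for gene_id in gene_ids:
        expr = np.full(len(samples), truth.baselines[gene_id])
        if gene_id in truth.regulated_genes:
            probe_ids, weights = truth.regulated_genes[gene_id]
            missing = [p for p in probe_ids if p not in beta.index]
            if missing:
                raise ValueError(f"effect probes absent from beta matrix: {missing}")
            expr = expr - config.effect_size * (
                np.asarray(weights) @ beta.loc[probe_ids].to_numpy())
        sens = truth.cnv_sensitivity.get(gene_id, 0.0)
        if gene_cnv is not None and gene_id in gene_cnv.index and sens > 0:
            expr = expr + config.cnv_effect_size * sens * gene_cnv.loc[gene_id].to_numpy()
        expr = expr + rng.normal(0.0, config.expression_noise_sd, size=len(samples))
        rows.append(expr)
    return pd.DataFrame(rows, index=gene_ids, columns=samples)


# ---------------------------------------------------------------------------
# CNV + clinical

def _chrom_spans(manifest: Manifest) -> dict[str, int]:
    spans = {}
    for chrom, grp in manifest.probes.groupby("chrom"):
        spans[chrom] = int(grp["pos"].max()) + 50_000
    return spans


def simulate_cnv_and_clinical(manifest: Manifest, truth: CohortTruth, config: SimConfig
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SEG-format copy-number segments and a clinical table for cancer samples.

    Segments are piecewise-constant log2 ratios partitioning each chromosome
    (baseline 0 with occasional gains/losses), independent of the methylation
    truth.  Survival is exponential with the hazard multiplied by the planted
    ratio of each sample's stratum, administratively censored at
    ``censor_years``.
    """
    samples = cancer_sample_ids(config)
    rng = _rng(config, "cnv")
    spans = _chrom_spans(manifest)
    seg_rows = []
    for s in samples:
        for chrom, length in spans.items():
            n_seg = int(rng.integers(3, 8))
            cuts = np.sort(rng.integers(1, length, size=n_seg - 1))
            bounds = np.concatenate([[0], cuts, [length]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b <= a:
                    continue
                mean = 0.0 if rng.random() < 0.6 else float(rng.normal(0.0, 0.5))
                seg_rows.append((s, chrom, int(a), int(b), max(1, (b - a) // 1000), mean))
    seg = pd.DataFrame(seg_rows, columns=["sample", "chrom", "start", "end",
                                          "num_mark", "seg_mean"])

    truth.planted_hr = {"low": 1.0,
                        "intermediate": config.hazard_ratio_intermediate,
                        "high": config.hazard_ratio_high}
    truth.planted_strata = _plant_strata(truth, samples)
    strata = pd.Series([truth.planted_strata[s] for s in samples], index=samples)
    clin_rng = _rng(config, "clinical")
    clinical = simulate_survival_table(
        strata, truth.planted_hr, config.baseline_hazard_per_year,
        config.censor_years, clin_rng)
    return seg, clinical


def _plant_strata(truth: CohortTruth, samples: list[str]) -> dict[str, str]:
    """CIMP members -> high; non-members split at their median CIMP score."""
    strata: dict[str, str] = {}
    non_cimp = [s for s in samples if s not in truth.cimp_samples]
    if truth.cimp_score:
        scores = np.array([truth.cimp_score[s] for s in non_cimp])
    else:  # no 3up loci in this cohort: arbitrary but deterministic split
        scores = np.arange(len(non_cimp), dtype=float)
    med = np.median(scores) if len(scores) else 0.0
    for s, v in zip(non_cimp, scores):
        strata[s] = "low" if v <= med else "intermediate"
    for s in truth.cimp_samples:
        strata[s] = "high"
    return strata


def simulate_survival_table(strata: pd.Series, planted_hr: dict[str, float],
                            baseline_hazard_per_year: float, censor_years: float,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Exponential survival under per-stratum hazard ratios plus independent
    clinical covariates; administrative censoring at ``censor_years``."""
    n = len(strata)
    hr = strata.map(planted_hr).to_numpy(dtype=float)
    t_years = rng.exponential(1.0 / (baseline_hazard_per_year * hr))
    event = (t_years <= censor_years).astype(int)
    time_days = np.minimum(t_years, censor_years) * 365.25
    return pd.DataFrame({
        "sample": strata.index,
        "time": time_days,
        "event": event,
        "stratum": strata.to_numpy(),
        "ER": (rng.random(n) < 0.7).astype(int),
        "HER2": (rng.random(n) < 0.2).astype(int),
        "node": (rng.random(n) < 0.4).astype(int),
        "age": rng.normal(58.0, 12.0, size=n).round(1),
        "tumor_size": np.clip(rng.normal(25.0, 10.0, size=n), 1.0, None).round(1),
    }).set_index("sample")


# ---------------------------------------------------------------------------
# orchestration + I/O

@dataclass
class Cohort:
    config: SimConfig
    manifest: Manifest
    truth: CohortTruth
    beta_normal: pd.DataFrame
    beta_cancer: pd.DataFrame
    expr_normal: pd.DataFrame
    expr_cancer: pd.DataFrame
    seg: pd.DataFrame
    clinical: pd.DataFrame
    gene_cnv: pd.DataFrame


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate one full matched cohort (methylation, expression, CNV, clinical)."""
    from .cnv import gene_level_cnv  # local import: avoid module cycle

    manifest = generate_manifest(config)
    beta_cancer, truth = simulate_methylation(manifest, config, "cancer")
    beta_normal, truth = simulate_methylation(manifest, config, "normal", truth=truth)
    seg, clinical = simulate_cnv_and_clinical(manifest, truth, config)
    gene_cnv = gene_level_cnv(seg, manifest.genes).loc[:, cancer_sample_ids(config)]
    expr_cancer = simulate_expression(beta_cancer, truth, config, manifest,
                                      "cancer", gene_cnv=gene_cnv)
    expr_normal = simulate_expression(beta_normal, truth, config, manifest, "normal")
    return Cohort(config, manifest, truth, beta_normal, beta_cancer,
                  expr_normal, expr_cancer, seg, clinical, gene_cnv)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, str]:
    """Write every cohort table as plain text; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _tsv(name: str, df: pd.DataFrame, index: bool) -> None:
        p = out / name
        df.to_csv(p, sep="\t", float_format=_FLOAT_FMT, index=index)
        paths[name] = str(p)

    _tsv("manifest.tsv", cohort.manifest.probes, index=False)
    _tsv("islands.bed", cohort.manifest.islands[["chrom", "start", "end", "cgi_id"]],
         index=False)
    _tsv("annotation.tsv", cohort.manifest.genes, index=False)
    _tsv("beta_normal.tsv", cohort.beta_normal, index=True)
    _tsv("beta_cancer.tsv", cohort.beta_cancer, index=True)
    _tsv("expression_normal.tsv", cohort.expr_normal, index=True)
    _tsv("expression_cancer.tsv", cohort.expr_cancer, index=True)
    _tsv("cnv.seg", cohort.seg, index=False)
    _tsv("clinical.tsv", cohort.clinical, index=True)
    truth_path = out / "truth.json"
    truth_path.write_text(cohort.truth.to_json())
    paths["truth.json"] = str(truth_path)
    cfg_path = out / "sim_config.json"
    cfg_path.write_text(json.dumps(cohort.config.to_dict(), indent=1, sort_keys=True))
    paths["sim_config.json"] = str(cfg_path)
    return paths
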