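"""Assemble per-CGI+SS methylation profiles and condition-mean signatures.

A CGI+SS profile combines the probes of one CpG island with those of its
shores (<=2kb from the island edge) and shelves (2-4kb).  Profiles with fewer
than 20 probes are dropped: with fewer probes the within-locus variation that
the shape analysis relies on cannot be measured.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_PROBES = 20
MAX_PROBE_MISSING = 0.10  # probes missing in >10% of samples are excluded


@dataclass
class Signature:
    """Positions and mean beta values of one CGI+SS over a sample set."""

    cgi_id: str
    X: np.ndarray  # probe positions (genomic or standardized), strictly increasing
    Y: np.ndarray  # mean beta per probe, in [0, 1]
    condition: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape or self.X.ndim != 1:
            raise ValueError("X and Y must be 1-d vectors of equal length")

    @property
    def n(self) -> int:
        return len(self.X)


@dataclass
class CGISSProfile:
    """Ordered probes of one CGI plus its <=4kb flanks, with per-sample betas."""

    cgi_id: str
    probe_ids: list[str]
    positions: np.ndarray
    regions: list[str]
    betas: pd.DataFrame                      # probes x samples
    island: tuple[int, int] | None = None    # 0-based half-open interval
    linked_genes: list[tuple[str, int, str]] | None = None  # (gene_id, tss, strand)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def samples(self) -> list[str]:
        return list(self.betas.columns)


def build_profiles(beta: pd.DataFrame, manifest: pd.DataFrame,
                   annotation: pd.DataFrame | None = None,
                   islands: pd.DataFrame | None = None,
                   min_probes: int = MIN_PROBES) -> list[CGISSProfile]:
    """Group probes by CGI+SS, handle missing betas, apply the probe filter.

    Probes missing in more than 10% of samples are excluded; remaining gaps
    are filled by per-probe mean imputation so that every sample contributes a
    full-length profile.  Profiles with fewer than ``min_probes`` surviving
    probes are dropped.  Probes present in the beta matrix but absent from the
    manifest are a hard error.
    """
    if len(beta) == 0:
        return []
    known = set(manifest["probe_id"])
    orphans = [p for p in beta.index if p not in known]
    if orphans:
        raise ValueError(f"probes absent from manifest: {orphans[:10]}"
                         + ("..." if len(orphans) > 10 else ""))

    island_bounds = (islands.set_index("cgi_id") if islands is not None else None)
    gene_map: dict[str, list[tuple[str, int, str]]] = {}
    if annotation is not None:
        for _, g in annotation.iterrows():
            for cgi_id in str(g["cgi_ids"]).split(";"):
                gene_map.setdefault(cgi_id, []).append(
                    (g["gene_id"], int(g["tss"]), g["strand"]))

    profiles = []
    measured = manifest[manifest["probe_id"].isin(beta.index)]
    for cgi_id, grp in measured.groupby("cgi_id", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        sub = beta.loc[grp["probe_id"]]
        frac_missing = sub.isna().mean(axis=1)
        keep = frac_missing <= MAX_PROBE_MISSING
        grp, sub = grp[keep.to_numpy()], sub[keep.to_numpy()]
        if len(grp) < min_probes:
            continue
        if sub.isna().any().any():
            sub = sub.T.fillna(sub.mean(axis=1)).T
        island = None
        if island_bounds is not None and cgi_id in island_bounds.index:
            row = island_bounds.loc[cgi_id]
            island = (int(row["start"]), int(row["end"]))
        profiles.append(CGISSProfile(
            cgi_id=cgi_id,
            probe_ids=grp["probe_id"].tolist(),
            positions=grp["pos"].to_numpy(dtype=float),
            regions=grp["region"].tolist(),
            betas=sub,
            island=island,
            linked_genes=gene_map.get(cgi_id),
        ))
    return profiles


def mean_signature(profile: CGISSProfile, samples: list[str] | None = None,
                   condition: str = "") -> Signature:
    """Average each probe's beta across the sample subset (default: all)."""
    if samples is None:
        samples = profile.samples
    if len(samples) == 0:
        raise ValueError("sample subset is empty")
    missing = [s for s in samples if s not in profile.betas.columns]
    if missing:
        raise ValueError(f"samples not in profile: {missing[:5]}")
    y = profile.betas[list(samples)].mean(axis=1).to_numpy()
    return Signature(cgi_id=profile.cgi_id, X=profile.positions.copy(), Y=y,
                     condition=condition)


def standardize_axis(signature: Signature, island: tuple[int, int],
                     strand: str = "+") -> Signature:
    """Map probe positions onto a normalized CGI+SS axis.

    The island is mapped to [0, 1] whatever its width; flank positions are in
    signed kb from the nearest island edge: upstream shore [-2, 0), shelf
    [-4, -2), downstream shore (1, 3], shelf (3, 5].  For minus-strand genes
    the axis is reflected (x -> 1 - x) so positive coordinates beyond the
    island are always 3' of the gene.
    """
    start, end = island
    if end <= start:
        raise ValueError("island interval must be non-empty")
    if signature.X.min() < start - 4000 - 1 or signature.X.max() > end + 4000 + 1:
        raise ValueError("island interval outside profile span")
    x = signature.X
    coord = np.where(
        x < start, -(start - x) / 1000.0,
        np.where(x >= end, 1.0 + (x - end + 1) / 1000.0, (x - start) / (end - start)))
    y = signature.Y.copy()
    if strand == "-":
        coord = 1.0 - coord
        coord, y = coord[::-1].copy(), y[::-1].copy()
    return Signature(cgi_id=signature.cgi_id, X=coord, Y=y,
                     condition=signature.condition)
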