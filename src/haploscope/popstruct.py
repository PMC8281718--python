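"""Population-structure PCA for genotypes and haplotypes.

Two related analyses share one PCA engine: (i) genotype-level ancestry PCA
of cohort samples merged with a labeled reference panel, after the usual
site filters (minor allele frequency >= 0.05, missing call fraction < 0.1,
computed on the combined cohort), with population assignment by nearest
panel centroid in a chosen component subspace (components 2 and 3 by
default, the axes that separate the major populations); and (ii)
haplotype-level PCA of 0/1 haplotype vectors around the focal allele,
mutant and wild-type jointly with the panel, which exposes the
identity-by-descent clusters among mutant haplotypes.

The engine is a column-mean-centered (optionally variance-scaled) singular
value decomposition.  Component signs are fixed by forcing the
largest-magnitude loading of each component positive, so scores are
reproducible across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phased_vcf import HaplotypeVector

__all__ = [
    "GenotypeMatrix",
    "PcaResult",
    "filter_sites_for_pca",
    "run_pca",
    "assign_population",
    "haplotype_pca_report",
]


@dataclass
class GenotypeMatrix:
    """Sample x site dosage matrix; dosages in {0,1,2}, NaN = missing."""

    samples: list[str]
    sites: list[tuple]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError("dosage matrix shape must be (samples, sites)")

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, columns=[":".join(map(str, s)) for s in self.sites])
        df.insert(0, "sample", self.samples)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        samples = df["sample"].astype(str).tolist()
        site_cols = [c for c in df.columns if c != "sample"]
        sites = [tuple(c.split(":")) for c in site_cols]
        return cls(samples=samples, sites=sites, dosages=df[site_cols].to_numpy(float))


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_rows, k)
    explained_variance_fraction: np.ndarray  # (k,)
    component_loadings: np.ndarray  # (k, n_sites)

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if evf.size and (np.any(evf < -1e-12) or np.any(np.diff(evf) > 1e-12)
                         or evf.sum() > 1 + 1e-9):
            raise ValueError("explained variance fractions must be in [0,1], "
                             "non-increasing, and sum to <= 1")


def filter_sites_for_pca(
    gm: GenotypeMatrix,
    min_maf: float = 0.05,
    max_missing: float = 0.1,
) -> GenotypeMatrix:
    """Retain sites with MAF >= ``min_maf`` and missing fraction < ``max_missing``.

    Allele frequency is computed on non-missing dosages of the combined
    cohort (dosage sum over twice the called sample count).  Removing every
    site warns rather than raising.
    """
    if gm.dosages.size == 0:
        raise ValueError("empty genotype matrix")
    d = gm.dosages
    missing = np.isnan(d)
    miss_frac = missing.mean(axis=0)
    called = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(d, axis=0) / np.maximum(2 * called, 1)
    maf = np.minimum(freq, 1 - freq)
    keep = (maf >= min_maf) & (miss_frac < max_missing) & (called > 0)
    if not keep.any():
        warnings.warn("all sites removed by the PCA site filters")
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        samples=list(gm.samples),
        sites=[gm.sites[i] for i in idx],
        dosages=d[:, idx],
    )


def impute_site_mean(d: np.ndarray) -> np.ndarray:
    """Replace missing dosages by their site mean (frequency-preserving)."""
    d = np.array(d, dtype=float)
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(d))
    d[nan_r, nan_c] = col_mean[nan_c]
    return d


def run_pca(matrix, center: bool = True, scale: bool = False,
            n_components: int | None = None) -> PcaResult:
    """Centered SVD principal component analysis.

    Columns are mean-centered (no variance scaling by default, matching the
    untransformed treatment of 0/1 haplotype columns); missing entries must
    be imputed beforehand.  At most ``min(10, rank)`` components are
    returned unless ``n_components`` overrides the cap.  A constant matrix
    yields all-zero scores and zero explained variance.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("matrix must be 2-D with >= 2 rows and >= 1 column")
    if np.isnan(X).any():
        raise ValueError("impute missing entries before PCA")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    k = min(10, rank) if n_components is None else min(n_components, len(s))
    if rank == 0:
        k = max(k, 1)
        return PcaResult(
            scores=np.zeros((X.shape[0], k)),
            explained_variance_fraction=np.zeros(k),
            component_loadings=np.zeros((k, X.shape[1])),
        )
    total = float((s ** 2).sum())
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            loadings[j] = -loadings[j]
            scores[:, j] = -scores[:, j]
    return PcaResult(
        scores=scores,
        explained_variance_fraction=(s[:k] ** 2) / total,
        component_loadings=loadings,
    )


def assign_population(
    query_scores,
    panel_scores,
    panel_labels: Sequence[str],
    components: Sequence[int] = (1, 2),
) -> pd.DataFrame:
    """Nearest-centroid population assignment in a component subspace.

    ``components`` are 0-based score-column indices; the default (1, 2)
    selects the second and third components, the pair that separates the
    major populations in the genotype PCA.  Ties go to the
    lexicographically smaller label and are flagged.
    """
    panel_scores = np.asarray(panel_scores, dtype=float)
    query_scores = np.atleast_2d(np.asarray(query_scores, dtype=float))
    labels = list(panel_labels)
    if panel_scores.shape[0] != len(labels):
        raise ValueError("panel_scores rows must match panel_labels")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("panel must cover >= 2 population labels")
    comp = list(components)
    centroids = np.vstack([
        panel_scores[np.array(labels) == lab][:, comp].mean(axis=0) for lab in uniq
    ])
    rows = []
    for q in query_scores[:, comp]:
        dists = np.linalg.norm(centroids - q, axis=1)
        order = np.lexsort((uniq, dists))  # distance, then label
        best = order[0]
        margin = float(dists[order[1]] - dists[best]) if len(uniq) > 1 else np.inf
        rows.append({
            "label": uniq[best],
            "distance": float(dists[best]),
            "margin": margin,
            "tie": bool(np.isclose(margin, 0.0, atol=1e-12)),
        })
    return pd.DataFrame(rows)


def haplotype_pca_report(
    vectors: Sequence[HaplotypeVector],
    n_components: int | None = None,
) -> tuple[PcaResult, pd.DataFrame]:
    """Joint PCA of stacked 0/1 haplotype vectors (cohort + panel).

    All vectors must share one site index.  Returns the PCA result and a
    tidy per-haplotype table (id, label, origin, population, PC columns)
    ready for plotting or clustering.
    """
    vectors = list(vectors)
    if len(vectors) < 3:
        raise ValueError("need >= 3 haplotype vectors")
    index = vectors[0].site_index
    for v in vectors[1:]:
        if v.site_index != index:
            raise ValueError("haplotype vectors do not share a site index")
    X = np.vstack([v.values for v in vectors]).astype(float)
    res = run_pca(X, n_components=n_components)
    k = res.scores.shape[1]
    table = pd.DataFrame({
        "haplotype_id": [v.hap_id or f"hap{i}" for i, v in enumerate(vectors)],
        "label": [v.label for v in vectors],
        "origin": [v.origin for v in vectors],
        "population": [v.population for v in vectors],
    })
    for j in range(k):
        table[f"PC{j + 1}"] = res.scores[:, j]
    return res, table
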