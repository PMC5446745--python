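"""Complete-case genotype PCA and a light k-means cluster summary."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model import MISSING, GenotypeMatrix, PcaResult, SnpRecord

logger = logging.getLogger(__name__)


def complete_case_matrix(
    records: Sequence[SnpRecord],
    population_of: Mapping[str, str],
) -> GenotypeMatrix:
    """Individuals x SNPs dosage matrix keeping only SNPs genotyped in
    every individual; constant columns are dropped (they carry no
    variance) with a logged count."""
    if not records:
        raise ValueError("no records")
    samples = records[0].samples
    cols, ids = [], []
    n_missing = n_constant = 0
    for r in records:
        if (r.genotypes == MISSING).any():
            n_missing += 1
            continue
        if (r.genotypes == r.genotypes[0]).all():
            n_constant += 1
            continue
        cols.append(r.genotypes.astype(np.float64))
        ids.append((r.unigene_id, r.pos))
    if not cols:
        raise ValueError(
            "no SNPs are genotyped in all individuals; consider laxer filters"
        )
    logger.info(
        "complete-case matrix: %d SNPs kept, %d dropped for missingness, "
        "%d constant",
        len(cols), n_missing, n_constant,
    )
    return GenotypeMatrix(
        X=np.column_stack(cols),
        samples=samples,
        populations=tuple(population_of[s] for s in samples),
        snp_ids=tuple(ids),
        n_dropped_missing=n_missing,
        n_dropped_constant=n_constant,
    )


def pca(
    matrix: GenotypeMatrix, n_components: int = 10, scale: bool = False
) -> PcaResult:
    """PCA of the dosage matrix via SVD of the column-centered data.

    ``scale=True`` divides each column by sqrt(p(1-p)) of its mean
    dosage frequency. Sign convention: the largest-magnitude loading of
    each component is positive, so scores are reproducible across runs
    and platforms.
    """
    X = matrix.X.astype(np.float64)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("pca needs >= 2 individuals and >= 2 SNPs")
    Xc = X - X.mean(axis=0)
    if scale:
        p = X.mean(axis=0) / 2.0
        denom = np.sqrt(p * (1.0 - p))
        Xc = Xc / np.where(denom > 0, denom, 1.0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, m) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank
    # deterministic signs: largest |loading| positive per component
    for i in range(n_components):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    total_var = float(np.sum(s**2))
    scores = U[:, :n_components] * s[:n_components]
    return PcaResult(
        scores=scores,
        variance_explained=(s[:n_components] ** 2) / total_var,
        loadings=Vt[:n_components],
        samples=matrix.samples,
        populations=matrix.populations,
    )


@dataclass
class ClusterSummary:
    assignments: np.ndarray  # per-individual cluster id
    silhouette: float
    composition: dict[int, dict[str, int]]  # cluster -> population -> count


def cluster_summary(
    result: PcaResult,
    k: int,
    n_components: int = 2,
    seed: int = 1,
    n_init: int = 25,
) -> ClusterSummary:
    """k-means on the top PCA components with a fixed seed.

    Returns assignments, per-cluster population composition and the mean
    silhouette (0 by convention for k = 1).
    """
    scores = result.scores[:, :n_components]
    n = scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} individuals")
    if k == 1:
        assign = np.zeros(n, dtype=int)
        sil = 0.0
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        assign = km.fit_predict(scores)
        sil = float(silhouette_score(scores, assign)) if len(set(assign)) > 1 else 0.0
    composition: dict[int, dict[str, int]] = {}
    for c in sorted(set(int(a) for a in assign)):
        comp: dict[str, int] = {}
        for a, pop in zip(assign, result.populations):
            if int(a) == c:
                comp[pop] = comp.get(pop, 0) + 1
        composition[c] = comp
    return ClusterSummary(assignments=assign, silhouette=sil, composition=composition)
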