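"""Low-dimensional embedding of samples from allele sharing.

The primary embedding is classical multidimensional scaling (principal
coordinates) of the distance D = 1 - A_s: eigen-decompose the double-centered
Gram matrix G = -1/2 J D^2 J and scale the top eigenvectors by the square
roots of their eigenvalues, so Euclidean distances among coordinates
approximate D (exactly, when D is Euclidean-embeddable).  A genotype-matrix
PCA with Patterson normalization is provided as an independent cross-check;
the two agree on cluster topology for drifted-population data.

A silhouette-based separation score turns "the groups take non-overlapping
positions" into a number: +1 for point-like, well-separated groups, ~0 for
labels scattered over one cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import silhouette_samples

from breedline.genotypes import MISSING, DataError, GenotypeMatrix, PopulationLabels
from breedline.sharing import SharingMatrix, sharing_matrix


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,) descending, >= 0
    variance_explained: np.ndarray  # (k,) fractions of positive-eigenvalue mass
    n_negative_eigenvalues: int = 0


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Eigenvector sign is arbitrary; make each column's largest-|loading| positive."""
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def pcoa_from_sharing(s: SharingMatrix, k: int) -> PcaResult:
    """Classical scaling of D = 1 - A_s into k coordinates."""
    n = len(s.samples)
    if k >= n:
        raise ValueError(f"k={k} must be < n_samples={n}")
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    d2 = d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    gram = -0.5 * j @ d2 @ j
    gram = (gram + gram.T) / 2.0
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(abs(eigval[0]), 1.0) * 1e-12
    n_negative = int((eigval < -tol).sum())
    eigval = np.clip(eigval, 0.0, None)

    top_val = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(top_val)
    coords = _fix_signs(coords)
    total = eigval.sum()
    var_explained = top_val / total if total > 0 else np.zeros(k)
    return PcaResult(
        samples=list(s.samples),
        coordinates=coords,
        eigenvalues=top_val,
        variance_explained=var_explained,
        n_negative_eigenvalues=n_negative,
    )


def genotype_pca(g: GenotypeMatrix, k: int) -> PcaResult:
    """PCA of mean-imputed genotypes with Patterson normalization.

    Each SNP column is centered at 2*p and divided by sqrt(p(1-p)); missing
    calls are imputed at the column mean.  Cross-check for the sharing-based
    embedding, not the primary surface.
    """
    if k >= g.n_samples:
        raise ValueError(f"k={k} must be < n_samples={g.n_samples}")
    codes = g.codes.astype(float)
    codes[g.codes == MISSING] = np.nan
    p = np.nanmean(codes, axis=0) / 2.0
    keep = ~np.isnan(p) & (p > 0) & (p < 1)
    x = codes[:, keep]
    p = p[keep]
    x = np.where(np.isnan(x), 2 * p, x)
    x = (x - 2 * p) / np.sqrt(p * (1 - p))
    gram = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    coords = _fix_signs(eigvec[:, order][:, :k] * np.sqrt(eigval[:k]))
    total = eigval.sum()
    return PcaResult(
        samples=list(g.samples),
        coordinates=coords,
        eigenvalues=eigval[:k],
        variance_explained=eigval[:k] / total if total > 0 else np.zeros(k),
    )


def subset_and_embed(
    g: GenotypeMatrix,
    snp_subset: list[str] | float,
    k: int,
    seed: int | None = None,
) -> PcaResult:
    """Recompute sharing on a SNP subset, then embed.

    ``snp_subset`` is either an explicit list of snp_ids or a fraction in
    (0,1]: a random draw of ceil(fraction * n_snps) SNPs without replacement
    from a generator seeded with ``seed``.
    """
    if isinstance(snp_subset, float):
        if not 0 < snp_subset <= 1:
            raise ValueError("subset fraction must be in (0,1]")
        n_take = int(np.ceil(snp_subset * g.n_snps))
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(g.n_snps, size=n_take, replace=False))
    else:
        if not len(snp_subset):
            raise DataError("empty SNP subset")
        idx = g.snps.index_of(list(snp_subset))
    sub = g.subset_snps(idx)
    return pcoa_from_sharing(sharing_matrix(sub), k)


def separation_score(p: PcaResult, labels: PopulationLabels, dims: int = 2) -> float:
    """Mean silhouette of population labels in the first ``dims`` coordinates.

    Samples in singleton groups contribute 0 (sklearn's convention).
    """
    lab = labels.as_array(p.samples)
    if len(np.unique(lab)) < 2:
        raise DataError("separation score needs >= 2 labelled groups")
    coords = p.coordinates[:, :dims]
    return float(np.mean(silhouette_samples(coords, lab)))


def write_coordinates_tsv(p: PcaResult, path) -> None:
    import pandas as pd

    k = p.coordinates.shape[1]
    df = pd.DataFrame(p.coordinates, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "sample", p.samples)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
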