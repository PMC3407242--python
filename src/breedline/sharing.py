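"""Pairwise identity-by-state allele sharing and heatmap ordering.

The similarity between two diploid genotypes is A_s = (IBS2 + 0.5*IBS1) / N,
where IBS2 and IBS1 count loci sharing two or one allele and N is the number
of loci where both samples are called (pairwise-complete).  Drift raises
within-population sharing relative to between-population sharing, so an
average-linkage ordering of 1 - A_s lays related animals out as contiguous
heatmap blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from breedline.genotypes import MISSING, DataError, GenotypeMatrix


@dataclass
class SharingMatrix:
    samples: list[str]
    values: np.ndarray  # (n, n) symmetric in [0,1], diagonal 1
    n_pairs_tested: np.ndarray  # (n, n) jointly-called locus counts

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.values.shape != (n, n) or self.n_pairs_tested.shape != (n, n):
            raise ValueError("matrix shapes do not match sample list")


@dataclass
class ClusterOrder:
    order: np.ndarray  # permutation of sample indices (leaf order)
    merges: np.ndarray  # scipy linkage matrix (n-1, 4)


def pairwise_ibs(
    g: GenotypeMatrix, i: int | str, j: int | str
) -> tuple[int, int, int, int]:
    """IBS0/1/2 counts and N for one sample pair, over jointly-called loci."""
    if isinstance(i, str):
        i = g.sample_index([i])[0]
    if isinstance(j, str):
        j = g.sample_index([j])[0]
    a, b = g.codes[i], g.codes[j]
    both = (a != MISSING) & (b != MISSING)
    diff = np.abs(a[both].astype(int) - b[both].astype(int))
    n = int(both.sum())
    ibs2 = int((diff == 0).sum())
    ibs1 = int((diff == 1).sum())
    ibs0 = n - ibs2 - ibs1
    return ibs0, ibs1, ibs2, n


def sharing_matrix(g: GenotypeMatrix) -> SharingMatrix:
    """All-pairs A_s via one-hot matrix products (fast for chip-scale panels)."""
    if g.n_samples < 2:
        raise DataError("sharing matrix needs >= 2 samples")
    codes = g.codes
    called = codes != MISSING
    onehot = [((codes == c) & called).astype(np.float64) for c in (0, 1, 2)]

    n = called.astype(np.float64) @ called.T.astype(np.float64)
    ibs2 = sum(h @ h.T for h in onehot)
    ibs0 = onehot[0] @ onehot[2].T + onehot[2] @ onehot[0].T
    ibs1 = n - ibs2 - ibs0

    off_diag = ~np.eye(g.n_samples, dtype=bool)
    if (n[off_diag] == 0).any():
        i, j = np.argwhere((n == 0) & off_diag)[0]
        raise DataError(
            f"no jointly-called SNPs for pair ({g.samples[i]!r}, {g.samples[j]!r})"
        )
    with np.errstate(invalid="ignore"):
        values = (ibs2 + 0.5 * ibs1) / n
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    return SharingMatrix(list(g.samples), values, n.astype(np.int64))


def cluster_order(s: SharingMatrix) -> ClusterOrder:
    """Average-linkage agglomeration on D = 1 - A_s; leaf order for the heatmap.

    scipy's linkage resolves distance ties deterministically by cluster index,
    which puts the lower original index first at exact ties.
    """
    d = 1.0 - s.values
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return ClusterOrder(order=np.asarray(leaves_list(z)), merges=z)


def write_sharing_tsv(s: SharingMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(s.values, index=s.samples, columns=s.samples).to_csv(
        path, sep="\t", index_label="sample", float_format="%.6f"
    )
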