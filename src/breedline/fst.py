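"""Pairwise F_ST under the drift parameterization, ranking, and enrichment.

Per SNP with allele-frequency estimates p1, p2 from n1, n2 called chromosomes,
the Hudson-form moment estimator uses

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)

and the global value is the ratio of sums sum(N)/sum(D) over informative SNPs
(never the mean of per-SNP ratios, which is badly biased at low-frequency
loci).  For two populations drifted independently from a common ancestor with
Balding-Nichols parameters c1 and c2, the estimator's expectation is
(c1 + c2)/2, which ties the statistic directly to the simulator's truth.

Per-SNP ratios may be negative through the finite-sample correction; they are
left unclamped so the lower tail of a ranking is not distorted.  The standard
deviation of the global value is a bootstrap over SNP loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from breedline.genotypes import MISSING, DataError, GenotypeMatrix, PopulationLabels, SnpMap


@dataclass
class FstComponents:
    snp_ids: np.ndarray
    numerator: np.ndarray  # N per SNP (NaN where uninformative)
    denominator: np.ndarray  # D per SNP
    n1: np.ndarray  # called chromosome counts, population 1
    n2: np.ndarray
    informative: np.ndarray  # bool: D > 0 and n1, n2 >= 2
    pair: tuple[str, str]

    @property
    def per_snp_fst(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.informative, self.numerator / self.denominator, np.nan)


@dataclass
class FstResult:
    pair: tuple[str, str]
    global_fst: float
    sd: float
    per_snp_fst: np.ndarray
    snp_ids: np.ndarray


def _pop_counts(g: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (allele-B count, called chromosome count) over given samples."""
    codes = g.codes[idx]
    called = codes != MISSING
    n_chrom = 2 * called.sum(axis=0)
    b_count = np.where(called, codes, 0).sum(axis=0)
    return b_count.astype(float), n_chrom.astype(float)


def fst_components(
    g: GenotypeMatrix, labels: PopulationLabels, pair: tuple[str, str]
) -> FstComponents:
    """Per-SNP Hudson numerator/denominator for one population pair.

    SNPs where either population has < 2 called chromosomes, or where D = 0
    (monomorphic across both populations), are flagged uninformative.
    """
    idx1 = g.sample_index(labels.samples_in(pair[0]))
    idx2 = g.sample_index(labels.samples_in(pair[1]))
    if len(idx1) < 1 or len(idx2) < 1:
        raise DataError(f"population missing samples in pair {pair}")
    b1, n1 = _pop_counts(g, idx1)
    b2, n2 = _pop_counts(g, idx2)

    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        raise DataError(f"no SNP with >= 2 called chromosomes in both of {pair}")
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = b1 / n1
        p2 = b2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    informative = ok & (den > 0)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return FstComponents(
        snp_ids=g.snps.snp_ids.copy(),
        numerator=num,
        denominator=den,
        n1=n1,
        n2=n2,
        informative=informative,
        pair=pair,
    )


def global_fst(c: FstComponents) -> float:
    """Ratio of sums over informative SNPs; slightly negative under the null."""
    if not c.informative.any():
        raise DataError(f"no informative SNPs for pair {c.pair}")
    return float(c.numerator[c.informative].sum() / c.denominator[c.informative].sum())


def bootstrap_sd(c: FstComponents, n_boot: int = 1000, seed: int = 0) -> float:
    """SD of the global ratio over bootstrap resamples of SNP loci."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    num = c.numerator[c.informative]
    den = c.denominator[c.informative]
    L = len(num)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, L, size=L)
        reps[b] = num[idx].sum() / den[idx].sum()
    return float(reps.std(ddof=1))


def pairwise_fst_matrix(
    g: GenotypeMatrix,
    labels: PopulationLabels,
    n_boot: int = 1000,
    seed: int = 0,
    min_samples: int = 2,
) -> dict[tuple[str, str], FstResult]:
    """Global F_ST and bootstrap SD for every unordered population pair.

    Populations with fewer than ``min_samples`` members are skipped with a
    warning.  Pair-specific bootstrap seeds derive from ``seed`` by offset.
    """
    import warnings

    pops = []
    for p in labels.populations():
        if len(labels.samples_in(p)) >= min_samples:
            pops.append(p)
        else:
            warnings.warn(f"population {p!r} has <{min_samples} samples; skipped")
    if len(pops) < 2:
        raise DataError("need >= 2 populations with enough samples")
    results: dict[tuple[str, str], FstResult] = {}
    offset = 0
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pair = (pops[i], pops[j])
            comp = fst_components(g, labels, pair)
            offset += 1
            results[pair] = FstResult(
                pair=pair,
                global_fst=global_fst(comp),
                sd=bootstrap_sd(comp, n_boot=n_boot, seed=seed + offset),
                per_snp_fst=comp.per_snp_fst,
                snp_ids=comp.snp_ids,
            )
    return results


def format_fst_table(results: dict[tuple[str, str], FstResult]) -> pd.DataFrame:
    """Square table with F_ST% above the diagonal and SD x 1000 below."""
    pops: list[str] = []
    for a, b in results:
        for p in (a, b):
            if p not in pops:
                pops.append(p)
    table = pd.DataFrame(0.0, index=pops, columns=pops)
    for (a, b), r in results.items():
        i, j = pops.index(a), pops.index(b)
        table.iloc[min(i, j), max(i, j)] = round(r.global_fst * 100, 1)
        table.iloc[max(i, j), min(i, j)] = round(r.sd * 1000, 1)
    return table


def rank_top_fraction(
    per_snp_fst: np.ndarray, snp_ids: np.ndarray, q: float
) -> list[str]:
    """Top-q fraction of SNPs by per-SNP F_ST.

    Sorts descending with ties broken by snp_id and returns the smallest count
    covering at least q of all ranked SNPs (ceiling rule: 1% of 49,034 SNPs is
    491).  SNPs with undefined (NaN) values rank last.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    per_snp_fst = np.asarray(per_snp_fst, dtype=float)
    snp_ids = np.asarray(snp_ids)
    L = len(per_snp_fst)
    n_take = math.ceil(q * L)
    key = np.where(np.isnan(per_snp_fst), -np.inf, per_snp_fst)
    order = sorted(range(L), key=lambda i: (-key[i], str(snp_ids[i])))
    return [str(snp_ids[i]) for i in order[:n_take]]


def chromosome_enrichment(top: list[str], m: SnpMap) -> pd.DataFrame:
    """Per-chromosome representation of outlier SNPs vs the panel's share.

    expected_fraction is the chromosome's share of all mapped SNPs,
    observed_fraction its share of the outlier set; p_value is the
    hypergeometric upper tail P(X >= n_top) drawing |top| SNPs from the panel.
    """
    ids = set(map(str, m.snp_ids))
    unknown = [s for s in top if s not in ids]
    if unknown:
        raise DataError(f"outlier SNPs absent from map: {unknown[:5]}")
    chrom_of = dict(zip(map(str, m.snp_ids), map(str, m.chromosomes)))
    total = len(m)
    n_top = len(top)
    top_counts: dict[str, int] = {}
    for s in top:
        top_counts[chrom_of[s]] = top_counts.get(chrom_of[s], 0) + 1

    rows = []
    panel_counts = pd.Series(list(map(str, m.chromosomes))).value_counts()
    for chrom in panel_counts.index:
        n_chrom = int(panel_counts[chrom])
        k = top_counts.get(chrom, 0)
        expected = n_chrom / total
        observed = k / n_top if n_top else 0.0
        pval = float(hypergeom.sf(k - 1, total, n_chrom, n_top)) if n_top else 1.0
        rows.append(
            {
                "chromosome": chrom,
                "n_snps": n_chrom,
                "n_top": k,
                "expected_fraction": expected,
                "observed_fraction": observed,
                "ratio": observed / expected if expected else np.nan,
                "p_value": pval,
            }
        )
    df = pd.DataFrame(rows)
    from breedline.genotypes import chromosome_sort_key

    return (
        df.sort_values("chromosome", key=lambda s: s.map(chromosome_sort_key))
        .reset_index(drop=True)
    )
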