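"""Within-population diversity: gene diversity, polymorphism, inbreeding,
and rarefied (private) allelic richness.

Gene diversity uses the small-sample (Nei) correction He = 2p(1-p) * n/(n-1)
with n the called chromosome count, appropriate for breeds sampled at only a
couple of dozen animals.  The individual inbreeding coefficient is
F = (O_hom - E_hom)/(L - E_hom) against expectations from the sample's own
population frequencies.  Allelic richness Ar(g) is the expected number of
distinct alleles in a random draw of g allele copies (closed-form
hypergeometric rarefaction); private richness pAr(g) additionally requires the
allele to be absent from an equally rarefied draw in every other population,
so it measures distinctiveness on a fair footing across unequal sample sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from breedline.genotypes import MISSING, DataError, GenotypeMatrix, PopulationLabels


def _counts(g: GenotypeMatrix, sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    codes = g.codes[sample_idx]
    called = codes != MISSING
    n_chrom = 2.0 * called.sum(axis=0)
    b = np.where(called, codes, 0).sum(axis=0).astype(float)
    return b, n_chrom


def gene_diversity(
    g: GenotypeMatrix, labels: PopulationLabels, pop: str
) -> tuple[float, float]:
    """(He, Pn) for one population.

    He is the mean over SNPs of 2p(1-p)*n/(n-1); SNPs with fewer than 2 called
    chromosomes are excluded.  Pn is the fraction of SNPs with 0 < p < 1.
    """
    idx = g.sample_index(labels.samples_in(pop))
    if len(idx) == 0:
        raise DataError(f"population {pop!r} is empty")
    b, n = _counts(g, idx)
    ok = n >= 2
    if not ok.any():
        raise DataError(f"population {pop!r} has no SNP with >= 2 called chromosomes")
    p = b[ok] / n[ok]
    he = 2.0 * p * (1.0 - p) * n[ok] / (n[ok] - 1.0)
    pn = float(((p > 0) & (p < 1)).mean())
    return float(he.mean()), pn


def inbreeding_f(
    g: GenotypeMatrix, labels: PopulationLabels, sample: str
) -> float:
    """Individual F = (O_hom - E_hom)/(L - E_hom) vs own-population frequencies.

    E_hom at each called SNP is 1 - He with He the population's unbiased gene
    diversity at that SNP.  Returns NaN when the denominator degenerates
    (every called SNP monomorphic in the population).
    """
    pop = labels.assignments.get(sample)
    if pop is None:
        raise DataError(f"sample {sample!r} has no population label")
    pop_idx = g.sample_index(labels.samples_in(pop))
    b, n = _counts(g, pop_idx)

    si = g.sample_index([sample])[0]
    codes = g.codes[si]
    called = (codes != MISSING) & (n >= 2)
    if not called.any():
        raise DataError(f"sample {sample!r} has no usable calls")
    p = b[called] / n[called]
    he = 2.0 * p * (1.0 - p) * n[called] / (n[called] - 1.0)
    L = float(called.sum())
    e_hom = float((1.0 - he).sum())
    o_hom = float((codes[called] != 1).sum())
    if abs(L - e_hom) < 1e-12:
        return float("nan")
    return (o_hom - e_hom) / (L - e_hom)


def _absence_prob(n_without: np.ndarray, n_total: np.ndarray, g: int) -> np.ndarray:
    """P(allele absent from g copies drawn without replacement) = C(N-Ni,g)/C(N,g)."""
    n_without = np.asarray(n_without, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    out = np.zeros_like(n_without)
    feasible = n_without >= g
    nw, nt = n_without[feasible], n_total[feasible]
    log_q = (
        gammaln(nw + 1)
        - gammaln(nw - g + 1)
        - gammaln(nt + 1)
        + gammaln(nt - g + 1)
    )
    out[feasible] = np.exp(log_q)
    return out


def allelic_richness(
    g: GenotypeMatrix,
    labels: PopulationLabels,
    pops: list[str] | None = None,
    g_copies: int = 2,
) -> pd.DataFrame:
    """Rarefied allelic richness Ar(g) and private richness pAr(g) per population.

    SNPs where any population has fewer than ``g_copies`` called chromosomes
    are excluded (their count is reported in the ``n_snps_excluded`` attribute
    of the returned frame).  For biallelic SNPs 1 <= Ar(g) <= 2 and Ar(1) = 1.
    """
    if g_copies < 1:
        raise ValueError("g_copies must be >= 1")
    if pops is None:
        pops = labels.populations()
    K = len(pops)
    b = np.empty((K, g.n_snps))
    n = np.empty((K, g.n_snps))
    for j, pop in enumerate(pops):
        idx = g.sample_index(labels.samples_in(pop))
        if len(idx) == 0:
            raise DataError(f"population {pop!r} is empty")
        b[j], n[j] = _counts(g, idx)

    ok = (n >= g_copies).all(axis=0)
    if not ok.any():
        raise DataError(f"no SNP with >= {g_copies} called chromosomes in every population")
    n_excluded = int((~ok).sum())
    b, n = b[:, ok], n[:, ok]
    a = n - b  # allele_a copies

    # presence/absence probabilities per allele (a and b), population, SNP
    q_a = np.stack([_absence_prob(n[j] - a[j], n[j], g_copies) for j in range(K)])
    q_b = np.stack([_absence_prob(n[j] - b[j], n[j], g_copies) for j in range(K)])
    p_a, p_b = 1.0 - q_a, 1.0 - q_b

    rows = []
    for j in range(K):
        ar = (p_a[j] + p_b[j]).mean()
        others = [k for k in range(K) if k != j]
        priv_a = p_a[j] * np.prod([q_a[k] for k in others], axis=0)
        priv_b = p_b[j] * np.prod([q_b[k] for k in others], axis=0)
        par = (priv_a + priv_b).mean()
        rows.append({"population": pops[j], "Ar": float(ar), "pAr": float(par)})
    df = pd.DataFrame(rows)
    df.attrs["g_copies"] = g_copies
    df.attrs["n_snps_used"] = int(ok.sum())
    df.attrs["n_snps_excluded"] = n_excluded
    return df


def diversity_report(
    g: GenotypeMatrix,
    labels: PopulationLabels,
    g_copies: int | None = None,
) -> pd.DataFrame:
    """Per-population He, Pn, mean F, Ar(g), pAr(g), ordered by decreasing He.

    Default g is twice the smallest population's sample size (allele copies).
    """
    pops = labels.populations()
    if g_copies is None:
        g_copies = 2 * min(len(labels.samples_in(p)) for p in pops)
    rich = allelic_richness(g, labels, pops, g_copies).set_index("population")
    rows = []
    for pop in pops:
        he, pn = gene_diversity(g, labels, pop)
        f_vals = [inbreeding_f(g, labels, s) for s in labels.samples_in(pop)]
        rows.append(
            {
                "population": pop,
                "n_animals": len(labels.samples_in(pop)),
                "He": he,
                "Pn": pn,
                "F": float(np.nanmean(f_vals)),
                "Ar": rich.loc[pop, "Ar"],
                "pAr": rich.loc[pop, "pAr"],
            }
        )
    df = pd.DataFrame(rows).sort_values("He", ascending=False).reset_index(drop=True)
    df.attrs["g_copies"] = g_copies
    return df
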