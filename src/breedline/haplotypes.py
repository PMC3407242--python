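"""EM estimation of multilocus haplotype frequencies from unphased genotypes.

For a window of m biallelic SNPs (m <= 8) the 2^m possible haplotypes are
enumerated; an individual's unphased genotype is compatible with every ordered
haplotype pair whose per-SNP dosages sum to its codes.  The EM iteration
(Excoffier-Slatkin style) alternates:

  E-step: each individual's compatible ordered pairs (a, b) get posterior
          weight proportional to f_a * f_b (heterozygous pairs appear twice in
          the ordered enumeration, which is the weight-2 bookkeeping);
  M-step: f_h = expected number of h gametes / (2n).

The observed-data log-likelihood sum_i log sum_pairs f_a f_b is non-decreasing
every iteration.  EM can stall on ridges, so the default run restarts from the
product of single-SNP allele frequencies plus seeded random Dirichlet points
and keeps the best likelihood.

Individuals with any missing call in the window are excluded and counted
(rather than wildcard-summed); the exclusion count is part of the result so a
report can show how many animals were actually used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from breedline.genotypes import MISSING, DataError, GenotypeMatrix
from breedline.simulate import haplotype_index_strings


@dataclass
class EmSettings:
    tol: float = 1e-8
    max_iter: int = 1000
    n_restarts: int = 10
    seed: int = 0
    min_report_freq: float = 0.005

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class EmResult:
    window: list[str]
    haplotypes: list[str]  # binary strings over (allele_a=0, allele_b=1)
    allele_strings: list[str]  # e.g. "GGAA"
    frequencies: np.ndarray  # (2^m,)
    log_likelihood: float
    n_used: int
    n_excluded: int
    n_iterations: int

    @property
    def n_observed(self) -> int:
        """Count of haplotypes estimated above the reporting threshold."""
        return int((self.frequencies > self._threshold).sum())

    _threshold: float = field(default=0.005, repr=False)


def compatible_pairs(genotype: np.ndarray) -> list[tuple[int, int]]:
    """Ordered haplotype-index pairs consistent with one genotype vector.

    Homozygous sites fix the allele on both haplotypes; each heterozygous site
    doubles the count, giving 2^h ordered pairs for h heterozygous sites
    (2^0 = 1 for fully homozygous individuals).
    """
    m = len(genotype)
    het = [i for i in range(m) if genotype[i] == 1]
    base = np.array([1 if genotype[i] == 2 else 0 for i in range(m)])
    weights = 1 << np.arange(m - 1, -1, -1)
    pairs = []
    for assignment in itertools.product((0, 1), repeat=len(het)):
        h1 = base.copy()
        h2 = base.copy()
        for site, bit in zip(het, assignment):
            h1[site] = bit
            h2[site] = 1 - bit
        pairs.append((int(h1 @ weights), int(h2 @ weights)))
    return pairs


def _log_likelihood(pair_lists: list[list[tuple[int, int]]], f: np.ndarray) -> float:
    ll = 0.0
    for pairs in pair_lists:
        lik = sum(f[a] * f[b] for a, b in pairs)
        if lik <= 0:
            return -np.inf
        ll += np.log(lik)
    return ll


def _em_run(
    pair_lists: list[list[tuple[int, int]]],
    f0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int]:
    n = len(pair_lists)
    f = f0.copy()
    ll_prev = _log_likelihood(pair_lists, f)
    iters = 0
    for iters in range(1, max_iter + 1):
        counts = np.zeros_like(f)
        for pairs in pair_lists:
            w = np.array([f[a] * f[b] for a, b in pairs])
            total = w.sum()
            if total <= 0:
                # individual incompatible with current f: restart mass uniformly
                w = np.ones(len(pairs))
                total = float(len(pairs))
            w /= total
            for (a, b), wt in zip(pairs, w):
                counts[a] += wt
                counts[b] += wt
        f = counts / (2 * n)
        ll = _log_likelihood(pair_lists, f)
        if ll < ll_prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        if ll - ll_prev < tol:
            ll_prev = ll
            break
        ll_prev = ll
    return f, ll_prev, iters


def em_haplotype_frequencies(
    g: GenotypeMatrix,
    window: list[str],
    pop_samples: list[str],
    settings: EmSettings | None = None,
) -> EmResult:
    """Maximum-likelihood haplotype frequencies for one population's window."""
    settings = settings or EmSettings()
    m = len(window)
    if m > 8:
        raise ValueError("window limited to 8 SNPs (2^m haplotypes)")
    col_idx = g.snps.index_of(window)
    row_idx = g.sample_index(pop_samples)
    codes = g.codes[np.ix_(row_idx, col_idx)]
    complete = (codes != MISSING).all(axis=1)
    n_excluded = int((~complete).sum())
    codes = codes[complete]
    if codes.shape[0] == 0:
        raise DataError("no samples with complete calls in the window")

    # deduplicate genotype rows: identical genotypes share a pair list
    pair_cache: dict[tuple[int, ...], list[tuple[int, int]]] = {}
    pair_lists = []
    for row in codes:
        key = tuple(int(x) for x in row)
        if key not in pair_cache:
            pair_cache[key] = compatible_pairs(np.array(key))
        pair_lists.append(pair_cache[key])

    n_hap = 2**m
    # initialization 1: product of single-SNP allele frequencies
    p = codes.mean(axis=0) / 2.0
    haps = np.array(list(itertools.product((0, 1), repeat=m)))
    f_init = np.prod(np.where(haps == 1, p, 1 - p), axis=1)
    f_init = np.clip(f_init, 1e-12, None)
    f_init /= f_init.sum()

    rng = np.random.default_rng(settings.seed)
    starts = [f_init] + [
        rng.dirichlet(np.ones(n_hap)) for _ in range(settings.n_restarts - 1)
    ]
    best: tuple[np.ndarray, float, int] | None = None
    for f0 in starts:
        f, ll, iters = _em_run(pair_lists, f0, settings.tol, settings.max_iter)
        if best is None or ll > best[1] + 1e-12:
            best = (f, ll, iters)
    assert best is not None
    f, ll, iters = best

    alleles = [
        (g.snps.table["allele_a"].iloc[i], g.snps.table["allele_b"].iloc[i])
        for i in col_idx
    ]
    allele_strings = [
        "".join(alleles[i][bit] for i, bit in enumerate(h)) for h in haps
    ]
    return EmResult(
        window=list(window),
        haplotypes=haplotype_index_strings(m),
        allele_strings=allele_strings,
        frequencies=f,
        log_likelihood=ll,
        n_used=int(codes.shape[0]),
        n_excluded=n_excluded,
        n_iterations=iters,
        _threshold=settings.min_report_freq,
    )


def max_likelihood_oracle(
    codes: np.ndarray, n_restarts: int = 50, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Independent maximizer of the haplotype likelihood for tiny instances.

    Optimizes the observed-data log-likelihood over the frequency simplex via
    softmax-parameterized L-BFGS from many random starts; shares no code with
    the EM path beyond the pair enumeration.  Intended for m <= 3, n <= 4.
    """
    from scipy.optimize import minimize

    m = codes.shape[1]
    n_hap = 2**m
    pair_lists = [compatible_pairs(row) for row in codes]

    def neg_ll(z: np.ndarray) -> float:
        z = z - z.max()
        f = np.exp(z)
        f /= f.sum()
        return -_log_likelihood(pair_lists, f)

    rng = np.random.default_rng(seed)
    best_f, best_ll = None, -np.inf
    for _ in range(n_restarts):
        z0 = rng.normal(size=n_hap)
        res = minimize(neg_ll, z0, method="L-BFGS-B")
        z = res.x - res.x.max()
        f = np.exp(z)
        f /= f.sum()
        ll = _log_likelihood(pair_lists, f)
        if ll > best_ll:
            best_ll, best_f = ll, f
    assert best_f is not None
    return best_f, float(best_ll)


def poll_style_report(
    tables: dict[str, EmResult],
    named: list[tuple[str, str]],
) -> pd.DataFrame:
    """Table-3-style rendering: named haplotypes, residual mass as "Other".

    ``named`` lists (label, allele string) pairs, e.g. [("H1", "GGAA"), ...];
    one row per population with the animal count used, the number of
    haplotypes estimated above the reporting threshold, named-haplotype
    frequencies rounded to 2 decimals, and "Other" as 1 minus the named sum.
    """
    labels = [lab for lab, _ in named]
    if len(set(labels)) != len(labels):
        raise DataError("duplicate haplotype labels")
    rows = []
    for pop, res in tables.items():
        row: dict[str, object] = {
            "population": pop,
            "n_animals": res.n_used,
            "n_haplotypes": res.n_observed,
        }
        named_total = 0.0
        for lab, hap in named:
            if hap not in res.allele_strings:
                raise DataError(f"{lab}={hap!r} is not a haplotype of this window")
            freq = float(res.frequencies[res.allele_strings.index(hap)])
            row[lab] = round(freq, 2)
            named_total += freq
        row["Other"] = round(max(1.0 - named_total, 0.0), 2)
        rows.append(row)
    return pd.DataFrame(rows)
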