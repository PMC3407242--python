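"""Synthetic genotype panels under pure drift from a common ancestor.

Each population's allele frequency at a SNP is drawn around a shared ancestral
frequency p under the Balding-Nichols model: p_pop ~ Beta(p(1-c)/c,
(1-p)(1-c)/c), so that E[p_pop] = p and Var(p_pop) = c * p(1-p).  The drift
parameter c equals the expected pairwise F_ST between two symmetric
populations, which is what makes simulated panels usable as truth for
estimator-recovery checks.  SNPs are independent (no background linkage);
the only linkage structure available is an explicitly injected multi-SNP
haplotype block with per-population haplotype frequency vectors, emulating a
selected region such as the sheep Poll locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from breedline.genotypes import (
    CHROMOSOMES,
    MISSING,
    DataError,
    GenotypeMatrix,
    PopulationLabels,
    SnpMap,
)

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


def default_chromosome_layout(n_snps: int) -> list[tuple[str, int]]:
    """Spread SNPs as evenly as possible across 26 autosomes + X."""
    n_chrom = len(CHROMOSOMES)
    base, extra = divmod(n_snps, n_chrom)
    return [(c, base + (1 if i < extra else 0)) for i, c in enumerate(CHROMOSOMES)]


@dataclass
class DriftConfig:
    """Study conditions for a drift simulation.

    drift_c values are per population, in [0,1); samples_per_pop are diploid
    counts.  Ancestral frequencies are uniform on ``ancestral_maf_range``
    (default (0.05, 0.5), mimicking SNP-chip ascertainment against rare
    variants).  Positions fall on a regular per-chromosome grid: only
    chromosome membership matters downstream.
    """

    n_pops: int
    drift_c: list[float]
    n_snps: int
    samples_per_pop: list[int]
    seed: int
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    chromosomes: list[tuple[str, int]] | None = None
    missing_rate: float = 0.0
    pop_names: list[str] | None = None
    position_spacing_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if len(self.drift_c) != self.n_pops or len(self.samples_per_pop) != self.n_pops:
            raise ValueError("drift_c and samples_per_pop must have n_pops entries")
        if any(not 0.0 <= c < 1.0 for c in self.drift_c):
            raise ValueError("drift_c values must lie in [0,1); c=1 makes the Beta undefined")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0,1)")
        if self.chromosomes is None:
            self.chromosomes = default_chromosome_layout(self.n_snps)
        if sum(n for _, n in self.chromosomes) != self.n_snps:
            raise ValueError("per-chromosome SNP counts must sum to n_snps")
        if self.pop_names is None:
            self.pop_names = [f"POP{j + 1}" for j in range(self.n_pops)]


@dataclass
class HaplotypeBlockConfig:
    """A small SNP window with per-population haplotype frequency vectors.

    ``frequencies`` maps population code to a vector over the 2^m possible
    haplotypes of the m-SNP window, ordered as the binary expansion over
    (allele_a=0, allele_b=1) with the first window SNP as the most
    significant bit.
    """

    window_snps: list[str]
    frequencies: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        m = len(self.window_snps)
        if len(set(self.window_snps)) != m:
            raise DataError("window SNPs not distinct")
        for pop, vec in self.frequencies.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (2**m,):
                raise ValueError(f"{pop}: frequency vector must have 2^{m} entries")
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{pop}: haplotype frequencies sum to {vec.sum()}, not 1")
            self.frequencies[pop] = vec


@dataclass
class SimTruth:
    """Generating quantities recorded for recovery tests."""

    ancestral_freq: np.ndarray  # (n_snps,)
    pop_freq: np.ndarray  # (n_pops, n_snps)
    pop_names: list[str]
    hap_pairs: pd.DataFrame | None = None  # sample, hap1, hap2 (binary strings)
    block_window: list[str] = field(default_factory=list)


def simulate_balding_nichols(
    cfg: DriftConfig,
) -> tuple[GenotypeMatrix, SnpMap, PopulationLabels, SimTruth]:
    """Simulate independent SNP genotypes for K drifted populations.

    Per SNP l: p_l ~ Uniform(maf range); per population j with drift c_j > 0,
    p_jl ~ Beta(p_l(1-c_j)/c_j, (1-p_l)(1-c_j)/c_j) (p_jl = p_l when c_j = 0);
    genotype codes ~ Binomial(2, p_jl) independently per sample; missing calls
    i.i.d. at ``missing_rate``.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_snps
    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=L)

    pop_freq = np.empty((cfg.n_pops, L))
    for j, c in enumerate(cfg.drift_c):
        if c == 0.0:
            pop_freq[j] = p_anc
        else:
            scale = (1.0 - c) / c
            pop_freq[j] = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    samples: list[str] = []
    assignments: dict[str, str] = {}
    blocks = []
    for j, (name, n) in enumerate(zip(cfg.pop_names, cfg.samples_per_pop)):
        ids = [f"{name}_{i + 1:03d}" for i in range(n)]
        samples += ids
        assignments.update({s: name for s in ids})
        blocks.append(rng.binomial(2, pop_freq[j], size=(n, L)).astype(np.int8))
    codes = np.vstack(blocks) if blocks else np.empty((0, L), np.int8)

    if cfg.missing_rate > 0:
        codes[rng.random(codes.shape) < cfg.missing_rate] = MISSING

    rows = []
    for chrom, n in cfg.chromosomes:
        for i in range(n):
            pos = (i + 1) * cfg.position_spacing_bp
            rows.append((f"SNP{chrom}_{pos}", chrom, pos))
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), size=L)]
    snp_map = SnpMap(
        pd.DataFrame(
            {
                "snp_id": [r[0] for r in rows],
                "chromosome": [r[1] for r in rows],
                "position_bp": [r[2] for r in rows],
                "allele_a": [p[0] for p in pairs],
                "allele_b": [p[1] for p in pairs],
            }
        )
    ).sorted()

    g = GenotypeMatrix(samples, snp_map, codes)
    labels = PopulationLabels(assignments)
    truth = SimTruth(ancestral_freq=p_anc, pop_freq=pop_freq, pop_names=list(cfg.pop_names))
    return g, snp_map, labels, truth


def haplotype_index_strings(m: int) -> list[str]:
    """Binary haplotype labels ('00', '01', ...) for an m-SNP window."""
    return ["".join(str(b) for b in bits) for bits in itertools.product((0, 1), repeat=m)]


def vector_from_named(
    named: dict[str, float], window_alleles: list[tuple[str, str]], other: float = 0.0
) -> np.ndarray:
    """Build a 2^m frequency vector from allele-string haplotypes.

    ``named`` maps allele strings (e.g. "GGAA") to frequencies; residual mass
    ``other`` is spread uniformly over the remaining haplotypes.
    """
    m = len(window_alleles)
    haps = list(itertools.product((0, 1), repeat=m))
    strings = [
        "".join(window_alleles[i][bit] for i, bit in enumerate(h)) for h in haps
    ]
    vec = np.zeros(len(haps))
    for s, f in named.items():
        if s not in strings:
            raise DataError(f"haplotype {s!r} incompatible with window alleles")
        vec[strings.index(s)] = f
    rest = [i for i, s in enumerate(strings) if s not in named]
    if rest:
        vec[rest] = other / len(rest)
    elif other:
        raise ValueError("no unnamed haplotypes to carry 'other' mass")
    total = vec.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies sum to {total}, not 1")
    return vec


def inject_haplotype_block(
    g: GenotypeMatrix,
    truth: SimTruth,
    labels: PopulationLabels,
    block: HaplotypeBlockConfig,
    seed: int,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overwrite a SNP window with genotypes implied by drawn haplotype pairs.

    For each sample, two haplotypes are drawn i.i.d. from its population's
    frequency vector (random union of gametes); the window's genotype codes
    become the per-SNP sums.  The drawn pair is recorded in the returned
    truth.  Window SNPs must be distinct and lie on one chromosome.
    """
    idx = g.snps.index_of(block.window_snps)
    chroms = set(g.snps.table["chromosome"].iloc[idx])
    if len(chroms) != 1:
        raise DataError(f"window spans multiple chromosomes: {sorted(chroms)}")
    m = len(block.window_snps)
    haps = np.array(list(itertools.product((0, 1), repeat=m)), dtype=np.int8)
    strings = haplotype_index_strings(m)

    rng = np.random.default_rng(seed)
    codes = g.codes.copy()
    records = []
    for si, sample in enumerate(g.samples):
        pop = labels.assignments.get(sample)
        if pop is None or pop not in block.frequencies:
            continue
        vec = block.frequencies[pop]
        h1, h2 = rng.choice(len(vec), size=2, p=vec)
        codes[si, idx] = haps[h1] + haps[h2]
        records.append((sample, strings[h1], strings[h2]))

    new_truth = SimTruth(
        ancestral_freq=truth.ancestral_freq,
        pop_freq=truth.pop_freq,
        pop_names=truth.pop_names,
        hap_pairs=pd.DataFrame(records, columns=["sample", "hap1", "hap2"]),
        block_window=list(block.window_snps),
    )
    return GenotypeMatrix(list(g.samples), g.snps, codes), new_truth
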