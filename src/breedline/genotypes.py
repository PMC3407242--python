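"""Genotype/marker data model, PED/MAP I/O, population labels, and QC filters.

Genotypes are stored as allele-B dosage codes: each cell of the sample x SNP
matrix counts copies of ``allele_b`` (0, 1 or 2), with :data:`MISSING` (-1)
marking no-calls.  0 copies is a valid genotype, so missingness needs its own
sentinel.  Marker positions are 1-based base pairs; chromosome labels are kept
as strings so the X chromosome needs no special case (it is treated as an
ordinary diploid autosome throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (0 copies is a valid code).
MISSING: int = -1

VALID_ALLELES = frozenset("ACGT")

#: Chromosome labels accepted for sheep: 26 autosomes plus X.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 27)) + ("X",)


class PedMapError(ValueError):
    """Malformed PED/MAP input."""


class DataError(ValueError):
    """Structurally valid input with inadmissible content."""


def chromosome_sort_key(label: str) -> tuple[int, int]:
    """Order autosomes numerically with X (and any other label) after them."""
    try:
        return (0, int(label))
    except ValueError:
        return (1, 0)


@dataclass
class SnpMap:
    """Per-SNP marker map: id, chromosome, 1-based position, allele pair.

    Entries are kept sorted by (chromosome, position); ``allele_a`` is the
    reference for code 0 and ``allele_b`` the counted allele.
    """

    table: pd.DataFrame  # columns: snp_id, chromosome, position_bp, allele_a, allele_b

    def __post_init__(self) -> None:
        required = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"SnpMap table missing columns {missing_cols}")
        if self.table["snp_id"].duplicated().any():
            dup = self.table["snp_id"][self.table["snp_id"].duplicated()].iloc[0]
            raise DataError(f"duplicate snp_id {dup!r}")
        if (self.table["position_bp"] < 1).any():
            raise DataError("position_bp must be a positive 1-based integer")
        same = self.table["allele_a"] == self.table["allele_b"]
        if same.any():
            raise DataError(
                f"allele_a == allele_b at snp_id {self.table['snp_id'][same].iloc[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    def sorted(self) -> "SnpMap":
        key = self.table["chromosome"].map(chromosome_sort_key)
        order = sorted(
            range(len(self.table)),
            key=lambda i: (key.iloc[i], self.table["position_bp"].iloc[i]),
        )
        return SnpMap(self.table.iloc[order].reset_index(drop=True))

    def index_of(self, snp_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.table["snp_id"])}
        unknown = [s for s in snp_ids if s not in lookup]
        if unknown:
            raise DataError(f"unknown snp_id(s): {unknown}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)


@dataclass
class GenotypeMatrix:
    """Diploid allele-B dosage matrix for an ordered sample list."""

    samples: list[str]
    snps: SnpMap
    codes: np.ndarray  # (n_samples, n_snps) int8 in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError(f"invalid genotype code {self.codes[bad].flat[0]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.codes != MISSING

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        unknown = [s for s in sample_ids if s not in lookup]
        if unknown:
            raise DataError(f"unknown sample id(s): {unknown}")
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            [self.samples[i] for i in np.arange(self.n_samples)[keep]]
            if keep.dtype == bool
            else [self.samples[i] for i in keep],
            self.snps,
            self.codes[keep],
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.arange(self.n_snps)[keep] if keep.dtype == bool else keep
        sub_map = SnpMap(self.snps.table.iloc[idx].reset_index(drop=True))
        return GenotypeMatrix(list(self.samples), sub_map, self.codes[:, idx])

    def allele_b_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP allele-B frequency over called genotypes (NaN if none)."""
        codes = self.codes if sample_idx is None else self.codes[sample_idx]
        called = codes != MISSING
        n_chrom = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called, codes, 0).sum(axis=0) / n_chrom


@dataclass
class PopulationLabels:
    """sample_id -> population code, with optional population -> region map."""

    assignments: dict[str, str]
    regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not p for p in self.assignments.values()):
            raise DataError("empty population code")

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def validate_against(self, g: GenotypeMatrix) -> None:
        unknown = [s for s in self.assignments if s not in set(g.samples)]
        if unknown:
            raise DataError(f"labelled samples absent from genotype matrix: {unknown}")

    def as_array(self, samples: list[str]) -> np.ndarray:
        return np.array([self.assignments[s] for s in samples])


@dataclass
class QcReport:
    n_snps_in: int
    n_snps_removed: int
    n_snps_out: int
    n_samples_in: int
    n_samples_removed: int
    per_filter: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_snps_in - self.n_snps_removed != self.n_snps_out:
            raise ValueError("inconsistent SNP tallies in QcReport")


# ---------------------------------------------------------------------------
# PED/MAP I/O
#
# MAP: 4 whitespace-delimited columns (chromosome, snp_id, genetic distance --
# ignored on read, written as 0 -- and bp position).  PED: 6 leading columns
# (family, sample, sire=0, dam=0, sex, phenotype=-9) then one allele pair per
# SNP in {A,C,G,T,0}; "0 0" encodes a missing call.
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> tuple[GenotypeMatrix, SnpMap]:
    """Read a PED/MAP pair into a dosage matrix and marker map.

    Allele assignment per SNP: ``allele_a`` is the first allele observed
    scanning samples in file order; when a genotype introduces two new alleles
    at once the lexicographically smaller becomes ``allele_a``.  Codes count
    ``allele_b``; a SNP where only one allele is ever observed gets a
    placeholder ``allele_b`` (first of ACGT differing from ``allele_a``),
    which cannot affect the all-zero codes.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PedMapError(f"{map_path}:{lineno}: expected 4 MAP columns, got {len(parts)}")
            chrom, snp_id, _gd, pos = parts
            map_rows.append((snp_id, chrom, int(pos)))
    n_snps = len(map_rows)

    samples: list[str] = []
    genotype_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PedMapError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            samples.append(parts[1])
            genotype_rows.append(parts[6:])

    allele_a: list[str | None] = [None] * n_snps
    allele_b: list[str | None] = [None] * n_snps
    codes = np.full((len(samples), n_snps), MISSING, dtype=np.int8)

    for si, row in enumerate(genotype_rows):
        for li in range(n_snps):
            a1, a2 = row[2 * li], row[2 * li + 1]
            if a1 == "0" or a2 == "0":
                if a1 != a2:
                    raise PedMapError(
                        f"{ped_path}: sample {samples[si]!r} SNP {map_rows[li][0]!r}: "
                        f"allele '0' paired with {a1 if a2 == '0' else a2!r}"
                    )
                continue
            for a in (a1, a2):
                if a not in VALID_ALLELES:
                    raise PedMapError(
                        f"{ped_path}: invalid allele {a!r} at SNP {map_rows[li][0]!r}"
                    )
                if allele_a[li] is None:
                    # both alleles new in one genotype: lexicographic tie-break
                    if a1 != a2 and a is a1:
                        allele_a[li], allele_b[li] = sorted((a1, a2))
                    else:
                        allele_a[li] = a
                elif a != allele_a[li] and allele_b[li] is None:
                    allele_b[li] = a
                elif a not in (allele_a[li], allele_b[li]):
                    raise DataError(f">2 distinct alleles at SNP {map_rows[li][0]!r}")
            codes[si, li] = (a1 == allele_b[li]) + (a2 == allele_b[li])

    for li in range(n_snps):
        if allele_a[li] is None:
            allele_a[li] = "A"
        if allele_b[li] is None:
            allele_b[li] = next(b for b in "ACGT" if b != allele_a[li])

    table = pd.DataFrame(
        {
            "snp_id": [r[0] for r in map_rows],
            "chromosome": [r[1] for r in map_rows],
            "position_bp": [r[2] for r in map_rows],
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    snp_map = SnpMap(table).sorted()
    # reorder code columns to the sorted map
    order = {s: i for i, s in enumerate(table["snp_id"])}
    col_order = np.array([order[s] for s in snp_map.table["snp_id"]], dtype=int)
    return GenotypeMatrix(samples, snp_map, codes[:, col_order]), snp_map


def write_ped_map(
    g: GenotypeMatrix, m: SnpMap, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write the PED/MAP dialect; MISSING becomes "0 0". Returns the two paths."""
    out_prefix = Path(out_prefix)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for row in m.table.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")
    aa = m.table["allele_a"].to_numpy()
    bb = m.table["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for si, sample in enumerate(g.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            row = g.codes[si]
            for li in range(g.n_snps):
                c = row[li]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [aa[li], aa[li]]
                elif c == 1:
                    fields += [aa[li], bb[li]]
                else:
                    fields += [bb[li], bb[li]]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_population_labels(path: str | Path) -> PopulationLabels:
    """Read headerless TSV: sample_id<TAB>population[<TAB>region]."""
    assignments: dict[str, str] = {}
    regions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if parts == [""]:
                continue
            if len(parts) not in (2, 3):
                raise PedMapError(f"{path}:{lineno}: expected 2 or 3 TSV columns")
            assignments[parts[0]] = parts[1]
            if len(parts) == 3:
                regions[parts[1]] = parts[2]
    return PopulationLabels(assignments, regions)


def write_population_labels(labels: PopulationLabels, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for sample, pop in labels.assignments.items():
            if pop in labels.regions:
                fh.write(f"{sample}\t{pop}\t{labels.regions[pop]}\n")
            else:
                fh.write(f"{sample}\t{pop}\n")
    return path


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def apply_qc(
    g: GenotypeMatrix,
    snp_call_rate_min: float = 0.0,
    sample_call_rate_min: float = 0.0,
    maf_min: float = 0.0,
) -> tuple[GenotypeMatrix, QcReport]:
    """Generic call-rate and MAF filtering.

    Order is fixed: SNPs failing call rate or MAF (both computed over all
    input samples) are removed first, then samples failing call rate over the
    retained SNPs.  A SNP fails MAF when min(p, 1-p) < ``maf_min`` (so
    monomorphic SNPs fall to any positive threshold); thresholds at 0 are
    no-ops.
    """
    for name, v in (
        ("snp_call_rate_min", snp_call_rate_min),
        ("sample_call_rate_min", sample_call_rate_min),
        ("maf_min", maf_min),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")

    called = g.called()
    n_samples, n_snps = g.codes.shape

    snp_call_rate = called.mean(axis=0) if n_samples else np.ones(n_snps)
    fail_call = snp_call_rate < snp_call_rate_min
    p = g.allele_b_freq()
    maf = np.minimum(p, 1.0 - p)
    fail_maf = np.where(np.isnan(maf), True, maf < maf_min) if maf_min > 0 else np.zeros(n_snps, bool)
    keep_snps = ~(fail_call | fail_maf)
    if n_snps and not keep_snps.any():
        raise DataError("QC removed every SNP: empty marker panel")

    g2 = g.subset_snps(keep_snps)
    sample_call_rate = g2.called().mean(axis=1) if g2.n_snps else np.ones(n_samples)
    keep_samples = sample_call_rate >= sample_call_rate_min
    g3 = g2.subset_samples(keep_samples)

    report = QcReport(
        n_snps_in=n_snps,
        n_snps_removed=int((~keep_snps).sum()),
        n_snps_out=int(keep_snps.sum()),
        n_samples_in=n_samples,
        n_samples_removed=int((~keep_samples).sum()),
        per_filter={
            "snp_call_rate": int(fail_call.sum()),
            "snp_maf": int((fail_maf & ~fail_call).sum()),
            "sample_call_rate": int((~keep_samples).sum()),
        },
    )
    return g3, report
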