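"""Calibration of a candidate divergence against known breed comparisons.

A single pairwise F_ST number means little on its own; the calibration ladder
averages pairwise F_ST within comparison categories of increasing expected
divergence (selection lines within one breed < breeds of shared regional
origin < breeds from different European regions < European vs Asian breeds)
and asks where a candidate pair falls.  The verdict rule: a candidate at or
above the recognised-breed-pair average shows breed-level divergence.

A published 14-population sheep F_ST matrix (SNP50 panel; percent above the
diagonal, bootstrap-style SD x 1000 below) ships as a packaged fixture so the
ladder arithmetic is reproducible without the original genotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from breedline.genotypes import DataError

#: 4-SNP window spanning ~77 kb at the Poll (horns) locus on sheep chromosome 10.
POLL_WINDOW: tuple[str, ...] = (
    "OAR10_29469450",
    "OAR10_29511510",
    "OAR10_29538398",
    "OAR10_29546872",
)

#: Named haplotypes of the Poll window; H1 is associated with polledness.
POLL_NAMED: tuple[tuple[str, str], ...] = (("H1", "GGAA"), ("H2", "AGGT"), ("H3", "GGAT"))


@dataclass
class FstFixture:
    codes: list[str]
    regions: dict[str, str]
    animals: dict[str, int]
    fst_percent: pd.DataFrame  # symmetric, diagonal 0
    sd_x1000: pd.DataFrame  # symmetric, diagonal 0


@dataclass
class CategoryDef:
    """A comparison category over a pairwise matrix.

    rule: "pairs" (explicit pair list), "across" (all cross pairs of two
    disjoint sets), or "all_pairs" (every unordered pair within one set).
    """

    name: str
    rule: str
    populations: list[str] = field(default_factory=list)
    other_populations: list[str] = field(default_factory=list)
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def expand_pairs(self) -> list[tuple[str, str]]:
        if self.rule == "pairs":
            return list(self.pairs)
        if self.rule == "all_pairs":
            return list(itertools.combinations(self.populations, 2))
        if self.rule == "across":
            if set(self.populations) & set(self.other_populations):
                raise DataError(f"category {self.name!r}: sets not disjoint")
            return [
                (a, b) for a in self.populations for b in self.other_populations
            ]
        raise ValueError(f"unknown category rule {self.rule!r}")


#: The four ladder rungs plus the candidate pair, as used in the fixture study.
LADDER_CATEGORIES: tuple[CategoryDef, ...] = (
    CategoryDef(
        name="Selection lines within breed",
        rule="pairs",
        pairs=[("MER", "APM"), ("MEL", "MIL")],
    ),
    CategoryDef(
        name="Breed pairs of Mediterranean origin",
        rule="all_pairs",
        populations=["MER", "CAS", "CHU", "OJA", "RAM", "RAS"],
    ),
    CategoryDef(
        name="Breed pairs of Southern vs Northern European origin",
        rule="across",
        populations=["APD"],
        other_populations=["MER", "CAS", "CHU", "OJA", "RAM", "RAS"],
    ),
    CategoryDef(
        name="Breed pairs of Asian vs European origin",
        rule="across",
        populations=["SUM", "TIB"],
        other_populations=["APD", "MER", "CAS", "CHU", "OJA", "RAM", "RAS"],
    ),
    CategoryDef(
        name="Florida Native v Louisiana Native",
        rule="pairs",
        pairs=[("FLN", "LUN")],
    ),
)


def load_fst_fixture() -> FstFixture:
    """Load the packaged 14-population F_ST matrix fixture."""
    with resources.files("breedline.data").joinpath("breed_fst_reference.tsv").open() as fh:
        raw = pd.read_csv(fh, sep="\t")
    codes = list(raw["code"])
    mat = raw[codes].to_numpy(dtype=float)
    upper = np.triu(mat, k=1)
    lower = np.tril(mat, k=-1)
    fst = upper + upper.T
    sd = lower + lower.T
    return FstFixture(
        codes=codes,
        regions=dict(zip(codes, raw["origin"])),
        animals=dict(zip(codes, raw["animals"].astype(int))),
        fst_percent=pd.DataFrame(fst, index=codes, columns=codes),
        sd_x1000=pd.DataFrame(sd, index=codes, columns=codes),
    )


def load_poll_fixture() -> pd.DataFrame:
    """Published per-population frequencies of the named Poll haplotypes."""
    with resources.files("breedline.data").joinpath("poll_haplotypes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def category_average(
    matrix: pd.DataFrame, cat: CategoryDef
) -> tuple[int, float, float]:
    """(n_pairs, unrounded mean, mean rounded half-up to 1 dp) for a category."""
    pairs = cat.expand_pairs()
    if not pairs:
        raise DataError(f"category {cat.name!r} yields no pairs")
    missing = [p for pair in pairs for p in pair if p not in matrix.index]
    if missing:
        raise DataError(f"category {cat.name!r}: unknown populations {missing}")
    # symmetrize so pair orientation never matters
    sym = (matrix + matrix.T) / 2.0 if not matrix.equals(matrix.T) else matrix
    values = [float(sym.loc[a, b]) for a, b in pairs]
    avg = float(np.mean(values))
    return len(values), avg, round_half_up(avg, 1)


def calibration_table(
    matrix: pd.DataFrame, categories: list[CategoryDef] | tuple[CategoryDef, ...] = LADDER_CATEGORIES
) -> pd.DataFrame:
    rows = []
    for cat in categories:
        n, avg, rounded = category_average(matrix, cat)
        rows.append(
            {
                "category": cat.name,
                "n_comparisons": n,
                "avg_fst_percent": rounded,
                "avg_fst_percent_unrounded": avg,
            }
        )
    return pd.DataFrame(rows)


def breed_verdict(
    candidate_fst: float,
    calib: pd.DataFrame,
    line_category: str,
    breed_category: str,
) -> dict:
    """Classify a candidate pairwise F_ST (percent) against the ladder.

    "breed-level divergence" iff the candidate is at or above the
    recognised-breed-pair category average (boundary inclusive: the logic is
    'as divergent as recognised breeds', and exact ties are vanishingly rare).
    """
    by_name = calib.set_index("category")
    for name in (line_category, breed_category):
        if name not in by_name.index:
            raise DataError(f"category {name!r} not in calibration table")
    line_avg = float(by_name.loc[line_category, "avg_fst_percent_unrounded"])
    breed_avg = float(by_name.loc[breed_category, "avg_fst_percent_unrounded"])
    is_breed = candidate_fst >= breed_avg
    verdict = "breed-level divergence" if is_breed else "within-breed-scale divergence"
    # display averages with the same half-up rounding as the table itself
    narrative = (
        f"Candidate F_ST {round_half_up(candidate_fst, 1)}% is "
        f"{candidate_fst / breed_avg:.2f}x the recognised-breed-pair average "
        f"({round_half_up(breed_avg, 1)}%) and {candidate_fst / line_avg:.2f}x the "
        f"within-breed-line average ({round_half_up(line_avg, 1)}%): {verdict}."
    )
    return {
        "candidate_fst_percent": candidate_fst,
        "verdict": verdict,
        "ratio_to_line_avg": candidate_fst / line_avg,
        "ratio_to_breed_avg": candidate_fst / breed_avg,
        "line_category_avg": line_avg,
        "breed_category_avg": breed_avg,
        "narrative": narrative,
    }
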