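"""Mendelian cross statistics: penetrance, expected ratios, goodness of fit.

Offspring of engineered crosses are tabulated as genotype x tail-phenotype
counts over the categories no_tail, short_tail, kinked_tail and long_tail.
"Affected" means any of the first three categories. Penetrance is the
affected fraction with an exact (Clopper-Pearson) two-sided 95% confidence
interval — several observed cells sit at 0% or 100%, where the normal
approximation fails. Expected offspring proportions come from the Punnett
square of the two biallelic parents, computed before any viability
selection; the chi-square ratio test quantifies deviation from them (e.g.
missing homozygotes or under-represented compound heterozygotes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("no_tail", "short_tail", "kinked_tail", "long_tail")
AFFECTED_CATEGORIES = ("no_tail", "short_tail", "kinked_tail")


@dataclass
class PhenotypeTable:
    """Genotype x phenotype-category count matrix.

    ``counts`` is indexed by genotype label with the four category columns;
    optional extra columns (``breeding_type``, ``runt_death``) are carried
    through untouched — runt/death annotations are bookkeeping inside the
    no-tail cells, never added to totals.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.counts.columns]
        if missing:
            raise ValueError(f"missing phenotype columns: {missing}")
        if (self.counts[list(CATEGORIES)] < 0).any().any():
            raise ValueError("phenotype counts must be non-negative")

    @property
    def genotypes(self) -> list[str]:
        return list(self.counts.index)

    def row(self, genotype: str) -> pd.Series:
        if genotype not in self.counts.index:
            raise KeyError(f"unknown genotype {genotype!r}")
        r = self.counts.loc[genotype]
        if isinstance(r, pd.DataFrame):  # duplicated label (e.g. per breeding type)
            r = r[list(CATEGORIES)].sum()
        return r

    def total(self, genotype: str) -> int:
        return int(self.row(genotype)[list(CATEGORIES)].sum())

    def genotype_totals(self) -> dict[str, int]:
        return {g: self.total(g) for g in dict.fromkeys(self.genotypes)}

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"genotype": str})
        return cls(df.set_index("genotype"))

    def to_tsv(self, path) -> None:
        self.counts.reset_index().to_csv(path, sep="\t", index=False)


def aggregate_phenotypes(table: PhenotypeTable, genotype: str) -> tuple[int, int]:
    """(affected, total) for one genotype; affected = no/short/kinked tail."""
    row = table.row(genotype)
    affected = int(sum(row[c] for c in AFFECTED_CATEGORIES))
    return affected, table.total(genotype)


@dataclass(frozen=True)
class PenetranceEstimate:
    affected: int
    total: int
    estimate: float  # NaN when total == 0
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)


def penetrance(
    affected: int, total: int, confidence: float = 0.95
) -> PenetranceEstimate:
    """Point estimate with exact two-sided Clopper-Pearson interval."""
    if affected < 0 or affected > total:
        raise ValueError(f"affected must lie in [0, total], got {affected}/{total}")
    if total == 0:
        return PenetranceEstimate(0, 0, float("nan"), 0.0, 1.0, confidence)
    ci = stats.binomtest(affected, total).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return PenetranceEstimate(
        affected, total, affected / total, ci.low, ci.high, confidence
    )


@dataclass(frozen=True)
class CrossDesign:
    """Two biallelic parents; offspring proportions from the Punnett square."""

    parent1: tuple[str, str]
    parent2: tuple[str, str]

    @staticmethod
    def genotype_label(a: str, b: str) -> str:
        # deterministic label: named alleles alphabetically, wild type last
        key = lambda al: (al == "+", al)
        x, y = sorted((a, b), key=key)
        return f"{x}/{y}"


def expected_offspring(design: CrossDesign) -> dict[str, float]:
    """Punnett-square offspring genotype proportions (sum to 1)."""
    props: dict[str, float] = {}
    for a in design.parent1:
        for b in design.parent2:
            g = CrossDesign.genotype_label(a, b)
            props[g] = props.get(g, 0.0) + 0.25
    return props


@dataclass(frozen=True)
class RatioTestResult:
    statistic: float
    df: int
    pvalue: float


def ratio_test(
    observed: Union[Mapping[str, int], Sequence[int]],
    expected: Union[Mapping[str, float], Sequence[float]],
) -> RatioTestResult:
    """Chi-square goodness of fit of observed counts to expected proportions.

    ``statistic = sum (O - E)^2 / E`` with ``E = proportion * total`` and
    ``df = categories - 1``. The p-value is reported for convenience.
    """
    if isinstance(observed, Mapping):
        if not isinstance(expected, Mapping):
            raise TypeError("observed and expected must both be mappings or both sequences")
        keys = list(observed)
        if set(keys) != set(expected):
            raise ValueError("observed and expected categories differ")
        obs = np.array([observed[k] for k in keys], dtype=float)
        props = np.array([expected[k] for k in keys], dtype=float)
    else:
        obs = np.asarray(list(observed), dtype=float)
        props = np.asarray(list(expected), dtype=float)
    if len(obs) < 2:
        raise ValueError("ratio test needs at least two categories")
    if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError(f"expected proportions must sum to 1, got {props.sum()}")
    exp = props * obs.sum()
    if np.any(exp == 0):
        raise ValueError("expected count of zero in some category")
    res = stats.chisquare(obs, exp)
    return RatioTestResult(float(res.statistic), len(obs) - 1, float(res.pvalue))


# --- printed study tables ----------------------------------------------------


def _load_table(name: str) -> PhenotypeTable:
    with resources.files("tailscan.data").joinpath(name).open() as fh:
        return PhenotypeTable.from_tsv(fh)


def load_f2_intercross() -> PhenotypeTable:
    """F2 offspring of exon-6-deletion heterozygote intercrosses.

    63 heterozygotes (4 no-tail, 9 short, 8 kinked, 42 long), 35 wild-type
    littermates all long-tailed, and no viable homozygotes.
    """
    return _load_table("f2_intercross.tsv")


def load_compound_cross() -> PhenotypeTable:
    """Offspring of exon-6-deletion x intronic-RCS-insertion breeding pairs.

    Carries a ``breeding_type`` column (het x het, hom x het) and a
    ``runt_death`` column for the parenthetical runt counts inside the
    no-tail cells.
    """
    return _load_table("compound_cross.tsv")
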