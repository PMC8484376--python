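"""Segregation-distortion tests, phenotype-genotype association tables,
and two-point LOD scores for a backcross design.

In a backcross from a heterozygous F1 dam and a homozygous wild-type
sire, every progeny's informative (maternal) gamete is directly
observable, so the two-point recombination fraction is the binomial
maximum-likelihood estimate r_hat = R/N over N informative meioses with
R recombinants, and the LOD score has the closed form

    LOD = R log10(r_hat / 0.5) + (N - R) log10((1 - r_hat) / 0.5)

with the R = 0 limit N log10 2.  No interference or multipoint
machinery is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegregationTest",
    "TwoPointResult",
    "segregation_chisq",
    "association_table",
    "two_point_lod",
    "lod_at",
    "double_het_expectation",
]


@dataclass(frozen=True)
class SegregationTest:
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    chi2: float
    df: int
    p_value: float


def segregation_chisq(observed: Sequence[int],
                      expected_ratio: Sequence[float] | None = None
                      ) -> SegregationTest:
    """Pearson chi-square of observed class counts against an expected
    ratio (default 1:1:...), without continuity correction.

    The classic check is carrier vs non-carrier counts at a marker
    against the Mendelian 1:1 backcross expectation.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two classes")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    if expected_ratio is None:
        ratio = np.ones_like(obs)
    else:
        ratio = np.asarray(expected_ratio, dtype=float)
        if ratio.size != obs.size:
            raise ValueError("ratio length must match number of classes")
        if np.any(ratio <= 0):
            raise ValueError("expected ratio entries must be > 0")
    exp = total * ratio / ratio.sum()
    if np.any(exp == 0):
        raise ValueError("expected count of zero")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegregationTest(tuple(int(o) for o in obs), tuple(exp), chi2, df, p)


def association_table(genotypes: pd.DataFrame, loci: Sequence[str],
                      phenotype_col: str = "phenotype",
                      categories: Sequence[str] = ("AB", "WT", "UNCLEAR", "RB")
                      ) -> dict[str, pd.DataFrame]:
    """Phenotype x genotype contingency table per locus.

    ``genotypes`` has one row per individual with a phenotype column and
    one column per locus holding the Fayoumi-allele count (0/1/2).
    Rows are the genotype classes observed at the locus plus a Total
    row; columns the phenotype categories plus Total.
    """
    out: dict[str, pd.DataFrame] = {}
    for locus in loci:
        if locus not in genotypes.columns:
            raise KeyError(f"locus {locus!r} not in the genotype table")
        tab = pd.crosstab(genotypes[locus], genotypes[phenotype_col])
        tab = tab.reindex(columns=list(categories), fill_value=0)
        tab.index = [f"fay_count={int(i)}" for i in tab.index]
        tab["Total"] = tab.sum(axis=1)
        tab.loc["Total"] = tab.sum(axis=0)
        out[locus] = tab
    return out


@dataclass(frozen=True)
class TwoPointResult:
    n_informative: int
    n_recombinant: int
    r_hat: float
    lod: float


def _lod(r: float, n: int, rec: int) -> float:
    # 0 * log(0) -> 0 convention at the boundary estimates
    lod = 0.0
    if rec > 0:
        lod += rec * np.log10(r / 0.5)
    if n - rec > 0:
        lod += (n - rec) * np.log10((1 - r) / 0.5)
    return lod


def lod_at(r: float, n: int, n_recombinant: int) -> float:
    """LOD evaluated at an arbitrary recombination fraction r in (0, 1)."""
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    return _lod(r, n, n_recombinant)


def two_point_lod(geno_a: Sequence[float], geno_b: Sequence[float]
                  ) -> TwoPointResult:
    """Two-point linkage between two loci in a backcross.

    Inputs are per-progeny Fayoumi-allele counts (0 or 1; the trait can
    stand in for a locus by passing carrier indicators).  Meioses with
    a missing value at either locus are excluded.  Returns r_hat = R/N
    and the closed-form LOD at r_hat.
    """
    a = pd.to_numeric(pd.Series(geno_a), errors="coerce").to_numpy(float)
    b = pd.to_numeric(pd.Series(geno_b), errors="coerce").to_numpy(float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if not (set(np.unique(a)) <= {0.0, 1.0} and set(np.unique(b)) <= {0.0, 1.0}):
        raise ValueError("backcross genotypes must be coded 0/1")
    n = int(a.size)
    if n == 0:
        raise ValueError("no informative meioses")
    rec = int((a != b).sum())
    r_hat = rec / n
    return TwoPointResult(n, rec, r_hat, _lod(r_hat, n, rec))


def double_het_expectation(r: float) -> float:
    """Expected fraction of backcross progeny heterozygous at both of
    two linked loci, as a function of the recombination fraction r.

    The double heterozygote requires the non-recombinant maternal
    gamete carrying both founder alleles: (1 - r) / 2, i.e. 0.50 for
    fully linked loci and 0.25 for unlinked ones.
    """
    if not 0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    return (1 - r) / 2
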