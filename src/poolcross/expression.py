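"""Relative expression (delta-delta-Ct) and allelic-imbalance analysis
for the feather-follicle assays.

ddCt model: with amplification efficiency fixed at 2, a sample's
normalised expression of a target gene is

    dCt  = Ct_target - mean(Ct_HK1, Ct_HK2)
    ddCt = dCt - mean(dCt over the calibrator group)
    fold = 2 ** -ddCt

so the calibrator group has mean fold 1 by construction, and any
per-plate additive shift of all Cts cancels.  The arithmetic mean of
the two housekeeping Cts corresponds to the geometric mean of their
linear quantities.

Allelic imbalance compares the variant-allele fraction measured by
pyrosequencing in cDNA of heterozygotes against the genomic-DNA
heterozygote control, where a 50:50 ratio is expected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_expression",
    "group_compare",
    "allelic_imbalance",
    "ExpressionResult",
    "AllelicImbalanceResult",
]


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


def group_compare(values_a, values_b, equal_var: bool = True
                  ) -> tuple[float, float]:
    """Two-sided Student's t test (pooled variance by default; Welch
    with ``equal_var=False``).  Returns (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if equal_var and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class ExpressionResult:
    """ddCt output for one target gene."""

    gene: str
    per_sample: pd.DataFrame       # sample, group, dct, ddct, fold
    summary: pd.DataFrame          # group, n, mean_fold, sem_fold
    t_stat: float | None
    p_value: float | None

    def __str__(self) -> str:
        lines = [f"{self.gene}:"]
        for _, row in self.summary.iterrows():
            lines.append(f"  {row['group']}: fold change "
                         f"{row['mean_fold']:.2f} ± {row['sem_fold']:.2f} "
                         f"(n={int(row['n'])})")
        if self.p_value is not None:
            lines.append(f"  Student's t test p = {self.p_value:.4g}")
        return "\n".join(lines)


def relative_expression(samples: pd.DataFrame, target: str,
                        housekeeping: tuple[str, str] = ("EEF2", "ACTB"),
                        calibrator: str = "non_barred",
                        group_col: str = "group") -> ExpressionResult:
    """ddCt relative expression of ``target`` normalised to two
    housekeeping genes, calibrated to the mean of one group.

    ``samples`` is long format: sample, group, gene, ct.  Samples
    missing the target or either housekeeping Ct are dropped with a
    warning.  The between-group Student's t test is run on the
    per-sample fold changes when both groups have >= 2 usable samples.
    """
    wide = samples.pivot_table(index=["sample", group_col], columns="gene",
                               values="ct", aggfunc="mean").reset_index()
    needed = [target, *housekeeping]
    missing = [g for g in needed if g not in wide.columns]
    if missing:
        raise KeyError(f"no Ct measurements for gene(s): {missing}")
    usable = wide.dropna(subset=needed)
    dropped = len(wide) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} sample(s) dropped for missing Ct values")
    if usable.empty:
        raise ValueError("no usable samples")
    groups = usable[group_col].unique()
    if calibrator not in groups:
        raise ValueError(f"calibrator group {calibrator!r} has no samples")

    hk = usable[list(housekeeping)].mean(axis=1)
    dct = usable[target] - hk
    cal_mean = dct[usable[group_col] == calibrator].mean()
    ddct = dct - cal_mean
    fold = np.power(2.0, -ddct)

    per_sample = pd.DataFrame({
        "sample": usable["sample"].to_numpy(),
        "group": usable[group_col].to_numpy(),
        "dct": dct.to_numpy(), "ddct": ddct.to_numpy(),
        "fold": fold.to_numpy(),
    })
    # group fold = 2**-mean(ddCt), the geometric mean of per-sample
    # folds, so the calibrator group is exactly 1 by construction;
    # the quoted +/- is the SEM of the per-sample fold changes
    summary = (per_sample.groupby("group")
               .apply(lambda g: pd.Series({
                   "n": len(g),
                   "mean_fold": float(2.0 ** -g["ddct"].mean()),
                   "sem_fold": _sem(g["fold"].to_numpy()),
               }), include_groups=False)
               .reset_index())
    t = p = None
    others = [g for g in groups if g != calibrator]
    if len(others) == 1:
        fa = per_sample.loc[per_sample["group"] == others[0], "fold"]
        fb = per_sample.loc[per_sample["group"] == calibrator, "fold"]
        if len(fa) >= 2 and len(fb) >= 2:
            if fa.var(ddof=1) == 0 and fb.var(ddof=1) == 0:
                # noiseless groups: perfectly separated or identical
                t, p = (0.0, 1.0) if fa.mean() == fb.mean() \
                    else (float("inf") * np.sign(fa.mean() - fb.mean()), 0.0)
            else:
                t, p = group_compare(fa, fb)
    return ExpressionResult(target, per_sample, summary, t, p)


@dataclass
class AllelicImbalanceResult:
    """Variant-allele fractions in cDNA heterozygotes vs the gDNA
    heterozygote control, as percentages."""

    gene: str
    cdna_mean_pct: float
    cdna_sem_pct: float
    n_cdna: int
    gdna_mean_pct: float | None
    gdna_sem_pct: float | None
    n_gdna: int
    t_stat: float | None
    p_value: float | None
    deviation_from_half_pct: float = field(default=float("nan"))
    p_vs_half: float | None = None

    def __str__(self) -> str:
        s = (f"{self.gene}: Fayoumi-allele fraction in cDNA "
             f"{self.cdna_mean_pct:.1f} ± {self.cdna_sem_pct:.2f}% "
             f"(n={self.n_cdna})")
        if self.gdna_mean_pct is not None:
            s += (f"; gDNA control {self.gdna_mean_pct:.1f} ± "
                  f"{self.gdna_sem_pct:.2f}% (n={self.n_gdna})")
        if self.p_value is not None:
            s += f"; cDNA vs gDNA Student's t p = {self.p_value:.4g}"
        return s


def allelic_imbalance(obs: pd.DataFrame, gene: str | None = None
                      ) -> AllelicImbalanceResult:
    """Allelic-imbalance test from pyrosequencing fractions.

    ``obs`` is long format with columns sample, template (cDNA/gDNA),
    genotype (het/hom_ref/hom_fay), fraction (Fayoumi-allele fraction
    in [0, 1]) and optionally gene.  Only heterozygotes enter the test.
    With no gDNA heterozygote controls the cDNA means are still
    reported and the test skipped with a warning.
    """
    sub = obs
    if gene is not None and "gene" in obs.columns:
        sub = obs[obs["gene"] == gene]
    het = sub[sub["genotype"] == "het"]
    cdna = het.loc[het["template"] == "cDNA", "fraction"].to_numpy(float)
    gdna = het.loc[het["template"] == "gDNA", "fraction"].to_numpy(float)
    if cdna.size < 2:
        raise ValueError("need at least two cDNA heterozygote observations")
    if np.any((cdna < 0) | (cdna > 1)) or np.any((gdna < 0) | (gdna > 1)):
        raise ValueError("allele fractions must lie in [0, 1]")

    t = p = None
    gdna_mean = gdna_sem = None
    if gdna.size >= 2:
        gdna_mean, gdna_sem = 100 * gdna.mean(), 100 * _sem(gdna)
        if cdna.var(ddof=1) == 0 and gdna.var(ddof=1) == 0:
            t, p = (0.0, 1.0) if cdna.mean() == gdna.mean() else (np.inf, 0.0)
        else:
            t, p = group_compare(cdna, gdna)
    else:
        warnings.warn("no gDNA heterozygote controls; cDNA vs gDNA test skipped")

    if cdna.var(ddof=1) == 0:
        p_half = 1.0 if cdna.mean() == 0.5 else 0.0
    else:
        p_half = float(stats.ttest_1samp(cdna, 0.5).pvalue)
    return AllelicImbalanceResult(
        gene=gene or "", cdna_mean_pct=100 * cdna.mean(),
        cdna_sem_pct=100 * _sem(cdna), n_cdna=int(cdna.size),
        gdna_mean_pct=gdna_mean, gdna_sem_pct=gdna_sem, n_gdna=int(gdna.size),
        t_stat=t, p_value=p,
        deviation_from_half_pct=100 * (cdna.mean() - 0.5), p_vs_half=p_half)
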