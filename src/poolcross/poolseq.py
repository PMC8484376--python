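"""Pool-seq genome scans: per-variant F_ST, windowed statistics with
genome-wide Z scores and Bonferroni calls, and the pooled-heterozygosity
(Hp / Z_Hp) scan used to look for identical-by-descent regions.

Estimators
----------
Per biallelic variant with pool alt-allele frequencies ``p1, p2``
(``q = 1 - p``):

    pi_within  = (2 p1 q1 + 2 p2 q2) / 2
    pi_between = p1 q2 + p2 q1
    F_ST       = (pi_between - pi_within) / pi_between

F_ST is undefined (flagged, excluded from windows) when pi_between = 0.

Pooled heterozygosity over a window, with nMAJ/nMIN the per-variant
major/minor read counts summed across all breed pools:

    Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))**2

bounded in [0, 0.5].  Window statistics are standardised genome-wide
(sample sd), with a one-tailed normal p-value and Bonferroni correction
over the retained windows; the Hp scan additionally exposes the fixed
cutoff Z_Hp < -4.70.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pool_names",
    "variant_fst",
    "window_scan",
    "zscore_windows",
    "pooled_heterozygosity",
    "hp_windows",
    "hp_scan",
    "fst_scan",
    "ZeroVarianceError",
    "HP_Z_CUTOFF",
]

#: fixed significance cutoff for the Hp scan (p < .05 after Bonferroni
#: at genome scale in the original screen)
HP_Z_CUTOFF = -4.70


class ZeroVarianceError(ValueError):
    """All retained windows share the same statistic; Z scores undefined."""


def pool_names(counts: pd.DataFrame) -> list[str]:
    """Pool names from the ``<pool>_ref`` / ``<pool>_alt`` columns."""
    names = [c[:-4] for c in counts.columns if c.endswith("_ref")]
    for n in names:
        if f"{n}_alt" not in counts.columns:
            raise ValueError(f"pool {n!r} has a _ref but no _alt column")
    if not names:
        raise ValueError("no pool count columns found")
    return names


def variant_fst(counts: pd.DataFrame, pool_a: str, pool_b: str) -> pd.DataFrame:
    """Per-variant pool F_ST between two pools.

    Returns a frame with chrom, pos, p1, p2, pi_within, pi_between, fst
    plus two flags: ``covered`` (depth >= 1 in both pools) and
    ``defined`` (pi_between > 0).  Variants failing either flag carry
    NaN fst and are meant to be excluded from windowed averages.
    """
    for name in (pool_a, pool_b):
        if f"{name}_ref" not in counts.columns:
            raise KeyError(f"unknown pool {name!r}")
    r1 = counts[f"{pool_a}_ref"].to_numpy(float)
    a1 = counts[f"{pool_a}_alt"].to_numpy(float)
    r2 = counts[f"{pool_b}_ref"].to_numpy(float)
    a2 = counts[f"{pool_b}_alt"].to_numpy(float)
    d1, d2 = r1 + a1, r2 + a2
    covered = (d1 >= 1) & (d2 >= 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(covered, a1 / np.where(d1 > 0, d1, 1), np.nan)
        p2 = np.where(covered, a2 / np.where(d2 > 0, d2, 1), np.nan)
        q1, q2 = 1 - p1, 1 - p2
        pi_within = (2 * p1 * q1 + 2 * p2 * q2) / 2
        pi_between = p1 * q2 + p2 * q1
        fst = (pi_between - pi_within) / pi_between
    defined = covered & (pi_between > 0)
    fst = np.where(defined, fst, np.nan)
    return pd.DataFrame({
        "chrom": counts["chrom"].to_numpy(),
        "pos": counts["pos"].to_numpy(),
        "p1": p1, "p2": p2,
        "pi_within": pi_within, "pi_between": pi_between,
        "fst": fst, "covered": covered, "defined": defined,
    })


def _window_starts(max_pos: int, step_bp: int) -> np.ndarray:
    # window grid anchored at the chromosome start (0-based coordinate 0)
    last = ((max_pos - 1) // step_bp) * step_bp
    return np.arange(0, last + 1, step_bp, dtype=np.int64)


def _windowed_sums(pos: np.ndarray, values: np.ndarray, window_bp: int,
                   step_bp: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window counts and column sums over [start, start+window) in
    0-based half-open coordinates (variant positions are 1-based)."""
    starts = _window_starts(int(pos.max()), step_bp)
    pos0 = pos.astype(np.int64) - 1
    left = np.searchsorted(pos0, starts, side="left")
    right = np.searchsorted(pos0, starts + window_bp, side="left")
    n = right - left
    csum = np.vstack([np.zeros(values.shape[1]),
                      np.cumsum(values, axis=0)])
    sums = csum[right] - csum[left]
    return starts, n, sums


def window_scan(values: pd.DataFrame, value_col: str = "fst",
                window_bp: int = 30_000, step_bp: int | None = None,
                min_variants: int = 10) -> pd.DataFrame:
    """Arithmetic window means of a per-variant statistic.

    ``values`` needs chrom, pos (1-based) and ``value_col``; rows with
    NaN are dropped first (undefined variants).  Windows are
    ``[start, start + window_bp)`` in 0-based half-open coordinates on a
    grid anchored at the chromosome start; windows with fewer than
    ``min_variants`` variants are dropped.  Default step = window
    (non-overlapping), so the Bonferroni count is unambiguous.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    step = window_bp if step_bp is None else step_bp
    if step <= 0:
        raise ValueError("step_bp must be > 0")
    usable = values.dropna(subset=[value_col])
    rows = []
    for chrom in usable["chrom"].unique():
        sub = usable[usable["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        val = sub[value_col].to_numpy(float).reshape(-1, 1)
        starts, n, sums = _windowed_sums(pos, val, window_bp, step)
        keep = n >= max(min_variants, 1)
        with np.errstate(invalid="ignore"):
            mean = sums[:, 0] / np.where(n > 0, n, 1)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts[keep],
            "end": starts[keep] + window_bp,
            "n_variants": n[keep], "stat": mean[keep],
        }))
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_variants", "stat"])
    return pd.concat(rows, ignore_index=True)


def zscore_windows(windows: pd.DataFrame, alpha: float = 0.05,
                   tail: str = "upper",
                   fixed_cutoff: float | None = None) -> pd.DataFrame:
    """Standardise window statistics genome-wide and call significance.

    z = (stat - mean) / sd over all retained windows (sample sd, n-1);
    one-tailed normal p in the requested tail; a window is significant
    when p * n_windows < alpha (Bonferroni over retained windows).  When
    ``fixed_cutoff`` is given a ``below_cutoff`` column (z < cutoff) is
    added — the rule used by the Hp screen.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    n = len(windows)
    if n < 2:
        raise ValueError("need at least two retained windows")
    stat = windows["stat"].to_numpy(float)
    mu = stat.mean()
    sd = stat.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError(
            "window statistic has zero variance; Z scores are undefined")
    z = (stat - mu) / sd
    p = stats.norm.sf(z) if tail == "upper" else stats.norm.cdf(z)
    out = windows.copy()
    out["z"] = z
    out["p_bonferroni"] = np.minimum(p * n, 1.0)
    out["significant"] = p * n < alpha
    if fixed_cutoff is not None:
        out["below_cutoff"] = z < fixed_cutoff
    return out


def pooled_heterozygosity(sum_nmaj: float, sum_nmin: float,
                          literal: bool = False) -> float:
    """Hp for one window from major/minor read sums.

    Default: 2 * S_MAJ * S_MIN / (S_MAJ + S_MIN)^2, bounded in [0, 0.5]
    with the maximum at perfectly balanced counts.  ``literal=True``
    evaluates the alternative form 2 * S_MIN / (S_MAJ + S_MIN)^2 (a
    non-scale-invariant variant kept for comparison).
    """
    total = sum_nmaj + sum_nmin
    if total <= 0:
        raise ValueError("window has no reads")
    if literal:
        return 2.0 * sum_nmin / total ** 2
    return 2.0 * sum_nmaj * sum_nmin / total ** 2


def _major_minor(counts: pd.DataFrame,
                 pools: list[str] | None = None
                 ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    if pools is None:
        pools = pool_names(counts)
    ref_sum = sum(counts[f"{p}_ref"].to_numpy(np.int64) for p in pools)
    alt_sum = sum(counts[f"{p}_alt"].to_numpy(np.int64) for p in pools)
    # major allele per variant from counts summed across all pools;
    # ties resolved toward ref = major (choice does not affect Hp)
    nmaj = np.maximum(ref_sum, alt_sum)
    nmin = np.minimum(ref_sum, alt_sum)
    keep = (nmaj + nmin) >= 1
    return counts.loc[keep], nmaj[keep], nmin[keep]


def hp_windows(counts: pd.DataFrame, pools: list[str] | None = None,
               window_bp: int = 30_000, step_bp: int | None = None,
               min_variants: int = 10, literal: bool = False) -> pd.DataFrame:
    """Windowed Hp over a multi-pool counts table.

    Per variant the major/minor read counts are taken across all pools
    summed; per window the counts are summed over variants and Hp
    computed from the sums.  Variants with zero total depth are
    excluded; windows under ``min_variants`` are dropped.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    step = window_bp if step_bp is None else step_bp
    if step <= 0:
        raise ValueError("step_bp must be > 0")
    kept, nmaj, nmin = _major_minor(counts, pools)
    rows = []
    for chrom in kept["chrom"].unique():
        mask = (kept["chrom"] == chrom).to_numpy()
        sub = kept.loc[mask]
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        pos = sub["pos"].to_numpy()[order]
        vals = np.column_stack([nmaj[mask][order], nmin[mask][order]]).astype(float)
        starts, n, sums = _windowed_sums(pos, vals, window_bp, step)
        keep = n >= max(min_variants, 1)
        smaj, smin = sums[keep, 0], sums[keep, 1]
        total = smaj + smin
        with np.errstate(invalid="ignore", divide="ignore"):
            if literal:
                hp = 2.0 * smin / total ** 2
            else:
                hp = 2.0 * smaj * smin / total ** 2
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts[keep],
            "end": starts[keep] + window_bp, "n_variants": n[keep],
            "sum_nmaj": smaj.astype(np.int64),
            "sum_nmin": smin.astype(np.int64), "stat": hp,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_variants",
                                     "sum_nmaj", "sum_nmin", "stat"])
    return pd.concat(rows, ignore_index=True)


def hp_scan(counts: pd.DataFrame, pools: list[str] | None = None,
            window_bp: int = 30_000, step_bp: int | None = None,
            min_variants: int = 10, alpha: float = 0.05,
            cutoff: float = HP_Z_CUTOFF, literal: bool = False) -> pd.DataFrame:
    """Full pooled-heterozygosity scan: windowed Hp -> lower-tail Z_Hp
    with Bonferroni calls plus the fixed ``z < cutoff`` rule."""
    if pools is None:
        pools = pool_names(counts)
    if len(pools) < 2:
        raise ValueError("need at least two pools for an Hp scan")
    windows = hp_windows(counts, pools, window_bp, step_bp, min_variants,
                         literal=literal)
    return zscore_windows(windows, alpha=alpha, tail="lower",
                          fixed_cutoff=cutoff)


def fst_scan(counts: pd.DataFrame, pool_a: str, pool_b: str,
             window_bp: int = 30_000, step_bp: int | None = None,
             min_variants: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Full F_ST scan between two pools: per-variant F_ST -> 30 kb
    window means -> upper-tail Z with Bonferroni calls."""
    per_variant = variant_fst(counts, pool_a, pool_b)
    windows = window_scan(per_variant, "fst", window_bp, step_bp, min_variants)
    return zscore_windows(windows, alpha=alpha, tail="upper")
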