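"""Informative-marker selection, genotype-matrix coding, detection of
the non-recombining interval, and pool fixed/segregating state calls.

The marker filters reproduce the fine-mapping SNP selection: within a
candidate region, keep variants read-covered at >= ``min_depth`` in
both pools whose alt fraction lies in ``freq_range_pool_a`` in the
case pool and below ``freq_max_pool_b`` in the control pool (or, in the
alternative mode, whose per-variant F_ST exceeds a floor), then thin to
a randomly chosen subset with consecutive spacing inside a target
range.

Genotype matrices code each backcross individual at each line-
diagnostic marker by its count of Fayoumi-derived alleles:
HOM_WT (0), HET (1), HOM_FAY (2), MISSING.  A recombination event is a
change of code between adjacent markers within one individual; the
non-recombining interval is the maximal run of markers around an
anchor with zero such events across all individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .poolseq import variant_fst

__all__ = [
    "MarkerFilter",
    "GenotypeMatrix",
    "Interval",
    "apply_hard_filters",
    "select_markers",
    "build_genotype_matrix",
    "find_nonrecombining_interval",
    "classify_pool_state",
    "pool_state_matrix",
    "HOM_WT", "HET", "HOM_FAY", "MISSING",
    "CODE_LABELS",
]

HOM_WT, HET, HOM_FAY, MISSING = 0, 1, 2, -1
CODE_LABELS = {HOM_WT: "WT", HET: "HET", HOM_FAY: "FAY", MISSING: "MIS"}
_LABEL_CODES = {v: k for k, v in CODE_LABELS.items()}


@dataclass
class MarkerFilter:
    """Hard filters plus spacing for informative-SNP selection.

    Defaults follow the fine-mapping protocol: case-pool frequency in
    [0.4, 0.6], control-pool frequency < 0.2, >= 20 reads per pool, and
    neighbour spacing in 189-322 kb.  ``min_fst`` switches to the
    alternative high-differentiation mode (per-variant F_ST > min_fst
    instead of the two frequency windows).
    """

    region: tuple[str, int, int]  # chrom, start, end (1-based inclusive)
    freq_range_pool_a: tuple[float, float] = (0.4, 0.6)
    freq_max_pool_b: float = 0.2
    min_depth: int = 20
    spacing_range: tuple[int, int] = (189_000, 322_000)
    min_fst: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.freq_range_pool_a
        if not (0 <= lo <= hi <= 1) or not 0 <= self.freq_max_pool_b <= 1:
            raise ValueError("frequency bounds must lie in [0, 1]")
        if self.spacing_range[0] > self.spacing_range[1]:
            raise ValueError("spacing_min must be <= spacing_max")
        if self.region[1] > self.region[2]:
            raise ValueError("region start must be <= end")


def apply_hard_filters(counts: pd.DataFrame, pool_a: str, pool_b: str,
                       filt: MarkerFilter
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Region, depth and frequency (or F_ST) filters only; returns the
    surviving candidates sorted by position and per-filter attrition
    counts."""
    chrom, start, end = filt.region
    attrition: dict[str, int] = {"input": len(counts)}
    sub = counts[(counts["chrom"] == chrom) & (counts["pos"] >= start)
                 & (counts["pos"] <= end)].sort_values("pos")
    attrition["region"] = len(sub)

    da = sub[f"{pool_a}_ref"] + sub[f"{pool_a}_alt"]
    db = sub[f"{pool_b}_ref"] + sub[f"{pool_b}_alt"]
    sub = sub[(da >= filt.min_depth) & (db >= filt.min_depth)]
    attrition["depth"] = len(sub)

    fa = sub[f"{pool_a}_alt"] / (sub[f"{pool_a}_ref"] + sub[f"{pool_a}_alt"])
    fb = sub[f"{pool_b}_alt"] / (sub[f"{pool_b}_ref"] + sub[f"{pool_b}_alt"])
    if filt.min_fst is not None:
        fst = variant_fst(sub, pool_a, pool_b)["fst"].to_numpy()
        sub = sub[np.nan_to_num(fst, nan=-1.0) > filt.min_fst]
        attrition["fst"] = len(sub)
    else:
        lo, hi = filt.freq_range_pool_a
        sub = sub[(fa >= lo) & (fa <= hi) & (fb < filt.freq_max_pool_b)]
        attrition["frequency"] = len(sub)
    return sub, attrition


def select_markers(counts: pd.DataFrame, pool_a: str, pool_b: str,
                   filt: MarkerFilter, seed: int = 0) -> pd.DataFrame:
    """Apply hard filters, then thin to a spaced subset.

    Thinning is greedy left-to-right: the first marker is drawn at
    random among candidates within ``spacing_min`` of the leftmost
    candidate; each subsequent marker is drawn among candidates whose
    gap to the last selected one lies in ``spacing_range``.  When no
    candidate is in range, the next one beyond the range is taken and
    the oversized gap logged (``gap_exceeded`` column).  Deterministic
    for a given seed; re-applying the same filter to the output returns
    it unchanged provided 2 * spacing_min > spacing_max (true of the
    default 189-322 kb range).

    Returns the selected rows with an attrition record
    (``result.attrs['attrition']``) counting survivors of each filter.
    """
    sub, attrition = apply_hard_filters(counts, pool_a, pool_b, filt)
    if len(sub) == 0:
        raise ValueError(f"no markers survive the hard filters: {attrition}")

    pos = sub["pos"].to_numpy()
    rng = np.random.default_rng(seed)
    smin, smax = filt.spacing_range
    smin = max(smin, 1)  # a zero minimum gap would re-select the same marker
    chosen: list[int] = []
    gap_exceeded: list[bool] = []
    first_window = np.flatnonzero(pos < pos[0] + smin)
    i = int(rng.choice(first_window))
    chosen.append(i)
    gap_exceeded.append(False)
    while True:
        gaps = pos - pos[chosen[-1]]
        in_range = np.flatnonzero((gaps >= smin) & (gaps <= smax))
        if in_range.size:
            nxt = int(rng.choice(in_range))
            exceeded = False
        else:
            beyond = np.flatnonzero(gaps > smax)
            if beyond.size == 0:
                break
            nxt = int(beyond[0])
            exceeded = True
        chosen.append(nxt)
        gap_exceeded.append(exceeded)
    out = sub.iloc[chosen].copy()
    out["gap_exceeded"] = gap_exceeded
    attrition["selected"] = len(out)
    out.attrs["attrition"] = attrition
    return out.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Markers x individuals matrix of line-origin genotype codes.

    ``codes[i, j]`` is the code of marker ``i`` in individual ``j``:
    0 HOM_WT, 1 HET, 2 HOM_FAY, -1 MISSING.
    """

    chrom: str
    positions: np.ndarray            # 1-based bp, one per marker row
    marker_names: list[str]
    individuals: list[str]
    codes: np.ndarray                # int8, markers x individuals
    phenotypes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.marker_names), len(self.individuals)):
            raise ValueError("code matrix shape mismatch")
        valid = {HOM_WT, HET, HOM_FAY, MISSING}
        if not set(np.unique(self.codes)) <= valid:
            raise ValueError("invalid genotype codes")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.vectorize(CODE_LABELS.get)(self.codes),
            index=self.marker_names, columns=self.individuals)
        df.insert(0, "pos", self.positions)
        return df


def build_genotype_matrix(genotypes: pd.DataFrame, chrom: str,
                          positions: dict[str, int],
                          founder_alleles: dict[str, tuple[str, str]] | None = None,
                          phenotype_col: str = "phenotype") -> GenotypeMatrix:
    """Code a pedigree genotype table into a GenotypeMatrix.

    ``genotypes`` has one row per individual (column ``id``), a
    phenotype column, and one column per marker.  Marker cells are
    either Fayoumi-allele counts (0/1/2, NaN = missing) or ``"A/B"``
    allele pairs when ``founder_alleles`` maps marker -> (wt allele,
    fayoumi allele).  Markers whose two founder alleles coincide are
    not line-diagnostic and are dropped with a warning.
    """
    marker_names = [m for m in positions]
    order = np.argsort([positions[m] for m in marker_names], kind="stable")
    marker_names = [marker_names[i] for i in order]

    kept: list[str] = []
    rows: list[np.ndarray] = []
    for m in marker_names:
        col = genotypes[m]
        if founder_alleles is not None:
            wt, fay = founder_alleles[m]
            if wt == fay:
                warnings.warn(f"marker {m} is not line-diagnostic; excluded")
                continue
            codes = np.full(len(col), MISSING, dtype=np.int8)
            for j, cell in enumerate(col):
                if isinstance(cell, str) and "/" in cell:
                    alleles = cell.split("/")
                    if set(alleles) <= {wt, fay}:
                        codes[j] = alleles.count(fay)
        else:
            vals = pd.to_numeric(col, errors="coerce")
            codes = np.where(vals.isna(), MISSING, vals.fillna(MISSING)
                             ).astype(np.int8)
            if not set(np.unique(codes)) <= {HOM_WT, HET, HOM_FAY, MISSING}:
                raise ValueError(f"marker {m}: counts must be 0, 1, 2 or missing")
        kept.append(m)
        rows.append(codes)
    if not rows:
        raise ValueError("no line-diagnostic markers remain")
    phenos = (list(genotypes[phenotype_col]) if phenotype_col in genotypes
              else [])
    return GenotypeMatrix(
        chrom=chrom,
        positions=np.array([positions[m] for m in kept], dtype=np.int64),
        marker_names=kept,
        individuals=list(genotypes["id"]),
        codes=np.vstack(rows),
        phenotypes=phenos,
    )


@dataclass
class Interval:
    """A maximal non-recombining run of markers around an anchor."""

    chrom: str
    first_marker: str
    last_marker: str
    start: int
    end: int
    n_informative_meioses: int
    n_recombinants_at_borders: tuple[int, int]
    #: positions of the first flanking markers with >= 1 event
    #: (None at a chromosome end)
    flank_positions: tuple[int | None, int | None] = (None, None)


def _adjacent_events(codes: np.ndarray) -> np.ndarray:
    """Number of individuals changing code between each adjacent marker
    pair, skipping pairs where either code is missing."""
    a, b = codes[:-1], codes[1:]
    informative = (a != MISSING) & (b != MISSING)
    return ((a != b) & informative).sum(axis=1)


def find_nonrecombining_interval(matrix: GenotypeMatrix,
                                 carriers: np.ndarray | list[bool],
                                 anchor: str | None = None) -> Interval:
    """Maximal marker run with zero recombination events containing the
    anchor marker.

    ``carriers`` flags each individual (e.g. patterned phenotype).  The
    anchor defaults to the leftmost marker perfectly associated with
    carrier status (carrier <=> at least one Fayoumi allele, over all
    non-missing cells); an error listing the least-discordant markers
    is raised when none is perfect.  Borders are the first flanking
    markers with >= 1 event.
    """
    codes = matrix.codes
    if codes.shape[0] < 1:
        raise ValueError("empty genotype matrix")
    carriers = np.asarray(carriers, dtype=bool)
    if carriers.shape[0] != codes.shape[1]:
        raise ValueError("carrier flags do not match individuals")

    if anchor is None:
        observed = codes != MISSING
        has_fay = codes >= HET
        discord = ((has_fay != carriers[None, :]) & observed).sum(axis=1)
        perfect = np.flatnonzero(discord == 0)
        if perfect.size == 0:
            best = np.argsort(discord)[:3]
            cand = ", ".join(f"{matrix.marker_names[i]} ({discord[i]} discordant)"
                             for i in best)
            raise ValueError(
                f"no marker perfectly associated with carrier status; "
                f"best candidates: {cand}")
        a = int(perfect[0])  # leftmost on ties
    else:
        a = matrix.marker_names.index(anchor)

    events = _adjacent_events(codes)  # length n_markers - 1
    left = a
    while left > 0 and events[left - 1] == 0:
        left -= 1
    right = a
    while right < codes.shape[0] - 1 and events[right] == 0:
        right += 1

    left_flank = matrix.positions[left - 1] if left > 0 else None
    right_flank = (matrix.positions[right + 1]
                   if right < codes.shape[0] - 1 else None)
    n_border = (int(events[left - 1]) if left > 0 else 0,
                int(events[right]) if right < codes.shape[0] - 1 else 0)
    informative = int((codes[a] != MISSING).sum())
    return Interval(
        chrom=matrix.chrom,
        first_marker=matrix.marker_names[left],
        last_marker=matrix.marker_names[right],
        start=int(matrix.positions[left]),
        end=int(matrix.positions[right]),
        n_informative_meioses=informative,
        n_recombinants_at_borders=n_border,
        flank_positions=(None if left_flank is None else int(left_flank),
                         None if right_flank is None else int(right_flank)),
    )


def classify_pool_state(ref_count: int, alt_count: int,
                        fixed_threshold: float = 0.1) -> str:
    """Call a pool at one variant FIXED_REF / FIXED_ALT / SEGREGATING.

    With pools of 5 birds a single heterozygote gives an expected alt
    fraction of 0.1, so the default threshold sits exactly at that
    boundary and should be tuned to the pool size at hand.  Zero depth
    returns MISSING.
    """
    depth = ref_count + alt_count
    if depth < 1:
        return "MISSING"
    frac = alt_count / depth
    if frac < fixed_threshold:
        return "FIXED_REF"
    if frac > 1 - fixed_threshold:
        return "FIXED_ALT"
    return "SEGREGATING"


def pool_state_matrix(counts: pd.DataFrame, pools: list[str],
                      anchor: tuple[str, int, int] | None = None,
                      flank_bp: int = 5000,
                      fixed_threshold: float = 0.1) -> pd.DataFrame:
    """Fixed/segregating state per pool for variants around an anchor
    gene (``(chrom, start, end)`` 1-based), the haplotype-heatmap input.

    With ``anchor=None`` all variants are classified."""
    sub = counts
    if anchor is not None:
        chrom, start, end = anchor
        sub = counts[(counts["chrom"] == chrom)
                     & (counts["pos"] >= start - flank_bp)
                     & (counts["pos"] <= end + flank_bp)]
    out = sub[["chrom", "pos", "ref", "alt"]].copy()
    for p in pools:
        out[p] = [
            classify_pool_state(r, a, fixed_threshold)
            for r, a in zip(sub[f"{p}_ref"], sub[f"{p}_alt"])
        ]
    return out.reset_index(drop=True)
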