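"""Backcross pedigree and pooled read-count simulation.

The generator emulates the mapping design used for autosomal feather
patterning in chicken: a small number of founder dams from a patterned
line (here called "Fayoumi") crossed to wild-type ("Leghorn") sires, F1
dams backcrossed to a wild-type sire, and a few hundred backcross (BC)
progeny phenotyped into the categories AB (autosomal barring), WT
(wild-type), UNCLEAR and RB (red belly, males only).

Founders are fixed for alternative alleles at every marker, so each
marker is line-diagnostic and the allele carried (0 = Leghorn,
1 = Fayoumi) equals its line of origin.  BC progeny inherit one
recombinant maternal gamete (Haldane model, no crossover interference;
an optional cold region overrides the local rate) and one intact
Leghorn paternal gamete.

A fully penetrant biallelic causal locus plus an optional linked
modifier drive phenotype category probabilities through a configurable
conditional table (:class:`PhenotypeModel`).  Pooled sequencing is
emulated by Poisson depth and binomial allele sampling with a symmetric
per-read error flip.

All randomness flows from a single integer seed; identical arguments
give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "CrossConfig",
    "PhenotypeModel",
    "Individual",
    "Pedigree",
    "PoolSpec",
    "phenotype_in",
    "carrier_at",
    "simulate_cross",
    "simulate_pool_reads",
    "simulate_breed_pools",
]

SEXES = ("M", "F")
CATEGORIES = ("AB", "WT", "UNCLEAR", "RB")

#: 1 cM/Mb expressed in Morgans per base pair.
_CM_PER_MB_TO_M_PER_BP = 1e-8


@dataclass(frozen=True)
class Chromosome:
    """A chromosome with a uniform background recombination rate.

    The default rate of 4 cM/Mb is the genome-wide average reported for
    chicken.
    """

    name: str
    length_bp: int
    rate_cm_per_mb: float = 4.0

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"chromosome {self.name}: length must be >= 1 bp")
        if self.rate_cm_per_mb < 0:
            raise ValueError(f"chromosome {self.name}: rate must be >= 0")


class GeneticMap:
    """Piecewise-linear bp <-> Morgan map for one chromosome.

    Built from the chromosome background rate with an optional cold
    region ``(start, end, rate)`` (1-based inclusive bp) overriding the
    local rate.
    """

    def __init__(self, chrom: Chromosome,
                 cold_region: tuple[int, int, float] | None = None):
        bounds = [0, chrom.length_bp]
        rates = [chrom.rate_cm_per_mb]
        if cold_region is not None:
            start, end, rate = cold_region
            if not (1 <= start <= end <= chrom.length_bp):
                raise ValueError("cold region outside chromosome")
            if rate < 0:
                raise ValueError("cold region rate must be >= 0")
            bounds = [0, start - 1, end, chrom.length_bp]
            rates = [chrom.rate_cm_per_mb, rate, chrom.rate_cm_per_mb]
        self._bp = np.asarray(bounds, dtype=float)
        seg_len = np.diff(self._bp)
        seg_m = seg_len * np.asarray(rates) * _CM_PER_MB_TO_M_PER_BP
        self._cum_m = np.concatenate([[0.0], np.cumsum(seg_m)])
        self.total_morgans = float(self._cum_m[-1])

    def morgans(self, pos_bp: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(pos_bp, dtype=float), self._bp, self._cum_m)

    def bp(self, m: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(m, dtype=float), self._cum_m, self._bp)


def _default_markers(chrom: Chromosome, spacing: int) -> np.ndarray:
    return np.arange(spacing // 2, chrom.length_bp + 1, spacing, dtype=np.int64)


@dataclass
class CrossConfig:
    """Parameters of the two-line backcross design.

    Defaults mirror the mapping pedigree: 5 founder dams x 2 sires,
    12 F1 dams, 365 BC progeny.  ``transmission_distortion`` is the
    probability that an F1 gamete transmits the causal founder allele
    (0.5 = Mendelian; 159/365 ~ 0.436 mimics the observed deficit of
    carriers).
    """

    chromosomes: Sequence[Chromosome]
    causal_locus: tuple[str, int]
    modifier_locus: tuple[str, int] | None = None
    n_founder_dams: int = 5
    n_founder_sires: int = 2
    n_f1_dams: int = 12
    n_backcross: int = 365
    cold_region: tuple[str, int, int, float] | None = None
    transmission_distortion: float = 0.5
    variant_spacing_bp: int = 2000
    markers: Mapping[str, np.ndarray] | None = None
    seed: int = 0

    #: preset matching the observed carrier deficit (159 of 365 BC carriers)
    OBSERVED_DISTORTION = 159 / 365

    def __post_init__(self) -> None:
        self.chromosomes = tuple(self.chromosomes)
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n in ("n_founder_dams", "n_founder_sires", "n_f1_dams", "n_backcross"):
            if getattr(self, n) < 1:
                raise ValueError(f"{n} must be >= 1")
        if not 0.0 < self.transmission_distortion < 1.0:
            raise ValueError("transmission_distortion must be in (0, 1)")
        by_name = {c.name: c for c in self.chromosomes}
        for label, locus in (("causal", self.causal_locus),
                             ("modifier", self.modifier_locus)):
            if locus is None:
                continue
            chrom, pos = locus
            if chrom not in by_name:
                raise ValueError(f"{label} locus chromosome {chrom!r} not in genome")
            if not 1 <= pos <= by_name[chrom].length_bp:
                raise ValueError(f"{label} locus position outside chromosome")
        if self.cold_region is not None:
            chrom = self.cold_region[0]
            if chrom not in by_name:
                raise ValueError("cold region chromosome not in genome")
        # Marker map: auto-generated maps get the focal loci spliced in;
        # explicit maps must already contain them.
        if self.markers is None:
            if self.variant_spacing_bp < 1:
                raise ValueError("variant_spacing_bp must be >= 1")
            markers = {c.name: _default_markers(c, self.variant_spacing_bp)
                       for c in self.chromosomes}
            for locus in (self.causal_locus, self.modifier_locus):
                if locus is not None:
                    chrom, pos = locus
                    markers[chrom] = np.union1d(markers[chrom], [pos])
            self.markers = markers
        else:
            self.markers = {k: np.asarray(v, dtype=np.int64)
                            for k, v in self.markers.items()}
            for c in self.chromosomes:
                pos = self.markers.get(c.name)
                if pos is None or pos.size == 0:
                    raise ValueError(f"empty marker map on chromosome {c.name}")
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"markers not strictly sorted on {c.name}")
                if pos[0] < 1 or pos[-1] > c.length_bp:
                    raise ValueError(f"marker outside chromosome {c.name}")
            for label, locus in (("causal", self.causal_locus),
                                 ("modifier", self.modifier_locus)):
                if locus is not None:
                    chrom, pos = locus
                    if pos not in self.markers[chrom]:
                        raise ValueError(f"{label} locus not on the marker map")

    def genetic_map(self, chrom: Chromosome) -> GeneticMap:
        cold = None
        if self.cold_region is not None and self.cold_region[0] == chrom.name:
            cold = self.cold_region[1:]
        return GeneticMap(chrom, cold)


Key = tuple[bool, bool, str]  # (causal carrier, modifier carrier, sex)


@dataclass
class PhenotypeModel:
    """Conditional table P(category | causal genotype, modifier genotype, sex).

    The default model follows the observed backcross margins: zero AB or
    UNCLEAR among non-carriers, RB restricted to males, and — among
    causal carriers — AB:UNCLEAR:RB proportions of 66:3:5 with the
    modifier and 36:25:27 without (RB mass renormalised away for
    females).  Non-carrier males show the spurious red-belly class at a
    low rate (3/103).  The full table is a plain dict so alternative
    penetrance models can be supplied.
    """

    table: dict[Key, dict[str, float]]

    def __post_init__(self) -> None:
        for key, row in self.table.items():
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"phenotype probabilities for {key} do not sum to 1")
            if any(p < 0 for p in row.values()):
                raise ValueError("negative phenotype probability")
            for cat in row:
                if cat not in CATEGORIES:
                    raise ValueError(f"unknown phenotype category {cat!r}")

    @classmethod
    def default(cls) -> "PhenotypeModel":
        table: dict[Key, dict[str, float]] = {}
        for modifier in (True, False):
            table[(False, modifier, "M")] = {"WT": 100 / 103, "RB": 3 / 103}
            table[(False, modifier, "F")] = {"WT": 1.0}
        table[(True, True, "M")] = {"AB": 66 / 74, "UNCLEAR": 3 / 74, "RB": 5 / 74}
        table[(True, True, "F")] = {"AB": 66 / 69, "UNCLEAR": 3 / 69}
        table[(True, False, "M")] = {"AB": 36 / 88, "UNCLEAR": 25 / 88, "RB": 27 / 88}
        table[(True, False, "F")] = {"AB": 36 / 61, "UNCLEAR": 25 / 61}
        return cls(table)

    def draw(self, rng: np.random.Generator, carrier: bool, modifier: bool,
             sex: str) -> str:
        row = self.table[(carrier, modifier, sex)]
        cats = sorted(row)  # fixed order for determinism
        probs = np.array([row[c] for c in cats])
        return cats[rng.choice(len(cats), p=probs / probs.sum())]


@dataclass
class Individual:
    """One animal with phased line-origin haplotypes per chromosome.

    ``haplotypes[chrom]`` is a ``(maternal, paternal)`` pair of uint8
    arrays over the marker map, 0 = Leghorn-derived, 1 = Fayoumi-derived.
    """

    id: str
    sex: str
    generation: str  # P, F1 or BC
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]
    sire: str = "."
    dam: str = "."
    phenotype: str | None = None

    def fay_count(self, chrom: str, marker_index: int) -> int:
        mat, pat = self.haplotypes[chrom]
        return int(mat[marker_index]) + int(pat[marker_index])


@dataclass
class Pedigree:
    """Simulated pedigree plus the marker map and a crossover log.

    ``crossovers[individual_id][chrom]`` records the bp positions of
    the crossovers realised in that BC individual's maternal gamete —
    the ground truth against which breakpoint detection is checked.
    """

    config: CrossConfig
    model: PhenotypeModel
    markers: dict[str, np.ndarray]
    individuals: list[Individual]
    crossovers: dict[str, dict[str, np.ndarray]]

    def backcross(self) -> list[Individual]:
        return [i for i in self.individuals if i.generation == "BC"]

    def marker_index(self, chrom: str, pos: int) -> int:
        idx = int(np.searchsorted(self.markers[chrom], pos))
        if idx >= len(self.markers[chrom]) or self.markers[chrom][idx] != pos:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return idx

    def fay_counts(self, chrom: str, pos: int,
                   generation: str = "BC") -> np.ndarray:
        """Fayoumi allele count (0/1/2) at one marker across a generation."""
        idx = self.marker_index(chrom, pos)
        inds = [i for i in self.individuals if i.generation == generation]
        return np.array([i.fay_count(chrom, idx) for i in inds], dtype=np.int8)

    def genotype_table(self, generation: str = "BC") -> pd.DataFrame:
        """Flat table: id, sire, dam, sex, generation, phenotype, then one
        column per marker (``chrom:pos``) with the Fayoumi allele count."""
        inds = [i for i in self.individuals if i.generation == generation]
        meta = pd.DataFrame({
            "id": [i.id for i in inds],
            "sire": [i.sire for i in inds],
            "dam": [i.dam for i in inds],
            "sex": [i.sex for i in inds],
            "generation": [i.generation for i in inds],
            "phenotype": [i.phenotype if i.phenotype is not None else "."
                          for i in inds],
        })
        cols = {}
        for chrom, pos in self.markers.items():
            geno = np.stack([np.asarray(i.haplotypes[chrom][0], dtype=np.int16)
                             + i.haplotypes[chrom][1] for i in inds])
            for j, p in enumerate(pos):
                cols[f"{chrom}:{p}"] = geno[:, j]
        return pd.concat([meta, pd.DataFrame(cols)], axis=1)


def _gamete(rng: np.random.Generator, hap_a: np.ndarray, hap_b: np.ndarray,
            marker_m: np.ndarray, gmap: GeneticMap
            ) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete under Haldane's model (Poisson crossovers,
    no interference).  Returns (gamete, crossover bp positions)."""
    n_co = rng.poisson(gmap.total_morgans)
    co_m = np.sort(rng.uniform(0.0, gmap.total_morgans, n_co))
    start = int(rng.integers(2))
    phase = (start + np.searchsorted(co_m, marker_m)) % 2
    gam = np.where(phase == 0, hap_a, hap_b).astype(np.uint8)
    return gam, gmap.bp(co_m).astype(np.int64)


def simulate_cross(config: CrossConfig,
                   model: PhenotypeModel | None = None) -> Pedigree:
    """Simulate the full P -> F1 -> BC pedigree.

    Founder dams are homozygous Fayoumi (1) at every marker, founder and
    BC sires homozygous Leghorn (0); F1 dams are heterozygous
    everywhere.  Each BC progeny receives one recombinant maternal
    gamete and a non-recombinant Leghorn paternal gamete.  Transmission
    of the causal founder allele is biased to
    ``config.transmission_distortion`` by seeded rejection sampling of
    the causal-chromosome gamete.
    """
    if model is None:
        model = PhenotypeModel.default()
    rng = np.random.default_rng(config.seed)
    markers = {k: np.asarray(v) for k, v in config.markers.items()}
    chrom_names = [c.name for c in config.chromosomes]

    maps = {c.name: config.genetic_map(c) for c in config.chromosomes}
    marker_m = {name: maps[name].morgans(markers[name]) for name in chrom_names}

    def fixed_haps(value: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {name: (np.full(len(markers[name]), value, dtype=np.uint8),
                       np.full(len(markers[name]), value, dtype=np.uint8))
                for name in chrom_names}

    individuals: list[Individual] = []
    sires = [Individual(f"LBL_S{i+1}", "M", "P", fixed_haps(0))
             for i in range(config.n_founder_sires)]
    dams = [Individual(f"FAY_D{i+1}", "F", "P", fixed_haps(1))
            for i in range(config.n_founder_dams)]
    bc_sire = Individual("LBL_BC_SIRE", "M", "P", fixed_haps(0))
    individuals += sires + dams + [bc_sire]

    f1: list[Individual] = []
    for i in range(config.n_f1_dams):
        sire = sires[i % len(sires)]
        dam = dams[i % len(dams)]
        haps = {name: (np.ones(len(markers[name]), dtype=np.uint8),
                       np.zeros(len(markers[name]), dtype=np.uint8))
                for name in chrom_names}
        f1.append(Individual(f"F1_D{i+1}", "F", "F1", haps,
                             sire=sire.id, dam=dam.id))
    individuals += f1

    causal_chrom, causal_pos = config.causal_locus
    causal_idx = int(np.searchsorted(markers[causal_chrom], causal_pos))
    mod_idx = None
    if config.modifier_locus is not None:
        mod_chrom, mod_pos = config.modifier_locus
        mod_idx = int(np.searchsorted(markers[mod_chrom], mod_pos))

    td = config.transmission_distortion
    crossovers: dict[str, dict[str, np.ndarray]] = {}
    for k in range(config.n_backcross):
        dam = f1[k % len(f1)]
        haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        co_log: dict[str, np.ndarray] = {}
        for name in chrom_names:
            hap_fay, hap_leg = dam.haplotypes[name]
            gam, co = _gamete(rng, hap_fay, hap_leg, marker_m[name], maps[name])
            if name == causal_chrom and td != 0.5:
                target = 1 if rng.random() < td else 0
                while gam[causal_idx] != target:
                    gam, co = _gamete(rng, hap_fay, hap_leg,
                                      marker_m[name], maps[name])
            haps[name] = (gam, np.zeros(len(markers[name]), dtype=np.uint8))
            co_log[name] = co
        sex = SEXES[int(rng.integers(2))]
        carrier = bool(haps[causal_chrom][0][causal_idx])
        modifier = (bool(haps[mod_chrom][0][mod_idx])
                    if mod_idx is not None else False)
        phenotype = model.draw(rng, carrier, modifier, sex)
        ind = Individual(f"BC{k+1}", sex, "BC", haps,
                         sire=bc_sire.id, dam=dam.id, phenotype=phenotype)
        individuals.append(ind)
        crossovers[ind.id] = co_log

    return Pedigree(config, model, markers, individuals, crossovers)


# ---------------------------------------------------------------------------
# pooled read sampling


@dataclass
class PoolSpec:
    """A sequencing pool: a name, a membership predicate over
    ``(individual, pedigree)``, a target mean coverage and a symmetric
    per-read error rate."""

    name: str
    predicate: Callable[[Individual, Pedigree], bool]
    coverage: float = 45.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError(f"pool {self.name}: coverage must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"pool {self.name}: error rate must be in [0, 0.5)")


def phenotype_in(*categories: str) -> Callable[[Individual, Pedigree], bool]:
    cats = set(categories)
    return lambda ind, ped: ind.phenotype in cats


def carrier_at(locus: tuple[str, int] | None = None, *, carrier: bool = True
               ) -> Callable[[Individual, Pedigree], bool]:
    """Predicate selecting (non-)carriers at a locus (default: the causal
    locus of the pedigree's config)."""
    def pred(ind: Individual, ped: Pedigree) -> bool:
        chrom, pos = locus if locus is not None else ped.config.causal_locus
        idx = ped.marker_index(chrom, pos)
        return (ind.fay_count(chrom, idx) >= 1) == carrier
    return pred


_BASES = np.array(list("ACGT"))


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = rng.integers(4, size=n)
    alt = (ref + 1 + rng.integers(3, size=n)) % 4
    return _BASES[ref], _BASES[alt]


def _sample_reads(rng: np.random.Generator, freq: np.ndarray, coverage: float,
                  error_rate: float) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(coverage, size=len(freq))
    p_alt = freq * (1 - error_rate) + (1 - freq) * error_rate
    alt = rng.binomial(depth, p_alt)
    return depth - alt, alt


def simulate_pool_reads(pedigree: Pedigree, pools: Sequence[PoolSpec],
                        seed: int = 0) -> pd.DataFrame:
    """Pooled read counts at every marker for each pool.

    Each pool member contributes two chromosomes with equal weight; per
    variant the sequencing depth is Poisson(coverage) and each read is
    drawn from the pool allele frequency, flipped with the pool's error
    rate.  Returns the flat counts table (chrom, pos, ref, alt,
    ``<pool>_ref``, ``<pool>_alt``) with the Fayoumi allele as alt.
    """
    rng = np.random.default_rng(seed)
    bc = pedigree.backcross()
    members: dict[str, list[Individual]] = {}
    seen: dict[str, str] = {}
    for spec in pools:
        sel = [i for i in bc if spec.predicate(i, pedigree)]
        if not sel:
            raise ValueError(f"pool {spec.name!r} selected no individuals")
        for ind in sel:
            if ind.id in seen:
                raise ValueError(
                    f"pools must be disjoint: {ind.id} in both "
                    f"{seen[ind.id]!r} and {spec.name!r}")
            seen[ind.id] = spec.name
        members[spec.name] = sel

    frames = []
    for chrom, pos in pedigree.markers.items():
        n = len(pos)
        ref, alt = _alleles(rng, n)
        cols: dict[str, np.ndarray] = {
            "chrom": np.full(n, chrom), "pos": pos, "ref": ref, "alt": alt}
        for spec in pools:
            sel = members[spec.name]
            allele_sum = np.zeros(n, dtype=np.int64)
            for ind in sel:
                mat, pat = ind.haplotypes[chrom]
                allele_sum += mat.astype(np.int64) + pat
            freq = allele_sum / (2 * len(sel))
            r, a = _sample_reads(rng, freq, spec.coverage, spec.error_rate)
            cols[f"{spec.name}_ref"] = r
            cols[f"{spec.name}_alt"] = a
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def simulate_breed_pools(n_breeds: int, genome: Sequence[Chromosome],
                         ibd_segment: tuple[str, int, int] | None = None,
                         pool_size: int = 5, coverage: float = 10.0,
                         error_rate: float = 0.001,
                         variant_spacing_bp: int = 1000,
                         freq_range: tuple[float, float] = (0.05, 0.95),
                         breed_names: Sequence[str] | None = None,
                         seed: int = 0) -> pd.DataFrame:
    """Read counts for pools of unrelated breeds, optionally sharing an
    identical-by-descent (IBD) segment.

    Outside the segment each breed has an independent allele frequency
    per variant drawn uniformly from ``freq_range``; the pooled
    frequency is the realised frequency among ``2 * pool_size``
    chromosomes.  Inside ``ibd_segment`` (1-based inclusive) every breed
    is fixed for one shared allele per variant — the signature the
    pooled-heterozygosity scan is designed to detect.
    """
    if n_breeds < 2:
        raise ValueError("need at least two breed pools")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    genome = list(genome)
    names = {c.name for c in genome}
    if ibd_segment is not None:
        chrom, start, end = ibd_segment
        if chrom not in names:
            raise ValueError("IBD segment chromosome not in genome")
        length = next(c.length_bp for c in genome if c.name == chrom)
        if not (1 <= start <= end <= length):
            raise ValueError("IBD segment outside chromosome")
    if breed_names is None:
        breed_names = [f"breed{i+1}" for i in range(n_breeds)]
    elif len(breed_names) != n_breeds:
        raise ValueError("breed_names length mismatch")

    rng = np.random.default_rng(seed)
    lo, hi = freq_range
    frames = []
    for chrom in genome:
        pos = _default_markers(chrom, variant_spacing_bp)
        n = len(pos)
        ref, alt = _alleles(rng, n)
        ibd_mask = np.zeros(n, dtype=bool)
        if ibd_segment is not None and ibd_segment[0] == chrom.name:
            ibd_mask = (pos >= ibd_segment[1]) & (pos <= ibd_segment[2])
        shared = rng.integers(2, size=int(ibd_mask.sum()))
        cols: dict[str, np.ndarray] = {
            "chrom": np.full(n, chrom.name), "pos": pos, "ref": ref, "alt": alt}
        for name in breed_names:
            p = rng.uniform(lo, hi, size=n)
            freq = rng.binomial(2 * pool_size, p) / (2 * pool_size)
            freq[ibd_mask] = shared
            r, a = _sample_reads(rng, freq, coverage, error_rate)
            cols[f"{name}_ref"] = r
            cols[f"{name}_alt"] = a
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)
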