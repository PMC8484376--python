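"""One-config orchestration of the simulated mapping pipeline.

``run_pipeline`` executes, in order: backcross simulation, pooled read
sampling, the F_ST window scan (case vs control pool), optionally the
multi-breed Hp scan, informative-marker selection, genotype-matrix
construction with non-recombining-interval detection, and the
segregation chi-square at the causal locus.  Every stage writes a new
file under the run directory; a JSON manifest records the seed,
per-stage row counts and output checksums, and is byte-stable for a
fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as pio
from .linkage import segregation_chisq
from .markers import MarkerFilter, build_genotype_matrix, \
    find_nonrecombining_interval, select_markers
from .poolseq import HP_Z_CUTOFF, fst_scan, hp_scan
from .simulate import Chromosome, CrossConfig, PhenotypeModel, PoolSpec, \
    phenotype_in, simulate_breed_pools, simulate_cross, simulate_pool_reads

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    seed: int
    out_dir: Path
    cross: CrossConfig
    pool_a: PoolSpec
    pool_b: PoolSpec
    window_bp: int = 30_000
    step_bp: int | None = None
    min_variants: int = 10
    alpha: float = 0.05
    hp: dict[str, Any] | None = None
    marker_filter: MarkerFilter | None = None
    segregation_ratio: tuple[float, float] = (1.0, 1.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        seed = int(raw.get("seed", 0))
        sim = dict(raw["simulate"])
        chroms = [Chromosome(**c) for c in sim.pop("chromosomes")]
        causal = tuple(sim.pop("causal_locus"))
        modifier = sim.pop("modifier_locus", None)
        cold = sim.pop("cold_region", None)
        cross = CrossConfig(
            chromosomes=chroms, causal_locus=causal,
            modifier_locus=tuple(modifier) if modifier else None,
            cold_region=tuple(cold) if cold else None,
            seed=seed, **sim)

        pools_cfg = raw.get("pools")
        if not pools_cfg or "pool_a" not in pools_cfg or "pool_b" not in pools_cfg:
            raise ValueError("config must define pools.pool_a and pools.pool_b")

        def build_pool(cfg: dict[str, Any]) -> PoolSpec:
            cfg = dict(cfg)
            phenos = cfg.pop("phenotypes")
            return PoolSpec(cfg.pop("name"), phenotype_in(*phenos), **cfg)

        scan = raw.get("scan", {})
        mf = raw.get("marker_filter")
        filt = None
        if mf is not None:
            mf = dict(mf)
            mf["region"] = tuple(mf["region"])
            if "freq_range_pool_a" in mf:
                mf["freq_range_pool_a"] = tuple(mf["freq_range_pool_a"])
            if "spacing_range" in mf:
                mf["spacing_range"] = tuple(mf["spacing_range"])
            filt = MarkerFilter(**mf)
        return cls(
            seed=seed, out_dir=Path(raw["out_dir"]), cross=cross,
            pool_a=build_pool(pools_cfg["pool_a"]),
            pool_b=build_pool(pools_cfg["pool_b"]),
            window_bp=int(scan.get("window_bp", 30_000)),
            step_bp=scan.get("step_bp"),
            min_variants=int(scan.get("min_variants", 10)),
            alpha=float(scan.get("alpha", 0.05)),
            hp=raw.get("hp"), marker_filter=filt,
            segregation_ratio=tuple(raw.get("segregation_ratio", (1, 1))),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, path: Path, rows: int, **extra: Any) -> None:
        manifest["stages"][stage] = {
            "path": path.name, "rows": rows, "sha256": _sha256(path), **extra}
        manifest_path.write_text(json.dumps(manifest, indent=2))

    stage = "simulate"
    try:
        pedigree = simulate_cross(config.cross, PhenotypeModel.default())
        ped_path = out / "pedigree.tsv"
        table = pedigree.genotype_table("BC")
        pio.write_pedigree_tsv(table, ped_path)
        record(stage, ped_path, len(table))

        stage = "pool_reads"
        counts = simulate_pool_reads(
            pedigree, [config.pool_a, config.pool_b], seed=config.seed + 1)
        counts_path = out / "pool_counts.tsv"
        pio.write_counts_tsv(counts, counts_path)
        pio.write_counts_vcf(counts, out / "pool_counts.vcf")
        record(stage, counts_path, len(counts))

        stage = "fst_scan"
        windows = fst_scan(counts, config.pool_a.name, config.pool_b.name,
                           config.window_bp, config.step_bp,
                           config.min_variants, config.alpha)
        fst_path = out / "fst_windows.tsv"
        pio.write_windows_tsv(windows, fst_path)
        top = windows.iloc[int(np.argmax(windows["stat"].to_numpy()))]
        record(stage, fst_path, len(windows),
               top_window={"chrom": str(top["chrom"]),
                           "start": int(top["start"]), "end": int(top["end"]),
                           "stat": float(top["stat"])})

        if config.hp is not None and config.hp.get("enabled", True):
            stage = "hp_scan"
            hp_cfg = dict(config.hp)
            hp_cfg.pop("enabled", None)
            genome = [Chromosome(**c) for c in hp_cfg.pop("genome")]
            ibd = hp_cfg.pop("ibd_segment", None)
            cutoff = float(hp_cfg.pop("cutoff", HP_Z_CUTOFF))
            breed_counts = simulate_breed_pools(
                genome=genome, ibd_segment=tuple(ibd) if ibd else None,
                seed=config.seed + 2, **hp_cfg)
            hp_out = hp_scan(breed_counts, window_bp=config.window_bp,
                             step_bp=config.step_bp,
                             min_variants=config.min_variants,
                             alpha=config.alpha, cutoff=cutoff)
            hp_path = out / "hp_windows.tsv"
            pio.write_windows_tsv(hp_out, hp_path)
            record(stage, hp_path, len(hp_out))

        if config.marker_filter is not None:
            stage = "select_markers"
            selected = select_markers(counts, config.pool_a.name,
                                      config.pool_b.name,
                                      config.marker_filter,
                                      seed=config.seed + 3)
            sel_path = out / "selected_markers.tsv"
            selected.to_csv(sel_path, sep="\t", index=False)
            record(stage, sel_path, len(selected),
                   attrition=selected.attrs["attrition"])

        stage = "interval"
        causal_chrom, causal_pos = config.cross.causal_locus
        chrom_markers = pedigree.markers[causal_chrom]
        positions = {f"{causal_chrom}:{p}": int(p) for p in chrom_markers}
        matrix = build_genotype_matrix(table, causal_chrom, positions)
        carriers = pedigree.fay_counts(causal_chrom, causal_pos) >= 1
        interval = find_nonrecombining_interval(matrix, carriers)
        bed_path = out / "interval.bed"
        pio.write_interval_bed(interval, bed_path)
        record(stage, bed_path, 1,
               interval={"start": interval.start, "end": interval.end})

        stage = "segregation"
        n_car = int(carriers.sum())
        test = segregation_chisq([len(carriers) - n_car, n_car],
                                 config.segregation_ratio)
        seg_path = out / "segregation.json"
        seg_path.write_text(json.dumps({
            "observed": list(test.observed), "chi2": test.chi2,
            "df": test.df, "p_value": test.p_value}, indent=2))
        record(stage, seg_path, 1, chi2=test.chi2)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise

    manifest["status"] = "complete"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
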