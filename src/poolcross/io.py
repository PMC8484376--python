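"""Readers and writers for the flat formats used across the pipeline.

Variant pool counts travel either as a TSV dialect
(``chrom pos ref alt <pool>_ref <pool>_alt ...``, positions 1-based) or
as VCF 4.2 with one sample per pool and per-sample AD (ref,alt depth)
fields; VCF parsing goes through pysam.  Only biallelic SNV records are
used — others are skipped and counted.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .markers import Interval
from .poolseq import pool_names

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_counts_vcf", "write_counts_vcf",
    "read_pedigree_tsv", "write_pedigree_tsv",
    "write_windows_tsv", "read_windows_tsv", "write_interval_bed",
    "read_genotype_matrix_tsv", "write_genotype_matrix_tsv",
]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t")
    pool_names(counts)  # validates column structure
    return counts


def write_counts_vcf(counts: pd.DataFrame, path: str | Path) -> None:
    """Write the counts table as uncompressed VCF 4.2, one sample per
    pool, AD carrying (ref, alt) read depths."""
    pools = pool_names(counts)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Read depth per allele">',
    ]
    for chrom in counts["chrom"].unique():
        end = int(counts.loc[counts["chrom"] == chrom, "pos"].max())
        lines.append(f"##contig=<ID={chrom},length={end + 1}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(pools))
    for row in counts.itertuples(index=False):
        sample_fields = "\t".join(
            f"{getattr(row, f'{p}_ref')},{getattr(row, f'{p}_alt')}"
            for p in pools)
        lines.append(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tAD\t{sample_fields}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_vcf(path: str | Path) -> pd.DataFrame:
    """Read pool counts from a VCF with per-sample AD fields.

    Multi-allelic or non-SNV records are skipped with a summary
    warning.
    """
    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if (len(rec.alts or ()) != 1 or len(rec.ref) != 1
                    or len(rec.alts[0]) != 1):
                skipped += 1
                continue
            row = {"chrom": rec.chrom, "pos": rec.pos,
                   "ref": rec.ref, "alt": rec.alts[0]}
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    row[f"{s}_ref"], row[f"{s}_alt"] = 0, 0
                else:
                    row[f"{s}_ref"], row[f"{s}_alt"] = int(ad[0]), int(ad[1])
            rows.append(row)
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic/non-SNV record(s)")
    if not rows:
        raise ValueError(f"no usable biallelic SNV records in {path}")
    return pd.DataFrame(rows)


def write_pedigree_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_windows_tsv(windows: pd.DataFrame, path: str | Path) -> None:
    windows.to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps read -> write byte-identical
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_interval_bed(interval: Interval, path: str | Path,
                       name: str = "nonrecombining_interval") -> None:
    """BED (0-based half-open) line for a marker interval, plus a
    side-car JSON with the full report."""
    bed = f"{interval.chrom}\t{interval.start - 1}\t{interval.end}\t{name}\n"
    Path(path).write_text(bed)
    report = {
        "chrom": interval.chrom,
        "first_marker": interval.first_marker,
        "last_marker": interval.last_marker,
        "start_1based": interval.start,
        "end_1based": interval.end,
        "n_informative_meioses": interval.n_informative_meioses,
        "n_recombinants_at_borders": list(interval.n_recombinants_at_borders),
        "flank_positions": list(interval.flank_positions),
    }
    Path(path).with_suffix(".json").write_text(json.dumps(report, indent=2))


def write_genotype_matrix_tsv(matrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="marker")


def read_genotype_matrix_tsv(path: str | Path, chrom: str = ""):
    from .markers import GenotypeMatrix, _LABEL_CODES

    df = pd.read_csv(path, sep="\t", index_col="marker")
    pos = df.pop("pos").to_numpy(np.int64)
    codes = df.apply(lambda col: col.map(_LABEL_CODES)).to_numpy()
    return GenotypeMatrix(chrom=chrom, positions=pos,
                          marker_names=list(df.index),
                          individuals=list(df.columns), codes=codes)
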