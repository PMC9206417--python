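"""Format readers and writers.

Conventions: genomic coordinates are 1-based inclusive everywhere inside
the package; BED-like output converts to 0-based half-open at the
boundary (start0 = start - 1, end unchanged).  All tabular formats are
plain text and round-trip losslessly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .variants import CNVCall, CoverageTrack, VARIANT_CLASSES

__all__ = [
    "read_growth_table",
    "write_growth_table",
    "read_rates",
    "write_rates",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_coverage",
    "write_coverage",
    "write_cnv_bed",
    "read_cnv_bed",
    "read_meta",
    "write_meta",
    "SchemaError",
]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{os.fspath(path)}: missing column(s) {missing}; found {list(df.columns)}"
        )


GROWTH_COLUMNS = ["genotype", "sugar", "replicate", "time_min", "od600"]


def read_growth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, GROWTH_COLUMNS, path)
    return df


def write_growth_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, GROWTH_COLUMNS, path)
    df.to_csv(path, index=False)


RATES_COLUMNS = ["genotype", "sugar", "mu_max", "n_replicates"]


def read_rates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RATES_COLUMNS, path)
    return df


def write_rates(df: pd.DataFrame, path) -> None:
    _require_columns(df, RATES_COLUMNS, path)
    df.to_csv(path, index=False)


META_COLUMNS = ["strain", "treatment", "phenotype", "replicate", "timepoint"]


def read_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["strain", "treatment", "phenotype"], path)
    return df


def write_meta(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF-lite: one record per (strain, variant); metadata in INFO fields.

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##INFO=<ID=STRAIN,Number=1,Type=String,Description="Carrier strain id">
##INFO=<ID=GENE,Number=1,Type=String,Description="Locus name">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant class: SNP, indel, CNV_dup or CNV_del">
##INFO=<ID=ANN,Number=0,Type=Flag,Description="Locus fully annotated">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(
    df: pd.DataFrame, path, chrom: str = "chr1", contig_length: int = 2_500_000
) -> None:
    """Write a variant table as minimal single-contig VCF."""
    _require_columns(df, ["strain", "gene", "position", "var_class", "annotated"], path)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=contig_length))
        for row in df.sort_values(["position", "strain"]).itertuples(index=False):
            info = f"STRAIN={row.strain};GENE={row.gene};CLASS={row.var_class}"
            if bool(row.annotated):
                info += ";ANN"
            fh.write(f"{chrom}\t{int(row.position)}\t.\tN\t<VAR>\t.\tPASS\t{info}\n")


def read_variants_vcf(path) -> pd.DataFrame:
    """Read a VCF-lite file back into the tabular variant representation."""
    import pysam

    rows = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            info = rec.info
            try:
                var_class = info["CLASS"]
                rows.append(
                    {
                        "strain": info["STRAIN"],
                        "gene": info["GENE"],
                        "position": rec.pos,
                        "var_class": var_class,
                        "annotated": bool(info.get("ANN", False)),
                    }
                )
            except KeyError as exc:
                raise SchemaError(
                    f"{os.fspath(path)}: record at pos {rec.pos} lacks INFO field {exc}"
                ) from exc
    df = pd.DataFrame(rows, columns=["strain", "gene", "position", "var_class", "annotated"])
    bad = set(df["var_class"]) - set(VARIANT_CLASSES)
    if bad:
        raise SchemaError(f"{os.fspath(path)}: unknown variant class(es) {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Coverage and CNV calls


def write_coverage(track: CoverageTrack, path) -> None:
    """Binned depth as TSV: bin_start (1-based), depth."""
    starts = np.arange(track.n_bins) * track.bin_size + 1
    pd.DataFrame({"bin_start": starts, "depth": track.depth}).to_csv(
        path, sep="\t", index=False
    )


def read_coverage(path, bin_size: int | None = None) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["bin_start", "depth"], path)
    starts = df["bin_start"].to_numpy()
    if bin_size is None:
        if len(starts) < 2:
            raise SchemaError(f"{os.fspath(path)}: cannot infer bin size from one bin")
        bin_size = int(starts[1] - starts[0])
    expected = np.arange(len(starts)) * bin_size + 1
    if not np.array_equal(starts, expected):
        raise SchemaError(f"{os.fspath(path)}: bins do not tile the genome from base 1")
    return CoverageTrack(df["depth"].to_numpy(), bin_size=bin_size)


def write_cnv_bed(calls: list[CNVCall], path, chrom: str = "chr1") -> None:
    """CNV calls as BED-like TSV (0-based half-open: start0 = start - 1)."""
    rows = [
        {
            "chrom": chrom,
            "start0": c.start - 1,
            "end": c.end,
            "type": c.type,
            "copy_ratio": c.copy_ratio,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=["chrom", "start0", "end", "type", "copy_ratio"]).to_csv(
        path, sep="\t", index=False
    )


def read_cnv_bed(path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "start0", "end", "type", "copy_ratio"], path)
    return [
        CNVCall(start=int(r.start0) + 1, end=int(r.end), copy_ratio=float(r.copy_ratio), type=r.type)
        for r in df.itertuples(index=False)
    ]
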