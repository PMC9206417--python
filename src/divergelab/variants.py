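"""Evolve-and-resequence variant filtering and coverage-based CNV calling.

Variants are presence/absence records per evolved strain (SNP, indel or
copy-number change at a named locus).  The pipeline subtracts everything
already present in the ancestor, then short-lists candidate
specialization loci by three criteria: phenotype-exclusive occurrence,
full annotation, and a minimum recurrence (>= 5 carrier strains with
SNP/indels, or >= 5 variants of any class).  Copy-number variants are
called from binned read depth as runs of bins whose ratio to the
genome-wide median depth crosses a duplication or deletion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "CNVCall",
    "subtract_ancestral",
    "candidate_loci",
    "call_cnv",
    "mutation_spectrum",
    "VARIANT_CLASSES",
]

VARIANT_CLASSES = ("SNP", "indel", "CNV_dup", "CNV_del")
SNP_INDEL = ("SNP", "indel")

VARIANT_COLUMNS = ["strain", "gene", "position", "var_class", "annotated"]


def _check_variants(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table is missing columns: {sorted(missing)}")
    bad = set(df["var_class"]) - set(VARIANT_CLASSES)
    if bad:
        raise ValueError(f"unknown variant classes: {sorted(bad)}")
    if (df["position"] < 1).any():
        raise ValueError("positions are 1-based and must be >= 1")
    return df


def subtract_ancestral(evolved: pd.DataFrame, ancestral: pd.DataFrame) -> pd.DataFrame:
    """Drop evolved records matching an ancestral (position, var_class) pair.

    Allele detail beyond position and class is deliberately ignored: the
    comparison is presence/absence of a lesion at a site.  Idempotent and
    order-independent.
    """
    evolved = _check_variants(evolved)
    if len(ancestral) == 0:
        return evolved.copy()
    anc = set(zip(ancestral["position"], ancestral["var_class"]))
    keep = [
        (pos, cls) not in anc
        for pos, cls in zip(evolved["position"], evolved["var_class"])
    ]
    return evolved.loc[keep].reset_index(drop=True)


def candidate_loci(
    variants: pd.DataFrame,
    meta: pd.DataFrame,
    min_strains: int = 5,
    min_variants: int = 5,
    strict_exclusive: bool = False,
) -> pd.DataFrame:
    """Short-list loci most strongly associated with one specialist phenotype.

    A locus is retained for phenotype P (FS or GS) iff
      1. its carriers occur exclusively on P's side of the design:
         strains from the matching single-sugar treatment and, unless
         ``strict_exclusive``, mix-treatment strains labeled P;
      2. the locus is fully annotated (every record flagged annotated);
      3. >= ``min_strains`` distinct carrier strains have a SNP/indel
         there, OR the locus carries >= ``min_variants`` distinct
         variants of any class.

    Returns one row per locus with per-criterion booleans; only rows with
    ``retained`` satisfy all three.
    """
    variants = _check_variants(variants)
    if not {"strain", "treatment", "phenotype"} <= set(meta.columns):
        raise ValueError("meta needs columns strain, treatment, phenotype")
    meta_idx = meta.set_index("strain")
    unknown = set(variants["strain"]) - set(meta_idx.index)
    if unknown:
        raise ValueError(f"strains without metadata: {sorted(unknown)}")

    sides = {"FS": "fructose", "GS": "galactose"}
    rows = []
    for gene, grp in variants.groupby("gene", sort=True):
        carriers = grp["strain"].unique()
        car_meta = meta_idx.loc[list(carriers)]
        annotated = bool(grp["annotated"].all())
        n_snp_strains = grp.loc[grp["var_class"].isin(SNP_INDEL), "strain"].nunique()
        n_variants = len(
            grp.drop_duplicates(subset=["strain", "position", "var_class"])
        )
        recurrent = (n_snp_strains >= min_strains) or (n_variants >= min_variants)

        phenotype = None
        exclusive = False
        for pheno, sugar in sides.items():
            if strict_exclusive:
                consistent = (car_meta["treatment"] == sugar).all()
            else:
                consistent = (
                    (car_meta["treatment"] == sugar)
                    | ((car_meta["treatment"] == "mix") & (car_meta["phenotype"] == pheno))
                ).all()
            if consistent:
                phenotype = pheno
                exclusive = True
                break
        rows.append(
            {
                "locus": gene,
                "phenotype": phenotype,
                "exclusive": exclusive,
                "annotated": annotated,
                "recurrent": recurrent,
                "n_carrier_strains": len(carriers),
                "n_snp_indel_strains": int(n_snp_strains),
                "n_variants": int(n_variants),
                "retained": exclusive and annotated and recurrent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus",
            "phenotype",
            "exclusive",
            "annotated",
            "recurrent",
            "n_carrier_strains",
            "n_snp_indel_strains",
            "n_variants",
            "retained",
        ],
    )


@dataclass
class CoverageTrack:
    """Binned read depth tiling a linear genome (1-based, bin-aligned)."""

    depth: np.ndarray
    bin_size: int = 100
    genome_length: int | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")
        if self.genome_length is None:
            self.genome_length = len(self.depth) * self.bin_size

    @property
    def n_bins(self) -> int:
        return len(self.depth)

    def bin_start(self, i: int) -> int:
        """1-based inclusive start of bin i."""
        return i * self.bin_size + 1

    def bin_end(self, i: int) -> int:
        """1-based inclusive end of bin i."""
        return (i + 1) * self.bin_size


@dataclass
class CNVCall:
    """One copy-number call, 1-based inclusive and bin-aligned."""

    start: int
    end: int
    copy_ratio: float
    type: str  # "dup" | "del"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if self.type not in ("dup", "del"):
            raise ValueError(f"invalid CNV type {self.type!r}")


def call_cnv(
    track: CoverageTrack,
    dup_ratio: float = 1.5,
    del_ratio: float = 0.5,
    min_bins: int = 3,
) -> list[CNVCall]:
    """Threshold-run CNV segmentation on median-normalized depth.

    Each bin's ratio is depth / genome-wide median depth.  Runs of at
    least ``min_bins`` consecutive bins at ratio >= ``dup_ratio`` (or
    <= ``del_ratio``) become calls; two runs separated by a single
    discordant bin are merged.  The reported copy_ratio is the median bin
    ratio of the run.  Scaling the track by a positive constant leaves
    the calls unchanged.
    """
    median_depth = float(np.median(track.depth))
    if median_depth <= 0:
        raise ValueError("genome-wide median depth must be positive")
    ratio = track.depth / median_depth

    calls: list[CNVCall] = []
    for kind, mask in (("dup", ratio >= dup_ratio), ("del", ratio <= del_ratio)):
        runs = _mask_runs(mask, bridge=1)
        for i0, i1 in runs:  # bin index range, inclusive
            if i1 - i0 + 1 < min_bins:
                continue
            calls.append(
                CNVCall(
                    start=track.bin_start(i0),
                    end=track.bin_end(i1),
                    copy_ratio=float(np.median(ratio[i0 : i1 + 1])),
                    type=kind,
                )
            )
    calls.sort(key=lambda c: c.start)
    return calls


def _mask_runs(mask: np.ndarray, bridge: int = 1) -> list[tuple[int, int]]:
    """Maximal True runs; runs separated by <= ``bridge`` False bins merge."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= bridge + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def mutation_spectrum(variants: pd.DataFrame) -> dict[str, float]:
    """Fractions of the mutation spectrum by class.

    Returns ``{"cnv_total", "dup", "del", "snp_indel"}``; cnv_total is
    dup + del, and dup + del + snp_indel sums to 1.
    """
    variants = _check_variants(variants)
    n = len(variants)
    if n == 0:
        raise ValueError("empty variant list has no spectrum")
    counts = variants["var_class"].value_counts()
    dup = counts.get("CNV_dup", 0) / n
    dele = counts.get("CNV_del", 0) / n
    snp_indel = (counts.get("SNP", 0) + counts.get("indel", 0)) / n
    return {
        "cnv_total": dup + dele,
        "dup": dup,
        "del": dele,
        "snp_indel": snp_indel,
    }
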