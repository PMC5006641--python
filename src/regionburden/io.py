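"""Variant, panel, interval and annotation I/O with fixed coordinate conventions.

All coordinates are held internally as 1-based inclusive positions, matching
how genomic regions are printed in the literature (e.g. ``chr3:182,189,714-
182,229,714``).  BED files are 0-based half-open *only at the file boundary*;
:func:`read_bed` / :func:`write_bed` convert on the way in and out, and the
two conversions are mutually inverse.

Variant tables are long-format :class:`pandas.DataFrame` objects with one row
per carrier call, columns :data:`VARIANT_COLUMNS`.  Quality flags follow the
caller vocabulary ``{"pass", "allele_bias"}``; any other flag is preserved
verbatim but fails the quality gate downstream.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample_id",
    "genotype",
    "quality_flag",
    "somatic_status",
]

#: variant identity used throughout the package (zygosity is ignored)
VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

QUALITY_PASS = "pass"
QUALITY_ALLELE_BIAS = "allele_bias"
ALLOWED_QUALITY_FLAGS = (QUALITY_PASS, QUALITY_ALLELE_BIAS)

SOMATIC_STATUSES = ("somatic", "germline", "unknown")

_BASES = ("A", "C", "G", "T")

_FILTER_TO_FLAG = {"PASS": QUALITY_PASS, "alleleBias": QUALITY_ALLELE_BIAS}
_FLAG_TO_FILTER = {v: k for k, v in _FILTER_TO_FLAG.items()}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start ({self.start}) > end ({self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse genomic interval {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def empty_variant_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "sample_id": pd.Series(dtype=str),
            "genotype": pd.Series(dtype=np.int64),
            "quality_flag": pd.Series(dtype=str),
            "somatic_status": pd.Series(dtype=str),
        }
    )


def validate_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a variant table against the record invariants.

    Returns the table unchanged (for chaining).  Single-nucleotide
    substitutions only: ``ref`` and ``alt`` are single distinct bases and
    positions are >= 1.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if len(df) == 0:
        return df
    if (df["pos"] < 1).any():
        raise ValueError("variant positions must be >= 1")
    bad = (df["ref"].str.len() != 1) | (df["alt"].str.len() != 1) | (df["ref"] == df["alt"])
    if bad.any():
        raise ValueError(f"{int(bad.sum())} records are not single-nucleotide substitutions")
    return df


def sort_variants(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(VARIANT_KEY + ["sample_id"], kind="mergesort").reset_index(drop=True)


def distinct_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long carrier table to one row per (chrom, pos, ref, alt)."""
    return df[VARIANT_KEY].drop_duplicates().reset_index(drop=True)


# ---------------------------------------------------------------------------
# variant tables: VCF and TSV
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    if name.endswith(".vcf"):
        return "vcf"
    if name.endswith((".tsv", ".txt")):
        return "tsv"
    raise ValueError(f"cannot infer variant file format from {path.name!r}")


def read_variants(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a variant table from VCF (4.2) or TSV.

    Multi-allelic VCF rows are split into biallelic records; records that are
    not single-nucleotide substitutions are dropped (a count is logged).
    Only carrier calls (genotype > 0) are materialised: the long table holds
    one row per (variant, carrying sample).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        return read_variants_tsv(path)
    if fmt == "vcf":
        return read_variants_vcf(path)
    raise ValueError(f"unknown variant format {fmt!r}")


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "sample_id": str})
    if len(df) == 0:
        return empty_variant_table()
    df["pos"] = df["pos"].astype(np.int64)
    df["genotype"] = df["genotype"].astype(np.int64)
    return validate_variants(sort_variants(df[VARIANT_COLUMNS]))


def write_variants_tsv(df: pd.DataFrame, path) -> None:
    validate_variants(df)
    df[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variants_vcf(path) -> pd.DataFrame:
    rows: list[tuple] = []
    n_dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        has_ss = "SS" in vcf.header.info
        for line_no, rec in enumerate(vcf, start=1):
            filters = list(rec.filter.keys())
            raw = filters[0] if filters else "PASS"
            flag = _FILTER_TO_FLAG.get(raw, raw)
            status = rec.info.get("SS", "unknown") if has_ss else "unknown"
            try:
                alts = rec.alts or ()
            except ValueError as exc:  # malformed ALT
                raise ValueError(f"{path}: malformed record near line {line_no}: {exc}") from exc
            for alt_index, alt in enumerate(alts, start=1):
                if alt is None or len(rec.ref) != 1 or len(alt) != 1 or alt == rec.ref or alt not in _BASES:
                    n_dropped += 1
                    continue
                for sample in samples:
                    gt = rec.samples[sample].get("GT") or ()
                    genotype = sum(1 for a in gt if a == alt_index)
                    if genotype > 0:
                        rows.append((rec.chrom, rec.pos, rec.ref, alt, sample, genotype, flag, status))
    if n_dropped:
        log.info("read_variants: dropped %d non-SNV allele(s) from %s", n_dropped, path)
    if not rows:
        return empty_variant_table()
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return validate_variants(sort_variants(df))


def write_variants_vcf(df: pd.DataFrame, path) -> None:
    """Write a multi-sample VCF 4.2.

    Quality flag and somatic status are site-level in VCF (FILTER and the
    ``SS`` INFO field); a table whose rows disagree within one variant cannot
    be represented losslessly here — use TSV for full fidelity.
    """
    validate_variants(df)
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SS,Number=1,Type=String,Description="Somatic status">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FILTER=<ID=alleleBias,Description="Allele bias flagged by the caller">')
    for chrom in pd.unique(df["chrom"]) if len(df) else []:
        header.contigs.add(str(chrom))
    extra_filters = set(df["quality_flag"]) - set(_FLAG_TO_FILTER) if len(df) else set()
    for f in sorted(extra_filters):
        header.add_line(f'##FILTER=<ID={f},Description="Caller-specific flag">')
    samples = sorted(pd.unique(df["sample_id"])) if len(df) else []
    for s in samples:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        if len(df) == 0:
            return
        grouped = df.groupby(VARIANT_KEY, sort=True)
        for (chrom, pos, ref, alt), sub in grouped:
            rec = out.new_record(contig=str(chrom), start=int(pos) - 1, alleles=(ref, alt))
            flag = sub["quality_flag"].iloc[0]
            rec.filter.add(_FLAG_TO_FILTER.get(flag, flag))
            rec.info["SS"] = str(sub["somatic_status"].iloc[0])
            carriers = dict(zip(sub["sample_id"], sub["genotype"]))
            for s in samples:
                g = int(carriers.get(s, 0))
                rec.samples[s]["GT"] = (1, 1) if g >= 2 else ((0, 1) if g == 1 else (0, 0))
            out.write(rec)


# ---------------------------------------------------------------------------
# allele-frequency panel
# ---------------------------------------------------------------------------


def read_panel(path, provenance: str | None = None) -> pd.DataFrame:
    """Read a reference-panel allele-frequency table (TSV).

    Columns: chrom, pos, ref, alt, maf.  Keys must be unique and MAFs must
    lie in [0, 0.5].
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    df["pos"] = df["pos"].astype(np.int64)
    df["maf"] = df["maf"].astype(float)
    dup = df.duplicated(VARIANT_KEY)
    if dup.any():
        first = df.loc[dup, VARIANT_KEY].iloc[0].tolist()
        raise ValueError(f"duplicate panel key {tuple(first)}")
    if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
        raise ValueError("panel MAFs must lie in [0, 0.5]")
    df = df.sort_values(VARIANT_KEY, kind="mergesort").reset_index(drop=True)
    df.attrs["provenance"] = provenance or str(path)
    return df


def write_panel(df: pd.DataFrame, path) -> None:
    df[VARIANT_KEY + ["maf"]].to_csv(path, sep="\t", index=False)


def panel_index(panel: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(panel[VARIANT_KEY])


# ---------------------------------------------------------------------------
# BED intervals (0-based half-open on disk, 1-based inclusive in memory)
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read BED3(+name) into 1-based inclusive intervals: start+1, end."""
    opener = gzip.open if str(path).endswith(".gz") else open
    rows = []
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {line_no}: expected >= 3 BED fields")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            rows.append((chrom, start0 + 1, end0, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as BED (start-1, end)."""
    out = df.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    cols = ["chrom", "start", "end"] + (["name"] if "name" in out.columns else [])
    out[cols].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# gene annotation and gene sets
# ---------------------------------------------------------------------------


def read_genes(path) -> pd.DataFrame:
    """Read a gene table (TSV: gene_id, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    df["tss"] = df["tss"].astype(np.int64)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand value(s): {sorted(df.loc[bad, 'strand'].unique())}")
    return df.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)


def write_genes(df: pd.DataFrame, path) -> None:
    df[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")
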