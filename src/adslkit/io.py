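"""Readers and writers for the pipeline's on-disk formats.

Delimited text (comma for ``.csv``, tab for ``.tsv``/``.txt``/``.tab``)
for events, rosters, metabolite tables and reports; plain VCF for
haplotypes. Column schemas:

* visit events: ``cage, day, timestamp, animal, corner, licks``
  (timestamp in seconds from day start; corner in 1..4)
* roster: ``animal, genotype, sex, cage`` (genotype hAdsl/WT, sex F/M)
* metabolite table: ``sample, tissue, sex, genotype`` followed by one
  column per metabolite holding peak areas

The IntelliCage vendor export format varies by software version; this
minimal generic schema is the documented interchange format, and the
columns above are what an export must be mapped to.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .behavior import GENOTYPES
from .metabolomics import SAMPLE_COLUMNS, MetaboliteTable
from .popgen import HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_visit_events",
    "write_visit_events",
    "read_roster",
    "write_roster",
    "read_metabolite_table",
    "write_metabolite_table",
    "read_haplotypes_vcf",
    "write_haplotypes_vcf",
]

EVENT_COLUMNS = ("cage", "day", "timestamp", "animal", "corner", "licks")
ROSTER_COLUMNS = ("animal", "genotype", "sex", "cage")
SEXES = ("F", "M")


class FormatError(ValueError):
    """An input file violates the documented schema."""


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_visit_events(path: str | Path) -> pd.DataFrame:
    """Read a visit-event file, validate, and sort by (cage, day, timestamp).

    Timestamp ties are broken by animal id. Raises
    :class:`FormatError` naming the offending column or data line
    (1-based, header = line 1) on schema violations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str).rename(columns=str.strip)
    _require_columns(df, EVENT_COLUMNS, path)
    df = df[list(EVENT_COLUMNS)].copy()
    for col, kind in (("day", int), ("timestamp", float), ("corner", int), ("licks", int)):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (kind is int) & (parsed % 1 != 0)
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise FormatError(f"{path}: unparsable {col} value on line {line}")
        df[col] = parsed.astype(kind)
    for col, ok, desc in (
        ("timestamp", df["timestamp"] >= 0, "nonnegative timestamp"),
        ("corner", df["corner"].isin((1, 2, 3, 4)), "corner in 1..4"),
        ("licks", df["licks"] >= 0, "nonnegative lick count"),
        ("day", df["day"] >= 1, "day >= 1"),
    ):
        bad = ~ok
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise FormatError(f"{path}: expected {desc} on line {line}")
    return df.sort_values(
        ["cage", "day", "timestamp", "animal"], kind="mergesort"
    ).reset_index(drop=True)


def write_visit_events(events: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    events[list(EVENT_COLUMNS)].to_csv(path, sep=_sep(path), index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read and validate an animal roster (animal, genotype, sex, cage)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), dtype=str).rename(columns=str.strip)
    _require_columns(df, ROSTER_COLUMNS, path)
    df = df[list(ROSTER_COLUMNS)].copy()
    dup = df["animal"][df["animal"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate animal id(s) {sorted(set(dup))}")
    bad_g = set(df["genotype"]) - set(GENOTYPES)
    if bad_g:
        raise FormatError(
            f"{path}: unknown genotype label(s) {sorted(bad_g)}; "
            f"accepted labels are {list(GENOTYPES)} (case-sensitive)"
        )
    bad_s = set(df["sex"]) - set(SEXES)
    if bad_s:
        raise FormatError(
            f"{path}: unknown sex label(s) {sorted(bad_s)}; accepted: {list(SEXES)}"
        )
    return df.reset_index(drop=True)


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    roster[list(ROSTER_COLUMNS)].to_csv(path, sep=_sep(path), index=False)


def read_metabolite_table(path: str | Path) -> MetaboliteTable:
    """Read a wide metabolite table (sample metadata + one column per metabolite)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    _require_columns(df, ("sample",) + SAMPLE_COLUMNS, path)
    df = df.set_index("sample")
    meta_cols = [c for c in df.columns if c in SAMPLE_COLUMNS + ("true_scale",)]
    metab_cols = [c for c in df.columns if c not in meta_cols]
    if not metab_cols:
        raise FormatError(f"{path}: no metabolite columns found")
    return MetaboliteTable(
        values=df[metab_cols].astype(float), samples=df[meta_cols], normalized=False
    )


def write_metabolite_table(table: MetaboliteTable, path: str | Path) -> None:
    path = Path(path)
    out = pd.concat([table.samples, table.values], axis=1)
    out.index.name = "sample"
    out.to_csv(path, sep=_sep(path))


def read_haplotypes_vcf(
    path: str | Path,
    region: str | tuple[str, int, int] | None = None,
) -> HaplotypeMatrix:
    """Load phased biallelic SNVs from a VCF into a haplotype matrix.

    ``region`` is either ``"contig:start-end"`` (1-based inclusive) or
    a (contig, start, end) tuple; None takes the whole file.
    Multiallelic records, non-SNVs and sites with any missing allele
    are dropped (count logged and recorded in ``metadata``). Any
    unphased genotype raises, since haplotype statistics require
    phasing. An empty region yields a 0-column matrix.
    """
    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path))
    if isinstance(region, str):
        contig, span = region.split(":")
        start, end = (int(x) for x in span.split("-"))
        region = (contig, start, end)
    n_samples = len(vcf.samples)
    columns, positions, n_dropped = [], [], 0
    contig = region[0] if region else ""
    # filter in Python rather than via tabix so uncompressed VCFs work
    for rec in vcf:
        if region is not None and (
            rec.CHROM != region[0] or not region[1] <= rec.POS <= region[2]
        ):
            continue
        contig = rec.CHROM
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = np.asarray(rec.genotypes)  # (n_samples, ploidy+1); last col = phased flag
        if not gts[:, -1].all():
            raise FormatError(
                f"{path}: unphased genotype at {rec.CHROM}:{rec.POS}; "
                "phased haplotypes are required"
            )
        alleles = gts[:, :-1]
        if (alleles < 0).any():
            n_dropped += 1
            continue
        columns.append(alleles.reshape(-1).astype(np.int8))
        positions.append(rec.POS)
    if n_dropped:
        logger.info("%s: dropped %d non-biallelic-SNV/missing records", path, n_dropped)
    matrix = (
        np.column_stack(columns)
        if columns
        else np.zeros((2 * n_samples, 0), dtype=np.int8)
    )
    return HaplotypeMatrix(
        matrix=matrix,
        positions=np.asarray(positions, dtype=np.int64),
        contig=contig or "chr",
        metadata={"n_dropped": n_dropped, "source": str(path)},
    )


def write_haplotypes_vcf(
    hap: HaplotypeMatrix, path: str | Path, sample_prefix: str = "ind"
) -> None:
    """Write a haplotype matrix as an uncompressed phased VCF.

    Consecutive haplotype pairs (2i, 2i+1) become one diploid sample;
    the haplotype count must therefore be even. REF=A carries the
    ancestral (0) and ALT=G the derived (1) allele at every site.
    """
    if hap.n_haplotypes % 2:
        raise ValueError("haplotype count must be even to pair into diploid samples")
    n_ind = hap.n_haplotypes // 2
    samples = [f"{sample_prefix}{i+1}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hap.contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, pos in enumerate(hap.positions):
            col = hap.matrix[:, j]
            gts = "\t".join(f"{col[2*i]}|{col[2*i+1]}" for i in range(n_ind))
            fh.write(f"{hap.contig}\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
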