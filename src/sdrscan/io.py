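"""Readers and writers for the plain-text formats the pipeline exchanges.

The central interchange format is the "sync" table used for pooled
resequencing counts: one row per genomic site, one column of
colon-separated ``A:T:C:G:N:del`` read counts per pool.  The dialect
emitted and expected here carries exactly two pools, male before female,
and declares itself in a leading comment line.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = ("A", "T", "C", "G")
COUNT_FIELDS = ("A", "T", "C", "G", "N", "del")

#: column names of the per-pool count block in a site table
MALE_COLS = tuple(f"m_{f}" for f in COUNT_FIELDS)
FEMALE_COLS = tuple(f"f_{f}" for f in COUNT_FIELDS)

SYNC_DIALECT_LINE = "#sync dialect: chrom\tpos\tref\tmale A:T:C:G:N:del\tfemale A:T:C:G:N:del"


class SyncParseError(ValueError):
    """Raised when a sync line cannot be interpreted."""


@dataclasses.dataclass
class PoolSiteCounts:
    """Read counts for one genomic site in the male and female pools."""

    chrom: str
    pos: int  # 1-based
    ref: str
    male_counts: tuple[int, ...]  # A, T, C, G, N, del
    female_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if len(self.male_counts) != 6 or len(self.female_counts) != 6:
            raise ValueError("each pool needs 6 count fields (A,T,C,G,N,del)")
        if min(self.male_counts) < 0 or min(self.female_counts) < 0:
            raise ValueError("read counts must be non-negative")


def _parse_count_field(field: str, lineno: int | None) -> tuple[int, ...]:
    parts = field.split(":")
    if len(parts) != 6:
        where = f" on line {lineno}" if lineno is not None else ""
        raise SyncParseError(
            f"count field {field!r}{where} has {len(parts)} values, expected 6 (A:T:C:G:N:del)"
        )
    try:
        return tuple(int(p) for p in parts)
    except ValueError as exc:
        where = f" on line {lineno}" if lineno is not None else ""
        raise SyncParseError(f"non-integer count in field {field!r}{where}") from exc


def parse_sync(line: str, male_col: int = 3, female_col: int = 4, lineno: int | None = None) -> PoolSiteCounts:
    """Parse one sync line into :class:`PoolSiteCounts`.

    ``male_col``/``female_col`` give the 0-based column indices of the two
    pools, so dialects with swapped or extra pools can be read.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        where = f" on line {lineno}" if lineno is not None else ""
        raise SyncParseError(f"sync line{where} has {len(fields)} fields, expected at least 5")
    if max(male_col, female_col) >= len(fields):
        raise SyncParseError("pool column index beyond end of line; fewer than two pools present")
    return PoolSiteCounts(
        chrom=fields[0],
        pos=int(fields[1]),
        ref=fields[2],
        male_counts=_parse_count_field(fields[male_col], lineno),
        female_counts=_parse_count_field(fields[female_col], lineno),
    )


def read_sync(path: str | Path, male_col: int = 3, female_col: int = 4) -> pd.DataFrame:
    """Read a sync file into a site table.

    Returns a DataFrame with columns ``chrom``, ``pos``, ``ref`` and the
    twelve per-pool count columns ``m_A ... m_del``, ``f_A ... f_del``.
    """
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    mcounts: list[tuple[int, ...]] = []
    fcounts: list[tuple[int, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            rec = parse_sync(line, male_col=male_col, female_col=female_col, lineno=lineno)
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            mcounts.append(rec.male_counts)
            fcounts.append(rec.female_counts)
    df = pd.DataFrame({"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64), "ref": refs})
    m = np.asarray(mcounts, dtype=np.int64).reshape(len(df), 6)
    f = np.asarray(fcounts, dtype=np.int64).reshape(len(df), 6)
    for i, col in enumerate(MALE_COLS):
        df[col] = m[:, i]
    for i, col in enumerate(FEMALE_COLS):
        df[col] = f[:, i]
    return df


def write_sync(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table as a sync file (byte-stable for a given table)."""
    m = sites[list(MALE_COLS)].to_numpy(dtype=np.int64)
    f = sites[list(FEMALE_COLS)].to_numpy(dtype=np.int64)
    with open(path, "w") as fh:
        fh.write(SYNC_DIALECT_LINE + "\n")
        for i in range(len(sites)):
            mfield = ":".join(str(x) for x in m[i])
            ffield = ":".join(str(x) for x in f[i])
            fh.write(
                f"{sites['chrom'].iat[i]}\t{sites['pos'].iat[i]}\t{sites['ref'].iat[i]}\t{mfield}\t{ffield}\n"
            )


def read_vcf(
    path: str | Path,
    male_sample: str | None = None,
    female_sample: str | None = None,
) -> pd.DataFrame:
    """Read pooled counts from a VCF with per-sample allelic depths (AD).

    Uses the first two samples as male then female unless names are
    given.  Only single-base REF/ALT alleles contribute counts; other
    records are skipped.  Returns the same site-table layout as
    :func:`read_sync`.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if len(samples) < 2:
        raise ValueError("VCF needs at least two samples (male and female pools)")
    male = male_sample or samples[0]
    female = female_sample or samples[1]
    for name in (male, female):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF header")

    base_idx = {b: i for i, b in enumerate(BASES)}
    rows = []
    for rec in vcf:
        alleles = [rec.ref, *(rec.alts or ())]
        if any(len(a) != 1 or a.upper() not in base_idx for a in alleles):
            continue  # indels / symbolic alleles are out of scope
        counts = {}
        ok = True
        for name in (male, female):
            ad = rec.samples[name].get("AD")
            if ad is None or any(x is None for x in ad[: len(alleles)]):
                ok = False
                break
            vec = [0] * 6
            for allele, depth in zip(alleles, ad):
                vec[base_idx[allele.upper()]] += int(depth)
            counts[name] = vec
        if not ok:
            continue
        rows.append((rec.chrom, rec.pos, rec.ref.upper(), counts[male], counts[female]))

    df = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "pos": np.asarray([r[1] for r in rows], dtype=np.int64),
            "ref": [r[2] for r in rows],
        }
    )
    m = np.asarray([r[3] for r in rows], dtype=np.int64).reshape(len(df), 6)
    f = np.asarray([r[4] for r in rows], dtype=np.int64).reshape(len(df), 6)
    for i, col in enumerate(MALE_COLS):
        df[col] = m[:, i]
    for i, col in enumerate(FEMALE_COLS):
        df[col] = f[:, i]
    return df


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read chromosome lengths from a two-column TSV (``.fai``-compatible:
    extra columns beyond name and length are ignored)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            lengths[parts[0]] = int(parts[1])
    return lengths


def write_chrom_lengths(lengths: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in lengths.items():
            fh.write(f"{name}\t{length}\n")


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
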