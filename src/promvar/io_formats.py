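"""Readers and writers for the external formats the pipeline touches.

Supported inputs:

* transcript annotation tables in the UCSC genePred/refGene dialect
  (16 columns) or a minimal 8-column dialect
  (accession, symbol, chrom, strand, txStart, txEnd, cdsStart, cdsEnd);
* SNP tables in the UCSC common-SNP track dialect (BED-like, 0-based
  chromStart) and, optionally, plain-text VCF;
* GMT gene-set collections and one-symbol-per-line gene lists.

All coordinates are stored 0-based half-open (the UCSC storage
convention).  Chromosome names are normalized by stripping a leading
``chr`` prefix; writers restore it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptRecord",
    "SnpRecord",
    "SnpTable",
    "GeneSetCollection",
    "ParseReport",
    "ParseError",
    "normalize_chrom",
    "normalize_flag",
    "read_transcript_table",
    "read_snp_table",
    "read_snp_vcf",
    "read_gene_sets",
    "read_gene_list",
    "write_table",
    "write_transcript_table",
    "write_snp_table",
]


class ParseError(ValueError):
    """Fatal parse failure (unreadable file or strict-mode violation)."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive). Idempotent."""
    name = name.strip()
    if name.lower().startswith("chr"):
        return name[3:]
    return name


_FLAG_CANON = re.compile(r"[-_]+")


def normalize_flag(token: str) -> str:
    """Canonical form of a validation-flag token.

    Lower-cased; runs of hyphens/underscores collapsed to a single
    hyphen, so ``by-1000genomes``, ``BY_1000GENOMES`` and
    ``by_1000genomes`` compare equal.
    """
    return _FLAG_CANON.sub("-", token.strip().lower())


@dataclass(frozen=True, slots=True)
class TranscriptRecord:
    """One transcript annotation with 0-based half-open coordinates.

    ``cds_start == cds_end`` encodes a non-coding annotation (rejected
    later by catalog filtering, not at parse time).
    """

    accession: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if self.strand not in ("+", "-"):
            problems.append(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            problems.append(
                f"require 0 <= tx_start < tx_end, got [{self.tx_start}, {self.tx_end})"
            )
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            problems.append(
                "require tx_start <= cds_start <= cds_end <= tx_end, got "
                f"tx=[{self.tx_start}, {self.tx_end}) cds=[{self.cds_start}, {self.cds_end})"
            )
        return problems


@dataclass(frozen=True, slots=True)
class SnpRecord:
    """A single-nucleotide variant at one 0-based position."""

    chrom: str
    pos: int
    rsid: str
    variant_class: str
    validation_flags: frozenset[str]


@dataclass
class ParseReport:
    """Per-file account of rows that did not make it into the output."""

    path: str = ""
    n_rows: int = 0
    n_parsed: int = 0
    n_duplicates: int = 0
    bad_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_bad(self) -> int:
        return len(self.bad_rows)

    def add_bad(self, lineno: int, reason: str) -> None:
        self.bad_rows.append((lineno, reason))


class SnpTable:
    """SNP records sorted by (chrom, pos), array-backed for fast lookup.

    Columns are parallel numpy arrays; ``positions(chrom)`` exposes the
    sorted position vector of one chromosome for binary search.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        rsid: np.ndarray,
        variant_class: np.ndarray,
        validation_flags: np.ndarray,
        *,
        presorted: bool = False,
    ):
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        rsid = np.asarray(rsid, dtype=object)
        variant_class = np.asarray(variant_class, dtype=object)
        validation_flags = np.asarray(validation_flags, dtype=object)
        if not presorted and len(pos):
            order = np.lexsort((rsid.astype(str), pos, chrom.astype(str)))
            chrom, pos, rsid = chrom[order], pos[order], rsid[order]
            variant_class = variant_class[order]
            validation_flags = validation_flags[order]
        self.chrom = chrom
        self.pos = pos
        self.rsid = rsid
        self.variant_class = variant_class
        self.validation_flags = validation_flags
        self._index: dict[str, tuple[int, int]] = {}
        if len(pos):
            change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(pos)]))
            for s, e in zip(starts, ends):
                self._index[str(chrom[s])] = (int(s), int(e))

    @classmethod
    def from_records(cls, records: Iterable[SnpRecord]) -> "SnpTable":
        records = list(records)
        return cls(
            np.array([r.chrom for r in records], dtype=object),
            np.array([r.pos for r in records], dtype=np.int64),
            np.array([r.rsid for r in records], dtype=object),
            np.array([r.variant_class for r in records], dtype=object),
            np.array([r.validation_flags for r in records], dtype=object),
        )

    def __len__(self) -> int:
        return len(self.pos)

    def __iter__(self) -> Iterator[SnpRecord]:
        for i in range(len(self.pos)):
            yield self[i]

    def __getitem__(self, i: int) -> SnpRecord:
        return SnpRecord(
            chrom=self.chrom[i],
            pos=int(self.pos[i]),
            rsid=self.rsid[i],
            variant_class=self.variant_class[i],
            validation_flags=self.validation_flags[i],
        )

    def chromosomes(self) -> list[str]:
        return list(self._index)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted positions on ``chrom`` (empty array if absent)."""
        span = self._index.get(normalize_chrom(chrom))
        if span is None:
            return np.empty(0, dtype=np.int64)
        return self.pos[span[0] : span[1]]

    def per_chrom_counts(self) -> dict[str, int]:
        return {c: e - s for c, (s, e) in self._index.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpTable):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.rsid == other.rsid))
            and bool(np.all(self.variant_class == other.variant_class))
            and bool(np.all(self.validation_flags == other.validation_flags))
        )


@dataclass
class GeneSetCollection:
    """Named sets of uppercase gene symbols (one GMT row per set)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# transcript tables

_REFGENE_NCOLS = 16
_MINIMAL_NCOLS = 8


def _parse_transcript_row(fields: Sequence[str], dialect: str) -> TranscriptRecord:
    if dialect == "refgene-16col":
        # bin name chrom strand txStart txEnd cdsStart cdsEnd exonCount
        # exonStarts exonEnds score name2 cdsStartStat cdsEndStat exonFrames
        acc, chrom, strand = fields[1], fields[2], fields[3]
        tx_start, tx_end, cds_start, cds_end = fields[4:8]
        symbol = fields[12]
    else:
        acc, symbol, chrom, strand = fields[0:4]
        tx_start, tx_end, cds_start, cds_end = fields[4:8]
    return TranscriptRecord(
        accession=acc,
        gene_symbol=symbol,
        chrom=normalize_chrom(chrom),
        strand=strand.replace("−", "-"),  # tolerate unicode minus
        tx_start=int(tx_start),
        tx_end=int(tx_end),
        cds_start=int(cds_start),
        cds_end=int(cds_end),
    )


def read_transcript_table(
    path: str | Path,
    dialect: str = "minimal-8col",
    *,
    strict: bool = False,
) -> tuple[list[TranscriptRecord], ParseReport]:
    """Read a transcript annotation table.

    Malformed rows (wrong column count, bad integers, invariant
    violations) are collected in the :class:`ParseReport`; in strict
    mode any such row raises :class:`ParseError` instead.
    """
    if dialect not in ("refgene-16col", "minimal-8col"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = _REFGENE_NCOLS if dialect == "refgene-16col" else _MINIMAL_NCOLS
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cannot read {path}: no such file")
    records: list[TranscriptRecord] = []
    report = ParseReport(path=str(path))
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        report.n_rows += 1
        fields = line.rstrip("\n").split("\t")
        if len(fields) != ncols:
            reason = f"expected {ncols} columns, found {len(fields)}"
            if strict:
                raise ParseError(f"{path}:{lineno}: {reason}")
            report.add_bad(lineno, reason)
            continue
        try:
            rec = _parse_transcript_row(fields, dialect)
        except ValueError as exc:
            if strict:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            report.add_bad(lineno, str(exc))
            continue
        problems = rec.validate()
        if problems:
            if strict:
                raise ParseError(f"{path}:{lineno}: {problems[0]}")
            report.add_bad(lineno, "; ".join(problems))
            continue
        records.append(rec)
    report.n_parsed = len(records)
    return records, report


def write_transcript_table(
    records: Iterable[TranscriptRecord], path: str | Path
) -> None:
    """Write records in the minimal 8-column dialect (``chr`` restored).

    Like the UCSC source tables, the file carries no header row, so it
    round-trips through :func:`read_transcript_table`.
    """
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                f"{r.accession}\t{r.gene_symbol}\tchr{r.chrom}\t{r.strand}"
                f"\t{r.tx_start}\t{r.tx_end}\t{r.cds_start}\t{r.cds_end}\n"
            )


# ---------------------------------------------------------------------------
# SNP tables

_SNP_NCOLS = 6  # chrom chromStart chromEnd name class valid


def read_snp_table(
    path: str | Path, *, strict: bool = False
) -> tuple[SnpTable, ParseReport]:
    """Read a UCSC-dialect SNP table (6 tab-separated columns).

    Output is sorted by (chrom, pos); exact duplicate (chrom, pos, rsid)
    triples are collapsed, with the number collapsed recorded in the
    report.  Records whose span is not 1 bp despite class ``single`` are
    flagged in the report but kept.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cannot read {path}: no such file")
    report = ParseReport(path=str(path))
    chroms: list[str] = []
    positions: list[int] = []
    rsids: list[str] = []
    classes: list[str] = []
    flags: list[frozenset[str]] = []
    seen: set[tuple[str, int, str]] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        report.n_rows += 1
        fields = line.rstrip("\n").split("\t")
        if len(fields) != _SNP_NCOLS:
            reason = f"expected {_SNP_NCOLS} columns, found {len(fields)}"
            if strict:
                raise ParseError(f"{path}:{lineno}: {reason}")
            report.add_bad(lineno, reason)
            continue
        chrom_raw, start_s, end_s, rsid, vclass, valid = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            if strict:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            report.add_bad(lineno, f"non-integer coordinates: {start_s!r}, {end_s!r}")
            continue
        if start < 0:
            if strict:
                raise ParseError(f"{path}:{lineno}: negative chromStart")
            report.add_bad(lineno, "negative chromStart")
            continue
        chrom = normalize_chrom(chrom_raw)
        if vclass == "single" and end != start + 1:
            # flagged, not dropped: upstream releases contain such rows
            report.add_bad(lineno, f"class single but span {end - start} bp (kept)")
        key = (chrom, start, rsid)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        chroms.append(chrom)
        positions.append(start)
        rsids.append(rsid)
        classes.append(vclass)
        flags.append(
            frozenset(normalize_flag(t) for t in valid.split(",") if t.strip())
        )
    report.n_parsed = len(positions)
    table = SnpTable(
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(rsids, dtype=object),
        np.array(classes, dtype=object),
        np.array(flags, dtype=object),
    )
    return table, report


def read_snp_vcf(
    path: str | Path,
    *,
    assumed_flags: Iterable[str] = ("by-1000genomes",),
) -> tuple[SnpTable, ParseReport]:
    """Read a plain-text VCF, keeping biallelic-style SNVs only.

    POS is 1-based in VCF and mapped to ``pos = POS - 1``.  Records with
    a single-base REF and all single-base ALTs become class ``single``;
    others are skipped (counted in the report).  ``assumed_flags`` is
    attached to every record since VCFs carry no UCSC validation column.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cannot read {path}: no such file")
    flagset = frozenset(normalize_flag(t) for t in assumed_flags)
    report = ParseReport(path=str(path))
    chroms: list[str] = []
    positions: list[int] = []
    rsids: list[str] = []
    seen: set[tuple[str, int, str]] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        report.n_rows += 1
        fields = line.split("\t")
        if len(fields) < 8:
            report.add_bad(lineno, "fewer than 8 VCF columns")
            continue
        chrom_raw, pos_s, rsid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
        try:
            pos = int(pos_s) - 1
        except ValueError:
            report.add_bad(lineno, f"non-integer POS {pos_s!r}")
            continue
        if len(ref) != 1 or any(len(a) != 1 for a in alt.split(",")):
            report.add_bad(lineno, "not a single-base substitution (skipped)")
            continue
        chrom = normalize_chrom(chrom_raw)
        key = (chrom, pos, rsid)
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        chroms.append(chrom)
        positions.append(pos)
        rsids.append(rsid)
    report.n_parsed = len(positions)
    n = len(positions)
    table = SnpTable(
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(rsids, dtype=object),
        np.array(["single"] * n, dtype=object),
        np.array([flagset] * n, dtype=object),
    )
    return table, report


def write_snp_table(table: SnpTable, path: str | Path) -> None:
    """Write a SnpTable back in the 6-column UCSC dialect."""
    path = Path(path)
    with path.open("w") as fh:
        for i in range(len(table)):
            flags = ",".join(sorted(table.validation_flags[i]))
            fh.write(
                f"chr{table.chrom[i]}\t{table.pos[i]}\t{table.pos[i] + 1}"
                f"\t{table.rsid[i]}\t{table.variant_class[i]}\t{flags}\n"
            )


# ---------------------------------------------------------------------------
# gene sets and gene lists


def read_gene_sets(path: str | Path, *, strict: bool = True) -> GeneSetCollection:
    """Read a GMT file: name, description, then one symbol per column."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cannot read {path}: no such file")
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            if strict:
                raise ParseError(
                    f"{path}:{lineno}: GMT row needs name, description and >=1 member"
                )
            continue
        name = fields[0]
        members = frozenset(f.strip().upper() for f in fields[2:] if f.strip())
        if not members:
            if strict:
                raise ParseError(f"{path}:{lineno}: empty gene set {name!r}")
            continue
        sets[name] = members
        descriptions[name] = fields[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; uppercased, de-duplicated, order kept."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cannot read {path}: no such file")
    out: list[str] = []
    seen: set[str] = set()
    for line in path.read_text().splitlines():
        sym = line.strip().upper()
        if sym and not sym.startswith("#") and sym not in seen:
            seen.add(sym)
            out.append(sym)
    return out


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in symbols))


# ---------------------------------------------------------------------------
# generic TSV output


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write any tabular result as TSV with a header row.

    Numeric formatting uses ``repr``-style floats (locale-independent);
    tables written here round-trip through ``pandas.read_csv``.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
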