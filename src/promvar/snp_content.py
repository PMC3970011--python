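"""Per-transcript SNP contents in upstream windows.

Variants are first screened by class and validation flag, then counted
inside each transcript's upstream window by binary search over the
per-chromosome sorted position vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import SnpTable, TranscriptRecord, normalize_flag, write_table
from .transcript_catalog import CaseSpec, GenomicInterval, upstream_window

__all__ = [
    "SnpContentTable",
    "filter_snps",
    "count_snps_in_window",
    "build_content_table",
    "snp_rich_subset",
    "read_content_table",
    "write_content_table",
    "SNP_RICH_MIN_CONTENT",
]

#: Default content threshold defining the SNP-rich subset.
SNP_RICH_MIN_CONTENT = 6

_CONTENT_COLUMNS = [
    "accession",
    "gene_symbol",
    "chrom",
    "strand",
    "window_start",
    "window_end",
    "effective_length",
    "snp_content",
]


@dataclass
class SnpContentTable:
    """Per-transcript SNP counts for one :class:`CaseSpec`.

    ``frame`` holds one row per transcript satisfying the case's 5'UTR
    requirement, with columns accession, gene_symbol, chrom, strand,
    window_start, window_end, effective_length, snp_content.
    """

    case: CaseSpec
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def contents(self) -> np.ndarray:
        return self.frame["snp_content"].to_numpy(dtype=np.int64)

    def gene_symbols(self) -> list[str]:
        """Unique gene symbols in table order."""
        return list(dict.fromkeys(self.frame["gene_symbol"]))

    def subset_by_symbols(self, symbols: Iterable[str]) -> "SnpContentTable":
        wanted = {s.upper() for s in symbols}
        mask = self.frame["gene_symbol"].str.upper().isin(wanted)
        return SnpContentTable(self.case, self.frame[mask].reset_index(drop=True))


def filter_snps(
    snps: SnpTable,
    required_class: str = "single",
    required_flag: str = "by-1000genomes",
) -> SnpTable:
    """Keep records with the required class and validation flag.

    Flag matching is on normalized tokens (case-insensitive, hyphens and
    underscores equated).  Order is preserved.
    """
    if len(snps) == 0:
        return snps
    flag = normalize_flag(required_flag)
    class_ok = snps.variant_class == required_class
    flag_ok = np.fromiter(
        (flag in fs for fs in snps.validation_flags), dtype=bool, count=len(snps)
    )
    mask = class_ok & flag_ok
    return SnpTable(
        snps.chrom[mask],
        snps.pos[mask],
        snps.rsid[mask],
        snps.variant_class[mask],
        snps.validation_flags[mask],
        presorted=True,
    )


def count_snps_in_window(snps: SnpTable, window: GenomicInterval) -> int:
    """Number of SNPs with ``window.start <= pos < window.end`` on
    ``window.chrom`` (binary search; O(log n) after sorting)."""
    positions = snps.positions(window.chrom)
    lo = np.searchsorted(positions, window.start, side="left")
    hi = np.searchsorted(positions, window.end, side="left")
    return int(hi - lo)


def build_content_table(
    transcripts: Sequence[TranscriptRecord],
    snps: SnpTable,
    case: CaseSpec,
) -> SnpContentTable:
    """SNP content for every transcript passing ``case.utr_requirement``.

    ``transcripts`` should already have gone through catalog filtering
    and ``snps`` through :func:`filter_snps`.
    """
    eligible = [t for t in transcripts if case.admits(t)]
    windows = [upstream_window(t, case) for t in eligible]

    # vectorized per chromosome: both searchsorted ends at once
    starts = np.fromiter((w.start for w in windows), dtype=np.int64, count=len(windows))
    ends = np.fromiter((w.end for w in windows), dtype=np.int64, count=len(windows))
    chroms = np.array([w.chrom for w in windows], dtype=object)
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom in set(chroms.tolist()):
        idx = np.flatnonzero(chroms == chrom)
        positions = snps.positions(chrom)
        lo = np.searchsorted(positions, starts[idx], side="left")
        hi = np.searchsorted(positions, ends[idx], side="left")
        counts[idx] = hi - lo

    frame = pd.DataFrame(
        {
            "accession": [t.accession for t in eligible],
            "gene_symbol": [t.gene_symbol for t in eligible],
            "chrom": [t.chrom for t in eligible],
            "strand": [t.strand for t in eligible],
            "window_start": starts,
            "window_end": ends,
            "effective_length": ends - starts,
            "snp_content": counts,
        },
        columns=_CONTENT_COLUMNS,
    )
    return SnpContentTable(case=case, frame=frame)


def snp_rich_subset(
    table: SnpContentTable, min_content: int = SNP_RICH_MIN_CONTENT
) -> list[tuple[str, str]]:
    """Transcripts with ``snp_content >= min_content`` as
    (accession, gene_symbol) pairs, sorted by descending content then by
    accession."""
    if min_content < 0:
        raise ValueError("min_content must be non-negative")
    sub = table.frame[table.frame["snp_content"] >= min_content]
    sub = sub.sort_values(
        ["snp_content", "accession"], ascending=[False, True], kind="mergesort"
    )
    return list(zip(sub["accession"], sub["gene_symbol"]))


# ---------------------------------------------------------------------------
# serialization


def write_content_table(table: SnpContentTable, path: str | Path) -> None:
    """TSV with the case encoded in comment lines before the header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# anchor={table.case.anchor}\n")
        fh.write(f"# window_length={table.case.window_length}\n")
        fh.write(f"# utr_requirement={table.case.utr_requirement}\n")
    table.frame.to_csv(path, sep="\t", index=False, mode="a", lineterminator="\n")


def read_content_table(path: str | Path) -> SnpContentTable:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    case = CaseSpec(
        anchor=meta.get("anchor", "TSS"),
        window_length=int(meta.get("window_length", "500")),
        utr_requirement=meta.get("utr_requirement", "any"),
    )
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={
            "accession": str,
            "gene_symbol": str,
            "chrom": str,
            "strand": str,
            "window_start": np.int64,
            "window_end": np.int64,
            "effective_length": np.int64,
            "snp_content": np.int64,
        },
    )
    return SnpContentTable(case=case, frame=frame[_CONTENT_COLUMNS])
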