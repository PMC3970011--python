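"""Transcript selection, 5'UTR lengths, anchors and upstream windows.

The catalog keeps curated, coding transcripts on canonical chromosomes
and retains one transcript per distinct (chrom, strand, TSS) key.  For
every kept transcript it can derive the strand-aware window upstream of
either the transcription start site (TSS) or the coding region start
(CRS), in 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import TranscriptRecord

__all__ = [
    "CaseSpec",
    "GenomicInterval",
    "FilterReport",
    "DEFAULT_CHROMOSOMES",
    "DEFAULT_CASES",
    "filter_transcripts",
    "utr5_length",
    "anchor_position",
    "upstream_window",
]

#: Canonical chromosome names (normalized, no "chr" prefix).
DEFAULT_CHROMOSOMES: frozenset[str] = frozenset(
    [str(i) for i in range(1, 23)] + ["X", "Y"]
)


@dataclass(frozen=True, slots=True)
class CaseSpec:
    """One analysis configuration.

    anchor
        ``"TSS"`` or ``"CRS"``: which boundary the window is upstream of.
    window_length
        Window size in bases (any positive integer; 500 and 1000 are the
        conventional choices).
    utr_requirement
        ``"any"`` keeps every transcript (5'UTR length >= 0);
        ``"positive"`` keeps only transcripts whose TSS and CRS differ.
    """

    anchor: str = "TSS"
    window_length: int = 500
    utr_requirement: str = "any"

    def __post_init__(self):
        if self.anchor not in ("TSS", "CRS"):
            raise ValueError(f"anchor must be 'TSS' or 'CRS', got {self.anchor!r}")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if self.utr_requirement not in ("any", "positive"):
            raise ValueError(
                f"utr_requirement must be 'any' or 'positive', got {self.utr_requirement!r}"
            )

    @property
    def label(self) -> str:
        utr = "utr5_gt0" if self.utr_requirement == "positive" else "utr5_ge0"
        return f"{utr}_{self.anchor}_{self.window_length}"

    def admits(self, record: TranscriptRecord) -> bool:
        """Does ``record`` satisfy this case's 5'UTR requirement?"""
        return self.utr_requirement == "any" or utr5_length(record) > 0


#: The six default configurations exercised by the full analysis.
DEFAULT_CASES: tuple[CaseSpec, ...] = (
    CaseSpec("TSS", 500, "any"),
    CaseSpec("TSS", 1000, "any"),
    CaseSpec("CRS", 500, "any"),
    CaseSpec("TSS", 500, "positive"),
    CaseSpec("CRS", 500, "positive"),
    CaseSpec("CRS", 1000, "positive"),
)


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """0-based half-open interval; ``effective_length`` reflects clipping
    at position 0 (it always equals ``end - start`` after clipping)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"require 0 <= start <= end, got [{self.start}, {self.end})")

    @property
    def effective_length(self) -> int:
        return self.end - self.start


@dataclass
class FilterReport:
    """Counts of transcripts removed by each selection criterion."""

    n_input: int = 0
    removed_non_curated: int = 0
    removed_non_canonical_chrom: int = 0
    removed_non_coding: int = 0
    removed_duplicate_tss: int = 0
    n_kept: int = 0
    n_kept_utr5_positive: int = 0
    n_kept_utr5_zero: int = 0
    removed_accessions: dict[str, str] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return (
            self.removed_non_curated
            + self.removed_non_canonical_chrom
            + self.removed_non_coding
            + self.removed_duplicate_tss
        )

    def to_rows(self) -> list[dict]:
        return [
            {"metric": "input", "count": self.n_input},
            {"metric": "removed_non_curated", "count": self.removed_non_curated},
            {
                "metric": "removed_non_canonical_chrom",
                "count": self.removed_non_canonical_chrom,
            },
            {"metric": "removed_non_coding", "count": self.removed_non_coding},
            {"metric": "removed_duplicate_tss", "count": self.removed_duplicate_tss},
            {"metric": "kept", "count": self.n_kept},
            {"metric": "kept_utr5_positive", "count": self.n_kept_utr5_positive},
            {"metric": "kept_utr5_zero", "count": self.n_kept_utr5_zero},
        ]


def utr5_length(record: TranscriptRecord) -> int:
    """Length of the 5'UTR in bases; zero when TSS and CRS coincide."""
    if record.strand == "+":
        return record.cds_start - record.tx_start
    return record.tx_end - record.cds_end


def anchor_position(record: TranscriptRecord, anchor: str) -> int:
    """Half-open boundary coordinate of the TSS or CRS.

    The transcript body lies on the downstream side of the returned
    boundary: for "+" strand that is to the right, for "-" to the left.
    """
    if anchor == "TSS":
        return record.tx_start if record.strand == "+" else record.tx_end
    if anchor == "CRS":
        return record.cds_start if record.strand == "+" else record.cds_end
    raise ValueError(f"anchor must be 'TSS' or 'CRS', got {anchor!r}")


def upstream_window(record: TranscriptRecord, case: CaseSpec) -> GenomicInterval:
    """The strictly-upstream window of length ``case.window_length``.

    ``[boundary - L, boundary)`` on "+" strand, ``[boundary, boundary + L)``
    on "-" strand.  A variant sitting exactly on the boundary is
    downstream and is never inside the window.  Windows running off the
    chromosome start are clipped at 0 (see ``effective_length``).
    """
    boundary = anchor_position(record, case.anchor)
    length = case.window_length
    if record.strand == "+":
        return GenomicInterval(record.chrom, max(0, boundary - length), boundary)
    return GenomicInterval(record.chrom, boundary, boundary + length)


def filter_transcripts(
    records: Sequence[TranscriptRecord] | Iterable[TranscriptRecord],
    *,
    accession_prefix: str = "NM_",
    chromosomes: frozenset[str] | set[str] = DEFAULT_CHROMOSOMES,
    dedup_by_strand: bool = True,
) -> tuple[list[TranscriptRecord], FilterReport]:
    """Apply the transcript-selection criteria.

    Order: curated-accession prefix, canonical chromosome, coding
    annotation (``cds_start < cds_end``), then TSS de-duplication.  When
    several transcripts share a (chrom, strand, TSS boundary) key — or a
    (chrom, TSS) key with ``dedup_by_strand=False`` — the one with the
    lexicographically smallest accession survives (deterministic and
    idempotent).
    """
    records = list(records)
    report = FilterReport(n_input=len(records))
    stage: list[TranscriptRecord] = []
    for rec in records:
        if not rec.accession.startswith(accession_prefix):
            report.removed_non_curated += 1
            report.removed_accessions[rec.accession] = "non_curated"
        elif rec.chrom not in chromosomes:
            report.removed_non_canonical_chrom += 1
            report.removed_accessions[rec.accession] = "non_canonical_chrom"
        elif rec.cds_start == rec.cds_end:
            report.removed_non_coding += 1
            report.removed_accessions[rec.accession] = "non_coding"
        else:
            stage.append(rec)

    best: dict[tuple, TranscriptRecord] = {}
    for rec in stage:
        tss = anchor_position(rec, "TSS")
        key = (rec.chrom, rec.strand, tss) if dedup_by_strand else (rec.chrom, tss)
        held = best.get(key)
        if held is None or rec.accession < held.accession:
            best[key] = rec
    kept = [rec for rec in stage if best[_dedup_key(rec, dedup_by_strand)] is rec]
    report.removed_duplicate_tss = len(stage) - len(kept)
    for rec in stage:
        if best[_dedup_key(rec, dedup_by_strand)] is not rec:
            report.removed_accessions[rec.accession] = "duplicate_tss"

    report.n_kept = len(kept)
    report.n_kept_utr5_positive = sum(1 for r in kept if utr5_length(r) > 0)
    report.n_kept_utr5_zero = report.n_kept - report.n_kept_utr5_positive
    return kept, report


def _dedup_key(rec: TranscriptRecord, by_strand: bool) -> tuple:
    tss = anchor_position(rec, "TSS")
    return (rec.chrom, rec.strand, tss) if by_strand else (rec.chrom, tss)
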