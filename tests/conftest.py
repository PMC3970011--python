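from __future__ import annotations

import numpy as np
import pytest

from promvar.io_formats import SnpRecord, SnpTable, TranscriptRecord
from promvar.synthetic_data import make_fixture


def make_tx(
    accession="NM_0001",
    gene_symbol="GENE",
    chrom="1",
    strand="+",
    tx_start=10_000,
    tx_end=12_000,
    cds_start=None,
    cds_end=None,
):
    if cds_start is None:
        cds_start = tx_start + 100
    if cds_end is None:
        cds_end = tx_end - 100
    return TranscriptRecord(
        accession=accession,
        gene_symbol=gene_symbol,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
    )


def make_snp(chrom="1", pos=0, rsid=None, variant_class="single",
             flags=("by-1000genomes",)):
    return SnpRecord(
        chrom=chrom,
        pos=pos,
        rsid=rsid or f"rs{chrom}_{pos}",
        variant_class=variant_class,
        validation_flags=frozenset(flags),
    )


def snp_table_at(positions_by_chrom: dict[str, list[int]]) -> SnpTable:
    records = [
        make_snp(chrom=c, pos=p)
        for c, positions in positions_by_chrom.items()
        for p in positions
    ]
    return SnpTable.from_records(records)


def mirror_transcript(rec: TranscriptRecord, chrom_len: int) -> TranscriptRecord:
    """Map every coordinate x -> chrom_len - x and flip the strand."""
    return TranscriptRecord(
        accession=rec.accession,
        gene_symbol=rec.gene_symbol,
        chrom=rec.chrom,
        strand="-" if rec.strand == "+" else "+",
        tx_start=chrom_len - rec.tx_end,
        tx_end=chrom_len - rec.tx_start,
        cds_start=chrom_len - rec.cds_end,
        cds_end=chrom_len - rec.cds_start,
    )


def mirror_snp_table(table: SnpTable, chrom_len: int) -> SnpTable:
    """A 1-bp feature at pos occupies [pos, pos+1); its mirror is
    [chrom_len - pos - 1, chrom_len - pos)."""
    return SnpTable(
        table.chrom.copy(),
        chrom_len - 1 - table.pos,
        table.rsid.copy(),
        table.variant_class.copy(),
        table.validation_flags.copy(),
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    make_fixture(out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240324)
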