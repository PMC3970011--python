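"""Synthetic annotation and SNP datasets, plus a tiny auditable fixture.

The simulator emulates the statistical structure the analysis assumes:
transcripts on a few chromosomes with random strand and a 5'UTR length
mixture (point mass at zero plus a geometric positive part), and SNPs
placed by a per-base Bernoulli process at a baseline density, elevated
by a configurable multiplier inside the 1000-bp upstream windows of a
designated gene group (so every analysis case sees the enrichment).

Placement uses one non-overlapping slot per transcript so that upstream
windows of different transcripts are disjoint; per-window SNP counts
are then independent, which the downstream test's variance model
assumes.  The Bernoulli process is sampled exactly via its equivalent
law: a Binomial(L, rate) count followed by a uniform draw of that many
distinct positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import SnpTable, TranscriptRecord

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_annotation",
    "simulate_snps",
    "simulate_dataset",
    "make_fixture",
    "FIXTURE_MANIFEST",
]

#: Baseline per-base SNP density (3.7 SNPs per 1000 bp).
DEFAULT_BASELINE_DENSITY = 0.0037

#: Length of the upstream region in which group density is elevated;
#: covers every default analysis window.
ELEVATION_WINDOW = 1000


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset."""

    n_chromosomes: int = 4
    chromosome_length: int = 20_000_000
    n_transcripts: int = 20_000
    group_sizes: tuple[tuple[str, int], ...] = (("group1", 400),)
    strand_prob: float = 0.5
    utr5_zero_weight: float = 0.05
    utr5_mean: float = 150.0
    transcript_length_range: tuple[int, int] = (1500, 2500)
    baseline_density: float = DEFAULT_BASELINE_DENSITY
    group_multiplier: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise ValueError("chromosome counts and lengths must be positive")
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if any(size <= 0 for _, size in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if sum(size for _, size in self.group_sizes) > self.n_transcripts:
            raise ValueError("group sizes exceed n_transcripts")
        if not (0.0 <= self.strand_prob <= 1.0):
            raise ValueError("strand_prob must lie in [0, 1]")
        if not (0.0 <= self.utr5_zero_weight <= 1.0):
            raise ValueError("utr5_zero_weight must lie in [0, 1]")
        if self.utr5_mean <= 0:
            raise ValueError("utr5_mean must be positive")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ValueError("transcript_length_range must satisfy 0 < lo <= hi")
        if lo < 500:
            raise ValueError("transcripts shorter than 500 bp are not supported")
        if self.baseline_density < 0 or self.group_multiplier < 0:
            raise ValueError("densities must be non-negative")
        if self.baseline_density * self.group_multiplier > 1.0:
            raise ValueError("elevated per-base density exceeds 1")

    @property
    def group_size_map(self) -> dict[str, int]:
        return dict(self.group_sizes)


@dataclass
class GroundTruth:
    """What the simulator actually did, for parameter-recovery tests."""

    spec: SimulationSpec
    seed: int
    groups: dict[str, list[str]] = field(default_factory=dict)  # accessions
    group_symbols: dict[str, list[str]] = field(default_factory=dict)
    elevated_intervals: dict[str, np.ndarray] = field(default_factory=dict)
    realized_density_background: Optional[float] = None
    realized_density_elevated: Optional[float] = None


def _chrom_names(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def simulate_annotation(
    spec: SimulationSpec,
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Generate the transcript catalog and group assignment.

    Transcripts are laid out one per slot, slots evenly split across
    chromosomes, with randomized strand, length, 5'UTR and within-slot
    jitter.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_transcripts
    chroms = _chrom_names(spec.n_chromosomes)
    per_chrom = [n // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(n % spec.n_chromosomes):
        per_chrom[i] += 1
    max_per_chrom = max(per_chrom)
    slot = spec.chromosome_length // max_per_chrom
    lo, hi = spec.transcript_length_range
    pad = slot - (hi + ELEVATION_WINDOW)
    if pad < 16:
        need = (hi + ELEVATION_WINDOW + 16) * max_per_chrom
        raise ValueError(
            "transcripts cannot fit the chromosome: need chromosome_length >= "
            f"{need} for {max_per_chrom} transcripts per chromosome "
            f"(got {spec.chromosome_length})"
        )

    strands = np.where(rng.random(n) < spec.strand_prob, "+", "-")
    lengths = rng.integers(lo, hi + 1, size=n)
    jitter = rng.integers(0, pad, size=n)
    utr_zero = rng.random(n) < spec.utr5_zero_weight
    utr_pos = rng.geometric(min(1.0, 1.0 / spec.utr5_mean), size=n)
    utr5 = np.where(utr_zero, 0, utr_pos)
    # keep the CDS non-empty: reserve a 200-bp 3' tail plus one codon
    utr5 = np.minimum(utr5, lengths - 201)

    records: list[TranscriptRecord] = []
    i = 0
    for chrom, count in zip(chroms, per_chrom):
        for s in range(count):
            base = s * slot
            length = int(lengths[i])
            if strands[i] == "+":
                tx_start = base + ELEVATION_WINDOW + int(jitter[i])
                tx_end = tx_start + length
                cds_start = tx_start + int(utr5[i])
                cds_end = tx_end - 200
            else:
                tx_end = base + slot - ELEVATION_WINDOW - int(jitter[i])
                tx_start = tx_end - length
                cds_end = tx_end - int(utr5[i])
                cds_start = tx_start + 200
            records.append(
                TranscriptRecord(
                    accession=f"NM_SIM{i + 1:06d}",
                    gene_symbol=f"SIMG{i + 1:06d}",
                    chrom=chrom,
                    strand=str(strands[i]),
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
            i += 1

    truth = GroundTruth(spec=spec, seed=spec.seed)
    remaining = np.arange(n)
    for name, size in spec.group_sizes:
        picked_idx = rng.permutation(len(remaining))[:size]
        picked = np.sort(remaining[picked_idx])
        remaining = np.delete(remaining, np.sort(picked_idx))
        truth.groups[name] = [records[j].accession for j in picked]
        truth.group_symbols[name] = [records[j].gene_symbol for j in picked]

    member = set()
    for accs in truth.groups.values():
        member.update(accs)
    intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for rec in records:
        if rec.accession in member:
            if rec.strand == "+":
                start = max(0, rec.tx_start - ELEVATION_WINDOW)
                intervals[rec.chrom].append((start, rec.tx_start))
            else:
                intervals[rec.chrom].append((rec.tx_end, rec.tx_end + ELEVATION_WINDOW))
    for chrom in chroms:
        merged = _merge_intervals(intervals[chrom], spec.chromosome_length)
        truth.elevated_intervals[chrom] = merged
    return records, truth


def _merge_intervals(pairs: list[tuple[int, int]], chrom_len: int) -> np.ndarray:
    """Sort, clip to [0, chrom_len) and merge overlapping intervals."""
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    arr = sorted((max(0, a), min(b, chrom_len)) for a, b in pairs)
    merged: list[list[int]] = []
    for a, b in arr:
        if b <= a:
            continue
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.array(merged, dtype=np.int64).reshape(-1, 2)


def _sample_distinct(rng: np.random.Generator, length: int, k: int) -> np.ndarray:
    """A uniform random k-subset of range(length), sorted.

    Equivalent to conditioning a per-base Bernoulli draw on its success
    count: sample with replacement, de-duplicate, top up on the (rare)
    shortfall, then thin uniformly to exactly k.
    """
    if k < 0 or k > length:
        raise ValueError(f"cannot draw {k} distinct positions from {length}")
    if k == 0:
        return np.empty(0, dtype=np.int64)
    distinct = np.unique(rng.integers(0, length, size=min(length, int(k * 1.02) + 16)))
    while len(distinct) < k:
        extra = rng.integers(0, length, size=k - len(distinct) + 16)
        distinct = np.unique(np.concatenate([distinct, extra]))
    if len(distinct) > k:
        keep = rng.permutation(len(distinct))[:k]
        distinct = np.sort(distinct[keep])
    return distinct.astype(np.int64)


def _offsets_to_positions(offsets: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Map offsets in the concatenated interval space back to genomic
    coordinates (``intervals`` is (m, 2), sorted, non-overlapping)."""
    if len(offsets) == 0:
        return offsets
    lengths = intervals[:, 1] - intervals[:, 0]
    cum = np.concatenate(([0], np.cumsum(lengths)))
    idx = np.searchsorted(cum, offsets, side="right") - 1
    return intervals[idx, 0] + (offsets - cum[idx])


def _complement(intervals: np.ndarray, chrom_len: int) -> np.ndarray:
    edges = [0]
    for a, b in intervals:
        edges.extend([int(a), int(b)])
    edges.append(chrom_len)
    out = [
        (edges[i], edges[i + 1])
        for i in range(0, len(edges), 2)
        if edges[i + 1] > edges[i]
    ]
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def simulate_snps(
    transcripts: list[TranscriptRecord],
    truth: GroundTruth,
    spec: SimulationSpec,
) -> SnpTable:
    """Place SNPs by per-base Bernoulli at ``baseline_density``, elevated
    to ``baseline_density * group_multiplier`` inside group members'
    upstream windows.  All records are class ``single`` with validation
    flag ``by-1000genomes``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    lam0 = spec.baseline_density
    lam1 = min(1.0, lam0 * spec.group_multiplier)
    flagset = frozenset({"by-1000genomes"})
    all_chrom: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    n_bg = n_elev = 0
    bg_len = elev_len = 0
    for chrom in sorted(_chrom_names(spec.n_chromosomes)):
        elevated = truth.elevated_intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
        background = _complement(elevated, spec.chromosome_length)
        u = int((elevated[:, 1] - elevated[:, 0]).sum()) if len(elevated) else 0
        l_bg = spec.chromosome_length - u
        k_elev = rng.binomial(u, lam1) if u and lam1 > 0 else 0
        k_bg = rng.binomial(l_bg, lam0) if l_bg and lam0 > 0 else 0
        pos_elev = _offsets_to_positions(_sample_distinct(rng, u, k_elev), elevated)
        pos_bg = _offsets_to_positions(_sample_distinct(rng, l_bg, k_bg), background)
        pos = np.sort(np.concatenate([pos_elev, pos_bg]))
        all_pos.append(pos)
        all_chrom.append(np.full(len(pos), chrom, dtype=object))
        n_elev += k_elev
        n_bg += k_bg
        elev_len += u
        bg_len += l_bg
    pos = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
    chrom_arr = (
        np.concatenate(all_chrom) if all_chrom else np.empty(0, dtype=object)
    )
    # rsid is synthetic anyway; a position-derived id keeps this cheap
    rsid = np.char.add("rs", pos.astype(np.int64).astype("U12")).astype(object)
    truth.realized_density_background = n_bg / bg_len if bg_len else None
    truth.realized_density_elevated = n_elev / elev_len if elev_len else None
    return SnpTable(
        chrom_arr,
        pos.astype(np.int64),
        rsid,
        np.full(len(pos), "single", dtype=object),
        np.full(len(pos), flagset, dtype=object),
        presorted=True,
    )


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[list[TranscriptRecord], SnpTable, GroundTruth]:
    """Convenience wrapper: annotation then SNPs, shared ground truth."""
    transcripts, truth = simulate_annotation(spec)
    snps = simulate_snps(transcripts, truth, spec)
    return transcripts, snps, truth


# ---------------------------------------------------------------------------
# hand-auditable fixture
#
# 12 transcripts on chromosomes 1, 2 and M: both strands, a duplicate-TSS
# pair (NM_0001 / NM_0005), an XM_ accession, a chrM record, zero-length
# 5'UTRs (NM_0003, NM_0007, NM_0008) and a window clipped at position 0
# (NM_0003, TSS = 300).  Every expected value in FIXTURE_MANIFEST was
# enumerated by hand from these coordinates.

FIXTURE_REFGENE = """\
NM_0001\tGENA\tchr1\t+\t10000\t12000\t10400\t11800
NM_0002\tGENB\t1\t-\t20000\t23000\t20200\t22500
NM_0003\tGENC\tchr1\t+\t300\t4000\t300\t3800
NM_0004\tGEND\tchr1\t-\t40000\t42000\t40100\t41900
NM_0005\tGENE5\tchr1\t+\t10000\t13000\t10500\t12900
XM_0006\tGENF\tchr1\t+\t50000\t52000\t50200\t51800
NM_0007\tGENG\tchr2\t+\t10000\t12000\t10000\t11500
NM_0008\tGENH\tchr2\t-\t15000\t17000\t15500\t17000
NM_0009\tGENI\tchr2\t+\t30000\t33000\t30250\t32800
NM_0010\tGENJ\tchr2\t-\t40000\t44000\t41000\t43000
NM_0011\tGENK\tchrM\t+\t1000\t2000\t1100\t1900
NM_0012\tGENL\t2\t+\t60000\t62000\t60100\t61900
"""

# 35 rows: one exact duplicate pair (rs1003), one non-single class
# (rs9001) and one record lacking the 1000-genomes flag (rs9002).
FIXTURE_SNPS = """\
chr1\t9499\t9500\trs1001\tsingle\tby-1000genomes
chr1\t9500\t9501\trs1002\tsingle\tby-1000genomes,by-frequency
chr1\t9750\t9751\trs1003\tsingle\tby-1000genomes
chr1\t9750\t9751\trs1003\tsingle\tby-1000genomes
chr1\t9999\t10000\trs1004\tsingle\tby-1000genomes
chr1\t10000\t10001\trs1005\tsingle\tby-1000genomes
chr1\t10200\t10201\trs1006\tsingle\tby-1000genomes
chr1\t9450\t9451\trs1007\tsingle\tby-1000genomes
chr1\t23000\t23001\trs1008\tsingle\tby-1000genomes
chr1\t23499\t23500\trs1009\tsingle\tby-1000genomes
chr1\t23500\t23501\trs1010\tsingle\tby-1000genomes
chr1\t22500\t22501\trs1011\tsingle\tby-1000genomes
chr1\t22999\t23000\trs1012\tsingle\tby-1000genomes
chr1\t0\t1\trs1013\tsingle\tby-1000genomes
chr1\t150\t151\trs1014\tsingle\tby-1000genomes
chr1\t299\t300\trs1015\tsingle\tby-1000genomes
chr1\t300\t301\trs1016\tsingle\tby-1000genomes
chr1\t42100\t42101\trs1017\tsingle\tby-1000genomes
chr1\t42450\t42451\trs1018\tsingle\tby-1000genomes
chr1\t41950\t41951\trs1019\tsingle\tby-1000genomes
chr1\t9600\t9603\trs9001\tdeletion\tby-1000genomes
chr1\t9700\t9701\trs9002\tsingle\tby-frequency
chr2\t9510\t9511\trs2001\tsingle\tby-1000genomes
chr2\t9550\t9551\trs2002\tsingle\tby-1000genomes
chr2\t9600\t9601\trs2003\tsingle\tBY_1000GENOMES
chr2\t9650\t9651\trs2004\tsingle\tby-1000genomes
chr2\t9700\t9701\trs2005\tsingle\tby-1000genomes
chr2\t9800\t9801\trs2006\tsingle\tby-1000genomes
chr2\t9900\t9901\trs2007\tsingle\tby-1000genomes
chr2\t9200\t9201\trs2008\tsingle\tby-1000genomes
chr2\t17100\t17101\trs2009\tsingle\tby-1000genomes
chr2\t29800\t29801\trs2010\tsingle\tby-1000genomes
chr2\t30100\t30101\trs2011\tsingle\tby-1000genomes
chr2\t59550\t59551\trs2012\tsingle\tby-1000genomes
chr2\t60050\t60051\trs2013\tsingle\tby-1000genomes
"""

FIXTURE_GMT = """\
OLFACTORY_LIKE\ttoy olfactory-flavored set\tGENG\tGENA\tGENL
IMMUNE_LIKE\ttoy immune-flavored set\tGENB\tGENI\tGENJ
HOUSEKEEPING\ttoy background set\tGENC\tGEND\tGENH\tGENL
"""

#: Hand-enumerated expected values for the fixture.
FIXTURE_MANIFEST: dict = {
    "transcripts": [
        ["NM_0001", "GENA", "1", "+", 10000, 12000, 10400, 11800],
        ["NM_0002", "GENB", "1", "-", 20000, 23000, 20200, 22500],
        ["NM_0003", "GENC", "1", "+", 300, 4000, 300, 3800],
        ["NM_0004", "GEND", "1", "-", 40000, 42000, 40100, 41900],
        ["NM_0005", "GENE5", "1", "+", 10000, 13000, 10500, 12900],
        ["XM_0006", "GENF", "1", "+", 50000, 52000, 50200, 51800],
        ["NM_0007", "GENG", "2", "+", 10000, 12000, 10000, 11500],
        ["NM_0008", "GENH", "2", "-", 15000, 17000, 15500, 17000],
        ["NM_0009", "GENI", "2", "+", 30000, 33000, 30250, 32800],
        ["NM_0010", "GENJ", "2", "-", 40000, 44000, 41000, 43000],
        ["NM_0011", "GENK", "M", "+", 1000, 2000, 1100, 1900],
        ["NM_0012", "GENL", "2", "+", 60000, 62000, 60100, 61900],
    ],
    "snp_table": {
        "n_rows": 35,
        "n_records": 34,
        "n_duplicates": 1,
        "per_chrom_counts": {"1": 21, "2": 13},
        "per_chrom_counts_filtered": {"1": 19, "2": 13},
    },
    "filter_report": {
        "n_input": 12,
        "removed_non_curated": 1,
        "removed_non_canonical_chrom": 1,
        "removed_non_coding": 0,
        "removed_duplicate_tss": 1,
        "n_kept": 9,
        "n_kept_utr5_positive": 6,
        "n_kept_utr5_zero": 3,
    },
    "kept_accessions": [
        "NM_0001", "NM_0002", "NM_0003", "NM_0004", "NM_0007",
        "NM_0008", "NM_0009", "NM_0010", "NM_0012",
    ],
    "utr5_lengths": {
        "NM_0001": 400, "NM_0002": 500, "NM_0003": 0, "NM_0004": 100,
        "NM_0007": 0, "NM_0008": 0, "NM_0009": 250, "NM_0010": 1000,
        "NM_0012": 100,
    },
    "contents": {
        "utr5_ge0_TSS_500": {
            "NM_0001": 3, "NM_0002": 2, "NM_0003": 3, "NM_0004": 2,
            "NM_0007": 7, "NM_0008": 1, "NM_0009": 1, "NM_0010": 0,
            "NM_0012": 1,
        },
        "utr5_ge0_TSS_1000": {
            "NM_0001": 5, "NM_0002": 3, "NM_0003": 3, "NM_0004": 2,
            "NM_0007": 8, "NM_0008": 1, "NM_0009": 1, "NM_0010": 0,
            "NM_0012": 1,
        },
        "utr5_ge0_CRS_500": {
            "NM_0001": 3, "NM_0002": 2, "NM_0003": 3, "NM_0004": 2,
            "NM_0007": 7, "NM_0008": 1, "NM_0009": 2, "NM_0010": 0,
            "NM_0012": 1,
        },
        "utr5_gt0_TSS_500": {
            "NM_0001": 3, "NM_0002": 2, "NM_0004": 2, "NM_0009": 1,
            "NM_0010": 0, "NM_0012": 1,
        },
        "utr5_gt0_CRS_500": {
            "NM_0001": 3, "NM_0002": 2, "NM_0004": 2, "NM_0009": 2,
            "NM_0010": 0, "NM_0012": 1,
        },
        "utr5_gt0_CRS_1000": {
            "NM_0001": 7, "NM_0002": 4, "NM_0004": 3, "NM_0009": 2,
            "NM_0010": 0, "NM_0012": 2,
        },
    },
    "effective_lengths_utr5_ge0_TSS_500": {
        "NM_0003": 300,  # clipped at position 0; all others 500
    },
    "snp_rich_min6_utr5_ge0_TSS_500": [["NM_0007", "GENG"]],
    "gene_sets": {
        "OLFACTORY_LIKE": ["GENA", "GENG", "GENL"],
        "IMMUNE_LIKE": ["GENB", "GENI", "GENJ"],
        "HOUSEKEEPING": ["GENC", "GEND", "GENH", "GENL"],
    },
}


def make_fixture(out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture bundle; regeneration is byte-identical."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "refgene": out_dir / "tiny_refgene.tsv",
        "snps": out_dir / "tiny_snps.tsv",
        "gene_sets": out_dir / "toy_sets.gmt",
        "manifest": out_dir / "manifest.json",
    }
    paths["refgene"].write_text(FIXTURE_REFGENE)
    paths["snps"].write_text(FIXTURE_SNPS)
    paths["gene_sets"].write_text(FIXTURE_GMT)
    paths["manifest"].write_text(
        json.dumps(FIXTURE_MANIFEST, indent=2, sort_keys=True) + "\n"
    )
    return paths
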