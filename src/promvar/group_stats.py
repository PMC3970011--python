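"""Group-vs-background tests on SNP-content distributions.

For a gene group and a background catalog, the tail proportion of
transcripts with at least N upstream SNPs is compared at each threshold
N via the angular (arcsine square root) transformation,
``y = 2*arcsin(sqrt(p))``, whose variance is approximately ``1/n``.
The test statistic ``(y1 - y2) / sqrt(1/n1 + 1/n2)`` is referred to the
standard normal by default (no variance is estimated after the
transform, so no finite degrees of freedom are defined); a finite-df
t-reference is available for sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SnpTable, TranscriptRecord, write_table
from .snp_content import SnpContentTable, build_content_table
from .transcript_catalog import DEFAULT_CASES, CaseSpec

__all__ = [
    "ComparisonResult",
    "SweepTable",
    "content_histogram",
    "angular_transform",
    "compare_proportions",
    "threshold_sweep",
    "run_case_matrix",
    "match_group",
    "read_sweep_table",
    "write_sweep_table",
]

_SIDEDNESS = ("one-sided-greater", "two-sided")


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    """Group-vs-background comparison of tail proportions at one threshold."""

    N: int
    n1: int
    n2: int
    x1: int
    x2: int
    p1: float
    p2: float
    y1: float
    y2: float
    z_stat: float
    p_value: float
    sidedness: str


@dataclass
class SweepTable:
    """Ordered :class:`ComparisonResult` rows over a threshold range."""

    case: CaseSpec
    group_name: str
    results: list[ComparisonResult]

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def at(self, N: int) -> ComparisonResult:
        for r in self.results:
            if r.N == N:
                return r
        raise KeyError(f"no result at threshold {N}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.results])


def content_histogram(
    table: SnpContentTable,
) -> tuple[dict[int, int], dict[int, int]]:
    """Histogram of SNP contents and its "at least N" cumulative form.

    Returns ``(hist, at_least)`` where ``hist[c]`` counts transcripts
    with content exactly ``c`` and ``at_least[N]`` counts those with
    content >= N for every N from 1 to the maximum observed content.
    Histogram counts sum to the table's row count.
    """
    values, counts = np.unique(table.contents, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(values, counts)}
    at_least: dict[int, int] = {}
    if hist:
        top = max(hist)
        running = 0
        for n in range(top, 0, -1):
            running += hist.get(n, 0)
            at_least[n] = running
        at_least = dict(sorted(at_least.items()))
    return hist, at_least


def angular_transform(p):
    """Variance-stabilizing transform ``2*arcsin(sqrt(p))`` in radians.

    Accepts scalars or arrays; values must lie in [0, 1].
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("proportions must lie in [0, 1]")
    out = 2.0 * np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def compare_proportions(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    sidedness: str = "one-sided-greater",
    *,
    N: int = 0,
    df_mode: str = "normal",
) -> ComparisonResult:
    """Two-proportion test on angular-transformed values.

    ``z = (y1 - y2) / sqrt(1/n1 + 1/n2)`` with ``y_i`` the transformed
    proportions.  ``df_mode="normal"`` (default) uses the standard
    normal reference; ``df_mode="pooled"`` uses a t reference with
    ``n1 + n2 - 2`` degrees of freedom.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if sidedness not in _SIDEDNESS:
        raise ValueError(f"sidedness must be one of {_SIDEDNESS}")
    p1, p2 = x1 / n1, x2 / n2
    y1, y2 = angular_transform(p1), angular_transform(p2)
    z = (y1 - y2) / np.sqrt(1.0 / n1 + 1.0 / n2)
    if df_mode == "normal":
        ref = stats.norm
    elif df_mode == "pooled":
        ref = stats.t(df=n1 + n2 - 2)
    else:
        raise ValueError(f"df_mode must be 'normal' or 'pooled', got {df_mode!r}")
    if sidedness == "one-sided-greater":
        p_value = float(ref.sf(z))
    else:
        p_value = float(2.0 * ref.sf(abs(z)))
    return ComparisonResult(
        N=N,
        n1=n1,
        n2=n2,
        x1=x1,
        x2=x2,
        p1=p1,
        p2=p2,
        y1=y1,
        y2=y2,
        z_stat=float(z),
        p_value=p_value,
        sidedness=sidedness,
    )


def threshold_sweep(
    group_table: SnpContentTable,
    background_table: SnpContentTable,
    n_range: Iterable[int] = range(1, 21),
    sidedness: str = "one-sided-greater",
    *,
    group_name: str = "group",
    df_mode: str = "normal",
) -> SweepTable:
    """One :func:`compare_proportions` per threshold N.

    Both tables must have been built under the same :class:`CaseSpec`.
    The background conventionally contains the group's transcripts; pass
    a pre-subtracted table for a disjoint-background analysis.
    """
    if group_table.case != background_table.case:
        raise ValueError(
            "CaseSpec mismatch: group table is "
            f"{group_table.case.label}, background is {background_table.case.label}"
        )
    thresholds = sorted(set(int(n) for n in n_range))
    if any(n < 1 for n in thresholds):
        raise ValueError("thresholds must be >= 1")
    c1 = group_table.contents
    c2 = background_table.contents
    n1, n2 = len(c1), len(c2)
    results = []
    for N in thresholds:
        x1 = int(np.count_nonzero(c1 >= N))
        x2 = int(np.count_nonzero(c2 >= N))
        results.append(
            compare_proportions(x1, n1, x2, n2, sidedness, N=N, df_mode=df_mode)
        )
    return SweepTable(case=group_table.case, group_name=group_name, results=results)


def match_group(
    symbols: Iterable[str], table: SnpContentTable
) -> tuple[SnpContentTable, list[str]]:
    """Subset ``table`` to the group's symbols; also return the symbols
    with no transcript in the table."""
    wanted = {s.upper() for s in symbols}
    present = {s.upper() for s in table.frame["gene_symbol"]}
    unmatched = sorted(wanted - present)
    return table.subset_by_symbols(wanted), unmatched


def run_case_matrix(
    transcripts: Sequence[TranscriptRecord],
    snps: SnpTable,
    groups: Mapping[str, Iterable[str]],
    cases: Sequence[CaseSpec] = DEFAULT_CASES,
    *,
    n_range: Iterable[int] = range(1, 21),
    sidedness: str = "one-sided-greater",
    df_mode: str = "normal",
) -> dict[tuple[str, str], SweepTable]:
    """Threshold sweeps for every (group, case) pair.

    ``transcripts`` must already be catalog-filtered and ``snps``
    class/flag-filtered.  Group symbols absent from a case's table
    trigger a warning with the unmatched count.  Returns a mapping from
    ``(group_name, case.label)`` to the sweep.
    """
    n_range = list(n_range)
    out: dict[tuple[str, str], SweepTable] = {}
    for case in cases:
        background = build_content_table(transcripts, snps, case)
        for name, symbols in groups.items():
            group_table, unmatched = match_group(symbols, background)
            if unmatched:
                warnings.warn(
                    f"group {name!r}, case {case.label}: "
                    f"{len(unmatched)} symbol(s) not in the catalog",
                    stacklevel=2,
                )
            out[(name, case.label)] = threshold_sweep(
                group_table,
                background,
                n_range,
                sidedness,
                group_name=name,
                df_mode=df_mode,
            )
    return out


# ---------------------------------------------------------------------------
# serialization

_SWEEP_COLUMNS = [
    "N", "n1", "n2", "x1", "x2", "p1", "p2", "y1", "y2",
    "z_stat", "p_value", "sidedness",
]


def write_sweep_table(sweep: SweepTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# group={sweep.group_name}\n")
        fh.write(f"# anchor={sweep.case.anchor}\n")
        fh.write(f"# window_length={sweep.case.window_length}\n")
        fh.write(f"# utr_requirement={sweep.case.utr_requirement}\n")
    frame = pd.DataFrame(
        [{k: getattr(r, k) for k in _SWEEP_COLUMNS} for r in sweep.results],
        columns=_SWEEP_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, mode="a", lineterminator="\n",
                 float_format="%.17g")


def read_sweep_table(path: str | Path) -> SweepTable:
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
    frame = pd.read_csv(path, sep="\t", comment="#")
    results = [
        ComparisonResult(
            N=int(row.N), n1=int(row.n1), n2=int(row.n2),
            x1=int(row.x1), x2=int(row.x2),
            p1=float(row.p1), p2=float(row.p2),
            y1=float(row.y1), y2=float(row.y2),
            z_stat=float(row.z_stat), p_value=float(row.p_value),
            sidedness=str(row.sidedness),
        )
        for row in frame.itertuples()
    ]
    return SweepTable(case=case, group_name=meta.get("group", "group"),
                      results=results)
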