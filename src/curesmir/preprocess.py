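"""sRNA read cleanup, collapsing, and library comparison statistics.

The central container is :class:`UniqueReadTable`: collapsed read sequences
with one count column per library. All comparison statistics (shared/specific
partitions, length distributions, annotation breakdown, TPM) are computed from
it. Percent columns are rounded half-up to two decimals, the precision such
tables are conventionally printed at.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import is_nucleotide, round_half_up, to_rna

MIN_LEN_DEFAULT = 15
LENGTH_RANGE = range(15, 45)  # 15-44 nt


@dataclass
class UniqueReadTable:
    """Collapsed unique reads x libraries count matrix.

    ``counts`` is indexed by read sequence (RNA alphabet, uppercase) with one
    integer column per library.
    """

    counts: pd.DataFrame

    @property
    def library_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_unique(self) -> pd.Series:
        return (self.counts > 0).sum(axis=0)

    def sequences(self) -> pd.Index:
        return self.counts.index

    def library_counts(self, library: str) -> dict[str, int]:
        if library not in self.counts.columns:
            raise KeyError(f"unknown library id {library!r}")
        col = self.counts[library]
        return {s: int(c) for s, c in col[col > 0].items()}

    def subset(self, sequences: Iterable[str]) -> "UniqueReadTable":
        keep = self.counts.index.intersection(pd.Index(sequences))
        return UniqueReadTable(self.counts.loc[keep])


@dataclass
class LibraryComparison:
    """Shared/specific partition of two libraries, as in collapsed sRNA reports.

    Percentages of unique counts use the size of the unique-sequence union as
    the denominator; percentages of total counts use the grand total of reads
    across both libraries. Mean frequencies are reads per unique sequence
    (per library for the shared partition).
    """

    libraries: tuple[str, str]
    shared_unique: int
    specific_unique: dict[str, int]
    shared_total: dict[str, int]
    specific_total: dict[str, int]
    pct_shared_unique: float
    pct_specific_unique: dict[str, float]
    pct_shared_total: float
    pct_specific_total: dict[str, float]
    mean_freq_shared: float
    mean_freq_specific: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        a, b = self.libraries
        rows = [
            ("shared", self.shared_unique, self.pct_shared_unique,
             sum(self.shared_total.values()), self.pct_shared_total,
             self.mean_freq_shared),
            (f"{a}-specific", self.specific_unique[a], self.pct_specific_unique[a],
             self.specific_total[a], self.pct_specific_total[a],
             self.mean_freq_specific[a]),
            (f"{b}-specific", self.specific_unique[b], self.pct_specific_unique[b],
             self.specific_total[b], self.pct_specific_total[b],
             self.mean_freq_specific[b]),
        ]
        return pd.DataFrame(
            rows,
            columns=["partition", "unique", "pct_unique", "total", "pct_total",
                     "mean_frequency"],
        )


def _to_count_map(reads: Iterable[str] | Mapping[str, int]) -> dict[str, int]:
    if isinstance(reads, Mapping):
        return {str(s): int(c) for s, c in reads.items()}
    out: dict[str, int] = {}
    for s in reads:
        out[s] = out.get(s, 0) + 1
    return out


def clean_reads(
    raw: Mapping[str, Iterable[str] | Mapping[str, int]],
    min_len: int = MIN_LEN_DEFAULT,
    singleton_rule: bool = True,
) -> tuple[UniqueReadTable, pd.DataFrame]:
    """Collapse and filter raw reads from one or more libraries.

    Filters, in order: non-nucleotide sequences, reads shorter than
    ``min_len``, and (if ``singleton_rule``) unique sequences whose summed
    count across all libraries is 1 — i.e. detected only once, in a single
    library. Returns the cleaned table and a per-library report with raw and
    clean read counts and the clean percentage (2 decimals, half-up).

    ``raw`` maps library id to either an iterable of read sequences or an
    already-collapsed ``{sequence: count}`` mapping.
    """
    if not raw:
        raise ValueError("at least one library is required")

    libs = list(raw)
    maps = {}
    report_rows = []
    per_lib_invalid: dict[str, int] = {}
    per_lib_short: dict[str, int] = {}
    for lib in libs:
        cm = _to_count_map(raw[lib])
        kept: dict[str, int] = {}
        n_invalid = 0
        n_short = 0
        for seq, c in cm.items():
            s = to_rna(seq)
            if not is_nucleotide(s):
                n_invalid += c
                continue
            if len(s) < min_len:
                n_short += c
                continue
            kept[s] = kept.get(s, 0) + c
        maps[lib] = kept
        per_lib_invalid[lib] = n_invalid
        per_lib_short[lib] = n_short

    all_seqs = sorted(set().union(*(m.keys() for m in maps.values())))
    counts = pd.DataFrame(
        {lib: [maps[lib].get(s, 0) for s in all_seqs] for lib in libs},
        index=pd.Index(all_seqs, name="sequence"),
        dtype=np.int64,
    )

    n_singleton = {lib: 0 for lib in libs}
    if singleton_rule and len(counts):
        is_singleton = counts.sum(axis=1) == 1
        if is_singleton.any():
            removed = counts.loc[is_singleton]
            for lib in libs:
                n_singleton[lib] = int(removed[lib].sum())
            counts = counts.loc[~is_singleton]

    for lib in libs:
        raw_n = sum(_to_count_map(raw[lib]).values())
        clean_n = int(counts[lib].sum()) if len(counts) else 0
        pct = round_half_up(100.0 * clean_n / raw_n, 2) if raw_n else 0.0
        report_rows.append((lib, raw_n, clean_n, pct, per_lib_short[lib],
                            n_singleton[lib], per_lib_invalid[lib]))

    report = pd.DataFrame(
        report_rows,
        columns=["library", "raw_reads", "clean_reads", "pct_clean",
                 "dropped_short", "dropped_singleton", "dropped_invalid"],
    )
    return UniqueReadTable(counts), report


def clean_percentage(raw_reads: int, clean_reads: int) -> float:
    """Clean reads as a percent of raw reads, 2 decimals half-up."""
    return round_half_up(100.0 * clean_reads / raw_reads, 2) if raw_reads else 0.0


def comparison_from_counts(
    lib_a: str,
    lib_b: str,
    shared_unique: int,
    specific_unique: Mapping[str, int],
    shared_total: Mapping[str, int],
    specific_total: Mapping[str, int],
) -> LibraryComparison:
    """Comparison statistics from aggregate partition counts.

    The arithmetic core of :func:`compare_libraries`; useful on its own when
    only the published aggregate counts of two libraries are available.
    Unique percentages are taken over the unique-sequence union, total
    percentages over the grand total reads of both libraries, and mean
    frequencies are reads per unique sequence (per library for the shared
    partition).
    """
    union = shared_unique + specific_unique[lib_a] + specific_unique[lib_b]
    grand_total = (sum(shared_total.values())
                   + specific_total[lib_a] + specific_total[lib_b])

    def pct(x: int, denom: int) -> float:
        return round_half_up(100.0 * x / denom, 2) if denom else 0.0

    mean_shared = (sum(shared_total.values()) / 2 / shared_unique) if shared_unique else 0.0
    mean_spec = {
        lib: (specific_total[lib] / specific_unique[lib]) if specific_unique[lib] else 0.0
        for lib in (lib_a, lib_b)
    }
    return LibraryComparison(
        libraries=(lib_a, lib_b),
        shared_unique=shared_unique,
        specific_unique=dict(specific_unique),
        shared_total=dict(shared_total),
        specific_total=dict(specific_total),
        pct_shared_unique=pct(shared_unique, union),
        pct_specific_unique={lib: pct(specific_unique[lib], union) for lib in (lib_a, lib_b)},
        pct_shared_total=pct(sum(shared_total.values()), grand_total),
        pct_specific_total={lib: pct(specific_total[lib], grand_total) for lib in (lib_a, lib_b)},
        mean_freq_shared=round_half_up(mean_shared, 2),
        mean_freq_specific={lib: round_half_up(v, 2) for lib, v in mean_spec.items()},
    )


def compare_libraries(table: UniqueReadTable, lib_a: str, lib_b: str) -> LibraryComparison:
    """Partition unique sequences of two libraries into shared and specific."""
    for lib in (lib_a, lib_b):
        if lib not in table.counts.columns:
            raise KeyError(f"unknown library id {lib!r}")
    a = table.counts[lib_a]
    b = table.counts[lib_b]
    in_a = a > 0
    in_b = b > 0
    shared = in_a & in_b
    return comparison_from_counts(
        lib_a, lib_b,
        shared_unique=int(shared.sum()),
        specific_unique={lib_a: int((in_a & ~in_b).sum()),
                         lib_b: int((in_b & ~in_a).sum())},
        shared_total={lib_a: int(a[shared].sum()), lib_b: int(b[shared].sum())},
        specific_total={lib_a: int(a[in_a & ~in_b].sum()),
                        lib_b: int(b[in_b & ~in_a].sum())},
    )


def length_distribution(table: UniqueReadTable, library: str,
                        lengths: Sequence[int] = tuple(LENGTH_RANGE)) -> pd.DataFrame:
    """Per-length unique/total counts and fractions for one library."""
    if library not in table.counts.columns:
        raise KeyError(f"unknown library id {library!r}")
    col = table.counts[library]
    col = col[col > 0]
    seq_len = col.index.str.len()
    rows = []
    total_unique = len(col)
    total_reads = int(col.sum())
    for n in lengths:
        mask = seq_len == n
        u = int(mask.sum())
        t = int(col[mask].sum())
        rows.append((n, u, t,
                     u / total_unique if total_unique else 0.0,
                     t / total_reads if total_reads else 0.0))
    return pd.DataFrame(
        rows, columns=["length", "unique_count", "total_count",
                       "unique_fraction", "total_fraction"],
    )


ANNOTATION_PRIORITY = ("tRNA", "rRNA", "snRNA", "snoRNA", "mRNA")


def annotate_reads(
    table: UniqueReadTable,
    annotations: Mapping[str, Iterable[str]],
    priority: Sequence[str] = ANNOTATION_PRIORITY,
) -> tuple[pd.DataFrame, UniqueReadTable]:
    """Assign each unique read to the first annotation class containing it.

    Membership is exact substring containment in any sequence of the class
    (both in RNA space); reads matching no class fall into ``others`` and are
    returned as the residual table that feeds miRNA discovery.
    """
    if not any(list(annotations.get(c, [])) for c in priority):
        warnings.warn("empty annotation: all reads classed as 'others'")

    # one concatenated haystack per class; '#' separators prevent junction hits
    haystacks = {}
    for cls in priority:
        seqs = [to_rna(s) for s in annotations.get(cls, [])]
        haystacks[cls] = "#".join(seqs) if seqs else ""

    assigned: dict[str, str] = {}
    for seq in table.sequences():
        cls_hit = "others"
        for cls in priority:
            hs = haystacks[cls]
            if hs and seq in hs:
                cls_hit = cls
                break
        assigned[seq] = cls_hit

    classes = list(priority) + ["others"]
    rows = []
    assigned_s = pd.Series(assigned)
    for lib in table.library_ids:
        col = table.counts[lib]
        present = col > 0
        tot_u = int(present.sum())
        tot_t = int(col.sum())
        for cls in classes:
            mask = (assigned_s == cls) & present
            u = int(mask.sum())
            t = int(col[mask.index[mask]].sum())
            rows.append((lib, cls, u, t,
                         u / tot_u if tot_u else 0.0,
                         t / tot_t if tot_t else 0.0))
    breakdown = pd.DataFrame(
        rows, columns=["library", "class", "unique_count", "total_count",
                       "unique_fraction", "total_fraction"],
    )
    residual_seqs = [s for s, c in assigned.items() if c == "others"]
    residual = UniqueReadTable(table.counts.loc[residual_seqs])
    return breakdown, residual


def tpm_normalize(table: UniqueReadTable,
                  totals: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Transcripts-per-million per entry per library.

    TPM = count / library_total x 1e6. The denominator defaults to the table's
    own per-library totals; pass ``totals`` (e.g. clean-read totals of the full
    libraries) to normalize a residual subset against the whole library.
    """
    denom = pd.Series(totals) if totals is not None else table.totals
    for lib in table.library_ids:
        if lib not in denom or denom[lib] <= 0:
            raise ValueError(f"library {lib!r} has zero total; cannot normalize")
    return table.counts / denom[table.library_ids] * 1e6
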