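"""Quality/length filtering, duplicate collapse, dataset merging and
per-chromosome counting of aligned reads.

The filter chain mirrors standard ancient-DNA practice: discard mapped reads
below a mapping-quality floor (default Q30), drop fragments at or below
35 bp (spurious short alignments) and above 70 bp, collapse PCR/optical
duplicates to unique molecules, and tabulate unique reads per chromosome for
the sexing statistics.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import normalize_chrom
from .reads import AlignedRead

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Read-retention thresholds.

    min_len/max_len are inclusive bounds on fragment length; the defaults
    keep 36–70 bp, i.e. remove reads <= 35 bp and > 70 bp.  min_mapq is the
    minimum retained mapping quality (reads with Q < 30 removed by default).
    """

    min_mapq: int = 30
    min_len: int = 36
    max_len: int = 70

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclasses.dataclass
class FilterStats:
    """Removal counts per criterion (a read failing several is counted once,
    in the order mapq, too-short, too-long)."""

    n_input: int = 0
    removed_mapq: int = 0
    removed_short: int = 0
    removed_long: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.removed_mapq - self.removed_short - self.removed_long


def filter_reads(
    reads: Iterable[AlignedRead], cfg: FilterConfig = FilterConfig()
) -> tuple[list[AlignedRead], FilterStats]:
    """Apply mapping-quality and length filters, preserving input order."""
    stats = FilterStats()
    kept: list[AlignedRead] = []
    for r in reads:
        stats.n_input += 1
        if r.mapq < cfg.min_mapq:
            stats.removed_mapq += 1
        elif r.length < cfg.min_len:
            stats.removed_short += 1
        elif r.length > cfg.max_len:
            stats.removed_long += 1
        else:
            kept.append(r)
    log.info("filter_reads: kept %d of %d (mapq %d, short %d, long %d removed)",
             stats.n_retained, stats.n_input, stats.removed_mapq,
             stats.removed_short, stats.removed_long)
    return kept, stats


def remove_duplicates(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Collapse duplicate molecules to one representative per key.

    The key is (chromosome, strand, 5'-most reference coordinate of the
    molecule, fragment length) — alignment start for plus-strand reads and
    alignment end for minus strand, emulating coordinate-based duplicate
    marking.  The representative is the read with highest mapping quality,
    ties broken by lexicographically smallest read_id; output order follows
    the first occurrence of each key, so the operation is idempotent and
    order-invariant as a set.
    """
    best: dict[tuple, tuple[int, AlignedRead]] = {}
    order: list[tuple] = []
    for idx, r in enumerate(reads):
        key = r.duplicate_key()
        if key not in best:
            best[key] = (idx, r)
            order.append(key)
        else:
            _, cur = best[key]
            if (r.mapq, _neg_id(r.read_id)) > (cur.mapq, _neg_id(cur.read_id)):
                best[key] = (best[key][0], r)
    return [best[k][1] for k in order]


class _neg_id(str):
    """Reverses string comparison so max() picks the lexicographically
    smallest read_id on mapq ties."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def _naming_style(chroms: set[str]) -> str | None:
    if not chroms:
        return None
    prefixed = {c.lower().startswith("chr") for c in chroms}
    if prefixed == {True}:
        return "chr"
    if prefixed == {False}:
        return "bare"
    return "mixed"


def merge_datasets(datasets: Sequence[Iterable[AlignedRead]]) -> list[AlignedRead]:
    """Concatenate read sets and collapse duplicates across them.

    Datasets must share a reference naming convention ('chr'-prefixed vs
    bare); mixing the two is almost certainly an accounting error and is
    rejected.
    """
    pooled: list[AlignedRead] = []
    styles: set[str] = set()
    for ds in datasets:
        ds = list(ds)
        style = _naming_style({r.chrom for r in ds})
        if style is not None:
            styles.add(style)
        pooled.extend(ds)
    if len(styles) > 1 or "mixed" in styles:
        raise ValueError(
            f"incompatible reference naming across datasets: {sorted(styles)}"
        )
    return remove_duplicates(pooled)


@dataclasses.dataclass
class ChromCountTable:
    """Unique-read counts per chromosome plus chromosome lengths (bp).

    Keys are canonical chromosome names ('1'..'22', 'X', 'Y', 'MT').  Every
    chromosome present in ``lengths`` appears in ``counts`` (zero-filled).
    """

    counts: dict[str, int]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if any(v <= 0 for v in self.lengths.values()):
            raise ValueError("lengths must be > 0")
        for chrom in self.lengths:
            self.counts.setdefault(chrom, 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "ChromCountTable") -> "ChromCountTable":
        """Per-chromosome sum of two tables (same lengths required)."""
        for c in set(self.lengths) & set(other.lengths):
            if self.lengths[c] != other.lengths[c]:
                raise ValueError(f"length mismatch for chromosome {c}")
        lengths = {**self.lengths, **other.lengths}
        counts = {c: self.counts.get(c, 0) + other.counts.get(c, 0)
                  for c in set(self.counts) | set(other.counts)}
        return ChromCountTable(counts=counts, lengths=lengths)

    def to_frame(self) -> pd.DataFrame:
        chroms = sorted(self.counts, key=_chrom_sort_key)
        return pd.DataFrame({
            "chrom": chroms,
            "count": [self.counts[c] for c in chroms],
            "length": [self.lengths.get(c, 0) for c in chroms],
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        counts = {normalize_chrom(r.chrom): int(r.count) for r in df.itertuples()}
        lengths = {normalize_chrom(r.chrom): int(r.length) for r in df.itertuples()
                   if r.length > 0}
        return cls(counts=counts, lengths=lengths)


def _chrom_sort_key(name: str):
    key = normalize_chrom(name)
    return (0, int(key)) if key.isdigit() else (1, key)


def count_by_chromosome(
    reads: Iterable[AlignedRead], lengths: Mapping[str, int]
) -> ChromCountTable:
    """Tabulate reads per chromosome; every chromosome in ``lengths`` is
    present (count 0 when unobserved).  A read on a chromosome without a
    length entry is an error."""
    norm_lengths = {normalize_chrom(k): int(v) for k, v in lengths.items()}
    counts = {c: 0 for c in norm_lengths}
    for r in reads:
        key = normalize_chrom(r.chrom)
        if key not in norm_lengths:
            raise KeyError(f"no length entry for chromosome {r.chrom!r}")
        counts[key] += 1
    return ChromCountTable(counts=counts, lengths=norm_lengths)
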