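"""Read-level quality control for shallow cfDNA sequencing.

Filters are applied in a fixed order:

1. 3' quality trimming — trailing bases with Phred quality <= threshold
   (default 15) are removed, i.e. the retained prefix ends on a base with
   quality strictly above the threshold;
2. length filter — trimmed reads shorter than 50 bp are removed (a read of
   exactly 50 bp is retained);
3. GC filter — reads whose G+C fraction over the retained bases falls outside
   the inclusive band [0.35, 0.45] are removed; ambiguous bases (N) count as
   non-GC;
4. unique-mapping selection — by default an alignment counts as unique when it
   is mapped, primary (not secondary/supplementary) and has mapping quality
   > 0; the predicate is configurable because "uniquely mapped" has no single
   aligner-independent definition;
5. duplicate removal — at most one alignment is retained per
   (chromosome, 0-based 5' start, strand); single-end positional dedup.

The trimming rule is a simple trailing-run rule, not a windowed (Mott-style)
algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import pandas as pd
import pysam

__all__ = [
    "QCConfig",
    "SequencedRead",
    "AlignedRead",
    "QCReport",
    "trim_3prime",
    "passes_length",
    "passes_gc",
    "gc_fraction",
    "remove_duplicates",
    "is_uniquely_mapped",
    "default_unique_rule",
    "read_fastq",
    "read_sam",
    "read_truth_alignments",
    "qc_reads",
    "run_qc",
]

logger = logging.getLogger(__name__)

_GC_BASES = frozenset("GCgc")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class SequencedRead:
    """A read with per-base Phred qualities (lengths always match)."""

    id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"{self.id}: {len(self.bases)} bases vs {len(self.qualities)} qualities")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignedRead:
    """Minimal single-end alignment record used by binning and dedup."""

    read_id: str
    chromosome: str
    start: int  # 0-based leftmost reference position
    strand: str  # "+" or "-"
    mapq: int = 60
    flags: int = 0
    length: int = 0
    gc: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.read_id}: negative start {self.start}")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.read_id}: gc {self.gc} outside [0, 1]")


def default_unique_rule(aln: AlignedRead) -> bool:
    """Mapped, primary (not secondary/supplementary), mapping quality > 0."""
    if aln.flags & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
        return False
    return aln.mapq > 0


@dataclass
class QCConfig:
    """Thresholds of the read-level filters; defaults are the screening values."""

    quality_threshold: int = 15
    min_length: int = 50
    gc_min: float = 0.35
    gc_max: float = 0.45
    unique_rule: Callable[[AlignedRead], bool] = field(default=default_unique_rule)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_min <= self.gc_max <= 1.0:
            raise ValueError(f"need 0 <= gc_min <= gc_max <= 1, got [{self.gc_min}, {self.gc_max}]")
        if self.min_length < 1:
            raise ValueError(f"min_length must be >= 1, got {self.min_length}")
        if self.quality_threshold < 0:
            raise ValueError(f"quality_threshold must be >= 0, got {self.quality_threshold}")


@dataclass
class QCReport:
    """Per-filter attrition counts, in pipeline order."""

    n_input: int = 0
    n_after_trim_length: int = 0
    n_after_gc: int = 0
    n_after_unique: int = 0
    n_after_dedup: int = 0

    def to_frame(self) -> pd.DataFrame:
        stages = [
            ("input", self.n_input),
            ("trim+length", self.n_after_trim_length),
            ("gc", self.n_after_gc),
            ("unique", self.n_after_unique),
            ("dedup", self.n_after_dedup),
        ]
        rows = []
        prev = self.n_input
        for name, retained in stages:
            rows.append((name, retained, prev - retained))
            prev = retained
        return pd.DataFrame(rows, columns=["stage", "retained", "removed"])


# -- read-level predicates ------------------------------------------------


def trim_3prime(read: SequencedRead, quality_threshold: int = 15) -> SequencedRead:
    """Drop trailing bases until the final base has quality > threshold.

    May return an empty read when every base from some point on (or the whole
    read) sits at or below the threshold.
    """
    end = len(read)
    while end > 0 and read.qualities[end - 1] <= quality_threshold:
        end -= 1
    if end == len(read):
        return read
    return SequencedRead(read.id, read.bases[:end], read.qualities[:end])


def passes_length(read: SequencedRead, min_length: int = 50) -> bool:
    """True iff the (trimmed) read is at least ``min_length`` bp."""
    return len(read) >= min_length


def gc_fraction(bases: str) -> float:
    if not bases:
        raise ValueError("GC fraction of an empty read is undefined")
    return sum(b in _GC_BASES for b in bases) / len(bases)


def passes_gc(read: SequencedRead, gc_min: float = 0.35, gc_max: float = 0.45) -> bool:
    """True iff the read's G+C fraction lies in the inclusive band [gc_min, gc_max]."""
    return gc_min <= gc_fraction(read.bases) <= gc_max


def is_uniquely_mapped(
    aln: AlignedRead, unique_rule: Callable[[AlignedRead], bool] = default_unique_rule
) -> bool:
    return unique_rule(aln)


def remove_duplicates(alignments: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Keep one alignment per (chromosome, start, strand).

    Candidates sharing a key are ordered by read id (stable sort), and the
    first is kept, so the output is deterministic regardless of input order.
    Idempotent; never increases the count.
    """
    ordered = sorted(
        alignments, key=lambda a: (a.chromosome, a.start, a.strand, a.read_id)
    )
    seen: set[tuple[str, int, str]] = set()
    out: list[AlignedRead] = []
    for aln in ordered:
        key = (aln.chromosome, aln.start, aln.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(aln)
    return out


# -- input parsing --------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[SequencedRead]:
    """Parse a Phred+33 FASTQ file (plain or gzip) into SequencedReads."""
    with pysam.FastxFile(str(path)) as handle:
        for entry in handle:
            quals = entry.get_quality_array()
            if quals is None:
                raise ValueError(f"{path}: record {entry.name} has no qualities")
            yield SequencedRead(entry.name, entry.sequence, tuple(quals))


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Parse SAM/BAM alignments into AlignedReads (POS converted to 0-based).

    Unmapped records are yielded with their flag set so the uniqueness
    predicate can reject them; GC and length are derived from SEQ when
    present.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for rec in handle:
            seq = rec.query_sequence or ""
            yield AlignedRead(
                read_id=rec.query_name or "",
                chromosome=rec.reference_name or "*",
                start=max(rec.reference_start, 0),
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                flags=rec.flag,
                length=len(seq),
                gc=gc_fraction(seq) if seq else 0.0,
            )


def read_truth_alignments(path: str | Path) -> pd.DataFrame:
    """Read the generator's truth TSV (sample, read_id, chrom, start0, strand, unique)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "read_id", "chrom", "start0", "strand", "unique"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: truth TSV needs columns {sorted(required)}")
    return frame


# -- pipeline -------------------------------------------------------------


def qc_reads(
    reads: Iterable[SequencedRead], config: QCConfig | None = None
) -> tuple[set[str], QCReport]:
    """Apply trim -> length -> GC to raw reads; return surviving read ids."""
    config = config or QCConfig()
    report = QCReport()
    after_gc: set[str] = set()
    for read in reads:
        report.n_input += 1
        trimmed = trim_3prime(read, config.quality_threshold)
        if not passes_length(trimmed, config.min_length):
            continue
        report.n_after_trim_length += 1
        if not passes_gc(trimmed, config.gc_min, config.gc_max):
            continue
        report.n_after_gc += 1
        after_gc.add(read.id)
    return after_gc, report


def run_qc(
    reads: Iterable[SequencedRead],
    alignments: Iterable[AlignedRead],
    config: QCConfig | None = None,
) -> tuple[list[AlignedRead], QCReport]:
    """Full QC: read filters, then unique-mapping selection and dedup.

    ``alignments`` are joined to the surviving reads by read id; alignments of
    reads that failed a read-level filter are dropped.
    """
    config = config or QCConfig()
    surviving_ids, report = qc_reads(reads, config)
    unique = [
        a
        for a in alignments
        if a.read_id in surviving_ids and is_uniquely_mapped(a, config.unique_rule)
    ]
    report.n_after_unique = len(unique)
    deduped = remove_duplicates(unique)
    report.n_after_dedup = len(deduped)
    logger.info(
        "QC: %d reads in, %d after trim+length, %d after GC, %d unique, %d after dedup",
        report.n_input,
        report.n_after_trim_length,
        report.n_after_gc,
        report.n_after_unique,
        report.n_after_dedup,
    )
    return deduped, report
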