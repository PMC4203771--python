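"""Genomic coordinate system: chromosomes, lengths, and a fixed-width bin grid.

Every counting stage of the pipeline shares one :class:`GenomeLayout`.
Coordinates are 0-based and bins are half-open intervals
``[i * bin_size, (i + 1) * bin_size)``; SAM input (1-based) is converted once,
at parse time.  Reads are assigned to exactly one bin by their leftmost
(5'-most) mapped position — the standard convention for count-based cfDNA
aneuploidy screening, where reads are counted, not base coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomeLayout",
    "LayoutError",
    "CoordinateError",
    "make_layout",
    "assign_bin",
    "read_layout_tsv",
    "hg19_layout",
]

DEFAULT_BIN_SIZE = 300_000

#: Chromosome names treated as sex chromosomes when none are given explicitly.
_SEX_NAMES = {"chrX", "chrY", "X", "Y"}


class LayoutError(ValueError):
    """Invalid layout definition (duplicate name, non-positive length, ...)."""


class CoordinateError(ValueError):
    """Position or chromosome outside the layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths plus a fixed bin width.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in base pairs (default 300 kb).
    autosome_names, sex_chromosome_names
        Disjoint partition of the chromosome names.  Autosomes form the
        denominator of fraction-mode chromosome representation downstream.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = DEFAULT_BIN_SIZE
    autosome_names: frozenset[str] = field(default_factory=frozenset)
    sex_chromosome_names: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise LayoutError(f"bin_size must be positive, got {self.bin_size}")
        names = [name for name, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise LayoutError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise LayoutError(f"chromosome {name!r} has non-positive length {length}")
        if self.autosome_names & self.sex_chromosome_names:
            raise LayoutError("autosome and sex chromosome sets overlap")
        if self.autosome_names | self.sex_chromosome_names != set(names):
            raise LayoutError("autosome + sex chromosome names must cover all chromosomes")

    # -- derived views ----------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        """Number of bins on ``chrom``; the last bin may be partial."""
        return math.ceil(self.length(chrom) / self.bin_size)

    def bin_width(self, chrom: str, bin_index: int) -> int:
        """Width in bp of one bin (the final bin may be shorter)."""
        n = self.n_bins(chrom)
        if not 0 <= bin_index < n:
            raise CoordinateError(f"bin {bin_index} out of range for {chrom!r} ({n} bins)")
        if bin_index < n - 1:
            return self.bin_size
        return self.length(chrom) - (n - 1) * self.bin_size

    def assign_bin(self, chrom: str, position: int) -> int:
        """Map a 0-based position to its bin index (half-open bins)."""
        length = self.length(chrom)
        if not 0 <= position < length:
            raise CoordinateError(
                f"position {position} outside [0, {length}) on {chrom!r}"
            )
        return position // self.bin_size


def make_layout(
    spec: Sequence[tuple[str, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
    sex_chromosome_names: Iterable[str] | None = None,
) -> GenomeLayout:
    """Build a :class:`GenomeLayout` from ``(name, length)`` pairs.

    When ``sex_chromosome_names`` is omitted, names matching chrX/chrY/X/Y
    are treated as sex chromosomes and everything else as autosomal.
    """
    names = [name for name, _ in spec]
    if sex_chromosome_names is None:
        sex = frozenset(n for n in names if n in _SEX_NAMES)
    else:
        sex = frozenset(sex_chromosome_names)
        unknown = sex - set(names)
        if unknown:
            raise LayoutError(f"sex chromosomes not in layout: {sorted(unknown)}")
    auto = frozenset(names) - sex
    return GenomeLayout(
        chromosomes=tuple((str(n), int(l)) for n, l in spec),
        bin_size=int(bin_size),
        autosome_names=auto,
        sex_chromosome_names=sex,
    )


def assign_bin(chrom: str, position: int, layout: GenomeLayout) -> int:
    """Functional form of :meth:`GenomeLayout.assign_bin`."""
    return layout.assign_bin(chrom, position)


def read_layout_tsv(path: str | Path, bin_size: int = DEFAULT_BIN_SIZE) -> GenomeLayout:
    """Read a 2-column (chrom, length) TSV; a header line is detected and skipped."""
    pairs: list[tuple[str, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise LayoutError(f"{path}:{lineno + 1}: expected 2 columns")
            try:
                length = int(fields[1])
            except ValueError:
                if lineno == 0:  # header row
                    continue
                raise LayoutError(f"{path}:{lineno + 1}: non-integer length {fields[1]!r}")
            pairs.append((fields[0], length))
    if not pairs:
        raise LayoutError(f"{path}: no chromosomes found")
    return make_layout(pairs, bin_size=bin_size)


def hg19_layout(bin_size: int = DEFAULT_BIN_SIZE) -> GenomeLayout:
    """The shipped hg19 layout: chr1-chr22, chrX, chrY (no alt/unplaced contigs)."""
    ref = resources.files("cfnipt.data").joinpath("hg19_chrom_lengths.tsv")
    with resources.as_file(ref) as path:
        return read_layout_tsv(path, bin_size=bin_size)
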