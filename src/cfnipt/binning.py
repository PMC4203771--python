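"""Per-bin and per-chromosome read counting.

QC-passed alignments are tallied into the shared 300 kb bin grid; chromosome
totals derived from the bins form the per-sample representation statistic fed
to the z-score.  Two representation modes exist:

``count``
    raw mapped-read count per chromosome — the statistic exactly as it enters
    the screening z-score formula, but sensitive to per-sample depth;
``fraction``
    chromosome count divided by the total autosomal count, which removes the
    depth nuisance and is the default.  Sex chromosomes are excluded from the
    denominator because fetal sex shifts chrX/chrY totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .genome_layout import GenomeLayout

__all__ = [
    "BinCounts",
    "SampleProfile",
    "count_bins",
    "profile_from_counts",
    "write_bin_counts_tsv",
    "read_bin_counts_tsv",
    "write_profiles_tsv",
]

logger = logging.getLogger(__name__)

RepresentationMode = Literal["count", "fraction"]


@dataclass
class BinCounts:
    """Read counts per (chromosome, bin) for one sample."""

    sample_id: str
    layout: GenomeLayout
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.layout.names:
            arr = self.counts.get(chrom)
            n = self.layout.n_bins(chrom)
            if arr is None:
                self.counts[chrom] = np.zeros(n, dtype=np.int64)
            else:
                arr = np.asarray(arr, dtype=np.int64)
                if arr.shape != (n,):
                    raise ValueError(
                        f"{self.sample_id}: {chrom} expects {n} bins, got {arr.shape}"
                    )
                if (arr < 0).any():
                    raise ValueError(f"{self.sample_id}: negative bin count on {chrom}")
                self.counts[chrom] = arr

    @property
    def total_retained(self) -> int:
        return int(sum(int(a.sum()) for a in self.counts.values()))

    def chrom_total(self, chrom: str) -> int:
        return int(self.counts[chrom].sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.sample_id, chrom, i, int(c))
            for chrom in self.layout.names
            for i, c in enumerate(self.counts[chrom])
        ]
        return pd.DataFrame(rows, columns=["sample", "chrom", "bin_index", "count"])


@dataclass(frozen=True)
class SampleProfile:
    """Per-chromosome representation statistic for one sample.

    ``counts`` are raw per-chromosome mapped-read totals; ``fractions`` divide
    each by the autosomal total.  ``statistic`` returns whichever the recorded
    mode selects.
    """

    sample_id: str
    counts: dict[str, int]
    fractions: dict[str, float]
    mode: RepresentationMode
    total_retained: int

    def statistic(self, chrom: str) -> float:
        if self.mode == "count":
            return float(self.counts[chrom])
        return self.fractions[chrom]


def count_bins(
    alignments: Iterable,
    layout: GenomeLayout,
    sample_id: str = "sample",
) -> BinCounts:
    """Tally alignments into bins by 5' start position.

    Each alignment increments exactly one bin.  Alignments on chromosomes
    absent from the layout are skipped and counted in the log.  Input is
    expected to be deduplicated and uniquely mapped already.
    """
    counts = {chrom: np.zeros(layout.n_bins(chrom), dtype=np.int64) for chrom in layout.names}
    skipped = 0
    for aln in alignments:
        chrom = aln.chromosome
        if chrom not in counts:
            skipped += 1
            continue
        counts[chrom][layout.assign_bin(chrom, aln.start)] += 1
    if skipped:
        logger.warning("count_bins: skipped %d alignments on chromosomes outside layout", skipped)
    return BinCounts(sample_id=sample_id, layout=layout, counts=counts)


def profile_from_counts(
    bins: BinCounts,
    layout: GenomeLayout,
    mode: RepresentationMode = "fraction",
) -> SampleProfile:
    """Collapse bin counts to the per-chromosome representation statistic."""
    if mode not in ("count", "fraction"):
        raise ValueError(f"unknown representation mode {mode!r}")
    counts = {chrom: bins.chrom_total(chrom) for chrom in layout.names}
    autosomal_total = sum(counts[c] for c in layout.names if c in layout.autosome_names)
    if mode == "fraction" and autosomal_total == 0:
        raise ValueError(f"{bins.sample_id}: zero autosomal total; fraction mode undefined")
    if autosomal_total > 0:
        fractions = {c: counts[c] / autosomal_total for c in layout.names}
    else:
        fractions = {c: float("nan") for c in layout.names}
    return SampleProfile(
        sample_id=bins.sample_id,
        counts=counts,
        fractions=fractions,
        mode=mode,
        total_retained=bins.total_retained,
    )


# -- TSV interfaces -------------------------------------------------------


def write_bin_counts_tsv(
    samples: Iterable[BinCounts], path: str | Path, seed: int | None = None
) -> None:
    frame = pd.concat([s.to_frame() for s in samples], ignore_index=True)
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_bin_counts_tsv(path: str | Path, layout: GenomeLayout) -> list[BinCounts]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "chrom", "bin_index", "count"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: bin-count TSV needs columns {sorted(required)}")
    out: list[BinCounts] = []
    for sample_id, group in frame.groupby("sample", sort=False):
        counts = {c: np.zeros(layout.n_bins(c), dtype=np.int64) for c in layout.names}
        for chrom, sub in group.groupby("chrom", sort=False):
            if chrom not in counts:
                logger.warning("%s: chromosome %s not in layout, skipped", path, chrom)
                continue
            counts[chrom][sub["bin_index"].to_numpy()] += sub["count"].to_numpy()
        out.append(BinCounts(sample_id=str(sample_id), layout=layout, counts=counts))
    return out


def write_profiles_tsv(
    profiles: Iterable[SampleProfile], path: str | Path, seed: int | None = None
) -> None:
    rows = [
        (p.sample_id, chrom, p.counts[chrom], p.fractions[chrom], p.mode)
        for p in profiles
        for chrom in p.counts
    ]
    frame = pd.DataFrame(rows, columns=["sample", "chrom", "count", "fraction", "mode"])
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        frame.to_csv(handle, sep="\t", index=False)
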