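"""Synthetic maternal-plasma sequencing cohorts.

The generator emulates the statistical structure that chromosome-dosage
screening assumes, so that every downstream stage — read QC, binning,
z-scores, cutoff selection, evaluation — is testable without any external
download.

Dosage model
------------
Maternal plasma cfDNA is a mixture of maternal (euploid) and fetal fragments.
With fetal fraction f, a fetal trisomy of chromosome t contributes three
chromosome-t copies instead of two, so chromosome t's weight in the mixture
is multiplied by (1 + f/2) before renormalization; all other chromosomes keep
their baseline weight (proportional to chromosome length, optionally modulated
by per-bin GC weights).  This is the standard cfDNA dosage model — a modelling
choice of this package, stated here because the screening analysis it feeds
never needs to articulate it.

Two simulation paths exist:

* :func:`simulate_bin_counts` draws retained-read bin counts directly from a
  multinomial — the primary, fast path for testing the z-score stage at any
  depth;
* :func:`simulate_reads` emits small read-level cohorts (FASTQ + truth
  alignment table) with 3'-decaying qualities, per-read GC targets, exact
  positional duplicates and a non-unique mapping share, to exercise the QC
  stage end-to-end.

Identical config + seed reproduces identical output, bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binning import BinCounts
from .genome_layout import GenomeLayout
from .read_qc import AlignedRead

__all__ = [
    "QualityDecay",
    "SimulationConfig",
    "TruthLabel",
    "SimulatedRead",
    "expected_chrom_proportions",
    "simulate_bin_counts",
    "simulate_reads",
    "truth_to_alignments",
    "write_fastq",
    "write_truth_tsv",
    "write_labels_tsv",
    "read_labels_tsv",
]

logger = logging.getLogger(__name__)

KARYOTYPES = ("euploid", "T18", "T21")
DEFAULT_TRISOMY_MAP = {"T18": "chr18", "T21": "chr21"}


@dataclass(frozen=True)
class QualityDecay:
    """Per-base Phred profile: a plateau with a linear 3' ramp.

    Bases before the final ``tail`` positions sit at ``start``; the last
    ``tail`` bases ramp linearly from ``start`` down to ``end`` (the final
    base has quality ``end``).
    """

    start: int = 36
    end: int = 8
    tail: int = 12

    def qualities(self, length: int) -> np.ndarray:
        if length <= 0:
            return np.zeros(0, dtype=np.int64)
        q = np.full(length, self.start, dtype=float)
        tail = min(self.tail, length)
        if tail > 0:
            q[length - tail :] = np.linspace(self.start, self.end, tail + 1)[1:]
        return np.clip(np.rint(q), 2, 41).astype(np.int64)


@dataclass(frozen=True)
class TruthLabel:
    """Ground truth for one simulated sample."""

    sample_id: str
    karyotype: str
    fetal_fraction: float

    def __post_init__(self) -> None:
        if self.karyotype not in KARYOTYPES:
            raise ValueError(f"unknown karyotype {self.karyotype!r}")


@dataclass(frozen=True)
class SimulatedRead:
    sample_id: str
    read_id: str
    bases: str
    qualities: tuple[int, ...]
    chrom: str
    start0: int
    strand: str
    unique: bool


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort and sequencing parameters of the generator.

    Defaults mirror the screening study design this package targets: a
    155-sample high-risk cohort of 139 euploid, 5 trisomy-18 and 11
    trisomy-21 pregnancies, ~6.5 million raw reads per sample of which 59%
    map uniquely, cfDNA fragments of ~150 bp and a mean fetal fraction of
    10% with substantial inter-individual spread.
    """

    n_euploid: int = 139
    n_t18: int = 5
    n_t21: int = 11
    reads_per_sample: int = 6_500_000
    unique_map_rate: float = 0.59
    fetal_fraction_mean: float = 0.10
    fetal_fraction_sd: float = 0.02
    fetal_fraction_min: float = 0.001
    fetal_fraction_max: float = 0.999
    read_length_mean: float = 150.0
    read_length_sd: float = 15.0
    duplicate_rate: float = 0.05
    read_gc_mean: float = 0.41
    read_gc_sd: float = 0.03
    quality_decay: QualityDecay = field(default_factory=QualityDecay)
    gc_bias: dict[str, np.ndarray] | None = None
    trisomy_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TRISOMY_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_euploid", "n_t18", "n_t21", "reads_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("unique_map_rate", "duplicate_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.fetal_fraction_min <= self.fetal_fraction_max < 1.0:
            raise ValueError("fetal fraction truncation bounds must satisfy 0 < min <= max < 1")
        if not 0.0 <= self.fetal_fraction_mean <= 1.0:
            raise ValueError("fetal_fraction_mean must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_euploid + self.n_t18 + self.n_t21

    def karyotypes(self) -> list[str]:
        return (
            ["euploid"] * self.n_euploid + ["T18"] * self.n_t18 + ["T21"] * self.n_t21
        )


# -- dosage model ---------------------------------------------------------


def _bin_weights(layout: GenomeLayout, gc_bias: dict[str, np.ndarray] | None) -> dict[str, np.ndarray]:
    """Baseline per-bin weights: bin width, optionally GC-modulated."""
    weights: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        w = np.array(
            [layout.bin_width(chrom, i) for i in range(layout.n_bins(chrom))], dtype=float
        )
        if gc_bias is not None and chrom in gc_bias:
            g = np.asarray(gc_bias[chrom], dtype=float)
            if g.shape != w.shape:
                raise ValueError(f"gc_bias for {chrom} has wrong number of bins")
            if (g < 0).any():
                raise ValueError(f"gc_bias for {chrom} has negative weights")
            w = w * g
        weights[chrom] = w
    return weights


def _trisomic_chrom(karyotype: str, trisomy_map: dict[str, str]) -> str | None:
    if karyotype == "euploid":
        return None
    try:
        return trisomy_map[karyotype]
    except KeyError:
        raise ValueError(f"unknown karyotype {karyotype!r}") from None


def expected_chrom_proportions(
    layout: GenomeLayout,
    karyotype: str,
    fetal_fraction: float,
    trisomy_map: dict[str, str] | None = None,
    gc_bias: dict[str, np.ndarray] | None = None,
) -> dict[str, float]:
    """Expected proportion of mapped reads per chromosome under the dosage model.

    Baseline proportions follow chromosome length (GC-weighted when bias is
    given); the trisomic chromosome's weight is multiplied by
    (1 + fetal_fraction / 2) and the vector renormalized.  With fetal
    fraction 0, or for a euploid karyotype, proportions equal the baseline.
    """
    if not 0.0 <= fetal_fraction <= 1.0:
        raise ValueError(f"fetal_fraction must be in [0, 1], got {fetal_fraction}")
    trisomy_map = trisomy_map if trisomy_map is not None else DEFAULT_TRISOMY_MAP
    tri = _trisomic_chrom(karyotype, trisomy_map)
    weights = {c: w.sum() for c, w in _bin_weights(layout, gc_bias).items()}
    if tri is not None:
        if tri not in weights:
            raise ValueError(f"trisomic chromosome {tri!r} not in layout")
        weights[tri] *= 1.0 + fetal_fraction / 2.0
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


# -- fetal fraction draws -------------------------------------------------


def _draw_fetal_fraction(config: SimulationConfig, rng: np.random.Generator) -> float:
    """Truncated-normal draw by rejection (deterministic given the rng state)."""
    if config.fetal_fraction_sd == 0:
        return float(
            np.clip(config.fetal_fraction_mean, config.fetal_fraction_min, config.fetal_fraction_max)
        )
    for _ in range(10_000):
        f = rng.normal(config.fetal_fraction_mean, config.fetal_fraction_sd)
        if config.fetal_fraction_min <= f <= config.fetal_fraction_max:
            return float(f)
    raise RuntimeError("fetal-fraction truncation bounds reject essentially all draws")


def _sample_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(config.n_samples)]


# -- bin-count simulation (primary path) ----------------------------------


def simulate_bin_counts(
    config: SimulationConfig, layout: GenomeLayout
) -> tuple[list[BinCounts], list[TruthLabel]]:
    """Draw per-sample bin counts as a multinomial over the bin grid.

    For each sample the fetal fraction is drawn, per-bin expected proportions
    are computed (bin width x optional GC weight, trisomic chromosome scaled
    by 1 + f/2), and ``round(reads_per_sample * unique_map_rate)`` retained
    reads are distributed multinomially.  Bin counts therefore sum exactly to
    the retained total for every sample.
    """
    rng = np.random.default_rng(config.seed)
    base_weights = _bin_weights(layout, config.gc_bias)
    chroms = layout.names
    sizes = {c: base_weights[c].size for c in chroms}
    flat_base = np.concatenate([base_weights[c] for c in chroms])
    offsets: dict[str, slice] = {}
    pos = 0
    for c in chroms:
        offsets[c] = slice(pos, pos + sizes[c])
        pos += sizes[c]

    retained = int(round(config.reads_per_sample * config.unique_map_rate))
    if config.reads_per_sample == 0:
        logger.warning("simulate_bin_counts: reads_per_sample is 0; emitting empty counts")

    samples: list[BinCounts] = []
    labels: list[TruthLabel] = []
    for sample_id, karyotype in zip(_sample_ids(config), config.karyotypes()):
        f = _draw_fetal_fraction(config, rng)
        weights = flat_base.copy()
        tri = _trisomic_chrom(karyotype, config.trisomy_map)
        if tri is not None:
            if tri not in offsets:
                raise ValueError(f"trisomic chromosome {tri!r} not in layout")
            weights[offsets[tri]] *= 1.0 + f / 2.0
        p = weights / weights.sum()
        flat_counts = (
            rng.multinomial(retained, p) if retained > 0 else np.zeros(p.size, dtype=np.int64)
        )
        counts = {c: flat_counts[offsets[c]].astype(np.int64) for c in chroms}
        samples.append(BinCounts(sample_id=sample_id, layout=layout, counts=counts))
        labels.append(TruthLabel(sample_id=sample_id, karyotype=karyotype, fetal_fraction=f))
    return samples, labels


# -- read-level simulation (QC exercise path) ------------------------------


def _draw_bases(rng: np.random.Generator, length: int, gc_target: float) -> str:
    """Bases whose composition matches the GC target exactly (rounded).

    ``round(gc_target * length)`` positions are G/C and the rest A/T, shuffled;
    a read drawn at target 0.40 therefore always has GC fraction 0.40 +- 1/(2L),
    so per-read GC variation comes from the per-read target draw alone.
    """
    n_gc = int(round(gc_target * length))
    is_gc = np.zeros(length, dtype=bool)
    is_gc[rng.permutation(length)[:n_gc]] = True
    pick = rng.integers(0, 2, size=length)
    bases = np.where(is_gc, np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
    return "".join(bases)


def simulate_reads(
    config: SimulationConfig, layout: GenomeLayout
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Emit read-level cohorts: reads with qualities plus a truth alignment table.

    Lengths are Normal(read_length_mean, read_length_sd) rounded and truncated
    to >= 1; qualities follow the 3' decay profile; each read's base
    composition targets a per-read GC fraction; a ``duplicate_rate`` share of
    reads are exact positional (and sequence) copies of earlier reads; a
    ``1 - unique_map_rate`` share is flagged non-unique in the truth table.

    Intended for small cohorts (QC-stage testing); bin-count simulation is
    the scalable path.
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(layout.names)
    lengths = layout.lengths
    reads: list[SimulatedRead] = []
    truth_rows: list[tuple] = []
    for sample_id, karyotype in zip(_sample_ids(config), config.karyotypes()):
        f = _draw_fetal_fraction(config, rng)
        props = expected_chrom_proportions(
            layout, karyotype, f, config.trisomy_map, config.gc_bias
        )
        p = np.array([props[c] for c in chroms])
        n_total = config.reads_per_sample
        n_dup = int(round(config.duplicate_rate * n_total)) if n_total > 1 else 0
        n_new = n_total - n_dup
        sample_reads: list[SimulatedRead] = []
        for i in range(n_new):
            chrom = chroms[rng.choice(len(chroms), p=p)]
            start = int(rng.integers(0, lengths[chrom]))
            strand = "+" if rng.random() < 0.5 else "-"
            length = max(1, int(round(rng.normal(config.read_length_mean, config.read_length_sd))))
            gc_target = float(np.clip(rng.normal(config.read_gc_mean, config.read_gc_sd), 0.0, 1.0))
            bases = _draw_bases(rng, length, gc_target)
            quals = tuple(int(q) for q in config.quality_decay.qualities(length))
            unique = bool(rng.random() < config.unique_map_rate)
            sample_reads.append(
                SimulatedRead(
                    sample_id, f"{sample_id}_r{i + 1:06d}", bases, quals, chrom, start, strand, unique
                )
            )
        for j in range(n_dup):
            src = sample_reads[int(rng.integers(0, n_new))]
            sample_reads.append(
                SimulatedRead(
                    sample_id,
                    f"{sample_id}_d{j + 1:06d}",
                    src.bases,
                    src.qualities,
                    src.chrom,
                    src.start0,
                    src.strand,
                    src.unique,
                )
            )
        for r in sample_reads:
            truth_rows.append(
                (r.sample_id, r.read_id, r.chrom, r.start0, r.strand, int(r.unique))
            )
        reads.extend(sample_reads)
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "read_id", "chrom", "start0", "strand", "unique"]
    )
    return reads, truth


def truth_to_alignments(truth: pd.DataFrame) -> list[AlignedRead]:
    """Convert truth-table rows into alignment records for the QC stage.

    Unique reads get mapq 37 and a clean flag; non-unique reads get mapq 0 so
    the default uniqueness predicate rejects them.
    """
    out: list[AlignedRead] = []
    for row in truth.itertuples(index=False):
        unique = bool(row.unique)
        out.append(
            AlignedRead(
                read_id=row.read_id,
                chromosome=row.chrom,
                start=int(row.start0),
                strand=row.strand,
                mapq=37 if unique else 0,
                flags=0,
            )
        )
    return out


# -- file interfaces ------------------------------------------------------


def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    """Standard 4-line FASTQ records, Phred+33."""
    with open(path, "w") as handle:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            handle.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


def write_truth_tsv(truth: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        truth.to_csv(handle, sep="\t", index=False)


def write_labels_tsv(labels: Sequence[TruthLabel], path: str | Path, seed: int | None = None) -> None:
    frame = pd.DataFrame(
        [(l.sample_id, l.karyotype, l.fetal_fraction) for l in labels],
        columns=["sample", "karyotype", "fetal_fraction"],
    )
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_labels_tsv(path: str | Path) -> list[TruthLabel]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        TruthLabel(str(r.sample), str(r.karyotype), float(r.fetal_fraction))
        for r in frame.itertuples(index=False)
    ]
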