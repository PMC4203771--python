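"""Euploid reference panel and per-chromosome z-scores.

For a sample s and chromosome c the screening statistic is

    z(s, c) = (x_sc - mean_c) / sd_c

where x_sc is the sample's chromosome representation (raw mapped-read count
or autosomal fraction), and mean_c, sd_c are the mean and sample standard
deviation (n - 1 denominator) of the same statistic over the euploid
reference cohort.  A scored euploid sample is not excluded from its own
panel by default, matching the study design in which all samples are scored
against the full euploid set; a leave-one-out variant is available for
bias-sensitive uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .binning import RepresentationMode, SampleProfile

__all__ = [
    "ReferencePanel",
    "ZScoreResult",
    "build_reference",
    "zscore",
    "zscore_table",
    "write_panel_tsv",
    "read_panel_tsv",
]


@dataclass(frozen=True)
class ReferencePanel:
    """Per-chromosome mean/SD of the representation statistic over euploids."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_ref: int
    mode: RepresentationMode

    def __post_init__(self) -> None:
        if self.n_ref < 2:
            raise ValueError(f"reference panel needs >= 2 samples, got {self.n_ref}")
        for chrom, sd in self.sd.items():
            if not sd > 0:
                raise ValueError(f"zero/invalid SD on {chrom}: panel cannot score it")


@dataclass(frozen=True)
class ZScoreResult:
    sample_id: str
    chromosome: str
    z: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.z):
            raise ValueError(f"non-finite z for {self.sample_id}/{self.chromosome}")


def build_reference(
    profiles: Sequence[SampleProfile],
    chromosomes: Iterable[str] | None = None,
) -> ReferencePanel:
    """Build the panel from euploid profiles (sample SD, n - 1 denominator).

    Raises if fewer than two profiles are given, if modes are mixed, or if any
    scored chromosome has zero spread (a degenerate panel cannot standardize).
    """
    if len(profiles) < 2:
        raise ValueError(f"need >= 2 euploid profiles, got {len(profiles)}")
    modes = {p.mode for p in profiles}
    if len(modes) != 1:
        raise ValueError(f"profiles mix representation modes: {sorted(modes)}")
    (mode,) = modes
    chroms = list(chromosomes) if chromosomes is not None else list(profiles[0].counts)
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for chrom in chroms:
        values = np.array([p.statistic(chrom) for p in profiles], dtype=float)
        mean[chrom] = float(values.mean())
        sd[chrom] = float(values.std(ddof=1))
    return ReferencePanel(mean=mean, sd=sd, n_ref=len(profiles), mode=mode)


def zscore(profile: SampleProfile, panel: ReferencePanel, chromosome: str) -> ZScoreResult:
    """Score one sample's chromosome against the panel."""
    if profile.mode != panel.mode:
        raise ValueError(
            f"representation mode mismatch: profile {profile.mode!r} vs panel {panel.mode!r}"
        )
    if chromosome not in panel.mean:
        raise ValueError(f"chromosome {chromosome!r} not in reference panel")
    z = (profile.statistic(chromosome) - panel.mean[chromosome]) / panel.sd[chromosome]
    return ZScoreResult(profile.sample_id, chromosome, float(z))


def zscore_table(
    profiles: Sequence[SampleProfile],
    panel: ReferencePanel,
    chromosomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Long-format z table (sample, chrom, z) for many samples/chromosomes."""
    chroms = list(chromosomes) if chromosomes is not None else list(panel.mean)
    rows = [
        (p.sample_id, c, zscore(p, panel, c).z) for p in profiles for c in chroms
    ]
    return pd.DataFrame(rows, columns=["sample", "chrom", "z"])


def write_panel_tsv(panel: ReferencePanel, path: str | Path, seed: int | None = None) -> None:
    frame = pd.DataFrame(
        {
            "chrom": list(panel.mean),
            "mean": [panel.mean[c] for c in panel.mean],
            "sd": [panel.sd[c] for c in panel.mean],
            "n_ref": panel.n_ref,
            "mode": panel.mode,
        }
    )
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_panel_tsv(path: str | Path) -> ReferencePanel:
    frame = pd.read_csv(path, sep="\t", comment="#")
    modes = frame["mode"].unique()
    n_refs = frame["n_ref"].unique()
    if len(modes) != 1 or len(n_refs) != 1:
        raise ValueError(f"{path}: inconsistent panel metadata")
    return ReferencePanel(
        mean=dict(zip(frame["chrom"], frame["mean"].astype(float))),
        sd=dict(zip(frame["chrom"], frame["sd"].astype(float))),
        n_ref=int(n_refs[0]),
        mode=str(modes[0]),  # type: ignore[arg-type]
    )
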