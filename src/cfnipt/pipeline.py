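"""End-to-end orchestration: cohort -> QC -> counts -> z-scores -> calls -> report.

Each stage emits a plain TSV artifact so any stage can be re-run or tested in
isolation; the TSVs are the contract between stages.  All randomness flows
from the single seed in the simulation config, and every artifact header
records it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .binning import (
    BinCounts,
    RepresentationMode,
    SampleProfile,
    profile_from_counts,
    write_bin_counts_tsv,
    write_profiles_tsv,
)
from .classification import ClassificationRule, classify_value, select_threshold
from .evaluation import CIMethod, confusion
from .genome_layout import GenomeLayout
from .synthetic_data import (
    SimulationConfig,
    TruthLabel,
    simulate_bin_counts,
    simulate_reads,
    write_fastq,
    write_labels_tsv,
    write_truth_tsv,
)
from .zscore import ReferencePanel, build_reference, write_panel_tsv, zscore_table

__all__ = ["PipelineResult", "run_simulate", "run_full"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All stage outputs of one full run."""

    profiles: list[SampleProfile]
    panel: ReferencePanel
    zscores: pd.DataFrame  # sample, chrom, z
    rules: dict[str, ClassificationRule]  # karyotype -> rule
    calls: pd.DataFrame  # sample, karyotype truth, per-target call, combined call
    summaries: dict[str, dict]  # target -> evaluation report

    def report_json(self) -> str:
        payload = {
            "rules": {k: {"chromosome": r.chromosome, "cutoff": r.cutoff} for k, r in self.rules.items()},
            "in_sample_thresholds": True,
            "summaries": self.summaries,
        }
        return json.dumps(payload, indent=2)


def run_simulate(
    config: SimulationConfig,
    layout: GenomeLayout,
    out_dir: str | Path,
    reads: bool = False,
) -> dict[str, Path]:
    """Write a synthetic cohort to ``out_dir``; returns the artifact paths.

    With ``reads=False`` (default) bin counts and truth labels are written;
    with ``reads=True`` a FASTQ per cohort plus the truth alignment table.
    A manifest echoes the parameters and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    if reads:
        sim_reads, truth = simulate_reads(config, layout)
        fastq = out / "reads.fastq"
        write_fastq(sim_reads, fastq)
        truth_path = out / "truth_alignments.tsv"
        write_truth_tsv(truth, truth_path, seed=config.seed)
        artifacts.update(fastq=fastq, truth=truth_path)
    else:
        counts, label_list = simulate_bin_counts(config, layout)
        counts_path = out / "bin_counts.tsv"
        write_bin_counts_tsv(counts, counts_path, seed=config.seed)
        labels_path = out / "labels.tsv"
        write_labels_tsv(label_list, labels_path, seed=config.seed)
        artifacts.update(bin_counts=counts_path, labels=labels_path)
    manifest = {
        "seed": config.seed,
        "n_euploid": config.n_euploid,
        "n_t18": config.n_t18,
        "n_t21": config.n_t21,
        "reads_per_sample": config.reads_per_sample,
        "unique_map_rate": config.unique_map_rate,
        "fetal_fraction_mean": config.fetal_fraction_mean,
        "fetal_fraction_sd": config.fetal_fraction_sd,
        "bin_size": layout.bin_size,
        "mode": "reads" if reads else "bin_counts",
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = manifest_path
    return artifacts


def run_full(
    counts: Sequence[BinCounts],
    labels: Sequence[TruthLabel],
    layout: GenomeLayout,
    mode: RepresentationMode = "fraction",
    trisomy_map: Mapping[str, str] | None = None,
    fixed_thresholds: Mapping[str, float] | None = None,
    ci_method: CIMethod = "exact",
    confidence: float = 0.95,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run binning-derived counts through the full screening analysis.

    The euploid-labelled samples form the reference panel; every sample is
    scored against it on the trisomy target chromosomes.  Cutoffs are either
    supplied (``fixed_thresholds``, keyed by karyotype, e.g. ``{"T21": 2.566}``)
    or selected in-sample by the dot-diagram (Youden) criterion.  Per-target
    and pooled ("combined") confusion summaries close the run.
    """
    if not counts:
        raise ValueError("no input samples")
    if len(counts) != len(labels):
        raise ValueError(f"{len(counts)} count tables vs {len(labels)} labels")
    by_id = {l.sample_id: l for l in labels}
    missing = [c.sample_id for c in counts if c.sample_id not in by_id]
    if missing:
        raise ValueError(f"samples without truth labels: {missing[:5]}")
    trisomy_map = dict(trisomy_map) if trisomy_map is not None else {"T18": "chr18", "T21": "chr21"}

    profiles = [profile_from_counts(c, layout, mode) for c in counts]
    euploid = [p for p in profiles if by_id[p.sample_id].karyotype == "euploid"]
    if len(euploid) < 2:
        raise ValueError(
            f"reference panel needs >= 2 euploid-labelled samples, found {len(euploid)}"
        )
    panel = build_reference(euploid, chromosomes=layout.names)
    targets = list(trisomy_map)
    target_chroms = [trisomy_map[t] for t in targets]
    ztab = zscore_table(profiles, panel, chromosomes=target_chroms)
    zwide = ztab.pivot(index="sample", columns="chrom", values="z")

    karyotype = {p.sample_id: by_id[p.sample_id].karyotype for p in profiles}
    sample_ids = [p.sample_id for p in profiles]

    rules: dict[str, ClassificationRule] = {}
    for target in targets:
        chrom = trisomy_map[target]
        if fixed_thresholds is not None and target in fixed_thresholds:
            rules[target] = ClassificationRule(chromosome=chrom, cutoff=float(fixed_thresholds[target]))
        else:
            pos = [zwide.loc[s, chrom] for s in sample_ids if karyotype[s] == target]
            neg = [zwide.loc[s, chrom] for s in sample_ids if karyotype[s] != target]
            rules[target] = select_threshold(neg, pos, chromosome=chrom)
            logger.info("selected in-sample cutoff for %s on %s: %.3f", target, chrom, rules[target].cutoff)

    call_rows = []
    for s in sample_ids:
        row: dict = {"sample": s, "karyotype": karyotype[s]}
        any_pos = False
        for target in targets:
            call = classify_value(float(zwide.loc[s, trisomy_map[target]]), rules[target])
            row[f"call_{target}"] = call
            any_pos = any_pos or call == "positive"
        row["call_combined"] = "positive" if any_pos else "negative"
        call_rows.append(row)
    calls = pd.DataFrame(call_rows)

    summaries: dict[str, dict] = {}
    for target in targets:
        cm = confusion(
            [karyotype[s] for s in sample_ids],
            list(calls[f"call_{target}"]),
            positive_truth=target,
        )
        summaries[target] = cm.report(method=ci_method, confidence=confidence)
    cm_combined = confusion(
        [karyotype[s] for s in sample_ids],
        list(calls["call_combined"]),
        positive_truth=targets,
    )
    summaries["combined"] = cm_combined.report(method=ci_method, confidence=confidence)

    result = PipelineResult(
        profiles=profiles, panel=panel, zscores=ztab, rules=rules, calls=calls, summaries=summaries
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_profiles_tsv(profiles, out / "profiles.tsv")
        write_panel_tsv(panel, out / "panel.tsv")
        ztab.to_csv(out / "zscores.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(t, r.chromosome, r.cutoff) for t, r in rules.items()],
            columns=["target", "chrom", "cutoff"],
        ).to_csv(out / "rules.tsv", sep="\t", index=False)
        calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        (out / "report.json").write_text(result.report_json())
    return result
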