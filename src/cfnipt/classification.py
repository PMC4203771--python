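"""Cutoff selection by the interactive dot-diagram criterion, and calling.

A sample is called positive for a chromosome when its z-score strictly
exceeds the chromosome's cutoff.  The cutoff is chosen among the observed z
values themselves (not between-point midpoints) to maximize the Youden index

    J(c) = sensitivity(c) + specificity(c) - 1
         = P(z_pos > c) + P(z_neg <= c) - 1,

with ties broken toward the largest qualifying cutoff.  When the two groups
are perfectly separated this reduces to cutoff = max(negative z), which is
how dot-diagram software reports the "minimal discriminating value".

Cutoffs selected on the evaluation data themselves are in-sample and
optimistic; report output records this.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .zscore import ZScoreResult

__all__ = [
    "ClassificationRule",
    "select_threshold",
    "classify",
    "classify_value",
    "plot_dot_diagram",
]


@dataclass(frozen=True)
class ClassificationRule:
    """Per-chromosome cutoff; the calling direction is fixed strict '>'."""

    chromosome: str
    cutoff: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError(f"non-finite cutoff for {self.chromosome}")


def select_threshold(
    negative_z: Sequence[float],
    positive_z: Sequence[float],
    chromosome: str = "",
) -> ClassificationRule:
    """Choose the Youden-optimal cutoff among the observed z values.

    Under the rule "positive iff z > c", every observed value is tried as c;
    among maximizers of sensitivity + specificity - 1 the largest cutoff wins.
    With perfect group separation the selected cutoff equals max(negative_z).
    """
    neg = np.asarray(negative_z, dtype=float)
    pos = np.asarray(positive_z, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty to select a threshold")
    candidates = np.unique(np.concatenate([neg, pos]))
    # vectorized scan: sens(c) = mean(pos > c), spec(c) = mean(neg <= c)
    sens = (pos[None, :] > candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] <= candidates[:, None]).mean(axis=1)
    youden = sens + spec - 1.0
    best = youden.max()
    cutoff = candidates[np.isclose(youden, best)].max()
    return ClassificationRule(chromosome=chromosome, cutoff=float(cutoff))


def classify_value(z: float, rule: ClassificationRule) -> str:
    """'positive' iff z strictly exceeds the cutoff, else 'negative'."""
    return "positive" if z > rule.cutoff else "negative"


def classify(z: ZScoreResult, rule: ClassificationRule) -> str:
    """Call one z-score against a rule; chromosomes must match."""
    if rule.chromosome and z.chromosome != rule.chromosome:
        raise ValueError(
            f"rule is for {rule.chromosome!r} but z-score is for {z.chromosome!r}"
        )
    return classify_value(z.z, rule)


def plot_dot_diagram(
    negative_z: Sequence[float],
    positive_z: Sequence[float],
    rule: ClassificationRule,
    path: str | Path,
    group_names: tuple[str, str] = ("negative", "positive"),
) -> None:
    """Two jittered strip columns with the selected cutoff as a horizontal line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(0)  # cosmetic jitter only
    fig, ax = plt.subplots(figsize=(4, 5))
    for i, (values, name) in enumerate(zip((negative_z, positive_z), group_names)):
        x = i + rng.uniform(-0.12, 0.12, size=len(values))
        ax.plot(x, values, "o", ms=4, alpha=0.7, label=name)
    ax.axhline(rule.cutoff, color="k", ls="--", lw=1)
    ax.text(0.5, rule.cutoff, f" cutoff {rule.cutoff:.3f}", va="bottom", fontsize=8)
    ax.set_xticks([0, 1])
    ax.set_xticklabels(group_names)
    ax.set_ylabel(f"z-score ({rule.chromosome or 'chromosome'})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
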