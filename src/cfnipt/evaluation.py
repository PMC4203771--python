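"""Confusion summaries, predictive values and binomial confidence intervals.

Point estimates are the standard 2x2 proportions: PPV = TP/(TP+FP),
NPV = TN/(TN+FN), sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).

Two 95% CI methods for a binomial proportion are provided:

* Clopper-Pearson ("exact") via Beta quantiles; at k = n the lower bound has
  the closed form (alpha/2)^(1/n);
* Wilson score interval; at k = n the lower bound is n / (n + z^2).

Screening reports of this kind often label their intervals "Wilson" while
printing Clopper-Pearson numbers (the two coincide only loosely); both
methods are therefore implemented and the report defaults to exact, with the
method recorded in every output.

``sample_size_all_success`` answers the planning question "how many all-
negative (or all-positive) subjects are needed before the CI lower bound
clears a target" by direct iteration over n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

from scipy import stats

__all__ = [
    "ConfusionSummary",
    "confusion",
    "predictive_values",
    "ci_exact",
    "ci_wilson",
    "ci_binomial",
    "sample_size_all_success",
    "round_percent",
]

CIMethod = Literal["exact", "wilson"]


def _check_kn(k: int, n: int) -> None:
    if n < 1:
        raise ValueError(f"trials must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {k}")


def ci_exact(successes: int, trials: int, confidence: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval from Beta quantiles.

    lower = BetaInv(alpha/2; k, n-k+1), upper = BetaInv(1-alpha/2; k+1, n-k),
    with lower = 0 at k = 0 and upper = 1 at k = n.
    """
    _check_kn(successes, trials)
    alpha = 1.0 - confidence
    k, n = successes, trials
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def ci_wilson(successes: int, trials: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (closed form); at k = n the lower bound is n/(n+z^2)."""
    _check_kn(successes, trials)
    z = float(stats.norm.ppf(1 - (1 - confidence) / 2))
    n = trials
    p = successes / n
    z2 = z * z
    center = (p + z2 / (2 * n)) / (1 + z2 / n)
    half = (z / (1 + z2 / n)) * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n))
    return max(0.0, center - half), min(1.0, center + half)


def ci_binomial(
    successes: int, trials: int, method: CIMethod = "exact", confidence: float = 0.95
) -> tuple[float, float]:
    if method == "exact":
        return ci_exact(successes, trials, confidence)
    if method == "wilson":
        return ci_wilson(successes, trials, confidence)
    raise ValueError(f"unknown CI method {method!r}")


def sample_size_all_success(
    target_lower: float,
    method: CIMethod = "exact",
    confidence: float = 0.95,
    max_n: int = 1_000_000,
) -> int:
    """Smallest n such that the k = n CI lower bound reaches ``target_lower``.

    The all-success lower bound is monotone increasing in n for both methods,
    so simple iteration terminates at the first qualifying n.
    """
    if not 0.0 < target_lower < 1.0:
        raise ValueError(f"target_lower must be in (0, 1), got {target_lower}")
    for n in range(1, max_n + 1):
        if ci_binomial(n, n, method, confidence)[0] >= target_lower:
            return n
    raise ValueError(f"no n <= {max_n} reaches lower bound {target_lower}")


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 tally for one designated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return self.tn / d if d else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def report(self, method: CIMethod = "exact", confidence: float = 0.95) -> dict:
        """Point estimates with CIs for PPV/NPV/sensitivity/specificity.

        Quantities with a zero denominator are reported as None ("not
        available") rather than raising.
        """
        out: dict = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n": self.n,
            "ci_method": method,
            "confidence": confidence,
        }
        pairs = {
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.tn + self.fn),
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (self.tn, self.tn + self.fp),
        }
        for name, (k, n) in pairs.items():
            if n == 0:
                out[name] = None
                out[f"{name}_ci"] = None
            else:
                out[name] = k / n
                out[f"{name}_ci"] = ci_binomial(k, n, method, confidence)
        return out


def confusion(
    truth: Sequence[str],
    calls: Sequence[str],
    positive_truth: str | Sequence[str] = "positive",
    positive_call: str = "positive",
) -> ConfusionSummary:
    """Tally a 2x2 table for a designated positive class.

    ``positive_truth`` may list several truth labels (e.g. both trisomies) to
    pool them into one positive class ("combined detection").
    """
    if len(truth) != len(calls):
        raise ValueError(f"truth has {len(truth)} samples but calls has {len(calls)}")
    pos_labels = {positive_truth} if isinstance(positive_truth, str) else set(positive_truth)
    tp = fp = tn = fn = 0
    for t, c in zip(truth, calls):
        is_pos = t in pos_labels
        called_pos = c == positive_call
        if is_pos and called_pos:
            tp += 1
        elif is_pos:
            fn += 1
        elif called_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)


def predictive_values(counts: ConfusionSummary) -> tuple[float | None, float | None]:
    """(PPV, NPV); either is None when its denominator is zero."""
    return counts.ppv, counts.npv


def round_percent(p: float, decimals: int = 1) -> float:
    """Proportion -> percentage rounded half-up, matching printed report tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(p * 100)).quantize(q, rounding=ROUND_HALF_UP))
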