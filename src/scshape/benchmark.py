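"""Benchmark reactivity profiles against reference secondary structures.

Single-stranded (unpaired) nucleotides are the truly modifiable bases, so
they are labeled True and double-stranded bases False; a good reactivity
profile ranks True above False.  Accuracy is summarized as the area under
the ROC curve, computed by the rank (Mann–Whitney) formulation with ½
credit per tie.  When a 2′-OH solvent-accessibility table is available,
bases the probe cannot physically reach (accessibility below threshold)
are excluded from both classes before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReferenceStructure
from .reactivity import ReactivityProfile

DEFAULT_ACCESSIBILITY_THRESHOLD = 3.0


@dataclass
class LabeledPositions:
    """Benchmark labels: True = single-stranded (truly modified)."""

    transcript_id: str
    label: np.ndarray     # bool per position
    included: np.ndarray  # bool per position; survives accessibility filter

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=bool)
        self.included = np.asarray(self.included, dtype=bool)
        if self.label.shape != self.included.shape:
            raise ValueError("label/included shape mismatch")


def label_positions(
    structure: ReferenceStructure,
    accessibility_threshold: float = DEFAULT_ACCESSIBILITY_THRESHOLD,
) -> LabeledPositions:
    """Label unpaired bases True; filter by solvent accessibility if present.

    Without an accessibility table all bases are included (the in-vitro
    benchmark mode); with one, only bases with accessibility >= threshold
    enter either class.
    """
    label = structure.unpaired
    if structure.solvent_accessibility is not None:
        acc = structure.solvent_accessibility
        included = np.isfinite(acc) & (acc >= accessibility_threshold)
    else:
        included = np.ones(len(structure), dtype=bool)
    return LabeledPositions(structure.transcript_id, label, included)


def _usable(profile: ReactivityProfile, labels: LabeledPositions):
    n = min(len(profile), len(labels.label))
    use = labels.included[:n] & profile.mask[:n]
    return profile.reactivity[:n][use], labels.label[:n][use]


def roc_auc(
    profile: ReactivityProfile,
    labels: LabeledPositions,
    min_per_class: int = 5,
) -> tuple[float, pd.DataFrame]:
    """AUC-ROC of reactivity against the structure labels, plus the curve.

    AUC is computed from rank sums (the Mann–Whitney statistic divided by
    n1·n2), which credits each tied pair ½ — identical to the area under
    the trapezoidal ROC curve.  Masked and accessibility-excluded
    positions are dropped from both classes, never imputed.
    """
    scores, y = _usable(profile, labels)
    n_true = int(y.sum())
    n_false = int(len(y) - n_true)
    if n_true == 0 or n_false == 0:
        raise ValueError("both label classes must be present")
    if n_true < min_per_class or n_false < min_per_class:
        raise ValueError(
            f"need >= {min_per_class} positions per class, got "
            f"{n_true} true / {n_false} false"
        )
    ranks = stats.rankdata(scores)  # average ranks handle ties
    auc = (ranks[y].sum() - n_true * (n_true + 1) / 2) / (n_true * n_false)

    # ROC curve: sweep thresholds from high to low
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_y = y[order]
    tps = np.cumsum(sorted_y)
    fps = np.cumsum(~sorted_y)
    # keep the last point of each tied-score run
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_true]
    fpr = np.r_[0.0, fps[distinct] / n_false]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return float(auc), curve


def paired_unpaired_test(
    profile: ReactivityProfile,
    labels: LabeledPositions,
    min_per_class: int = 3,
    exact_max: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparing unpaired vs paired reactivities.

    Exact enumeration when both classes have <= ``exact_max`` values and
    no ties; otherwise the normal approximation with tie correction.
    Returns (U of the unpaired class, p).
    """
    scores, y = _usable(profile, labels)
    unpaired, paired = scores[y], scores[~y]
    return mannwhitney(unpaired, paired, min_per_class=min_per_class, exact_max=exact_max)


def mannwhitney(
    a: np.ndarray,
    b: np.ndarray,
    min_per_class: int = 3,
    exact_max: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U engine shared by the benchmark and
    enrichment modules."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < min_per_class or len(b) < min_per_class:
        raise ValueError(
            f"both groups need >= {min_per_class} values, got {len(a)} and {len(b)}"
        )
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if len(a) <= exact_max and len(b) <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benchmark_summary(
    profile: ReactivityProfile, labels: LabeledPositions
) -> dict[str, float | int]:
    """One-line accuracy report: class sizes, AUC and the rank-sum test."""
    scores, y = _usable(profile, labels)
    auc, _ = roc_auc(profile, labels)
    _, p = paired_unpaired_test(profile, labels)
    return {
        "transcript_id": labels.transcript_id,
        "n_true": int(y.sum()),
        "n_false": int(len(y) - y.sum()),
        "auc": auc,
        "mannwhitney_p": p,
    }
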