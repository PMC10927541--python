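"""Feature/RBP enrichment over window classes and stratified reactivity.

Enrichment asks whether windows of interest (e.g. the most heterogeneous
quartile) overlap a feature's binding intervals more often than expected
among all detected background windows: an upper-tail hypergeometric test
per feature, Bonferroni-corrected across the features tested in the call,
significant at adjusted P <= 0.05.

Stratified analyses bin cells into expression quartiles of a regulator
(e.g. an RBP) and contrast per-cell window reactivities between the lowest
(q1) and highest (q4) bins with a Welch t-test and a log2 fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import mannwhitney
from .io import BaseCountMatrix, IntervalSet
from .reactivity import pseudobulk

DEFAULT_ALPHA = 0.05
DEFAULT_LOG2FC_PSEUDOCOUNT = 0.01


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The one-sided tail used by every overlap-enrichment test in the
    package (feature enrichment and metagene bins).
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# Window × feature overlap
# ---------------------------------------------------------------------------


def overlap_windows(
    windows: list[tuple[str, int, int]],
    intervals: IntervalSet,
) -> pd.DataFrame:
    """Boolean windows × features overlap table (half-open intersection).

    A window [a, b) overlaps an interval [s, e) on the same transcript
    when max(a, s) < min(b, e).
    """
    features = intervals.feature_names
    by_feature = intervals.by_feature()
    data = np.zeros((len(windows), len(features)), dtype=bool)
    for j, feat in enumerate(features):
        ivs = by_feature[feat]
        for i, (tx, a, b) in enumerate(windows):
            for iv in ivs:
                if iv.transcript_id == tx and max(a, iv.start) < min(b, iv.end):
                    data[i, j] = True
                    break
    index = pd.MultiIndex.from_tuples(windows, names=["transcript_id", "start", "end"])
    return pd.DataFrame(data, index=index, columns=features)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    feature_name: str
    k: int   # interest windows overlapping the feature
    K: int   # background windows overlapping the feature
    n: int   # interest windows
    N: int   # background windows
    p_value: float
    adj_p: float
    enriched: bool


def hypergeometric_enrichment(
    interest_windows: list[tuple[str, int, int]],
    background_windows: list[tuple[str, int, int]],
    intervals: IntervalSet,
    alpha: float = DEFAULT_ALPHA,
    tail: str = "upper",
) -> list[EnrichmentResult]:
    """Per-feature hypergeometric overlap test with Bonferroni correction.

    Drawing the n interest windows from the N background windows, of which
    K overlap the feature, the upper-tail p is P(X >= k) for the observed
    overlap count k.  ``tail="lower"`` reports depletion instead.  The
    Bonferroni family is the set of features tested in this call.
    """
    interest_set = set(interest_windows)
    background_set = set(background_windows)
    if not background_set:
        raise ValueError("background must be nonempty")
    if not interest_set <= background_set:
        raise ValueError("interest windows must be a subset of the background")
    if tail not in ("upper", "lower"):
        raise ValueError(f"unknown tail {tail!r}")
    bg = sorted(background_set)
    table = overlap_windows(bg, intervals)
    in_interest = np.array([w in interest_set for w in bg])
    n, N = int(in_interest.sum()), len(bg)
    n_features = table.shape[1]
    results = []
    for feat in table.columns:
        hits = table[feat].to_numpy()
        K = int(hits.sum())
        k = int((hits & in_interest).sum())
        if tail == "upper":
            p = hypergeom_upper_tail(k, N, K, n)
        else:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        adj_p = min(1.0, p * n_features)
        results.append(
            EnrichmentResult(feat, k, K, n, N, p, adj_p, enriched=adj_p <= alpha)
        )
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.feature_name, r.k, r.K, r.n, r.N, r.p_value, r.adj_p, r.enriched)
            for r in results
        ],
        columns=["feature", "k", "K", "n", "N", "p", "adj_p", "enriched"],
    )


# ---------------------------------------------------------------------------
# Expression-quartile stratification
# ---------------------------------------------------------------------------


def rbp_quartile_bins(
    expression: pd.DataFrame,
    gene_id: str,
    cells: list[str] | None = None,
) -> dict[str, str]:
    """Split cells into four equal-count bins q1..q4 by a gene's expression.

    q1 is the lowest-expressing quarter, q4 the highest.  Ties are broken
    by stable cell-id order; bin sizes differ by at most one.  An all-equal
    expression vector still splits (stably) with a warning.
    """
    sub = expression[expression["gene_id"] == gene_id]
    if sub.empty:
        raise KeyError(f"gene {gene_id!r} absent from expression table")
    if cells is not None:
        sub = sub[sub["cell_id"].isin(set(cells))]
    sub = sub.sort_values("cell_id").reset_index(drop=True)
    n = len(sub)
    if n < 8:
        raise ValueError(f"need >= 8 cells with expression for {gene_id!r}, got {n}")
    if sub["expression"].nunique() == 1:
        warnings.warn(f"all cells have equal {gene_id} expression; stable-order split")
    order = np.argsort(sub["expression"].to_numpy(), kind="stable")
    # equal-count split: bin sizes differ by <= 1, lowest ranks -> q1
    edges = [round(i * n / 4) for i in range(5)]
    bins = {}
    for q in range(4):
        for idx in order[edges[q] : edges[q + 1]]:
            bins[sub.loc[idx, "cell_id"]] = f"q{q + 1}"
    return bins


def _window_reactivity_per_cell(
    counts: BaseCountMatrix,
    cells: list[str],
    transcript_id: str,
    start: int,
    end: int,
    control_rate: float,
) -> dict[str, float]:
    """Aggregate (window-sum) treated rate per cell minus control rate."""
    df = counts.subset(cells=cells, transcript_id=transcript_id, condition="treated")
    df = df[(df["position"] >= start) & (df["position"] < end)]
    out = {}
    for cell, sub in df.groupby("cell_id"):
        cov = int(sub["coverage"].sum())
        if cov > 0:
            out[cell] = sub["mutated"].sum() / cov - control_rate
    return out


def stratified_reactivity_change(
    counts: BaseCountMatrix,
    bins: dict[str, str],
    target_windows: list[tuple[str, int, int]],
    control_cells: list[str] | None = None,
    pseudocount: float = DEFAULT_LOG2FC_PSEUDOCOUNT,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-window q4-vs-q1 reactivity contrast.

    For each target window, the per-cell window reactivity (window-summed
    treated mutation rate minus the control pseudobulk rate over the same
    window) is compared between the q4 and q1 expression bins:
    log2((mean_q4 + c)/(mean_q1 + c)) with pseudocount c guarding
    nonpositive means, and a Welch two-sided t-test on the per-cell
    values.  Windows with fewer than ``min_cells`` usable cells in either
    bin are skipped with a reason.
    """
    q1_cells = [c for c, q in bins.items() if q == "q1"]
    q4_cells = [c for c, q in bins.items() if q == "q4"]
    rows = []
    for tx, start, end in target_windows:
        ctrl = 0.0
        if control_cells:
            df = counts.subset(cells=control_cells, transcript_id=tx, condition="control")
            df = df[(df["position"] >= start) & (df["position"] < end)]
            cov = int(df["coverage"].sum())
            if cov > 0:
                ctrl = float(df["mutated"].sum() / cov)
        v1 = list(_window_reactivity_per_cell(counts, q1_cells, tx, start, end, ctrl).values())
        v4 = list(_window_reactivity_per_cell(counts, q4_cells, tx, start, end, ctrl).values())
        if len(v1) < min_cells or len(v4) < min_cells:
            rows.append((tx, start, end, np.nan, np.nan, np.nan,
                         f"skipped: {len(v1)} q1 / {len(v4)} q4 cells (< {min_cells})"))
            continue
        m1, m4 = float(np.mean(v1)), float(np.mean(v4))
        log2fc = float(np.log2((m4 + pseudocount) / (m1 + pseudocount)))
        t, p = stats.ttest_ind(v4, v1, equal_var=False)
        rows.append((tx, start, end, log2fc, float(t), float(p), ""))
    return pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "log2fc", "t", "p", "note"]
    )


def halflife_group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U on two groups of values (e.g. RNA
    half-lives of transcripts classed by heterogeneity change)."""
    return mannwhitney(np.asarray(values_a), np.asarray(values_b))
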