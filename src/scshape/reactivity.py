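"""Cell QC, mutation rates, reactivities, normalizations and pseudobulk.

The reactivity of a base is the treated-channel mutation rate minus the
control-channel (mock/DMSO) mutation rate: the chemical probe converts
modification of flexible nucleotides into reverse-transcription mutations,
and the control channel estimates background error.  Negative reactivities
are kept by default; downstream cosine statistics are sign-sensitive, so
clamping at zero is an explicit option, never silent.

Every per-position vector here travels with a boolean ``mask``: True where
the value is defined (coverage present), False where it is not.  Masked
positions carry no value (they are NaN in the payload array), and every
function preserves that invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BaseCountMatrix

DEFAULT_MIN_GENES = 5000
DEFAULT_MAX_MITO = 0.05


class LookupError_(KeyError):
    """Requested cell/transcript absent from the data."""


def _masked(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.where(mask, values, np.nan)
    return out


# ---------------------------------------------------------------------------
# Mutation rates
# ---------------------------------------------------------------------------


def _counts_to_vectors(
    df: pd.DataFrame, length: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Dense (coverage, mutated) vectors from long-form count records."""
    if length is None:
        length = int(df["position"].max()) + 1 if len(df) else 0
    coverage = np.zeros(length, dtype=np.int64)
    mutated = np.zeros(length, dtype=np.int64)
    pos = df["position"].to_numpy()
    # duplicate positions (e.g. several cells) accumulate
    np.add.at(coverage, pos, df["coverage"].to_numpy())
    np.add.at(mutated, pos, df["mutated"].to_numpy())
    return coverage, mutated


def mutation_rate(
    counts: BaseCountMatrix,
    cell: str,
    transcript_id: str,
    condition: str,
    length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position mutation rate for one cell and channel.

    Returns ``(rate, mask)``: ``rate = mutated / coverage`` where coverage
    is positive, NaN (mask False) where the base is uncovered.
    """
    if cell not in set(counts.data["cell_id"]):
        raise LookupError_(f"cell {cell!r} not in count matrix")
    df = counts.subset(cells=[cell], transcript_id=transcript_id, condition=condition)
    coverage, mutated = _counts_to_vectors(df, length)
    mask = coverage > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(mask, mutated / np.maximum(coverage, 1), np.nan)
    return rate, mask


def pseudobulk(
    counts: BaseCountMatrix,
    cells: set[str] | list[str],
    transcript_id: str,
    condition: str,
    length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled mutation rate over a cell set: sum counts, then divide.

    Summing counts before dividing weights each cell by its coverage,
    matching how a merged library of the same reads would behave; it is
    not the mean of per-cell rates.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("pseudobulk requires a nonempty cell set")
    df = counts.subset(cells=cells, transcript_id=transcript_id, condition=condition)
    coverage, mutated = _counts_to_vectors(df, length)
    mask = coverage > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(mask, mutated / np.maximum(coverage, 1), np.nan)
    return rate, mask


# ---------------------------------------------------------------------------
# Cell quality control
# ---------------------------------------------------------------------------


@dataclass
class CellQCRecord:
    cell_id: str
    genes_detected: int
    mito_fraction: float
    passed: bool


def cell_qc(
    expression: pd.DataFrame,
    mito_gene_set: set[str],
    min_genes: int = DEFAULT_MIN_GENES,
    max_mito: float = DEFAULT_MAX_MITO,
) -> list[CellQCRecord]:
    """Flag cells passing the detected-genes and mitochondrial filters.

    A cell passes when it has at least ``min_genes`` genes with
    expression > 0 AND a mitochondrial expression fraction of at most
    ``max_mito``.  Both bounds are inclusive: the published filter removes
    cells with *fewer than* 5,000 genes or *more than* 5% mitochondrial
    signal, so a cell at exactly 5,000 genes and exactly 5.0% passes.

    ``mito_fraction`` is computed from whatever the expression table
    carries (reads, TPM, normalized counts); the choice of denominator is
    the caller's, via the table supplied.
    """
    if not mito_gene_set:
        raise ValueError("mito_gene_set must be nonempty")
    records = []
    for cell_id, sub in expression.groupby("cell_id", sort=True):
        detected = int((sub["expression"] > 0).sum())
        total = float(sub["expression"].sum())
        mito = float(sub.loc[sub["gene_id"].isin(mito_gene_set), "expression"].sum())
        mito_fraction = mito / total if total > 0 else 0.0
        passed = detected >= min_genes and mito_fraction <= max_mito
        records.append(CellQCRecord(str(cell_id), detected, mito_fraction, passed))
    return records


def qc_table(records: list[CellQCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.cell_id, r.genes_detected, r.mito_fraction, r.passed) for r in records],
        columns=["cell_id", "genes_detected", "mito_fraction", "passed"],
    )


# ---------------------------------------------------------------------------
# Reactivity
# ---------------------------------------------------------------------------


@dataclass
class ReactivityProfile:
    """Per-base reactivity of one transcript in one cell or pseudobulk."""

    transcript_id: str
    source: str
    reactivity: np.ndarray
    mask: np.ndarray
    treated_rate: np.ndarray | None = None
    control_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.reactivity = np.asarray(self.reactivity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.reactivity.shape != self.mask.shape:
            raise ValueError("reactivity/mask shape mismatch")
        # masked positions carry no value
        self.reactivity = _masked(self.reactivity, self.mask)

    def __len__(self) -> int:
        return len(self.reactivity)


def compute_reactivity(
    treated_rate: np.ndarray,
    treated_mask: np.ndarray,
    control_rate: np.ndarray,
    control_mask: np.ndarray,
    transcript_id: str = "",
    source: str = "",
    clamp: bool = False,
) -> ReactivityProfile:
    """Reactivity = treated − control rate on the mask intersection.

    ``clamp=True`` truncates negative differences at zero.
    """
    treated_rate = np.asarray(treated_rate, dtype=float)
    control_rate = np.asarray(control_rate, dtype=float)
    if treated_rate.shape != control_rate.shape:
        raise ValueError(
            f"rate vectors disagree in length: {treated_rate.shape} vs {control_rate.shape}"
        )
    mask = np.asarray(treated_mask, bool) & np.asarray(control_mask, bool)
    with np.errstate(invalid="ignore"):
        delta = treated_rate - control_rate
    if clamp:
        delta = np.maximum(delta, 0.0)
    return ReactivityProfile(
        transcript_id,
        source,
        _masked(delta, mask),
        mask,
        treated_rate=_masked(treated_rate, mask),
        control_rate=_masked(control_rate, mask),
    )


def cell_reactivity_profile(
    counts: BaseCountMatrix,
    cell: str,
    transcript_id: str,
    control_cells: list[str] | None = None,
    length: int | None = None,
    clamp: bool = False,
) -> ReactivityProfile:
    """Reactivity profile of one cell.

    If the cell has its own control-channel counts those are used;
    otherwise the control rate is the pseudobulk over ``control_cells``
    (treated and control are typically disjoint cell populations, so a
    single treated cell has no matched control of its own).
    """
    t_rate, t_mask = mutation_rate(counts, cell, transcript_id, "treated", length)
    own_control = counts.subset(cells=[cell], transcript_id=transcript_id, condition="control")
    if len(own_control):
        c_rate, c_mask = mutation_rate(counts, cell, transcript_id, "control", length=len(t_rate))
    else:
        if not control_cells:
            raise ValueError(
                f"cell {cell!r} has no control channel and no control_cells given; "
                "the mock/DMSO channel is required for reactivity"
            )
        c_rate, c_mask = pseudobulk(counts, control_cells, transcript_id, "control", length=len(t_rate))
    n = max(len(t_rate), len(c_rate))
    t_rate, t_mask = _pad(t_rate, n), _pad_bool(t_mask, n)
    c_rate, c_mask = _pad(c_rate, n), _pad_bool(c_mask, n)
    return compute_reactivity(
        t_rate, t_mask, c_rate, c_mask, transcript_id=transcript_id, source=cell, clamp=clamp
    )


def _pad(v: np.ndarray, n: int) -> np.ndarray:
    if len(v) == n:
        return v
    out = np.full(n, np.nan)
    out[: len(v)] = v
    return out


def _pad_bool(v: np.ndarray, n: int) -> np.ndarray:
    if len(v) == n:
        return v
    out = np.zeros(n, dtype=bool)
    out[: len(v)] = v
    return out


def group_delta_reactivity(
    counts: BaseCountMatrix,
    cells_a: list[str],
    cells_b: list[str],
    transcript_id: str,
    condition: str = "treated",
    length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudobulk(A) − pseudobulk(B) rate difference on the mask intersection.

    Used e.g. to contrast cell-cycle groups; groups must be disjoint.
    """
    overlap = set(cells_a) & set(cells_b)
    if overlap:
        raise ValueError(f"cell groups overlap: {sorted(overlap)[:5]}")
    if not cells_a or not cells_b:
        raise ValueError("both cell groups must be nonempty")
    rate_a, mask_a = pseudobulk(counts, cells_a, transcript_id, condition, length)
    rate_b, mask_b = pseudobulk(counts, cells_b, transcript_id, condition, length)
    n = max(len(rate_a), len(rate_b))
    rate_a, mask_a = _pad(rate_a, n), _pad_bool(mask_a, n)
    rate_b, mask_b = _pad(rate_b, n), _pad_bool(mask_b, n)
    mask = mask_a & mask_b
    return _masked(rate_a - rate_b, mask), mask


# ---------------------------------------------------------------------------
# Normalizations
# ---------------------------------------------------------------------------


def gene_level_normalize(
    profile: ReactivityProfile,
) -> tuple[ReactivityProfile, float]:
    """Within-transcript 2–8% normalization.

    The standard SHAPE scaling: drop the top 2% of reactivities as
    outliers, divide every value by the mean of the next 8%.  Returns the
    normalized profile and the scale factor.  Requires >= 10 unmasked
    positions; a nonpositive normalizer flags a degenerate profile.
    """
    values = profile.reactivity[profile.mask]
    n = len(values)
    if n < 10:
        raise ValueError(f"need >= 10 unmasked positions, got {n}")
    order = np.sort(values)[::-1]
    n_top = int(np.ceil(0.02 * n))
    n_norm = int(np.ceil(0.08 * n))
    normalizer = float(np.mean(order[n_top : n_top + n_norm]))
    if normalizer <= 0:
        raise ValueError(
            f"degenerate profile: 2-8%% normalizer {normalizer:.4g} is nonpositive"
        )
    out = ReactivityProfile(
        profile.transcript_id,
        profile.source,
        profile.reactivity / normalizer,
        profile.mask,
        treated_rate=profile.treated_rate,
        control_rate=profile.control_rate,
    )
    return out, normalizer


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize a cells × positions reactivity matrix.

    NaN marks masked entries.  Each cell's unmasked values are replaced by
    the cross-cell mean quantile curve evaluated at the value's rank
    (average rank for ties, so tied values receive the average of the
    reference values over the tied ranks).  Cells may cover different
    position sets; the reference curve is built by linear interpolation of
    each cell's empirical quantile function on a common grid.  Cells with
    no unmasked positions are excluded with a warning and returned
    untouched (all NaN).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 cells")
    n_cells = matrix.shape[0]
    usable = [i for i in range(n_cells) if np.isfinite(matrix[i]).any()]
    if len(usable) < len(range(n_cells)):
        warnings.warn(
            f"{n_cells - len(usable)} cell(s) with no unmasked positions excluded "
            "from quantile normalization"
        )
    if len(usable) < 2:
        raise ValueError("fewer than 2 cells with data")
    grid_size = max(int(np.isfinite(matrix[i]).sum()) for i in usable)
    grid = np.linspace(0.0, 1.0, grid_size) if grid_size > 1 else np.array([0.5])
    # mean of per-cell empirical quantile functions = reference distribution
    curves = []
    for i in usable:
        vals = matrix[i][np.isfinite(matrix[i])]
        curves.append(np.quantile(vals, grid))
    reference = np.mean(curves, axis=0)
    out = np.full_like(matrix, np.nan)
    for i in usable:
        finite = np.isfinite(matrix[i])
        vals = matrix[i][finite]
        m = len(vals)
        ranks = pd.Series(vals).rank(method="average").to_numpy() - 1.0
        q = ranks / (m - 1) if m > 1 else np.full(m, 0.5)
        out[i, finite] = np.interp(q, grid, reference)
    return out


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------


def subsample_counts(
    counts: BaseCountMatrix,
    fraction: float,
    seed: int,
) -> BaseCountMatrix:
    """Binomially thin every record to a fraction of its reads.

    Each read is retained independently with probability ``fraction``;
    given the retained coverage, the retained mutated reads are drawn
    hypergeometrically (reads are exchangeable, so thinning coverage and
    mutations jointly preserves the expected mutation rate).
    Deterministic under a fixed seed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    df = counts.data.copy()
    cov = df["coverage"].to_numpy()
    mut = df["mutated"].to_numpy()
    if fraction == 1.0:
        return BaseCountMatrix(df)
    new_cov = rng.binomial(cov, fraction)
    # ngood = mutated reads, nbad = clean reads, nsample = retained coverage
    new_mut = np.zeros_like(mut)
    idx = new_cov > 0
    new_mut[idx] = rng.hypergeometric(mut[idx], (cov - mut)[idx], new_cov[idx])
    df["coverage"] = new_cov
    df["mutated"] = new_mut
    return BaseCountMatrix(df)


def subsample_to_depth(
    counts: BaseCountMatrix,
    target_depth: int,
    seed: int,
) -> BaseCountMatrix:
    """Thin each transcript's reads down to a total target depth.

    Used to bring abundant transcripts to a common depth (e.g. the median
    depth of detectable transcripts) before comparing statistics.  The
    per-transcript retention probability is target / current total
    coverage; a target above every transcript's depth is an error.
    """
    totals = counts.data.groupby("transcript_id")["coverage"].sum()
    if (target_depth > totals).all():
        raise ValueError(
            f"target depth {target_depth} exceeds every transcript's total coverage"
        )
    rng = np.random.default_rng(seed)
    pieces = []
    for i, (tx, sub) in enumerate(counts.data.groupby("transcript_id", sort=True)):
        frac = min(1.0, target_depth / max(int(totals[tx]), 1))
        thinned = subsample_counts(
            BaseCountMatrix(sub.reset_index(drop=True)),
            frac,
            int(rng.integers(0, 2**31 - 1)),
        )
        pieces.append(thinned.data)
    return BaseCountMatrix(pd.concat(pieces, ignore_index=True))
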