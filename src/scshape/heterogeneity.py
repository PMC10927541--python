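"""Structural-heterogeneity statistics at window and gene level.

Window level
------------
The transcriptome is tiled into non-overlapping 10-nt windows.  For each
window s and cell c let ``depth(c, s)`` be the summed read coverage and
``mutant(c, s)`` the summed mutated reads over the window.  If every cell
modifies the window at the same rate, the points (depth, mutant) lie on a
line through the origin with slope equal to that rate; cell-to-cell
structural variation scatters them.  We fit the linear model

    mutant(c, s) = mod(s) * depth(c, s) + eps

by ordinary least squares (with intercept, matching the regression routine
the statistic was defined with) and use the adjusted R² as the
homogeneity measure: near 1 = one shared conformation, near 0 =
heterogeneous.  The adjustment 1 − (1 − R²)(n − 1)/(n − 2) accounts for
the varying number of cells a window is detected in.

Gene level
----------
Per-cell reactivity profiles (quantile-normalized by the caller) are
compared to the pseudobulk profile by cosine distance
D_i = 1 − cos(R_i, R_pseudo); the transcript's heterogeneity is the RMS
dispersion sqrt(mean D_i²).

Also here: quartile classification, UTR/CDS region assignment, metagene
enrichment around start/stop codons, DTW k-means trajectory clustering,
and per-window covariates (GC, mean reactivity, coverage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .io import BaseCountMatrix, RegionAnnotation
from .reactivity import ReactivityProfile

DEFAULT_WINDOW_SIZE = 10
DEFAULT_MIN_WINDOW_READS = 600
DEFAULT_MIN_CELL_FRACTION = 0.5


# ---------------------------------------------------------------------------
# Window tiling and filtering
# ---------------------------------------------------------------------------


@dataclass
class WindowCountVector:
    """Aggregated per-cell counts for one tiled window."""

    transcript_id: str
    window_start: int
    window_end: int
    cells: list[str]
    depth: np.ndarray   # summed coverage per cell over the window
    mutant: np.ndarray  # summed mutated reads per cell
    detected: bool = False

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.mutant = np.asarray(self.mutant, dtype=np.int64)
        if np.any(self.mutant > self.depth):
            raise ValueError(
                f"window {self.transcript_id}:{self.window_start}: mutant > depth"
            )

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.transcript_id, self.window_start, self.window_end)

    @property
    def total_coverage(self) -> int:
        return int(self.depth.sum())


def tile_windows(
    counts: BaseCountMatrix,
    transcript_id: str,
    transcript_length: int,
    window_size: int = DEFAULT_WINDOW_SIZE,
    condition: str = "treated",
) -> list[WindowCountVector]:
    """Tile a transcript into consecutive non-overlapping windows.

    The grid is anchored at position 0; a trailing partial window is
    dropped.  Per-cell depth and mutant counts are summed over the window
    positions (uncovered positions contribute 0).
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    df = counts.subset(transcript_id=transcript_id, condition=condition)
    cells = sorted(counts.data["cell_id"].unique())
    cell_index = {c: i for i, c in enumerate(cells)}
    n_windows = transcript_length // window_size
    depth = np.zeros((n_windows, len(cells)), dtype=np.int64)
    mutant = np.zeros((n_windows, len(cells)), dtype=np.int64)
    if len(df):
        w = df["position"].to_numpy() // window_size
        keep = w < n_windows
        ci = df["cell_id"].map(cell_index).to_numpy()
        np.add.at(depth, (w[keep], ci[keep]), df["coverage"].to_numpy()[keep])
        np.add.at(mutant, (w[keep], ci[keep]), df["mutated"].to_numpy()[keep])
    return [
        WindowCountVector(
            transcript_id,
            i * window_size,
            (i + 1) * window_size,
            cells,
            depth[i],
            mutant[i],
        )
        for i in range(n_windows)
    ]


def filter_windows(
    windows: list[WindowCountVector],
    total_cells: int,
    min_total_reads: int = DEFAULT_MIN_WINDOW_READS,
    min_cell_fraction: float = DEFAULT_MIN_CELL_FRACTION,
) -> list[WindowCountVector]:
    """Set the ``detected`` flag on each window (in place; list returned).

    A window is detected in a cell when its depth there is positive, and
    detected overall when total coverage is *strictly greater* than
    ``min_total_reads`` (the published cutoff is "more than 600 reads")
    and the detected-cell fraction is at least ``min_cell_fraction``.
    """
    if total_cells < 1:
        raise ValueError("total_cells must be >= 1")
    for w in windows:
        n_detected = int((w.depth > 0).sum())
        w.detected = (
            w.total_coverage > min_total_reads
            and n_detected / total_cells >= min_cell_fraction
        )
    return windows


# ---------------------------------------------------------------------------
# Window-level heterogeneity (adjusted R² of the linear model)
# ---------------------------------------------------------------------------


@dataclass
class WindowHeterogeneityRecord:
    transcript_id: str
    window_start: int
    window_end: int
    n_cells: int
    fitted_modification_rate: float
    r_squared: float
    adj_r_squared: float
    detected: bool
    defined: bool
    residuals: np.ndarray | None = None

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.transcript_id, self.window_start, self.window_end)


MIN_CELLS_FOR_FIT = 4  # adj R² denominator n − 2 needs headroom


def window_heterogeneity(
    window: WindowCountVector,
    keep_residuals: bool = False,
) -> WindowHeterogeneityRecord:
    """Fit mutant ~ depth across cells; adjusted R² is the homogeneity score.

    Only cells where the window has coverage enter the fit.  Results are
    flagged undefined (never coerced to 0 or 1) when fewer than four such
    cells exist or the depths have zero variance.
    """
    covered = window.depth > 0
    depth = window.depth[covered].astype(float)
    mutant = window.mutant[covered].astype(float)
    n = len(depth)

    def _undefined() -> WindowHeterogeneityRecord:
        return WindowHeterogeneityRecord(
            window.transcript_id,
            window.window_start,
            window.window_end,
            n,
            np.nan,
            np.nan,
            np.nan,
            window.detected,
            defined=False,
        )

    if n < MIN_CELLS_FOR_FIT:
        return _undefined()
    if np.ptp(depth) == 0 or np.ptp(mutant) == 0:
        return _undefined()
    fit = stats.linregress(depth, mutant)
    r2 = fit.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    residuals = mutant - (fit.intercept + fit.slope * depth) if keep_residuals else None
    return WindowHeterogeneityRecord(
        window.transcript_id,
        window.window_start,
        window.window_end,
        n,
        float(fit.slope),
        float(r2),
        float(adj_r2),
        window.detected,
        defined=True,
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# Gene-level heterogeneity (cosine dispersion)
# ---------------------------------------------------------------------------


@dataclass
class GeneHeterogeneityRecord:
    transcript_id: str
    cell_ids: list[str]
    cosine_distances: np.ndarray
    heterogeneity: float

    @property
    def n(self) -> int:
        return len(self.cosine_distances)


MIN_SHARED_POSITIONS = 10


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 − cosine similarity; in [0, 2] for real vectors."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ZeroDivisionError("zero-norm vector in cosine distance")
    return float(1.0 - np.dot(a, b) / (na * nb))


def gene_heterogeneity(
    profiles: list[ReactivityProfile],
    pseudobulk_profile: ReactivityProfile,
    min_shared: int = MIN_SHARED_POSITIONS,
) -> GeneHeterogeneityRecord:
    """RMS cosine-distance dispersion of per-cell profiles vs pseudobulk.

    For each cell, the distance D_i = 1 − cos(R_i, R_pseudo) is computed
    over the positions unmasked in both that cell and the pseudobulk
    (cells may cover different positions).  Heterogeneity =
    sqrt(sum D_i² / n).  Cells with a zero-norm restricted vector or too
    few shared positions are excluded with a warning; fewer than two
    usable cells is an error.  Profiles are expected to be
    quantile-normalized by the caller.
    """
    distances, used = [], []
    for prof in profiles:
        if prof.transcript_id != pseudobulk_profile.transcript_id:
            raise ValueError(
                f"transcript mismatch: {prof.transcript_id} vs "
                f"{pseudobulk_profile.transcript_id}"
            )
        shared = prof.mask & pseudobulk_profile.mask
        if int(shared.sum()) < min_shared:
            warnings.warn(
                f"cell {prof.source}: only {int(shared.sum())} positions shared "
                f"with pseudobulk (< {min_shared}); excluded"
            )
            continue
        a = prof.reactivity[shared]
        b = pseudobulk_profile.reactivity[shared]
        try:
            d = cosine_distance(a, b)
        except ZeroDivisionError:
            warnings.warn(f"cell {prof.source}: zero-norm profile; excluded")
            continue
        distances.append(d)
        used.append(prof.source)
    if len(distances) < 2:
        raise ValueError(f"fewer than 2 usable cells ({len(distances)})")
    d = np.asarray(distances)
    return GeneHeterogeneityRecord(
        pseudobulk_profile.transcript_id,
        used,
        d,
        float(np.sqrt(np.mean(d**2))),
    )


# ---------------------------------------------------------------------------
# Quantile classification
# ---------------------------------------------------------------------------


class HeterogeneityClass(str, Enum):
    HOMOGENEOUS = "homogeneous"
    INTERMEDIATE = "intermediate"
    HETEROGENEOUS = "heterogeneous"


def classify_quantiles(values: np.ndarray) -> list[HeterogeneityClass]:
    """Quartile-bin items by heterogeneity.

    Bottom quartile (least heterogeneous) → homogeneous, top quartile →
    heterogeneous, middle half → intermediate.  Boundaries use
    linear-interpolation percentiles; values exactly at a boundary go to
    the extreme class.  If every value is equal the classes are undecidable
    and everything is intermediate, with a warning.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError(f"need >= 4 items, got {len(values)}")
    q25, q75 = np.percentile(values, [25, 75])
    if q25 == q75:
        warnings.warn("degenerate heterogeneity distribution (q25 == q75); "
                      "all items classed intermediate")
        return [HeterogeneityClass.INTERMEDIATE] * len(values)
    out = []
    for v in values:
        if v <= q25:
            out.append(HeterogeneityClass.HOMOGENEOUS)
        elif v >= q75:
            out.append(HeterogeneityClass.HETEROGENEOUS)
        else:
            out.append(HeterogeneityClass.INTERMEDIATE)
    return out


# ---------------------------------------------------------------------------
# Region assignment and metagene enrichment
# ---------------------------------------------------------------------------


class Region(str, Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    CDS = "cds"
    THREE_PRIME_UTR = "three_prime_utr"


def assign_region(
    window_start: int, window_end: int, annotation: RegionAnnotation
) -> Region:
    """Region of the window midpoint relative to the CDS (half-open)."""
    if annotation is None:
        raise ValueError("missing region annotation")
    mid = (window_start + window_end) // 2
    if not 0 <= mid < annotation.transcript_length:
        raise ValueError(
            f"window midpoint {mid} outside transcript "
            f"[0, {annotation.transcript_length})"
        )
    if mid < annotation.cds_start:
        return Region.FIVE_PRIME_UTR
    if mid < annotation.cds_end:
        return Region.CDS
    return Region.THREE_PRIME_UTR


def metagene_enrichment(
    interest_windows: list[tuple[str, int, int]],
    all_windows: list[tuple[str, int, int]],
    annotations: dict[str, RegionAnnotation],
    anchor: str = "start_codon",
    n_bins: int = 20,
    span: int = 300,
) -> pd.DataFrame:
    """Positional enrichment of a window class around the start/stop codon.

    Windows are placed by midpoint offset from the anchor, binned over
    [−span, +span).  Per bin, the one-sided (upper-tail) hypergeometric
    test asks whether the interest set over-represents that bin: with N =
    anchored background windows, K of them in the bin, n = anchored
    interest windows and k observed, p = P(X ≥ k).  Empty bins report
    density 0 and p = 1.
    """
    if not interest_windows or not all_windows:
        raise ValueError("both window sets must be nonempty")
    if anchor not in ("start_codon", "stop_codon"):
        raise ValueError(f"unknown anchor {anchor!r}")

    def offsets(windows):
        out = []
        for tx, start, end in windows:
            ann = annotations.get(tx)
            if ann is None:
                continue
            a = ann.cds_start if anchor == "start_codon" else ann.cds_end
            out.append((start + end) // 2 - a)
        return np.asarray(out)

    off_all = offsets(all_windows)
    off_int = offsets(interest_windows)
    edges = np.linspace(-span, span, n_bins + 1)
    in_all = (off_all >= -span) & (off_all < span)
    in_int = (off_int >= -span) & (off_int < span)
    big_n = int(in_all.sum())
    little_n = int(in_int.sum())
    counts_all, _ = np.histogram(off_all[in_all], bins=edges)
    counts_int, _ = np.histogram(off_int[in_int], bins=edges)
    rows = []
    for b in range(n_bins):
        big_k, k = int(counts_all[b]), int(counts_int[b])
        if big_k == 0:
            density, p = 0.0, 1.0
        else:
            from .enrichment import hypergeom_upper_tail

            density = k / little_n if little_n else 0.0
            p = hypergeom_upper_tail(k, big_n, big_k, little_n)
        rows.append((edges[b], edges[b + 1], big_k, k, density, p))
    return pd.DataFrame(
        rows,
        columns=["bin_start", "bin_end", "n_background", "n_interest", "density", "p_value"],
    )


# ---------------------------------------------------------------------------
# Dynamic-time-warping k-means for heterogeneity trajectories
# ---------------------------------------------------------------------------


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic dynamic-time-warping distance with squared local cost.

    Returns sqrt of the minimal summed squared difference along a
    monotone alignment path (standard step pattern: match, insert,
    delete).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            acc[i, j] = cost + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    return float(np.sqrt(acc[n, m]))


def _dtw_path(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Optimal alignment path for DTW (used by barycenter averaging)."""
    n, m = len(a), len(b)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            acc[i, j] = cost + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        step = np.argmin([acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]])
        if step == 0:
            i, j = i - 1, j - 1
        elif step == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    return path


def dtw_barycenter(series: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """DTW barycenter averaging (DBA): iterative alignment-and-average."""
    series = np.asarray(series, dtype=float)
    center = series.mean(axis=0)
    for _ in range(n_iter):
        sums = np.zeros_like(center)
        counts = np.zeros(len(center))
        for s in series:
            for ci, si in _dtw_path(center, s):
                sums[ci] += s[si]
                counts[ci] += 1
        new_center = np.where(counts > 0, sums / np.maximum(counts, 1), center)
        if np.allclose(new_center, center):
            break
        center = new_center
    return center


def cluster_trajectories(
    trajectories: np.ndarray,
    k: int = 6,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 30,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means under DTW distance with DBA centroids.

    ``trajectories`` is windows × stages (every window valued at every
    stage).  Runs ``n_restarts`` seeded restarts and keeps the labeling
    with the lowest within-cluster inertia (sum of squared DTW
    distances).  Returns (labels, centroids, inertia); deterministic
    under a fixed seed.
    """
    trajectories = np.asarray(trajectories, dtype=float)
    n = len(trajectories)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of trajectories ({n})")
    if not np.all(np.isfinite(trajectories)):
        raise ValueError("every trajectory must have a value at every stage")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers = trajectories[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for it in range(max_iter):
            dists = np.array(
                [[dtw_distance(t, c) for c in centers] for t in trajectories]
            )
            new_labels = dists.argmin(axis=1)
            if it > 0 and np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = trajectories[labels == j]
                if len(members):
                    centers[j] = dtw_barycenter(members)
        inertia = float(
            sum(dtw_distance(trajectories[i], centers[labels[i]]) ** 2 for i in range(n))
        )
        if best is None or inertia < best[2]:
            best = (labels.copy(), centers.copy(), inertia)
    return best


def cluster_cells_by_reactivity(
    profiles: list[ReactivityProfile],
    k: int,
    seed: int = 0,
    min_shared: int = MIN_SHARED_POSITIONS,
) -> np.ndarray:
    """k-means clustering of cells by their reactivity vectors.

    Profiles are restricted to the common unmasked position set (must
    hold >= ``min_shared`` positions).  Deterministic under the seed.
    """
    from sklearn.cluster import KMeans

    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the number of cells ({len(profiles)})")
    common = profiles[0].mask.copy()
    for p in profiles[1:]:
        common &= p.mask
    if int(common.sum()) < min_shared:
        raise ValueError(
            f"only {int(common.sum())} positions shared across cells (< {min_shared})"
        )
    X = np.vstack([p.reactivity[common] for p in profiles])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(X)


# ---------------------------------------------------------------------------
# Window covariates
# ---------------------------------------------------------------------------


def window_correlates(
    window: WindowCountVector,
    sequence: str,
    reactivity: np.ndarray | None = None,
    reactivity_mask: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """(GC fraction, mean reactivity over unmasked positions, total coverage).

    Mean reactivity is NaN when no unmasked position falls in the window
    or no profile is supplied.
    """
    if len(sequence) < window.window_end:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than window end {window.window_end}"
        )
    sub = sequence[window.window_start : window.window_end].upper()
    gc = sum(c in "GC" for c in sub) / len(sub)
    mean_react = np.nan
    if reactivity is not None and reactivity_mask is not None:
        sl = slice(window.window_start, window.window_end)
        m = reactivity_mask[sl]
        if m.any():
            mean_react = float(np.mean(reactivity[sl][m]))
    return gc, mean_react, window.total_coverage


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def window_table(records: list[WindowHeterogeneityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.transcript_id,
                r.window_start,
                r.window_end,
                r.n_cells,
                r.fitted_modification_rate,
                r.r_squared,
                r.adj_r_squared,
                r.detected,
                r.defined,
            )
            for r in records
        ],
        columns=[
            "transcript_id",
            "start",
            "end",
            "n_cells",
            "slope",
            "r2",
            "adj_r2",
            "detected",
            "defined",
        ],
    )


def gene_table(records: list[GeneHeterogeneityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.transcript_id, r.n, r.heterogeneity) for r in records],
        columns=["transcript_id", "n", "heterogeneity"],
    )
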