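"""Synthetic single-cell structure-probing data with known ground truth.

The generative model mirrors the measurement process: each cell draws one
conformation per transcript from a mixture; read coverage per base follows
a negative binomial (single-cell depth is overdispersed) whose mean decays
exponentially with distance from the 3′ end (library prep reads ~1 kb from
the 3′ end); treated-channel mutated reads are Binomial(coverage,
modification probability + background error, capped at 1) and
control-channel reads Binomial(coverage, background error).  Whole
cell × transcript observations drop out with a configurable probability.

Modification probabilities sit in the low-percent range typical of
mutational-profiling chemistry (a few percent at reactive bases), so the
statistics downstream operate in a realistic counting regime.

Every output is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BaseCountMatrix, ReferenceStructure

DEFAULT_CONTROL_ERROR = 0.002
DEFAULT_MEAN_DEPTH = 100.0
DEFAULT_DECAY_PER_BASE = 1.0 / 1000.0   # 3'-bias decay constant
DEFAULT_NB_DISPERSION = 10.0            # NB size; larger = closer to Poisson
DEFAULT_DROPOUT = 0.1


@dataclass
class TranscriptSpec:
    transcript_id: str
    length: int
    # per-conformation per-position modification probabilities
    conformations: list[np.ndarray]
    weights: np.ndarray
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.conformations = [np.asarray(c, dtype=float) for c in self.conformations]
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.conformations):
            raise ValueError("one weight per conformation required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("conformation weights must sum to 1")
        for c in self.conformations:
            if len(c) != self.length:
                raise ValueError("conformation vector length != transcript length")
            if np.any((c < 0) | (c > 1)):
                raise ValueError("modification probabilities must be in [0, 1]")


@dataclass
class SimulationConfig:
    n_cells: int
    transcripts: list[TranscriptSpec]
    control_error_rate: float = DEFAULT_CONTROL_ERROR
    mean_depth: float = DEFAULT_MEAN_DEPTH
    decay_per_base: float = DEFAULT_DECAY_PER_BASE
    nb_dispersion: float = DEFAULT_NB_DISPERSION
    dropout: float = DEFAULT_DROPOUT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for p in (self.control_error_rate, self.dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.mean_depth <= 0 or self.nb_dispersion <= 0:
            raise ValueError("mean_depth and nb_dispersion must be positive")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated counts."""

    # (cell_id, transcript_id) -> conformation index
    conformation: dict[tuple[str, str], int]
    # (transcript_id, window_start) -> "homogeneous" | "heterogeneous"
    window_labels: dict[tuple[str, int], str]
    # transcript_id -> conformations (list of per-position probability vectors)
    modification_probs: dict[str, list[np.ndarray]] = field(default_factory=dict)


def _coverage_means(length: int, mean_depth: float, decay: float) -> np.ndarray:
    # highest coverage at the 3' end, exponential decay toward 5'
    dist_from_3p = np.arange(length)[::-1]
    return mean_depth * np.exp(-decay * dist_from_3p)


def _window_truth_labels(
    spec: TranscriptSpec, window_size: int = 10
) -> dict[tuple[str, int], str]:
    labels = {}
    for start in range(0, spec.length - window_size + 1, window_size):
        sl = slice(start, start + window_size)
        segs = [c[sl] for c in spec.conformations]
        homogeneous = all(np.array_equal(segs[0], s) for s in segs[1:])
        labels[(spec.transcript_id, start)] = (
            "homogeneous" if homogeneous else "heterogeneous"
        )
    return labels


def simulate_counts(
    config: SimulationConfig,
) -> tuple[BaseCountMatrix, BaseCountMatrix, SimTruth]:
    """Draw (treated, control) base-count matrices and the ground truth.

    Both channels are generated for every cell with independent coverage
    draws; positions with zero coverage are omitted from the tables
    (they are unobserved).
    """
    rng = np.random.default_rng(config.seed)
    cell_ids = [f"cell{str(i).zfill(3)}" for i in range(config.n_cells)]
    truth = SimTruth({}, {}, {})
    treated_rows, control_rows = [], []
    for spec in config.transcripts:
        truth.window_labels.update(_window_truth_labels(spec))
        truth.modification_probs[spec.transcript_id] = spec.conformations
        means = _coverage_means(spec.length, config.mean_depth, config.decay_per_base)
        nb_n = config.nb_dispersion
        nb_p = nb_n / (nb_n + means)
        positions = np.arange(spec.length)
        for cell in cell_ids:
            conf_idx = int(rng.choice(len(spec.conformations), p=spec.weights))
            truth.conformation[(cell, spec.transcript_id)] = conf_idx
            mod = spec.conformations[conf_idx]
            p_treated = np.minimum(mod + config.control_error_rate, 1.0)
            for condition, p_mut, rows in (
                ("treated", p_treated, treated_rows),
                ("control", np.full(spec.length, config.control_error_rate), control_rows),
            ):
                if rng.random() < config.dropout:
                    continue
                coverage = rng.negative_binomial(nb_n, nb_p)
                mutated = rng.binomial(coverage, p_mut)
                keep = coverage > 0
                if keep.any():
                    rows.append(
                        pd.DataFrame(
                            {
                                "cell_id": cell,
                                "transcript_id": spec.transcript_id,
                                "position": positions[keep],
                                "coverage": coverage[keep],
                                "mutated": mutated[keep],
                                "condition": condition,
                            }
                        )
                    )
    columns = ["cell_id", "transcript_id", "position", "coverage", "mutated", "condition"]
    empty = pd.DataFrame(columns=columns)
    treated = BaseCountMatrix(
        pd.concat(treated_rows, ignore_index=True) if treated_rows else empty.copy()
    )
    control = BaseCountMatrix(
        pd.concat(control_rows, ignore_index=True) if control_rows else empty.copy()
    )
    return treated, control, truth


def merge_channels(treated: BaseCountMatrix, control: BaseCountMatrix) -> BaseCountMatrix:
    """Combine the two channel tables into one matrix."""
    return BaseCountMatrix(pd.concat([treated.data, control.data], ignore_index=True))


# ---------------------------------------------------------------------------
# Canned panels for recovery experiments
# ---------------------------------------------------------------------------


def make_two_conformation_panel(
    n_windows_homogeneous: int = 100,
    n_windows_heterogeneous: int = 100,
    rate_gap: float = 0.1,
    base_rate: float = 0.03,
    n_cells: int = 40,
    mean_depth: float = 1000.0,
    seed: int = 0,
    window_size: int = 10,
    dropout: float = 0.0,
) -> tuple[SimulationConfig, SimTruth]:
    """Two-conformation mixture panel with labeled windows.

    One transcript carries all windows.  Homogeneous windows have
    identical modification profiles in both conformations; heterogeneous
    windows differ by ``rate_gap`` at 5 of their 10 positions (alternating
    which conformation carries the higher rate).  Cells draw the two
    conformations 50/50.  A ``rate_gap`` of 0 makes every window
    effectively homogeneous, and the truth labels say so.
    """
    if not 0.0 <= rate_gap <= 0.15:
        raise ValueError("rate_gap must be in [0, 0.15]")
    rng = np.random.default_rng(seed)
    n_windows = n_windows_homogeneous + n_windows_heterogeneous
    length = n_windows * window_size
    rates_a = np.full(length, base_rate)
    rates_b = np.full(length, base_rate)
    kinds = ["homogeneous"] * n_windows_homogeneous + [
        "heterogeneous"
    ] * n_windows_heterogeneous
    rng.shuffle(kinds)
    half = window_size // 2
    for w, kind in enumerate(kinds):
        start = w * window_size
        # small per-window jitter so windows are not carbon copies
        jitter = rng.uniform(-0.005, 0.005, size=window_size)
        rates_a[start : start + window_size] += jitter
        rates_b[start : start + window_size] += jitter
        if kind == "heterogeneous" and rate_gap > 0:
            hot = rng.choice(window_size, size=half, replace=False)
            rates_b[start + hot] += rate_gap
    rates_a = np.clip(rates_a, 0.0, 1.0)
    rates_b = np.clip(rates_b, 0.0, 1.0)
    spec = TranscriptSpec(
        "panel_tx", length, [rates_a, rates_b], np.array([0.5, 0.5])
    )
    config = SimulationConfig(
        n_cells=n_cells,
        transcripts=[spec],
        mean_depth=mean_depth,
        decay_per_base=0.0,  # flat coverage: the panel isolates heterogeneity
        dropout=dropout,
        seed=seed,
    )
    truth = SimTruth({}, _window_truth_labels(spec, window_size), {
        spec.transcript_id: spec.conformations
    })
    return config, truth


def make_reference_fixture(
    length: int = 300,
    unpaired_fraction: float = 0.5,
    seed: int = 0,
    unpaired_rate: float = 0.08,
    paired_rate: float = 0.01,
    transcript_id: str = "synthetic_ref",
) -> tuple[ReferenceStructure, np.ndarray]:
    """Random nested structure plus a matched modification profile.

    A synthetic benchmark target: a well-formed nested pairing with the
    requested unpaired fraction; unpaired bases get a high modification
    probability (flexible), paired bases a low one (protected).
    """
    if not 0.0 < unpaired_fraction <= 1.0:
        raise ValueError("unpaired_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_paired = int(round(length * (1.0 - unpaired_fraction)))
    n_paired -= n_paired % 2
    partner = np.full(length, -1, dtype=np.int64)
    if n_paired:
        chosen = np.sort(rng.choice(length, size=n_paired, replace=False))
        # nest the chosen positions: i-th from the left pairs i-th from the right
        for i in range(n_paired // 2):
            a, b = int(chosen[i]), int(chosen[n_paired - 1 - i])
            partner[a], partner[b] = b, a
    structure = ReferenceStructure(transcript_id, partner)
    mod = np.where(partner < 0, unpaired_rate, paired_rate).astype(float)
    return structure, mod
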