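"""Cohesion scoring: per-cell split calls, per-sample aggregates, deficit calls.

Scoring conventions follow the assay definition: a cell with exactly two
scorable centrosomal structures is *split* when their separation is strictly
greater than the split threshold (default 1.3 μm); a sample has a *cohesion
deficit* when the percent of split cells is at or above the deficit threshold
(default 20%, inclusive). In dual-marker mode only structures positive for
both pericentrin and γ-tubulin are scorable ("duplicated centrosome" gating);
in single-marker mode every pericentrin dot counts (the C/C readout covering
both centriole and centrosome cohesion). The percent-splitting denominator is
the set of two-dot cells, since the inter-structure distance only exists when
two structures are present; percent two-dot uses all included cells.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptySampleError, PairingError
from .imaging import CellAssembly

Mode = Literal["dual_marker_duplicated", "single_marker_cc"]

EXCLUSION_REASONS = ("mitotic", "border", "too_large_nucleus",
                     "no_staining", "ambiguous_count", "none")

# Inhibitor dosing carried as annotation only; never enters computation.
MLI2_DOSING = {"LCL": "50 nM, 2 h", "PBMC": "200 nM, 30 min"}


@dataclasses.dataclass
class ScoringConfig:
    mode: Mode = "single_marker_cc"
    split_threshold_um: float = 1.3
    deficit_threshold_pct: float = 20.0
    min_cells: int = 100
    target_cells: tuple[int, int] = (150, 200)
    pbmc_mode: bool = False
    max_nuclear_diameter_um: float = 10.0
    histogram_bin_um: float = 0.2
    ambiguous_policy: Literal["exclude", "two_brightest"] = "exclude"

    def __post_init__(self) -> None:
        if self.split_threshold_um <= 0 or self.histogram_bin_um <= 0:
            raise ConfigurationError("thresholds and bin width must be > 0")
        if not 0 < self.deficit_threshold_pct < 100:
            raise ConfigurationError("deficit_threshold_pct must be in (0, 100)")
        if self.max_nuclear_diameter_um <= 0:
            raise ConfigurationError("max_nuclear_diameter_um must be > 0")


@dataclasses.dataclass
class CellScore:
    """Scoring outcome for one cell."""

    cell_id: int
    n_structures: int
    distance_um: float  # NaN unless exactly two scorable structures
    split: bool
    included: bool
    exclusion_reason: str = "none"


@dataclasses.dataclass
class SampleScore:
    """Per-sample aggregate under one treatment condition."""

    sample_id: str
    condition: str
    n_included: int
    n_two_dot: int
    pct_split: float
    pct_two_dot: float
    mean_distance_um: float
    hist_edges_um: np.ndarray
    hist_counts: np.ndarray
    deficit: bool
    low_n: bool


@dataclasses.dataclass
class ReversalRecord:
    """Inhibitor-reversal outcome for one sample (vehicle vs MLi2)."""

    sample_id: str
    vehicle_pct_split: float
    treated_pct_split: float
    delta: float
    reverted: bool
    vehicle: SampleScore
    treated: SampleScore


def score_cell(assembly: CellAssembly, config: ScoringConfig) -> CellScore:
    """Classify one cell as split / non-split / excluded-with-reason."""
    nucleus = assembly.nucleus
    cell_id = nucleus.label

    if nucleus.mitotic:
        return CellScore(cell_id, 0, math.nan, False, False, "mitotic")
    if nucleus.touches_border:
        return CellScore(cell_id, 0, math.nan, False, False, "border")
    if (config.pbmc_mode
            and nucleus.equivalent_diameter_um >= config.max_nuclear_diameter_um):
        return CellScore(cell_id, 0, math.nan, False, False, "too_large_nucleus")

    if config.mode == "dual_marker_duplicated":
        scorable = [s for s in assembly.structures if s.dual_positive]
    else:
        scorable = list(assembly.structures)

    n = len(scorable)
    if n == 0:
        return CellScore(cell_id, 0, math.nan, False, False, "no_staining")
    if n > 2:
        if config.ambiguous_policy == "two_brightest":
            scorable = sorted(scorable, key=lambda s: -s.quality)[:2]
            n = 2
        else:
            return CellScore(cell_id, n, math.nan, False, False,
                             "ambiguous_count")
    if n == 1:
        return CellScore(cell_id, 1, math.nan, False, True, "none")

    (x1, y1), (x2, y2) = scorable[0].xy, scorable[1].xy
    distance = math.hypot(x2 - x1, y2 - y1)
    return CellScore(cell_id, 2, distance,
                     distance > config.split_threshold_um, True, "none")


def score_cells(assemblies: Iterable[CellAssembly],
                config: ScoringConfig) -> list[CellScore]:
    return [score_cell(a, config) for a in assemblies]


def cell_scores_from_table(table: pd.DataFrame,
                           config: ScoringConfig) -> list[CellScore]:
    """Score cells from a per-cell table (shared schema with ground truth).

    Expected columns: ``cell_id``, ``n_dots`` (or ``n_structures``),
    ``distance_um``; optional ``mitotic``, ``border``,
    ``nuclear_diameter_um`` drive the corresponding exclusions.
    """
    n_col = "n_dots" if "n_dots" in table.columns else "n_structures"
    scores = []
    for row in table.itertuples():
        cell_id = int(getattr(row, "cell_id"))
        if bool(getattr(row, "mitotic", False)):
            scores.append(CellScore(cell_id, 0, math.nan, False, False,
                                    "mitotic"))
            continue
        if bool(getattr(row, "border", False)):
            scores.append(CellScore(cell_id, 0, math.nan, False, False,
                                    "border"))
            continue
        diameter = getattr(row, "nuclear_diameter_um",
                           getattr(row, "diameter_um", math.nan))
        if (config.pbmc_mode and not math.isnan(diameter)
                and diameter >= config.max_nuclear_diameter_um):
            scores.append(CellScore(cell_id, 0, math.nan, False, False,
                                    "too_large_nucleus"))
            continue
        n = int(getattr(row, n_col))
        if n == 0:
            scores.append(CellScore(cell_id, 0, math.nan, False, False,
                                    "no_staining"))
        elif n > 2:
            scores.append(CellScore(cell_id, n, math.nan, False, False,
                                    "ambiguous_count"))
        elif n == 1:
            scores.append(CellScore(cell_id, 1, math.nan, False, True))
        else:
            d = float(getattr(row, "distance_um"))
            scores.append(CellScore(cell_id, 2, d,
                                    d > config.split_threshold_um, True))
    return scores


def call_deficit(pct_split: float, config: ScoringConfig) -> bool:
    """Deficit call: percent splitting at or above the threshold (inclusive)."""
    return bool(pct_split >= config.deficit_threshold_pct)


def score_sample(cell_scores: Sequence[CellScore], config: ScoringConfig,
                 sample_id: str = "sample",
                 condition: str = "vehicle") -> SampleScore:
    """Aggregate per-cell scores into the per-sample readout.

    percent split = 100 × #split / #two-dot cells; percent two-dot =
    100 × #two-dot / #included. The distance histogram (bin width from
    config) covers two-dot cells and its counts sum to their number.
    """
    included = [c for c in cell_scores if c.included]
    if not included:
        raise EmptySampleError(f"sample {sample_id!r} has zero included cells")
    two_dot = [c for c in included if c.n_structures == 2]
    n_split = sum(c.split for c in two_dot)

    pct_two_dot = 100.0 * len(two_dot) / len(included)
    pct_split = 100.0 * n_split / len(two_dot) if two_dot else math.nan

    distances = np.array([c.distance_um for c in two_dot], dtype=float)
    if len(distances):
        mean_distance = float(distances.mean())
        bin_w = config.histogram_bin_um
        n_bins = int(math.floor(distances.max() / bin_w)) + 1
        edges = bin_w * np.arange(n_bins + 1)
        counts, _ = np.histogram(distances, bins=edges)
    else:
        mean_distance = math.nan
        edges = np.array([0.0, config.histogram_bin_um])
        counts = np.array([0])

    return SampleScore(
        sample_id=sample_id, condition=condition,
        n_included=len(included), n_two_dot=len(two_dot),
        pct_split=pct_split, pct_two_dot=pct_two_dot,
        mean_distance_um=mean_distance,
        hist_edges_um=edges, hist_counts=counts,
        deficit=call_deficit(pct_split, config) if two_dot else False,
        low_n=len(included) < config.min_cells,
    )


def sample_to_row(sample: SampleScore) -> dict:
    """Flatten a SampleScore for the per-sample CSV."""
    return {
        "sample_id": sample.sample_id, "condition": sample.condition,
        "n_included": sample.n_included, "n_two_dot": sample.n_two_dot,
        "pct_split": sample.pct_split, "pct_two_dot": sample.pct_two_dot,
        "mean_distance_um": sample.mean_distance_um,
        "deficit": sample.deficit, "low_n": sample.low_n,
    }


def mli2_reversal(vehicle: SampleScore, treated: SampleScore,
                  config: Optional[ScoringConfig] = None) -> ReversalRecord:
    """Vehicle-vs-MLi2 delta and per-sample reversal call.

    A sample is *reverted* when it has a deficit under vehicle and no deficit
    after inhibitor treatment. Cohort-level paired testing lives in
    :mod:`ccsplit.cohort`.
    """
    if vehicle.sample_id != treated.sample_id:
        raise PairingError(
            f"sample ids differ: {vehicle.sample_id!r} vs {treated.sample_id!r}")
    config = config or ScoringConfig()
    vehicle_deficit = call_deficit(vehicle.pct_split, config)
    treated_deficit = call_deficit(treated.pct_split, config)
    return ReversalRecord(
        sample_id=vehicle.sample_id,
        vehicle_pct_split=vehicle.pct_split,
        treated_pct_split=treated.pct_split,
        delta=vehicle.pct_split - treated.pct_split,
        reverted=vehicle_deficit and not treated_deficit,
        vehicle=vehicle, treated=treated,
    )
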