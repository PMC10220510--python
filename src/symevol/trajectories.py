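"""Allele-frequency trajectory analysis for serially sampled populations.

Whole-population sequencing of an evolving lineage yields, for every detected
mutation, a frequency at each sampled cycle.  Mutations swept together on one
clonal background show correlated trajectories; hierarchical clustering of
the trajectory rows with a fixed cut height groups them into *cohorts*.
Mutations that rise to intermediate frequency and later go extinct mark
clonal interference between competing subpopulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "TrajectoryMatrix",
    "CohortSet",
    "detect_above_threshold",
    "cluster_cohorts",
    "summarize_cohorts",
    "clonal_interference_fraction",
    "new_mutations_per_cycle",
]


@dataclass
class TrajectoryMatrix:
    """Mutations x sampled-cycles matrix of population allele frequencies.

    ``freq[i, j]`` is the frequency of ``mutation_ids[i]`` at cycle
    ``cycle_labels[j]``; NaN marks a cycle that was not sequenced.
    """

    mutation_ids: list[str]
    cycle_labels: list[int]
    freq: np.ndarray
    lineage: str = ""

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.mutation_ids), len(self.cycle_labels)):
            raise ValueError("frequency matrix shape does not match labels")
        if len(self.mutation_ids) != len(set(self.mutation_ids)):
            raise ValueError("mutation ids must be unique")
        vals = self.freq[~np.isnan(self.freq)]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.cycle_labels, self.cycle_labels[1:])):
            raise ValueError("cycle labels must be strictly increasing")

    @property
    def n_mutations(self) -> int:
        return len(self.mutation_ids)

    def subset(self, ids: list[str]) -> "TrajectoryMatrix":
        index = {m: i for i, m in enumerate(self.mutation_ids)}
        rows = [index[m] for m in ids]
        return TrajectoryMatrix(list(ids), list(self.cycle_labels),
                                self.freq[rows], self.lineage)

    def interpolated(self) -> np.ndarray:
        """Frequencies with unsequenced cycles filled by linear interpolation."""
        if np.isnan(self.freq).all(axis=1).any():
            raise ValueError("rows with all frequencies missing cannot be interpolated")
        df = pd.DataFrame(self.freq)
        return df.interpolate(axis=1, limit_direction="both").to_numpy()


@dataclass
class CohortSet:
    """A partition of mutations into cohorts of co-travelling trajectories."""

    assignment: dict[str, int]  # mutation id -> cohort label
    cycle_labels: list[int]
    mean_trajectories: dict[int, np.ndarray] = field(default_factory=dict)
    fix_threshold: float = 0.9

    def __post_init__(self) -> None:
        if set(self.assignment.values()) != set(self.mean_trajectories):
            raise ValueError("cohort labels and mean trajectories are inconsistent")

    @property
    def labels(self) -> list[int]:
        return sorted(self.mean_trajectories)

    def members(self, label: int) -> list[str]:
        return [m for m, c in self.assignment.items() if c == label]

    def size(self, label: int) -> int:
        return sum(1 for c in self.assignment.values() if c == label)

    def max_mean_frequency(self, label: int) -> float:
        return float(np.nanmax(self.mean_trajectories[label]))

    def is_fixed(self, label: int) -> bool:
        return self.max_mean_frequency(label) > self.fix_threshold


def detect_above_threshold(m: TrajectoryMatrix, threshold: float) -> set[str]:
    """Ids of mutations whose maximum observed frequency reaches ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    with np.errstate(all="ignore"):
        peaks = np.nanmax(np.where(np.isnan(m.freq), -np.inf, m.freq), axis=1)
    return {mid for mid, pk in zip(m.mutation_ids, peaks) if pk >= threshold}


def cluster_cohorts(
    m: TrajectoryMatrix,
    cut: float = 0.3,
    metric: str = "euclidean",
    linkage_method: str = "complete",
    fix_threshold: float = 0.9,
) -> CohortSet:
    """Group trajectories into cohorts by hierarchical clustering.

    Rows (after linear interpolation of unsequenced cycles) are clustered
    agglomeratively and the tree is cut at height ``cut``.  Mutations
    travelling alone form singleton cohorts.  Labels are assigned in order of
    first appearance along the input rows, so they are stable under row
    permutation only up to relabelling.
    """
    if m.n_mutations < 1:
        raise ValueError("at least one mutation is required")
    filled = m.interpolated()
    if m.n_mutations == 1:
        raw = np.array([1])
    else:
        z = linkage(pdist(filled, metric=metric), method=linkage_method)
        raw = fcluster(z, t=cut, criterion="distance")
    assignment = {mid: int(lbl) for mid, lbl in zip(m.mutation_ids, raw)}
    means = {
        lbl: np.nanmean(m.freq[raw == lbl], axis=0) for lbl in np.unique(raw)
    }
    return CohortSet(assignment, list(m.cycle_labels), means, fix_threshold)


def summarize_cohorts(c: CohortSet, fix_threshold: float | None = None) -> pd.DataFrame:
    """Per-cohort summary table.

    ``fixation_cycle`` is the first sampled cycle at which the cohort's mean
    trajectory exceeds the fixation threshold (NaN if never); ``rise_duration``
    is the number of cycles from the first sample at or above 5% to fixation
    (or to the peak, for cohorts that never fix).
    """
    thr = c.fix_threshold if fix_threshold is None else fix_threshold
    cycles = np.asarray(c.cycle_labels)
    rows = []
    for label in c.labels:
        mean = c.mean_trajectories[label]
        above = np.where(~np.isnan(mean) & (mean > thr))[0]
        fix_cycle = int(cycles[above[0]]) if above.size else math.nan
        detected = np.where(~np.isnan(mean) & (mean >= 0.05))[0]
        if detected.size:
            start = cycles[detected[0]]
            end = fix_cycle if above.size else cycles[int(np.nanargmax(mean))]
            rise = float(end - start)
        else:
            rise = math.nan
        rows.append(
            {
                "cohort": label,
                "size": c.size(label),
                "max_mean_frequency": c.max_mean_frequency(label),
                "fixed": bool(above.size),
                "fixation_cycle": fix_cycle,
                "rise_duration": rise,
            }
        )
    return pd.DataFrame(rows)


def clonal_interference_fraction(
    m: TrajectoryMatrix, rise: float = 0.3, extinct_below: float = 0.05
) -> float:
    """Fraction of high-rising mutations that later declined to extinction.

    Among mutations that ever reached ``rise``, the fraction whose final
    observed frequency is below ``extinct_below``.  Returns NaN when no
    mutation ever rose that high (undefined, distinct from zero).
    """
    risers = detect_above_threshold(m, rise)
    if not risers:
        return math.nan
    index = {mid: i for i, mid in enumerate(m.mutation_ids)}
    extinct = 0
    for mid in risers:
        row = m.freq[index[mid]]
        observed = row[~np.isnan(row)]
        if observed.size and observed[-1] < extinct_below:
            extinct += 1
    return extinct / len(risers)


def new_mutations_per_cycle(
    m: TrajectoryMatrix, detect: float = 0.05
) -> tuple[pd.Series, float]:
    """Count newly detected mutations per sampled cycle.

    A mutation is *new* at the first sampled cycle where its frequency
    reaches the detection threshold.  The mean is per elapsed cycle (total
    detected divided by the last sampled cycle), not per sampling point,
    since sampling is typically sparser than cycling.
    """
    counts = pd.Series(0, index=pd.Index(m.cycle_labels, name="cycle"), dtype=int)
    for row in m.freq:
        hits = np.where(~np.isnan(row) & (row >= detect))[0]
        if hits.size:
            counts.loc[m.cycle_labels[hits[0]]] += 1
    elapsed = max(m.cycle_labels) if m.cycle_labels else 0
    mean = counts.sum() / elapsed if elapsed > 0 else math.nan
    return counts, float(mean)
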