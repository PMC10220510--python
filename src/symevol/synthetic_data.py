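"""Ground-truthed synthetic inputs for every analysis stage.

Generators emulate the shape of the study system's data — five lineages
sequenced every other cycle to cycle 35, cohort-structured sweeps with
optional clonal interference, mutation tables over thousands of
length-annotated genes with planted per-gene enrichment, and binomial
nodule-occupancy counts with a known true competitive index — while
carrying the planted truth alongside, so recovery can be scored exactly.

Cohort sweeps are deliberately logistic curves rather than simulator output:
clustering correctness must be testable independently of the evolution
model.  Sweep midpoints are spread across the time course with jitter,
mimicking the sequential cohort sweeps seen in serially passaged lineages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .lifecycle_sim import SimulationResult
from .parallelism import GeneTable
from .fitness_metrics import CIObservation
from .trajectories import TrajectoryMatrix

__all__ = [
    "SyntheticTruth",
    "gen_gene_table",
    "gen_trajectories",
    "gen_mutation_table",
    "gen_ci_counts",
    "sim_to_tables",
    "MUTATION_TABLE_PREFIX",
    "LINEAGES",
]

#: fixed leading columns of the mutation-table TSV dialect
MUTATION_TABLE_PREFIX = [
    "lineage", "replicon", "position", "ref", "alt", "gene_id", "mutation_type",
]

LINEAGES = ("B", "F", "G", "K", "M")

_BASES = np.array(list("ACGT"))
_MUTATION_TYPES = ("synonymous", "nonsynonymous", "nonsense", "indel")
_TYPE_PROBS = (0.3, 0.55, 0.05, 0.10)


@dataclass
class SyntheticTruth:
    """Serializable record of what a generator planted."""

    kind: str
    seed: int | None
    params: dict[str, Any] = field(default_factory=dict)
    cohort_labels: dict[str, int] | None = None
    enriched_genes: dict[str, float] | None = None
    true_ci: dict[str, float] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def gen_gene_table(
    n_genes: int = 5000,
    seed: int | None = None,
    mean_length: float = 1000.0,
    replicons: Sequence[str] = ("chromosome", "megaplasmid", "plasmid"),
) -> GeneTable:
    """A synthetic coding-gene annotation with log-normal gene lengths."""
    rng = np.random.default_rng(seed)
    sigma = 0.5
    mu = np.log(mean_length) - sigma**2 / 2
    lengths = np.maximum(90, np.rint(rng.lognormal(mu, sigma, n_genes))).astype(int)
    width = len(str(max(n_genes, 1)))
    table = pd.DataFrame(
        {
            "gene_id": [f"g{i + 1:0{width}d}" for i in range(n_genes)],
            "length": lengths,
            "replicon": rng.choice(replicons, size=n_genes, p=None),
        }
    )
    return GeneTable(table)


def _logistic(t: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-steepness * (t - midpoint)))


def gen_trajectories(
    n_cohorts: int = 3,
    cohort_sizes: Sequence[int] | int = 5,
    n_cycles: int = 35,
    sample_every: int = 2,
    noise_sd: float = 0.02,
    frac_interference: float = 0.0,
    seed: int | None = None,
    lineage: str = "S",
) -> tuple[TrajectoryMatrix, SyntheticTruth]:
    """Cohort-structured sweep trajectories with known cohort labels.

    Each cohort follows one logistic sweep (midpoints spread over the time
    course with jitter, random steepness); with probability
    ``frac_interference`` a cohort instead peaks and then declines to
    extinction, emulating an outcompeted subpopulation.  Members share their
    cohort's sweep plus independent truncated-normal noise per time point;
    frequencies are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    if isinstance(cohort_sizes, int):
        sizes = [int(cohort_sizes)] * n_cohorts
    else:
        sizes = [int(s) for s in cohort_sizes]
    if len(sizes) != n_cohorts or any(s < 1 for s in sizes):
        raise ValueError("cohort_sizes must give a positive size per cohort")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    cycles = np.array(range(1, n_cycles + 1, sample_every))
    spacing = n_cycles / (n_cohorts + 1)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: dict[str, int] = {}
    for k in range(n_cohorts):
        midpoint = (k + 1) * spacing + rng.uniform(-0.3, 0.3) * spacing
        steepness = rng.uniform(0.4, 1.2)
        sweep = _logistic(cycles.astype(float), midpoint, steepness)
        if rng.random() < frac_interference:
            fall_mid = midpoint + rng.uniform(0.5, 1.0) * spacing
            sweep = sweep * (1.0 - _logistic(cycles.astype(float), fall_mid, steepness))
        for j in range(sizes[k]):
            mid = f"{lineage}_c{k + 1}m{j + 1}"
            noisy = sweep + rng.normal(0.0, noise_sd, size=cycles.size) if noise_sd else sweep
            rows.append(np.clip(noisy, 0.0, 1.0))
            ids.append(mid)
            labels[mid] = k + 1
    matrix = TrajectoryMatrix(ids, [int(c) for c in cycles], np.array(rows), lineage)
    truth = SyntheticTruth(
        kind="trajectories",
        seed=seed,
        params={
            "n_cohorts": n_cohorts, "cohort_sizes": sizes, "n_cycles": n_cycles,
            "sample_every": sample_every, "noise_sd": noise_sd,
            "frac_interference": frac_interference,
        },
        cohort_labels=labels,
    )
    return matrix, truth


def _random_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _gene_offsets(genes: GeneTable) -> np.ndarray:
    """Genomic start coordinate per gene, so positions are unique per replicon."""
    starts = np.zeros(len(genes), dtype=np.int64)
    table = genes.table
    for rep in table["replicon"].unique() if "replicon" in table else ["chr"]:
        idx = np.where(table["replicon"] == rep)[0] if "replicon" in table else np.arange(len(table))
        lengths = table["length"].to_numpy()[idx]
        starts[idx] = 1 + np.concatenate([[0], np.cumsum(lengths[:-1])])
    return starts


def gen_mutation_table(
    genes: GeneTable,
    n_tot: int = 3330,
    enriched: dict[str, float] | None = None,
    seed: int | None = None,
    cycle_labels: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Mutation table with length-proportional gene hits and planted enrichment.

    Genes receive mutations multinomially with weights ``L_i * multiplier_i``
    (multiplier 1 where not listed); each mutation gets a unique genomic
    position within its gene, a random lineage, and a maximum frequency of at
    least the 5% detection threshold.
    """
    rng = np.random.default_rng(seed)
    enriched = dict(enriched or {})
    mult = pd.Series(1.0, index=genes.gene_ids)
    for gid, m in enriched.items():
        if m < 0:
            raise ValueError("enrichment multipliers must be >= 0")
        mult.loc[gid] = m
    weights = genes.lengths * mult.to_numpy()
    if weights.sum() <= 0:
        raise ValueError("all gene weights are zero")
    counts = rng.multinomial(n_tot, weights / weights.sum())
    if cycle_labels is None:
        cycle_labels = list(range(1, 36, 2))
    starts = _gene_offsets(genes)
    table = genes.table
    has_rep = "replicon" in table.columns
    recs: list[dict[str, Any]] = []
    for gi in np.nonzero(counts)[0]:
        k = int(counts[gi])
        length = int(table["length"].iloc[gi])
        # sample distinct in-gene offsets so events never collide at one site
        local = rng.choice(length, size=min(k, length), replace=False)
        if k > length:  # pathological tiny gene: reuse sites, vary lineage
            local = np.concatenate([local, rng.choice(length, size=k - length)])
        refs, alts = _random_alleles(rng, k)
        for j in range(k):
            peak = rng.uniform(0.05, 1.0)
            recs.append(
                {
                    "lineage": rng.choice(LINEAGES),
                    "replicon": table["replicon"].iloc[gi] if has_rep else "chr",
                    "position": int(starts[gi] + local[j]),
                    "ref": refs[j],
                    "alt": alts[j],
                    "gene_id": table["gene_id"].iloc[gi],
                    "mutation_type": rng.choice(_MUTATION_TYPES, p=_TYPE_PROBS),
                    "_peak": peak,
                }
            )
    df = pd.DataFrame(recs, columns=MUTATION_TABLE_PREFIX + ["_peak"])
    # a minimal rising trajectory whose maximum equals the drawn peak
    n_cyc = len(cycle_labels)
    ramp = np.linspace(0.0, 1.0, n_cyc)
    freq = np.outer(df["_peak"].to_numpy() if len(df) else np.empty(0), ramp)
    for j, cyc in enumerate(cycle_labels):
        df[f"freq_c{cyc}"] = freq[:, j] if len(df) else pd.Series(dtype=float)
    df = df.drop(columns=["_peak"])
    truth = SyntheticTruth(
        kind="mutations",
        seed=seed,
        params={"n_tot": n_tot, "n_genes": len(genes)},
        enriched_genes=enriched,
    )
    return df, truth


def gen_ci_counts(
    true_ci: float,
    inoculum_ratio: float = 1.0,
    n_out: int = 96,
    n_replicates: int = 3,
    seed: int | None = None,
    strain: str = "mutant",
    assay: str = "nodulation",
) -> tuple[list[CIObservation], SyntheticTruth]:
    """Binomial nodule-occupancy counts with a known true competitive index.

    Each replicate scores ``n_out`` nodules; a nodule hosts the test strain
    with probability ``true_ci * r / (1 + true_ci * r)`` where ``r`` is the
    inoculum ratio.  Inoculum counts are fixed, not resampled.
    """
    if true_ci <= 0:
        raise ValueError("true_ci must be positive")
    if n_out < 1 or n_replicates < 1:
        raise ValueError("n_out and n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    p = true_ci * inoculum_ratio / (1.0 + true_ci * inoculum_ratio)
    ref_in = 500.0
    test_in = ref_in * inoculum_ratio
    obs = []
    for rep in range(1, n_replicates + 1):
        test_out = int(rng.binomial(n_out, p))
        obs.append(
            CIObservation(
                test_out=test_out, ref_out=n_out - test_out,
                test_in=test_in, ref_in=ref_in,
                replicate=f"r{rep}", strain=strain, assay=assay,
            )
        )
    truth = SyntheticTruth(
        kind="ci",
        seed=seed,
        params={"inoculum_ratio": inoculum_ratio, "n_out": n_out,
                "n_replicates": n_replicates},
        true_ci={strain: true_ci},
    )
    return obs, truth


def sim_to_tables(
    result: SimulationResult,
    genes: GeneTable | None = None,
    lineage: str = "SIM",
    sample_every: int = 2,
    seed: int | None = None,
) -> tuple[TrajectoryMatrix, pd.DataFrame]:
    """Convert simulator output into the analysis-table dialects.

    Frequency tracks are sampled every ``sample_every`` cycles into a
    trajectory matrix and a mutation table (one row per censused mutation,
    with synthetic gene assignments drawn length-proportionally from
    ``genes``), enabling end-to-end tests of the analysis stages on
    simulated evolution.
    """
    if genes is None:
        genes = gen_gene_table(200, seed=0 if seed is None else seed)
    rng = np.random.default_rng(result.seed if seed is None else seed)
    n_cycles = result.config.n_cycles
    cycles = list(range(1, n_cycles + 1, sample_every))
    mids = sorted(result.tracks)
    freq = np.zeros((len(mids), len(cycles)))
    for i, mid in enumerate(mids):
        track = result.tracks[mid]
        for j, cyc in enumerate(cycles):
            freq[i, j] = track.frequency_at(cyc)
    ids = [f"{lineage}_m{mid}" for mid in mids]
    matrix = TrajectoryMatrix(ids, cycles, freq, lineage)

    table = genes.table
    starts = _gene_offsets(genes)
    probs = genes.lengths / genes.total_length
    gene_idx = rng.choice(len(genes), size=len(mids), p=probs)
    refs, alts = _random_alleles(rng, len(mids))
    used: set[tuple[str, int]] = set()
    recs = []
    for i, mid in enumerate(mids):
        gi = int(gene_idx[i])
        rep = table["replicon"].iloc[gi] if "replicon" in table.columns else "chr"
        length = int(table["length"].iloc[gi])
        for _ in range(50):
            pos = int(starts[gi] + rng.integers(0, length))
            if (rep, pos) not in used:
                break
        used.add((rep, pos))
        recs.append(
            {
                "lineage": lineage,
                "replicon": rep,
                "position": pos,
                "ref": refs[i],
                "alt": alts[i],
                "gene_id": table["gene_id"].iloc[gi],
                "mutation_type": rng.choice(_MUTATION_TYPES, p=_TYPE_PROBS),
            }
        )
    df = pd.DataFrame(recs, columns=MUTATION_TABLE_PREFIX)
    for j, cyc in enumerate(cycles):
        df[f"freq_c{cyc}"] = freq[:, j] if len(df) else pd.Series(dtype=float)
    return matrix, df
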