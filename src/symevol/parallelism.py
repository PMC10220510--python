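"""Gene-level parallelism (G-score) statistics with a multinomial null.

Under a null of mutations landing on protein-coding genes in proportion to
their length, gene *i* with length ``L_i`` among a total coding length
``L_tot`` expects ``E_i = N_tot * L_i / L_tot`` of the ``N_tot`` observed
coding mutations.  The per-gene parallelism score is the log-likelihood-ratio
term ``G_i = 2 * N_i * ln(N_i / E_i)`` (zero at ``N_i = 0`` by the limit
convention; negative when a gene is hit less often than expected).  The null
distribution of per-gene scores and of their genome-wide sum is obtained by
repeatedly reassigning all ``N_tot`` mutations multinomially by gene length,
giving per-gene Z scores with one-sided (upper-tail) normal P values,
Bonferroni-adjusted across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "GeneTable",
    "NullDistribution",
    "GeneParallelismResult",
    "count_mutations_per_gene",
    "g_score",
    "expected_counts",
    "randomization_null",
    "parallelism_summary",
]

logger = logging.getLogger(__name__)

#: columns identifying one independent mutation event across populations
EVENT_KEY = ["lineage", "replicon", "position", "alt"]


@dataclass(frozen=True)
class GeneTable:
    """Protein-coding gene lengths, the basis of the length-proportional null."""

    table: pd.DataFrame  # columns: gene_id, length, replicon

    def __post_init__(self) -> None:
        required = {"gene_id", "length"}
        if not required <= set(self.table.columns):
            raise ValueError("gene table requires columns gene_id and length")
        if self.table["gene_id"].duplicated().any():
            dup = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r} in gene table")
        if (self.table["length"] < 1).any():
            raise ValueError("gene lengths must be >= 1")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.table["gene_id"])

    @property
    def lengths(self) -> np.ndarray:
        return self.table["length"].to_numpy(dtype=float)

    @property
    def total_length(self) -> float:
        return float(self.table["length"].sum())

    def __len__(self) -> int:
        return len(self.table)


def _max_frequency(mutations: pd.DataFrame) -> pd.Series:
    freq_cols = [c for c in mutations.columns if c.startswith("freq_")]
    if not freq_cols:
        raise ValueError("mutation table has no freq_* columns")
    return mutations[freq_cols].max(axis=1, skipna=True)


def count_mutations_per_gene(
    mutations: pd.DataFrame, genes: GeneTable, detect: float = 0.05
) -> tuple[pd.Series, int]:
    """Observed independent mutation counts per coding gene.

    A mutation event is one unique (lineage, replicon, position, alt) whose
    maximum frequency across sampled cycles reaches ``detect``; the same site
    mutated in two lineages counts twice (independent events), the same event
    listed at several cycles counts once.  Intergenic rows (empty gene id)
    are excluded; rows annotated to genes absent from the gene table are
    excluded with a logged warning.  Returns counts aligned to the gene table
    (zeros for unmutated genes) and their sum ``N_tot``.
    """
    df = mutations.copy()
    df["_maxfreq"] = _max_frequency(df)
    df = df[df["_maxfreq"] >= detect]
    df = df[df["gene_id"].notna() & (df["gene_id"].astype(str) != "")]
    df = df.drop_duplicates(subset=EVENT_KEY)
    known = df["gene_id"].isin(genes.gene_ids)
    if (~known).any():
        missing = sorted(df.loc[~known, "gene_id"].unique())
        logger.warning(
            "excluding %d mutation(s) in %d gene(s) absent from the gene table: %s",
            int((~known).sum()), len(missing), ", ".join(map(str, missing[:10])),
        )
        df = df[known]
    counts = (
        df.groupby("gene_id").size().reindex(genes.gene_ids, fill_value=0).astype(int)
    )
    return counts, int(counts.sum())


def expected_counts(genes: GeneTable, n_tot: int) -> np.ndarray:
    """Length-proportional expectations E_i = N_tot * L_i / L_tot."""
    return n_tot * genes.lengths / genes.total_length


def g_score(n_i, e_i):
    """G_i = 2 * N_i * ln(N_i / E_i); zero at N_i = 0, defined for E_i > 0.

    Accepts scalars or arrays; broadcasting follows numpy rules.
    """
    n = np.asarray(n_i, dtype=float)
    e = np.asarray(e_i, dtype=float)
    if (e <= 0).any():
        raise ValueError("expected counts must be positive")
    if (n < 0).any():
        raise ValueError("observed counts must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * n * np.log(n / e)
    g = np.where(n == 0, 0.0, g)
    if np.isscalar(n_i) and np.isscalar(e_i):
        return float(g)
    return g


@dataclass(frozen=True)
class NullDistribution:
    """Moments of per-gene G scores and the G-sum sample under the null."""

    sim_mean: np.ndarray
    sim_sd: np.ndarray
    g_sum_samples: np.ndarray
    n_sims: int
    n_tot: int
    count_mean: np.ndarray | None = None  # mean simulated hits per gene


def randomization_null(
    genes: GeneTable,
    n_tot: int,
    n_sims: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Multinomial randomization null for the G statistics.

    Each simulation scatters ``n_tot`` mutations over the genes with
    probabilities proportional to gene length and recomputes every G score
    and their genome-wide sum.
    """
    if len(genes) == 0:
        raise ValueError("gene table is empty")
    if n_tot < 0 or n_sims < 1:
        raise ValueError("n_tot must be >= 0 and n_sims >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = genes.lengths / genes.total_length
    e_i = expected_counts(genes, n_tot)
    sims = rng.multinomial(n_tot, probs, size=n_sims)
    g_sims = g_score(sims, e_i[None, :])
    ddof = 1 if n_sims > 1 else 0
    return NullDistribution(
        sim_mean=g_sims.mean(axis=0),
        sim_sd=g_sims.std(axis=0, ddof=ddof),
        g_sum_samples=g_sims.sum(axis=1),
        n_sims=n_sims,
        n_tot=n_tot,
        count_mean=sims.mean(axis=0),
    )


@dataclass
class GeneParallelismResult:
    """Per-gene and genome-wide parallelism statistics."""

    per_gene: pd.DataFrame
    n_tot: int
    g_sum_observed: float
    g_sum_null_mean: float
    g_sum_null_sd: float
    z_sum: float
    p_sum: float

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        return self.per_gene[self.per_gene["p_adj"] < alpha]


def parallelism_summary(
    observed: pd.Series, null: NullDistribution, genes: GeneTable
) -> GeneParallelismResult:
    """Combine observed counts with the randomization null.

    Per-gene ``Z_i = (G_i - sim_mean_i) / sim_sd_i`` with one-sided
    upper-tail normal P values (the question is whether a gene is mutated
    *more* often than chance), Bonferroni-adjusted.  Genes never hit in any
    simulation (``sim_sd = 0``) get an undefined Z and conservative P = 1.
    The genome-wide test compares the observed G-sum with the null sample of
    sums the same way.
    """
    observed = observed.reindex(genes.gene_ids)
    if observed.isna().any():
        raise ValueError("observed counts do not cover the gene table")
    n_i = observed.to_numpy(dtype=float)
    n_tot = int(n_i.sum())
    if n_tot != null.n_tot:
        raise ValueError(
            f"null was built for N_tot={null.n_tot}, observed N_tot={n_tot}"
        )
    e_i = expected_counts(genes, n_tot)
    g_i = g_score(n_i, e_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_i = (g_i - null.sim_mean) / null.sim_sd
    degenerate = null.sim_sd == 0
    z_i = np.where(degenerate, np.nan, z_i)
    p_i = np.where(degenerate, 1.0, norm.sf(np.where(degenerate, 0.0, z_i)))
    if degenerate.any():
        logger.info(
            "%d gene(s) were never hit in any randomization (sim_sd = 0); "
            "assigned P = 1", int(degenerate.sum()),
        )
    n_genes = len(genes)
    p_adj = np.minimum(1.0, p_i * n_genes)
    per_gene = pd.DataFrame(
        {
            "gene_id": genes.gene_ids.to_numpy(),
            "length": genes.lengths.astype(int),
            "n_obs": n_i.astype(int),
            "expected": e_i,
            "g_score": g_i,
            "sim_mean": null.sim_mean,
            "sim_sd": null.sim_sd,
            "z": z_i,
            "p": p_i,
            "p_adj": p_adj,
        }
    )
    g_sum_obs = float(g_i.sum())
    mu = float(null.g_sum_samples.mean())
    sd = float(null.g_sum_samples.std(ddof=1 if null.n_sims > 1 else 0))
    z_sum = (g_sum_obs - mu) / sd if sd > 0 else np.nan
    p_sum = float(norm.sf(z_sum)) if sd > 0 else 1.0
    return GeneParallelismResult(
        per_gene=per_gene,
        n_tot=n_tot,
        g_sum_observed=g_sum_obs,
        g_sum_null_mean=mu,
        g_sum_null_sd=sd,
        z_sum=float(z_sum),
        p_sum=p_sum,
    )
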