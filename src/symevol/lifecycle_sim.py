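"""Stochastic two-trait life-cycle evolution of a horizontally transmitted symbiont.

The model follows a bacterial population cycling between two compartments:
the rhizosphere, where transient hypermutagenesis generates new genotypes,
and host root nodules, entered through a stringent single-founder-per-nodule
bottleneck.  Each genotype carries two multiplicative traits in (0, 1]:

* ``c`` — nodulation competitiveness, the weight with which cells compete to
  found nodules at host entry;
* ``p`` — within-host proliferation, which scales the carrying capacity a
  founder's clonal nodule population reaches before harvest.

Population fitness is summarised as the product of the abundance-weighted
medians of the two traits, and partitioned into low / mid / high fitness
domains.  Two step orderings are supported: the default places the host-entry
bottleneck immediately after mutagenesis and before proliferation
(``bottleneck_first``); the alternative lets clonal multiplication act on the
rhizosphere population before the bottleneck (``proliferation_first``).

All bookkeeping is at the genotype level (a genotype is a clonal lineage with
an abundance), never per cell, so rhizosphere sizes of 10^6-10^7 are cheap.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal

import numpy as np

__all__ = [
    "EffectDistribution",
    "MutationArchitecture",
    "MutationEvent",
    "Genotype",
    "PopulationState",
    "SimulationConfig",
    "FitnessSummary",
    "MutationTrack",
    "SelectedMutation",
    "SimulationResult",
    "ConfigurationError",
    "SimulationError",
    "draw_mutation_effect",
    "apply_hypermutagenesis",
    "sample_founders",
    "proliferate_and_pool",
    "run_cycle",
    "run_simulation",
    "run_replicates",
    "classify_fitness_domain",
    "selected_mutation_fold_effects",
]


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


class SimulationError(RuntimeError):
    """Invalid population state encountered while simulating."""


# ---------------------------------------------------------------------------
# mutation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectDistribution:
    """Distribution of multiplicative trait-effect factors.

    ``log_uniform_mix`` draws a beneficial factor (log-uniform on
    ``beneficial_range``) with probability ``frac_beneficial`` supplied by the
    architecture, otherwise a deleterious-to-neutral factor (log-uniform on
    ``deleterious_range``).  ``point`` is a degenerate distribution at
    ``point_value``, useful for analytic checks.
    """

    name: Literal["log_uniform_mix", "point"] = "log_uniform_mix"
    beneficial_range: tuple[float, float] = (1.0, 1e4)
    deleterious_range: tuple[float, float] = (1e-4, 1.0)
    point_value: float = 1.0

    def draw(self, n: int, frac_beneficial: float, rng: np.random.Generator) -> np.ndarray:
        if self.name == "point":
            return np.full(n, float(self.point_value))
        if self.name != "log_uniform_mix":
            raise ConfigurationError(f"unknown effect distribution {self.name!r}")
        beneficial = rng.random(n) < frac_beneficial
        lo_b, hi_b = self.beneficial_range
        lo_d, hi_d = self.deleterious_range
        out = np.exp(rng.uniform(math.log(lo_d), math.log(hi_d), n))
        nb = int(beneficial.sum())
        if nb:
            out[beneficial] = np.exp(rng.uniform(math.log(lo_b), math.log(hi_b), nb))
        return out


@dataclass(frozen=True)
class MutationArchitecture:
    """Genetic architecture of the two symbiotic traits.

    ``pi_c``/``pi_p``/``pi_cp`` are the probabilities that a mutation affects
    competitiveness only, proliferation only, or both (independent factor
    draws per trait in the pleiotropic case); they must sum to one.
    """

    pi_c: float = 0.45
    pi_p: float = 0.45
    pi_cp: float = 0.10
    frac_beneficial: float = 0.10
    effect_dist: EffectDistribution = field(default_factory=EffectDistribution)

    def validate(self) -> None:
        probs = (self.pi_c, self.pi_p, self.pi_cp)
        if any(not (0.0 <= q <= 1.0) for q in probs):
            raise ConfigurationError("mutation class probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError("pi_c + pi_p + pi_cp must equal 1")
        if not 0.0 <= self.frac_beneficial <= 1.0:
            raise ConfigurationError("frac_beneficial must lie in [0, 1]")

    def draw_factors(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised draw of ``n`` (c_factor, p_factor) pairs."""
        self.validate()
        cat = rng.choice(3, size=n, p=[self.pi_c, self.pi_p, self.pi_cp])
        c_fac = np.ones(n)
        p_fac = np.ones(n)
        affects_c = cat != 1
        affects_p = cat != 0
        nc, npp = int(affects_c.sum()), int(affects_p.sum())
        if nc:
            c_fac[affects_c] = self.effect_dist.draw(nc, self.frac_beneficial, rng)
        if npp:
            p_fac[affects_p] = self.effect_dist.draw(npp, self.frac_beneficial, rng)
        return c_fac, p_fac


def draw_mutation_effect(
    arch: MutationArchitecture, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw one (c_factor, p_factor) pair under the given architecture."""
    c_fac, p_fac = arch.draw_factors(1, rng)
    return float(c_fac[0]), float(p_fac[0])


@dataclass(frozen=True)
class MutationEvent:
    id: int
    cycle_of_origin: int
    c_factor: float
    p_factor: float

    @property
    def fold_effect(self) -> float:
        """Competitiveness effect divided by proliferation effect."""
        return self.c_factor / self.p_factor


class MutationRegistry:
    """Compact per-simulation store of mutation events and genotype ids.

    Events arrive in per-cycle batches and are kept as chunked arrays
    (hundreds of thousands of events per replicate are routine, almost all
    belonging to mutants lost at the next bottleneck), with bisection lookup
    by id.
    """

    __slots__ = ("_starts", "_cycles", "_cfs", "_pfs", "_next_mut", "_next_geno")

    def __init__(self) -> None:
        self._starts: list[int] = []
        self._cycles: list[int] = []
        self._cfs: list[np.ndarray] = []
        self._pfs: list[np.ndarray] = []
        self._next_mut = 0
        self._next_geno = 0

    def new_genotype_id(self) -> int:
        self._next_geno += 1
        return self._next_geno - 1

    def reserve_genotype_ids(self, n: int) -> int:
        start = self._next_geno
        self._next_geno += n
        return start

    def add_batch(self, cycle: int, c_factors: np.ndarray, p_factors: np.ndarray) -> int:
        """Register a batch of events from one cycle; returns the first id."""
        start = self._next_mut
        self._starts.append(start)
        self._cycles.append(cycle)
        self._cfs.append(np.asarray(c_factors, dtype=float))
        self._pfs.append(np.asarray(p_factors, dtype=float))
        self._next_mut += len(c_factors)
        return start

    def new_event(self, cycle: int, c_factor: float, p_factor: float) -> int:
        return self.add_batch(cycle, np.array([c_factor]), np.array([p_factor]))

    def get(self, mid: int) -> MutationEvent:
        if not 0 <= mid < self._next_mut:
            raise KeyError(mid)
        j = bisect_right(self._starts, mid) - 1
        off = mid - self._starts[j]
        return MutationEvent(
            id=mid, cycle_of_origin=self._cycles[j],
            c_factor=float(self._cfs[j][off]), p_factor=float(self._pfs[j][off]),
        )

    def __len__(self) -> int:
        return self._next_mut


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------


class Genotype:
    """A clonal lineage: two trait values and its ordered mutation history.

    A deliberately minimal ``__slots__`` class: hundreds of thousands are
    created per replicate.  Traits are kept in (0, 1] by construction —
    multiplicative factors are strictly positive and products are clamped at
    the optimum 1 — so no per-instance validation happens here; use
    :func:`validate_genotype` where an explicit check is wanted.
    """

    __slots__ = ("id", "parent_id", "c", "p", "mutations")

    def __init__(
        self,
        id: int,
        parent_id: int | None,
        c: float,
        p: float,
        mutations: tuple[int, ...] = (),
    ) -> None:
        self.id = id
        self.parent_id = parent_id
        self.c = c
        self.p = p
        self.mutations = mutations

    def __repr__(self) -> str:  # pragma: no cover
        return (f"Genotype(id={self.id}, parent_id={self.parent_id}, "
                f"c={self.c:.4g}, p={self.p:.4g}, n_mutations={len(self.mutations)})")


def validate_genotype(g: Genotype) -> None:
    if not (0.0 < g.c <= 1.0 and 0.0 < g.p <= 1.0):
        raise ConfigurationError("trait values must lie in (0, 1]")


Stage = Literal["post_mutation", "founders", "post_harvest"]


@dataclass
class PopulationState:
    cycle: int
    stage: Stage
    genotypes: list[Genotype]
    counts: np.ndarray  # int64, parallel to genotypes
    registry: MutationRegistry = field(default_factory=MutationRegistry)
    # trait vectors parallel to `genotypes`, built lazily and carried through
    # the cycle operations so they are never reassembled from objects twice
    c_values: np.ndarray | None = None
    p_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.genotypes) != len(self.counts):
            raise SimulationError("genotype list and count vector length mismatch")
        if len(self.genotypes) == 0:
            raise SimulationError("population must contain at least one genotype")
        if (self.counts < 0).any():
            raise SimulationError("abundances must be nonnegative")

    @property
    def abundance(self) -> dict[int, int]:
        """Genotype-id -> abundance map (zero-count genotypes omitted)."""
        return {
            g.id: int(n) for g, n in zip(self.genotypes, self.counts) if n > 0
        }

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def trait_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self.c_values is None or self.p_values is None:
            n = len(self.genotypes)
            self.c_values = np.fromiter((g.c for g in self.genotypes), dtype=float, count=n)
            self.p_values = np.fromiter((g.p for g in self.genotypes), dtype=float, count=n)
        return self.c_values, self.p_values

    def pruned(self) -> "PopulationState":
        """Drop zero-count genotypes."""
        keep = self.counts > 0
        if keep.all():
            return self
        genos = [g for g, k in zip(self.genotypes, keep) if k]
        c, p = self.trait_arrays()
        return PopulationState(self.cycle, self.stage, genos, self.counts[keep],
                               self.registry, c[keep], p[keep])


def monomorphic_population(
    c0: float, p0: float, size: int, registry: MutationRegistry | None = None
) -> PopulationState:
    """A single-ancestor rhizosphere population at cycle 0 (post-harvest stage)."""
    reg = registry or MutationRegistry()
    anc = Genotype(id=reg.new_genotype_id(), parent_id=None, c=c0, p=p0)
    validate_genotype(anc)
    return PopulationState(0, "post_harvest", [anc], np.array([size]), reg)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the serial nodulation-cycle model.

    ``B`` is the host-entry bottleneck (nodules per cycle), ``U`` the expected
    number of hypermutagenesis events per cell per rhizosphere phase, and
    ``K_max`` the nodule carrying capacity at proliferation trait 1.  The
    ancestor is monomorphic with traits ``(c0, p0)``.  ``domain_bounds`` are
    the iso-fitness values separating low / mid / high fitness domains.
    """

    B: int = 100
    n_cycles: int = 50
    n_replicates: int = 100
    rhizosphere_size: int = 1_000_000
    U: float = 0.01
    K_max: int = 1_000_000
    c0: float = 1e-4
    p0: float = 1e-4
    ordering: Literal["bottleneck_first", "proliferation_first"] = "bottleneck_first"
    architecture: MutationArchitecture = field(default_factory=MutationArchitecture)
    seed: int = 0
    domain_bounds: tuple[float, float] = (1e-5, 1e-3)
    summary_stat: Literal["median", "mean"] = "median"

    def validate(self) -> None:
        if self.B < 1:
            raise ConfigurationError("B must be >= 1")
        if self.B > self.rhizosphere_size:
            raise ConfigurationError("B cannot exceed rhizosphere_size")
        if self.n_cycles < 0 or self.n_replicates < 1:
            raise ConfigurationError("n_cycles must be >= 0 and n_replicates >= 1")
        if self.U < 0:
            raise ConfigurationError("mutation rate U must be >= 0")
        if self.K_max < 1:
            raise ConfigurationError("K_max must be >= 1")
        if not (0 < self.c0 <= 1 and 0 < self.p0 <= 1):
            raise ConfigurationError("ancestor traits must lie in (0, 1]")
        lo, hi = self.domain_bounds
        if not lo < hi:
            raise ConfigurationError("domain_bounds must be strictly increasing")
        if self.ordering not in ("bottleneck_first", "proliferation_first"):
            raise ConfigurationError(f"unknown ordering {self.ordering!r}")
        self.architecture.validate()


# ---------------------------------------------------------------------------
# life-cycle operations
# ---------------------------------------------------------------------------


def apply_hypermutagenesis(
    pop: PopulationState,
    U: float,
    arch: MutationArchitecture,
    rng: np.random.Generator,
) -> PopulationState:
    """Rhizosphere hypermutagenesis: spawn new single-cell mutant genotypes.

    The number of mutation events per genotype is Poisson with mean
    ``abundance * U``; each event moves one cell from the parent into a new
    genotype whose traits are the parent's times the drawn factors, clamped
    at the theoretical optimum 1.  Total abundance is conserved.
    """
    if U < 0:
        raise ConfigurationError("mutation rate U must be >= 0")
    c_arr, p_arr = pop.trait_arrays()
    if U == 0:
        return PopulationState(pop.cycle, "post_mutation", list(pop.genotypes),
                               pop.counts.copy(), pop.registry, c_arr, p_arr)
    n_events = rng.poisson(pop.counts * U)
    # cannot mutate more cells than a genotype has
    n_events = np.minimum(n_events, pop.counts)
    total_new = int(n_events.sum())
    counts = pop.counts - n_events
    genotypes = list(pop.genotypes)
    new_c = new_p = np.empty(0)
    if total_new:
        c_fac, p_fac = arch.draw_factors(total_new, rng)
        reg = pop.registry
        cycle = pop.cycle + 1  # events happen during the upcoming cycle
        mid0 = reg.add_batch(cycle, c_fac, p_fac)
        gid0 = reg.reserve_genotype_ids(total_new)
        parent_idx = np.repeat(np.arange(len(genotypes)), n_events)
        new_c = np.minimum(1.0, c_arr[parent_idx] * c_fac)
        new_p = np.minimum(1.0, p_arr[parent_idx] * p_fac)
        mutation_histories = [genotypes[i].mutations for i in parent_idx]
        parent_ids = [genotypes[i].id for i in parent_idx]
        genotypes.extend(
            Genotype(gid0 + k, parent_ids[k], new_c[k], new_p[k],
                     mutation_histories[k] + (mid0 + k,))
            for k in range(total_new)
        )
        counts = np.concatenate([counts, np.ones(total_new, dtype=np.int64)])
    state = PopulationState(
        pop.cycle, "post_mutation", genotypes, counts, pop.registry,
        np.concatenate([c_arr, new_c]), np.concatenate([p_arr, new_p]),
    )
    return state.pruned()


def sample_founders(pop: PopulationState, B: int, rng: np.random.Generator) -> PopulationState:
    """Host-entry bottleneck: multinomial draw of B nodule founders.

    Each nodule is founded by a single cell; genotype weights are
    ``abundance * c`` (competitiveness-weighted lottery).
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    if pop.total < 1:
        raise SimulationError("cannot sample founders from an empty population")
    c, p = pop.trait_arrays()
    weights = pop.counts * c
    probs = weights / weights.sum()
    founder_counts = rng.multinomial(B, probs)
    state = PopulationState(pop.cycle, "founders", list(pop.genotypes),
                            founder_counts, pop.registry, c, p)
    return state.pruned()


def proliferate_and_pool(
    founders: PopulationState,
    K_max: int,
    rhizosphere_size: int,
    rng: np.random.Generator,
    uniform_output: bool = False,
) -> PopulationState:
    """Within-nodule clonal proliferation, harvest, and pooling.

    Each nodule founded by genotype ``g`` grows to ``round(K_max * p_g)``
    cells (at least one); with ``uniform_output`` every nodule contributes
    ``K_max`` regardless of trait (used when proliferation acted before the
    bottleneck).  The pooled harvest is resampled multinomially to
    ``rhizosphere_size``, preserving expected frequencies — the analogue of
    crushing, diluting and re-inoculating a fixed-size rhizosphere.
    """
    if K_max < 1:
        raise ConfigurationError("K_max must be >= 1")
    if founders.stage != "founders":
        raise SimulationError("proliferate_and_pool expects a founders-stage state")
    c, p = founders.trait_arrays()
    if uniform_output:
        per_nodule = np.full(len(p), float(K_max))
    else:
        per_nodule = np.maximum(1.0, np.rint(K_max * p))
    pooled = founders.counts * per_nodule
    probs = pooled / pooled.sum()
    counts = rng.multinomial(rhizosphere_size, probs)
    state = PopulationState(founders.cycle, "post_harvest", list(founders.genotypes),
                            counts, founders.registry, c, p)
    return state.pruned()


def _amplify_by_proliferation(
    pop: PopulationState, rhizosphere_size: int, rng: np.random.Generator
) -> PopulationState:
    """Clonal multiplication in the external compartment, proportional to p."""
    c, p = pop.trait_arrays()
    weights = pop.counts * p
    probs = weights / weights.sum()
    counts = rng.multinomial(rhizosphere_size, probs)
    state = PopulationState(pop.cycle, "post_mutation", list(pop.genotypes),
                            counts, pop.registry, c, p)
    return state.pruned()


def run_cycle(
    state: PopulationState, config: SimulationConfig, rng: np.random.Generator
) -> PopulationState:
    """One full host cycle; returns the next post-harvest rhizosphere state."""
    mutated = apply_hypermutagenesis(state, config.U, config.architecture, rng)
    if config.ordering == "bottleneck_first":
        founders = sample_founders(mutated, config.B, rng)
        nxt = proliferate_and_pool(founders, config.K_max, config.rhizosphere_size, rng)
    elif config.ordering == "proliferation_first":
        amplified = _amplify_by_proliferation(mutated, config.rhizosphere_size, rng)
        founders = sample_founders(amplified, config.B, rng)
        nxt = proliferate_and_pool(
            founders, config.K_max, config.rhizosphere_size, rng, uniform_output=True
        )
    else:
        raise ConfigurationError(f"unknown ordering {config.ordering!r}")
    nxt.cycle = state.cycle + 1
    return nxt


# ---------------------------------------------------------------------------
# summaries and results
# ---------------------------------------------------------------------------


def classify_fitness_domain(
    f: float, bounds: tuple[float, float] = (1e-5, 1e-3)
) -> Literal["low", "mid", "high"]:
    """Partition fitness into low (< lower bound), mid, high (> upper bound).

    Boundary values classify as mid (strict inequalities on both sides).
    """
    if f <= 0:
        raise ValueError("fitness must be positive")
    lo, hi = bounds
    if f < lo:
        return "low"
    if f > hi:
        return "high"
    return "mid"


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


@dataclass(frozen=True)
class FitnessSummary:
    cycle: int
    c_summary: float
    p_summary: float
    fitness: float
    domain: Literal["low", "mid", "high"]


def summarize_population(pop: PopulationState, config: SimulationConfig) -> FitnessSummary:
    """Abundance-weighted trait summary; fitness is the product of summaries."""
    c, p = pop.trait_arrays()
    w = pop.counts.astype(float)
    if config.summary_stat == "median":
        cs = _weighted_median(c, w)
        ps = _weighted_median(p, w)
    else:
        cs = float(np.average(c, weights=w))
        ps = float(np.average(p, weights=w))
    f = cs * ps
    return FitnessSummary(pop.cycle, cs, ps, f, classify_fitness_domain(f, config.domain_bounds))


@dataclass
class MutationTrack:
    """Sparse population-frequency track of one mutation.

    ``freqs[i]`` is the frequency at the post-harvest census of cycle
    ``first_census + i``; the track is contiguous (a mutation exists only in
    genotypes carrying it, so presence across censuses has no gaps) and the
    frequency is zero at every census outside the recorded window.
    """

    first_census: int
    freqs: list[float] = field(default_factory=list)

    @property
    def max_frequency(self) -> float:
        return max(self.freqs) if self.freqs else 0.0

    def frequency_at(self, cycle: int) -> float:
        i = cycle - self.first_census
        if 0 <= i < len(self.freqs):
            return self.freqs[i]
        return 0.0


@dataclass(frozen=True)
class SelectedMutation:
    id: int
    cycle_of_origin: int
    c_factor: float
    p_factor: float
    fold_effect: float
    domain_at_origin: Literal["low", "mid", "high"]
    max_frequency: float


@dataclass
class SimulationResult:
    config: SimulationConfig
    seed: int
    summaries: list[FitnessSummary]  # index = cycle, 0..n_cycles
    tracks: dict[int, MutationTrack]  # mutation id -> track (never-censused = all-zero, omitted)
    registry: MutationRegistry

    @property
    def n_mutation_events(self) -> int:
        return len(self.registry)


def selected_mutation_fold_effects(
    result: SimulationResult, threshold: float = 0.3
) -> list[SelectedMutation]:
    """Mutations whose frequency track ever reached ``threshold``.

    The fitness domain is evaluated at the population state in which the
    mutation arose (the census preceding its cycle of origin), not at the
    cycle where it crossed the threshold.
    """
    out: list[SelectedMutation] = []
    for mid, track in result.tracks.items():
        mx = track.max_frequency
        if mx >= threshold:
            ev = result.registry.get(mid)
            origin_summary = result.summaries[ev.cycle_of_origin - 1]
            out.append(
                SelectedMutation(
                    id=mid,
                    cycle_of_origin=ev.cycle_of_origin,
                    c_factor=ev.c_factor,
                    p_factor=ev.p_factor,
                    fold_effect=ev.fold_effect,
                    domain_at_origin=origin_summary.domain,
                    max_frequency=mx,
                )
            )
    out.sort(key=lambda s: s.id)
    return out


def run_simulation(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run one replicate from a monomorphic ancestor; bit-reproducible by seed."""
    config.validate()
    used_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    state = monomorphic_population(config.c0, config.p0, config.rhizosphere_size)
    summaries = [summarize_population(state, config)]
    tracks: dict[int, MutationTrack] = {}
    for t in range(1, config.n_cycles + 1):
        state = run_cycle(state, config, rng)
        summaries.append(summarize_population(state, config))
        # census mutation frequencies
        acc: dict[int, int] = {}
        for g, cnt in zip(state.genotypes, state.counts):
            n = int(cnt)
            for mid in g.mutations:
                acc[mid] = acc.get(mid, 0) + n
        total = state.total
        for mid, n in acc.items():
            track = tracks.get(mid)
            if track is None:
                track = MutationTrack(first_census=t)
                tracks[mid] = track
            track.freqs.append(n / total)
    return SimulationResult(
        config=config, seed=used_seed, summaries=summaries,
        tracks=tracks, registry=state.registry,
    )


def run_replicates(config: SimulationConfig) -> Iterator[SimulationResult]:
    """Yield ``config.n_replicates`` independent replicates.

    Per-replicate seeds are derived from ``config.seed`` via a seed sequence,
    so the whole ensemble is reproducible from the single master seed.
    """
    config.validate()
    child_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_replicates)
    for s in child_seeds:
        yield run_simulation(replace(config, seed=int(s & 0x7FFFFFFF)))
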