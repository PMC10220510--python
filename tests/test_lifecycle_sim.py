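"""Unit and property tests of the serial life-cycle simulator."""

import itertools
import math

import numpy as np
import pytest

from symevol import lifecycle_sim as ls


def point_arch(value, pi_c=0.0, pi_p=0.0, pi_cp=0.0):
    return ls.MutationArchitecture(
        pi_c=pi_c, pi_p=pi_p, pi_cp=pi_cp, frac_beneficial=1.0,
        effect_dist=ls.EffectDistribution(name="point", point_value=value),
    )


def two_genotype_pop(counts, c, p, size_scale=1):
    reg = ls.MutationRegistry()
    genos = [
        ls.Genotype(reg.new_genotype_id(), None, c[i], p[i]) for i in range(len(counts))
    ]
    return ls.PopulationState(
        0, "post_harvest", genos, np.array(counts) * size_scale, reg
    )


# ---------------------------------------------------------------------------
# mutation effects
# ---------------------------------------------------------------------------


class TestDrawMutationEffect:
    def test_point_mass_c_only(self, rng):
        c_fac, p_fac = ls.draw_mutation_effect(point_arch(10.0, pi_c=1.0), rng)
        assert (c_fac, p_fac) == (10.0, 1.0)

    def test_point_mass_p_only(self, rng):
        c_fac, p_fac = ls.draw_mutation_effect(point_arch(0.5, pi_p=1.0), rng)
        assert (c_fac, p_fac) == (1.0, 0.5)

    def test_log_uniform_moment(self, rng):
        # log10 of a log-uniform factor on [1, 100] is uniform on [0, 2]:
        # mean 1, sd 2/sqrt(12)
        arch = ls.MutationArchitecture(
            pi_c=1.0, pi_p=0.0, pi_cp=0.0, frac_beneficial=1.0,
            effect_dist=ls.EffectDistribution(beneficial_range=(1.0, 100.0)),
        )
        c_fac, _ = arch.draw_factors(100_000, rng)
        se = (2 / math.sqrt(12)) / math.sqrt(100_000)
        assert abs(np.log10(c_fac).mean() - 1.0) < 3 * se

    def test_invalid_probabilities_rejected(self, rng):
        arch = ls.MutationArchitecture(pi_c=0.8, pi_p=0.8, pi_cp=0.0)
        with pytest.raises(ls.ConfigurationError):
            ls.draw_mutation_effect(arch, rng)


# ---------------------------------------------------------------------------
# hypermutagenesis
# ---------------------------------------------------------------------------


class TestHypermutagenesis:
    def test_zero_rate_is_identity(self, rng):
        pop = two_genotype_pop([600, 400], c=[0.5, 0.2], p=[0.3, 0.9])
        out = ls.apply_hypermutagenesis(pop, 0.0, ls.MutationArchitecture(), rng)
        assert out.stage == "post_mutation"
        assert out.abundance == pop.abundance

    def test_poisson_event_count(self):
        # 1e6 cells at U=1e-5: mean 10 new genotypes per call
        rng = np.random.default_rng(5)
        arch = ls.MutationArchitecture()
        pop = ls.monomorphic_population(0.5, 0.5, 1_000_000)
        n_new = [
            len(ls.apply_hypermutagenesis(pop, 1e-5, arch, rng).genotypes) - 1
            for _ in range(1000)
        ]
        se = math.sqrt(10 / 1000)
        assert abs(np.mean(n_new) - 10) < 3 * se

    def test_total_abundance_conserved(self, rng):
        pop = two_genotype_pop([700, 300], c=[0.5, 0.2], p=[0.3, 0.9], size_scale=1000)
        out = ls.apply_hypermutagenesis(pop, 0.01, ls.MutationArchitecture(), rng)
        assert out.total == pop.total

    def test_traits_clamped_at_optimum_and_positive(self, rng):
        pop = two_genotype_pop([1000], c=[0.5], p=[0.5])
        arch = point_arch(100.0, pi_cp=1.0)
        out = ls.apply_hypermutagenesis(pop, 0.5, arch, rng)
        c, p = out.trait_arrays()
        assert c.max() <= 1.0 and p.max() <= 1.0
        assert c.min() > 0.0 and p.min() > 0.0
        # mutants reach the optimum exactly: 0.5 * 100 clamps to 1
        assert any(g.c == 1.0 and g.p == 1.0 for g in out.genotypes[1:])

    def test_fixed_seed_reproducible(self):
        outs = []
        for _ in range(2):
            pop = two_genotype_pop([900, 100], c=[0.4, 0.8], p=[0.3, 0.6],
                                   size_scale=100)
            rng = np.random.default_rng(77)
            out = ls.apply_hypermutagenesis(pop, 0.01, ls.MutationArchitecture(), rng)
            outs.append(
                (out.counts.tolist(), [(g.c, g.p, g.mutations) for g in out.genotypes])
            )
        assert outs[0] == outs[1]

    def test_negative_rate_rejected(self, rng):
        pop = two_genotype_pop([10], c=[0.5], p=[0.5])
        with pytest.raises(ls.ConfigurationError):
            ls.apply_hypermutagenesis(pop, -1e-5, ls.MutationArchitecture(), rng)


# ---------------------------------------------------------------------------
# host-entry bottleneck
# ---------------------------------------------------------------------------


def exact_founder_distribution(counts, c, B):
    """Brute-force multinomial pmf over founder count vectors."""
    weights = np.asarray(counts) * np.asarray(c)
    probs = weights / weights.sum()
    dist = {}
    k = len(counts)
    for combo in itertools.product(range(B + 1), repeat=k):
        if sum(combo) != B:
            continue
        coef = math.factorial(B)
        pr = 1.0
        for n_i, p_i in zip(combo, probs):
            coef //= math.factorial(n_i)
            pr *= p_i**n_i
        dist[combo] = coef * pr
    return dist


class TestSampleFounders:
    def test_single_genotype_all_founders(self, rng):
        pop = two_genotype_pop([1000], c=[0.3], p=[0.3])
        out = ls.sample_founders(pop, 50, rng)
        assert out.stage == "founders"
        assert out.total == 50
        assert len(out.genotypes) == 1

    def test_competitiveness_weighted_lottery(self):
        # equal abundance, c = (0.9, 0.1): P(founder is genotype 1) = 0.9
        rng = np.random.default_rng(3)
        pop = two_genotype_pop([500, 500], c=[0.9, 0.1], p=[0.5, 0.5])
        n = 30_000
        wins = 0
        for _ in range(n):
            out = ls.sample_founders(pop, 1, rng)
            wins += out.genotypes[0].id == 0
        se = math.sqrt(0.9 * 0.1 / n)
        assert abs(wins / n - 0.9) < 3 * se

    def test_abundance_weighted_expectation(self):
        # abundances (100, 300), equal c: founder fraction of genotype 2 -> 0.75
        rng = np.random.default_rng(4)
        pop = two_genotype_pop([100, 300], c=[0.5, 0.5], p=[0.5, 0.5])
        B = 20_000
        out = ls.sample_founders(pop, B, rng)
        frac = out.abundance.get(1, 0) / B
        se = math.sqrt(0.75 * 0.25 / B)
        assert abs(frac - 0.75) < 3 * se

    @pytest.mark.parametrize(
        "counts,c,B",
        [
            ([3, 7], [0.5, 0.5], 2),
            ([1, 1, 2], [0.9, 0.05, 0.05], 2),
            ([5, 5, 5], [0.2, 0.3, 0.5], 1),
        ],
    )
    def test_matches_exact_multinomial_enumeration(self, counts, c, B):
        rng = np.random.default_rng(11)
        pop = two_genotype_pop(counts, c=c, p=[0.5] * len(counts))
        exact = exact_founder_distribution(counts, c, B)
        n = 20_000
        seen = {combo: 0 for combo in exact}
        for _ in range(n):
            out = ls.sample_founders(pop, B, rng)
            combo = tuple(out.abundance.get(gid, 0) for gid in range(len(counts)))
            seen[combo] += 1
        for combo, prob in exact.items():
            se = math.sqrt(prob * (1 - prob) / n)
            assert abs(seen[combo] / n - prob) <= 3 * se + 1e-12

    def test_empty_population_rejected(self, rng):
        pop = two_genotype_pop([1], c=[0.5], p=[0.5])
        pop.counts[0] = 0
        with pytest.raises(ls.SimulationError):
            ls.sample_founders(pop, 5, rng)


# ---------------------------------------------------------------------------
# proliferation and pooling
# ---------------------------------------------------------------------------


class TestProliferateAndPool:
    def _founders(self, counts, p):
        pop = two_genotype_pop(counts, c=[0.5] * len(counts), p=p)
        pop.stage = "founders"
        return pop

    def test_proliferation_weighted_pool(self, rng):
        # nodule outputs 2*1000 and 1*500: expected frequencies 0.8 / 0.2
        founders = self._founders([2, 1], p=[1.0, 0.5])
        out = ls.proliferate_and_pool(founders, 1000, 1_000_000, rng)
        freq = out.counts[0] / out.total
        se = math.sqrt(0.8 * 0.2 / 1_000_000)
        assert abs(freq - 0.8) < 3 * se

    def test_equal_proliferation_preserves_founder_frequencies(self, rng):
        founders = self._founders([30, 70], p=[0.4, 0.4])
        out = ls.proliferate_and_pool(founders, 1000, 1_000_000, rng)
        se = math.sqrt(0.3 * 0.7 / 1_000_000)
        assert abs(out.counts[0] / out.total - 0.3) < 3 * se

    def test_single_founder_monomorphic(self, rng):
        founders = self._founders([5], p=[0.2])
        out = ls.proliferate_and_pool(founders, 1000, 10_000, rng)
        assert len(out.genotypes) == 1
        assert out.total == 10_000

    def test_invalid_kmax_rejected(self, rng):
        with pytest.raises(ls.ConfigurationError):
            ls.proliferate_and_pool(self._founders([1], p=[0.5]), 0, 100, rng)


# ---------------------------------------------------------------------------
# full cycle
# ---------------------------------------------------------------------------


class TestRunCycle:
    def test_no_mutation_monomorphic_identity(self, rng):
        cfg = ls.SimulationConfig(U=0.0, B=10, rhizosphere_size=10_000)
        state = ls.monomorphic_population(0.3, 0.4, 10_000)
        out = ls.run_cycle(state, cfg, rng)
        assert len(out.genotypes) == 1
        assert (out.genotypes[0].c, out.genotypes[0].p) == (0.3, 0.4)
        assert out.cycle == 1

    def test_bottleneck_of_one_fixes_single_genotype(self, rng):
        cfg = ls.SimulationConfig(U=0.01, B=1, rhizosphere_size=10_000)
        state = ls.monomorphic_population(0.3, 0.4, 10_000)
        out = ls.run_cycle(state, cfg, rng)
        assert len(out.genotypes) == 1

    def test_ordering_changes_founder_weights(self):
        # equal abundance and c, p ratio 2:1: founder fraction of the fast
        # proliferator is 2/3 when proliferation precedes the bottleneck,
        # 1/2 when the bottleneck comes first.
        rng = np.random.default_rng(8)
        B = 20_000
        pop = two_genotype_pop([50_000, 50_000], c=[0.5, 0.5], p=[0.8, 0.4])
        amplified = ls._amplify_by_proliferation(pop, 100_000, rng)
        founders = ls.sample_founders(amplified, B, rng)
        frac_pf = founders.abundance[0] / B
        se = math.sqrt((2 / 3) * (1 / 3) / B)
        assert abs(frac_pf - 2 / 3) < 4 * se
        founders_bf = ls.sample_founders(pop, B, rng)
        frac_bf = founders_bf.abundance[0] / B
        se = math.sqrt(0.25 / B)
        assert abs(frac_bf - 0.5) < 4 * se

    def test_neutral_drift_martingale(self):
        # with neutral mutations only, expected genotype frequency is
        # unchanged across one full cycle
        rng = np.random.default_rng(9)
        cfg = ls.SimulationConfig(
            U=0.01, B=50, rhizosphere_size=10_000, K_max=1000,
            architecture=point_arch(1.0, pi_cp=1.0),
        )
        fracs = []
        for _ in range(400):
            pop = two_genotype_pop([3000, 7000], c=[0.5, 0.5], p=[0.5, 0.5])
            out = ls.run_cycle(pop, cfg, rng)
            # genotype 1 plus its mutant descendants (all neutral)
            frac = sum(
                n for g, n in zip(out.genotypes, out.counts)
                if g.id == 1 or g.parent_id == 1
            ) / out.total
            fracs.append(frac)
        per_cycle_se = math.sqrt(0.3 * 0.7 / 50)  # founder sampling dominates
        assert abs(np.mean(fracs) - 0.7) < 3 * per_cycle_se / math.sqrt(len(fracs))


# ---------------------------------------------------------------------------
# whole simulations
# ---------------------------------------------------------------------------


class TestRunSimulation:
    def test_no_mutation_constant_fitness(self):
        cfg = ls.SimulationConfig(U=0.0, B=10, n_cycles=10, rhizosphere_size=10_000,
                                  c0=1e-2, p0=1e-1, seed=1)
        res = ls.run_simulation(cfg)
        assert len(res.summaries) == 11
        assert all(s.fitness == pytest.approx(1e-3) for s in res.summaries)
        assert res.tracks == {}

    def test_low_fitness_ancestor_starts_low(self):
        cfg = ls.SimulationConfig(n_cycles=0, seed=1)
        res = ls.run_simulation(cfg)
        assert res.summaries[0].fitness == pytest.approx(1e-8)
        assert res.summaries[0].domain == "low"

    def test_fixed_seed_bit_identical(self):
        cfg = ls.SimulationConfig(B=10, n_cycles=8, rhizosphere_size=100_000, seed=21)
        a = ls.run_simulation(cfg)
        b = ls.run_simulation(cfg)
        assert a.summaries == b.summaries
        assert {k: v.freqs for k, v in a.tracks.items()} == {
            k: v.freqs for k, v in b.tracks.items()
        }

    def test_median_fitness_nearly_monotone(self):
        # selection plus trait clamping make the across-replicate median
        # fitness essentially non-decreasing in time
        cfg = ls.SimulationConfig(B=100, n_cycles=25, n_replicates=20, seed=3)
        fits = np.array(
            [[s.fitness for s in res.summaries] for res in ls.run_replicates(cfg)]
        )
        med = np.median(fits, axis=0)
        frac_nondecreasing = np.mean(np.diff(med) >= 0)
        assert frac_nondecreasing >= 0.95

    def test_founder_total_always_B(self, rng):
        cfg = ls.SimulationConfig(B=7, rhizosphere_size=1000, U=0.05)
        state = ls.monomorphic_population(0.1, 0.1, 1000)
        mutated = ls.apply_hypermutagenesis(state, cfg.U, cfg.architecture, rng)
        founders = ls.sample_founders(mutated, cfg.B, rng)
        assert founders.total == cfg.B


class TestFitnessDomains:
    @pytest.mark.parametrize(
        "f,expected",
        [(1e-6, "low"), (1e-4, "mid"), (1e-2, "high"),
         (1e-5, "mid"), (1e-3, "mid")],  # boundaries are mid (strict bounds)
    )
    def test_classification(self, f, expected):
        assert ls.classify_fitness_domain(f) == expected

    def test_nonpositive_fitness_rejected(self):
        with pytest.raises(ValueError):
            ls.classify_fitness_domain(0.0)


class TestSelectedMutations:
    def _result(self, tracks_spec, effects):
        """Build a minimal SimulationResult by hand."""
        cfg = ls.SimulationConfig(n_cycles=5, seed=0)
        reg = ls.MutationRegistry()
        tracks = {}
        for (cycle, c_fac, p_fac), freqs in zip(effects, tracks_spec):
            mid = reg.new_event(cycle, c_fac, p_fac)
            tracks[mid] = ls.MutationTrack(first_census=cycle, freqs=freqs)
        summaries = [
            ls.FitnessSummary(t, 1e-4, 1e-4, 1e-8, "low") for t in range(6)
        ]
        return ls.SimulationResult(cfg, 0, summaries, tracks, reg)

    def test_fold_effect_and_domain(self):
        res = self._result([[0.1, 0.5]], [(1, 10.0, 1.0)])
        (sel,) = ls.selected_mutation_fold_effects(res)
        assert sel.fold_effect == pytest.approx(10.0)
        assert sel.domain_at_origin == "low"
        assert sel.max_frequency == pytest.approx(0.5)

    def test_neutral_hitchhiker_fold_one(self):
        res = self._result([[0.35]], [(2, 1.0, 1.0)])
        (sel,) = ls.selected_mutation_fold_effects(res)
        assert sel.fold_effect == pytest.approx(1.0)

    def test_no_track_reaching_threshold(self):
        res = self._result([[0.1, 0.29]], [(1, 5.0, 1.0)])
        assert ls.selected_mutation_fold_effects(res) == []


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"B": 0},
            {"B": 200, "rhizosphere_size": 100},
            {"U": -1.0},
            {"K_max": 0},
            {"c0": 0.0},
            {"c0": 1.5},
            {"domain_bounds": (1e-3, 1e-5)},
            {"ordering": "sideways"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ls.ConfigurationError):
            ls.SimulationConfig(**kwargs).validate()
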