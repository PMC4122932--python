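"""Selection-phase engine: demography, stopping rules, sampling, dynamics."""

import numpy as np
import pytest

from kskscan.coalescent import (
    seed_hard_sweep_variant,
    simulate_neutral_start,
)
from kskscan.models import MsatFitnessSurface, MsatMutationModel, SnvSelectionModel
from kskscan.wright_fisher import (
    DemographyPlan,
    DirectPopulation,
    SimConfig,
    _direct_generation,
    detect_equilibrium,
    population_size_at,
    run_selection_phase,
    sample_population,
)


class TestDetectEquilibrium:
    def test_examples(self):
        assert detect_equilibrium(0.4300, 0.43004, 10_000) is True
        assert detect_equilibrium(0.43, 0.44, 10_000) is False

    def test_threshold_is_half_per_chromosome(self):
        # at N = 10,000 the threshold is exactly 5e-5
        assert detect_equilibrium(0.5, 0.5 + 4.99e-5, 10_000)
        assert not detect_equilibrium(0.5, 0.5 + 5.01e-5, 10_000)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            detect_equilibrium(1.2, 0.5, 100)


class TestPopulationSizeAt:
    def test_constant(self):
        plan = DemographyPlan(mode="constant", n0=10_000)
        assert population_size_at(0, plan) == 10_000
        assert population_size_at(500, plan) == 10_000

    def test_bottleneck_onset(self):
        plan = DemographyPlan(mode="bottleneck_expansion", n0=10_000)
        assert population_size_at(0, plan) == 500
        assert population_size_at(1, plan) > 500 - 1
        # exponential growth at 0.005/generation
        assert population_size_at(200, plan) == round(500 * np.exp(1.0))

    def test_exponential_decline_value(self):
        plan = DemographyPlan(mode="exponential_decline", n0=10_000)
        # 10000 * exp(-0.003 * 231) = 5000.7 -> 5001 (independently computed)
        assert population_size_at(231, plan) == 5001

    def test_floor_of_two(self):
        plan = DemographyPlan(mode="exponential_decline", n0=10)
        assert population_size_at(10_000, plan) == 2

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            population_size_at(-1, DemographyPlan())


@pytest.fixture(scope="module")
def small_start():
    start = simulate_neutral_start(40, 2e4, population_size=20,
                                   mu=5e-6, r=5e-7, seed=42)
    return start


class TestSamplePopulation:
    def make_pop(self, start):
        return DirectPopulation.from_start(start)

    def test_fifty_individuals_give_hundred_chromosomes(self):
        start = simulate_neutral_start(200, 1e4, population_size=100,
                                       mu=1e-6, seed=1)
        pop = DirectPopulation.from_start(start)
        sample = sample_population(pop, 50, np.random.default_rng(0))
        assert sample.num_chromosomes == 100

    def test_whole_population_sampled_once(self, small_start):
        pop = self.make_pop(small_start)
        sample = sample_population(pop, 20, np.random.default_rng(1))
        assert sample.num_chromosomes == 40
        # every chromosome appears exactly once: multiset of row sums matches
        expected = sorted(h.size for h in pop.haplotypes)
        assert sorted(sample.matrix.sum(axis=1).tolist()) == expected

    def test_seeded_determinism(self, small_start):
        pop = self.make_pop(small_start)
        a = sample_population(pop, 5, np.random.default_rng(9))
        b = sample_population(pop, 5, np.random.default_rng(9))
        assert np.array_equal(a.matrix, b.matrix)

    def test_oversampling_rejected(self, small_start):
        pop = self.make_pop(small_start)
        with pytest.raises(ValueError):
            sample_population(pop, 21, np.random.default_rng(0))


class TestDirectGeneration:
    def test_no_recombination_no_mutation_copies_parents(self, small_start):
        pop = DirectPopulation.from_start(small_start)
        cfg = SimConfig(target="neutral", mu=0.0, r=0.0, run_generations=1)
        rng = np.random.default_rng(2)
        nxt = _direct_generation(pop, cfg, rng, "neutral", None, None, None, 20)
        parent_set = {h.tobytes() for h in pop.haplotypes}
        assert all(h.tobytes() in parent_set for h in nxt.haplotypes)

    def test_chromosome_count_tracks_demography(self, small_start):
        pop = DirectPopulation.from_start(small_start)
        cfg = SimConfig(target="neutral", mu=0.0, r=0.0, run_generations=5)
        rng = np.random.default_rng(3)
        for n_next in (20, 15, 30, 7):
            pop = _direct_generation(pop, cfg, rng, "neutral", None, None,
                                     None, n_next)
            assert len(pop.haplotypes) == 2 * n_next

    def test_mutation_count_is_poisson(self):
        """Per-generation neutral mutation count ~ Poisson(2 N mu L)."""
        start = simulate_neutral_start(100, 1e4, population_size=50,
                                       mu=0.0, seed=5)
        pop = DirectPopulation.from_start(start)
        cfg = SimConfig(target="neutral", mu=2e-5, r=0.0, run_generations=1)
        rng = np.random.default_rng(4)
        for _ in range(300):
            pop = _direct_generation(pop, cfg, rng, "neutral", None, None,
                                     None, 50)
        counts = np.array(pop.mutation_counts)
        lam = 2 * 50 * 2e-5 * 1e4  # = 20
        assert counts.mean() == pytest.approx(
            lam, abs=3 * np.sqrt(lam / counts.size))
        # Poisson dispersion: variance/mean near 1
        disp = counts.var(ddof=1) / counts.mean()
        assert disp == pytest.approx(1.0, abs=0.25)

    def test_neutral_frequency_change_is_martingale(self):
        start = simulate_neutral_start(200, 1e3, population_size=100,
                                       mu=0.0, seed=6)
        base = DirectPopulation.from_start(start)
        base.focal = np.zeros(200, dtype=np.int64)
        base.focal[:100] = 1
        cfg = SimConfig(target="snv", mu=0.0, r=0.0)
        snv = SnvSelectionModel(s=0.0)
        fit = snv.fitness_by_count()
        rng = np.random.default_rng(7)
        deltas = []
        for _ in range(400):
            pop = DirectPopulation(haplotypes=list(base.haplotypes),
                                   focal=base.focal.copy(),
                                   sequence_length=base.sequence_length)
            nxt = _direct_generation(pop, cfg, rng, "snv", None, fit, None, 100)
            deltas.append(nxt.focal.mean() - 0.5)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se


class TestRunSelectionPhase:
    def test_hard_sweep_reaches_fixation_and_samples(self):
        start = simulate_neutral_start(400, 1e5, population_size=200,
                                       mu=2.5e-7, r=1.25e-7, seed=11)
        rng = np.random.default_rng(0)
        start.focal = seed_hard_sweep_variant(400, rng)
        cfg = SimConfig(target="snv", mu=2.5e-7, r=1.25e-7,
                        max_generations=10**6, sample_individuals=20)
        res = run_selection_phase(start, cfg, seed=5,
                                  snv_model=SnvSelectionModel(s=0.5))
        assert res.converged
        assert res.samples["fixation"].num_chromosomes == 40
        assert res.trajectory[-1] == 1.0

    def test_restart_on_loss_counts(self):
        start = simulate_neutral_start(200, 1e3, population_size=100,
                                       mu=0.0, r=0.0, seed=12)
        rng = np.random.default_rng(1)
        start.focal = seed_hard_sweep_variant(200, rng)
        cfg = SimConfig(target="snv", mu=0.0, r=0.0, max_generations=10**6,
                        sample_individuals=10, include_focal_site=False)
        res = run_selection_phase(start, cfg, seed=6,
                                  snv_model=SnvSelectionModel(s=0.05))
        assert res.trajectory[-1] == 1.0  # conditioned on fixation via restart
        assert res.restarts >= 0

    def test_loss_probability_matches_diffusion(self):
        """Fraction of attempts ending in loss matches the diffusion fixation
        probability for a single copy under additive viability selection
        (u = (1 - exp(-2hs)) / (1 - exp(-4Nhs)))."""
        N, s, h = 500, 0.05, 0.5
        start = simulate_neutral_start(2 * N, 1e3, population_size=N,
                                       mu=0.0, r=0.0, seed=13)
        cfg = SimConfig(target="snv", mu=0.0, r=0.0, max_generations=10**6,
                        sample_individuals=5, include_focal_site=False,
                        record_trajectory=False)
        rng = np.random.default_rng(2)
        successes, attempts = 0, 0
        for i in range(60):
            start.focal = seed_hard_sweep_variant(2 * N, rng)
            res = run_selection_phase(start, cfg, seed=100 + i,
                                      snv_model=SnvSelectionModel(s=s, h=h))
            successes += 1
            attempts += res.restarts + 1
        alpha = 4 * N * h * s
        u = (1 - np.exp(-2 * h * s)) / (1 - np.exp(-alpha))
        se = np.sqrt(u * (1 - u) * attempts) / attempts
        assert successes / attempts == pytest.approx(u, abs=4 * se)

    def test_msat_run_reports_delta_and_balance(self):
        start = simulate_neutral_start(200, 1e4, population_size=100,
                                       mu=1e-6, r=1e-7, seed=14)
        model = MsatMutationModel(phi=5, rate_scale=10)
        surface = MsatFitnessSurface(optimum=10, gradient=-0.3)
        start.focal = np.full(200, 8)
        cfg = SimConfig(target="msat", mu=1e-6, r=1e-7, viability="exp_best",
                        max_generations=20_000, sample_individuals=20)
        res = run_selection_phase(start, cfg, seed=15, surface=surface,
                                  msat_model=model)
        assert res.delta_msat is not None and res.delta_msat > 0
        assert res.balance.frequency(10) > 0.5
        assert "msat_allele_sizes" in res.samples["fixation"].metadata

    def test_post_stop_sampling_offsets(self):
        start = simulate_neutral_start(100, 1e4, population_size=50,
                                       mu=1e-6, r=0.0, seed=16)
        cfg = SimConfig(target="neutral", mu=1e-6, r=0.0, run_generations=3,
                        sample_post_stop=True, post_stop_offsets=(2, 5),
                        sample_individuals=10)
        res = run_selection_phase(start, cfg, seed=17)
        assert set(res.samples) == {"fixation", "+2", "+5"}
        for sample in res.samples.values():
            assert sample.num_chromosomes == 20

    def test_demography_changes_final_size(self):
        start = simulate_neutral_start(200, 1e3, population_size=100,
                                       mu=0.0, r=0.0, seed=18)
        plan = DemographyPlan(mode="exponential_decline", n0=100,
                              decline_rate=-0.05)
        cfg = SimConfig(target="neutral", mu=0.0, r=0.0, run_generations=20,
                        sample_individuals=5)
        res = run_selection_phase(start, cfg, seed=19, demography=plan)
        assert res.final_population_size == population_size_at(19, plan)


class TestEnginesAgree:
    def test_neutral_diversity_distribution_matches(self):
        """The recorded (ancestry + overlay) and direct (literal mutation)
        engines produce samples with matching diversity levels."""
        stats = {"recorded": [], "direct": []}
        cfg = SimConfig(target="neutral", mu=4e-6, r=4e-7, run_generations=40,
                        sample_individuals=15, simplify_interval=25)
        for engine in stats:
            for i in range(12):
                start = simulate_neutral_start(
                    60, 2e4, population_size=30, mu=4e-6, r=4e-7,
                    seed=900 + i)
                res = run_selection_phase(start, cfg, seed=50 + i,
                                          engine=engine)
                sample = res.samples["fixation"]
                n = sample.num_chromosomes
                counts = sample.matrix.sum(axis=0)
                seg = (counts > 0) & (counts < n)
                stats[engine].append(seg.sum())
        a, b = np.array(stats["recorded"]), np.array(stats["direct"])
        pooled_se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert abs(a.mean() - b.mean()) < 3.5 * pooled_se
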