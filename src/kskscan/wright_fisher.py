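"""Forward-in-time Wright-Fisher selection phase.

Each generation applies, in order: viability selection (each diploid survives
with probability equal to its relative genotypic fitness), reproduction with
at most one crossover per transmitted chromosome (probability r*L, breakpoint
uniform), neutral infinite-sites mutation, focal-locus mutation (microsatellite
runs), restart-from-start on loss of the beneficial SNV, and a stopping test —
fixation for an SNV target, mutation-selection balance for a microsatellite
(optimal-allele frequency within 1/2N of its deterministic balance frequency).

Two engines implement the identical model:

* ``recorded`` (default) — transmissions are recorded as tskit ancestry
  tables and neutral mutations are laid onto the recorded genealogy of the
  *sampled* chromosomes afterwards, which yields samples with exactly the
  same distribution as per-generation mutation at a small fraction of the
  cost;
* ``direct`` — every chromosome materializes its derived-allele positions
  and new mutations are added generation by generation, literally following
  the numbered algorithm.  It is slower and serves as an independent
  cross-check of the recorded engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime
import numpy as np
import tskit

from .coalescent import StartState
from .models import (
    AlleleDistribution,
    MsatFitnessSurface,
    MsatMutationModel,
    SnvSelectionModel,
    deterministic_balance,
    delta_msat,
    mutate_sizes,
)
from .stats import HaplotypeSample

__all__ = [
    "DemographyPlan",
    "SimConfig",
    "SimulationResult",
    "population_size_at",
    "detect_equilibrium",
    "run_selection_phase",
    "DirectPopulation",
    "sample_population",
]


@dataclass(frozen=True)
class DemographyPlan:
    """Population-size trajectory from the onset of selection (t = 0).

    ``constant``: N0 throughout.  ``bottleneck_expansion``: instantaneous
    reduction to ``bottleneck_size`` at onset, then exponential growth at
    ``growth_rate`` per generation.  ``exponential_decline``: exponential
    decay from N0 at ``decline_rate`` (negative) per generation.
    """

    mode: str = "constant"
    n0: int = 10_000
    bottleneck_size: int = 500
    growth_rate: float = 0.005
    decline_rate: float = -0.003

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "bottleneck_expansion", "exponential_decline"):
            raise ValueError(f"unknown demography mode {self.mode!r}")

    def size_at(self, t: int) -> int:
        return population_size_at(t, self)


def population_size_at(t: int, plan: DemographyPlan) -> int:
    """Diploid population size ``t`` generations after selection onset."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if plan.mode == "constant":
        n = plan.n0
    elif plan.mode == "bottleneck_expansion":
        n = round(plan.bottleneck_size * math.exp(plan.growth_rate * t))
    else:  # exponential_decline
        n = round(plan.n0 * math.exp(plan.decline_rate * t))
    return max(2, int(n))


def detect_equilibrium(freq_x: float, balance_freq_x: float, N: int) -> bool:
    """Mutation-selection balance reached: |p_x - p̂_x| < 1/(2N)."""
    if not (0 <= freq_x <= 1 and 0 <= balance_freq_x <= 1):
        raise ValueError("frequencies must be in [0, 1]")
    return abs(freq_x - balance_freq_x) < 1.0 / (2 * N)


@dataclass
class SimConfig:
    """Run-time options for the selection phase.

    ``viability='absolute'`` uses survival probability max(0, w) with w the
    relative genotypic fitness; ``'best'`` references fitness to the best
    genotype currently present (survival = max(0, 1 + (w_raw - w_best)));
    ``'exp_best'`` uses survival = exp(g*(d - d_best)) with d the mean
    genotype distance from the optimum — the compounded (rescaled) form of
    the linear surface, appropriate when the gradient has been multiplied by
    a scale factor and a single generation stands for several.  Only
    fitness *differences* drive allele-frequency change, so at unscaled
    (full-N) conditions all three rules agree to first order in g.
    """

    target: str = "msat"  # 'msat' | 'snv' | 'neutral'
    mu: float = 2.5e-8
    r: float = 1.25e-8
    sample_individuals: int = 50
    sample_post_stop: bool = False
    post_stop_offsets: tuple = (100, 250, 500, 1000, 2000)
    max_generations: int | None = None
    run_generations: int | None = None  # for target='neutral'
    simplify_interval: int = 150
    viability: str = "absolute"
    include_focal_site: bool = True
    record_trajectory: bool = True
    restart_limit: int = 100_000
    redraw_limit: int = 1_000

    def __post_init__(self) -> None:
        if self.target not in ("msat", "snv", "neutral"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.viability not in ("absolute", "best", "exp_best"):
            raise ValueError(f"unknown viability rule {self.viability!r}")


@dataclass
class SimulationResult:
    """Outcome of one selection-phase replicate."""

    samples: dict[str, HaplotypeSample]
    stop_generation: int
    restarts: int
    converged: bool
    delta_msat: float | None = None
    balance: AlleleDistribution | None = None
    start_distribution: AlleleDistribution | None = None
    trajectory: np.ndarray | None = None
    seed: int | None = None
    final_population_size: int | None = None


class SimulationBudgetExceeded(RuntimeError):
    pass


def _msat_fitness_tables(surface: MsatFitnessSurface, max_size: int,
                         viability: str) -> np.ndarray:
    """Per-allele lookup: clamped fitness (absolute), raw linear fitness
    (best), or the log-fitness g|x-i| (exp_best)."""
    sizes = np.arange(max_size + 1)
    raw = 1.0 + surface.gradient * np.abs(surface.optimum - sizes)
    if viability == "absolute":
        return np.maximum(raw, 0.0)
    if viability == "best":
        return raw
    return surface.gradient * np.abs(surface.optimum - sizes)  # exp_best


def _survival_probs(focal: np.ndarray, target: str, allele_fit: np.ndarray | None,
                    snv_fit: np.ndarray | None, viability: str) -> np.ndarray:
    if target == "snv":
        counts = focal[0::2] + focal[1::2]
        return snv_fit[counts]
    if target == "neutral":
        return np.ones(focal.size // 2)
    w = 0.5 * (allele_fit[focal[0::2]] + allele_fit[focal[1::2]])
    if viability == "exp_best":
        return np.exp(w - w.max())
    if viability == "best":
        w = w - w.max() + 1.0
    return np.clip(w, 0.0, 1.0)


def run_selection_phase(
    start: StartState,
    config: SimConfig,
    seed: int,
    surface: MsatFitnessSurface | None = None,
    msat_model: MsatMutationModel | None = None,
    snv_model: SnvSelectionModel | None = None,
    demography: DemographyPlan | None = None,
    balance: AlleleDistribution | None = None,
    engine: str = "recorded",
) -> SimulationResult:
    """Run the selection phase from a seeded start state.

    ``start.focal`` must already hold the per-chromosome focal states
    (microsatellite sizes, or 0/1 for the beneficial SNV).  ``balance`` may
    pass a precomputed mutation-selection balance distribution; otherwise it
    is computed from the deterministic recursion.
    """
    if config.target != "neutral" and start.focal is None:
        raise ValueError("start.focal is not seeded")
    if config.target == "msat" and (surface is None or msat_model is None):
        raise ValueError("microsatellite runs need surface and msat_model")
    if config.target == "snv" and snv_model is None:
        raise ValueError("SNV runs need snv_model")
    if config.target == "neutral" and config.run_generations is None:
        raise ValueError("neutral runs need run_generations")
    if demography is None:
        demography = DemographyPlan(mode="constant", n0=start.population_size)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mut_seed = int(np.random.SeedSequence(seed).generate_state(3)[2] % (2**31 - 1)) + 1

    start_dist = balance_freq_x = None
    dmsat = None
    if config.target == "msat":
        start_dist = AlleleDistribution.from_sizes(start.focal)
        if balance is None:
            # the recursion's fixed point does not depend on the init; start
            # at the optimum, which stays well-defined under rescaled
            # gradients where distant alleles clamp to zero fitness
            balance = deterministic_balance(
                surface, msat_model,
                exponential=(config.viability == "exp_best"))
        balance_freq_x = balance.frequency(surface.optimum)
        dmsat = delta_msat(start_dist, balance)
        allele_fit = _msat_fitness_tables(surface, msat_model.max_size, config.viability)
        snv_fit = None
    elif config.target == "snv":
        allele_fit = None
        snv_fit = snv_model.fitness_by_count()
    else:
        allele_fit = snv_fit = None

    max_gen = config.max_generations
    if max_gen is None:
        max_gen = 100 * start.population_size

    if engine == "direct":
        return _run_direct(start, config, rng, mut_seed, surface, msat_model,
                           allele_fit, snv_fit, demography, balance_freq_x,
                           start_dist, balance, dmsat, max_gen, seed)
    if engine != "recorded":
        raise ValueError(f"unknown engine {engine!r}")
    return _run_recorded(start, config, rng, mut_seed, surface, msat_model,
                         allele_fit, snv_fit, demography, balance_freq_x,
                         start_dist, balance, dmsat, max_gen, seed)


# ---------------------------------------------------------------------------
# recorded engine
# ---------------------------------------------------------------------------

class _EdgeBuffer:
    """Bulk store for edges/nodes created since the last table flush."""

    def __init__(self) -> None:
        self.left: list[np.ndarray] = []
        self.right: list[np.ndarray] = []
        self.parent: list[np.ndarray] = []
        self.child: list[np.ndarray] = []
        self.node_times: list[tuple[int, float]] = []  # (count, time)

    def clear(self) -> None:
        self.__init__()

    def flush(self, tables: tskit.TableCollection) -> None:
        if self.node_times:
            counts = np.array([c for c, _ in self.node_times])
            times = np.repeat([t for _, t in self.node_times], counts)
            tables.nodes.append_columns(
                flags=np.zeros(times.size, dtype=np.uint32), time=times)
        if self.left:
            tables.edges.append_columns(
                left=np.concatenate(self.left),
                right=np.concatenate(self.right),
                parent=np.concatenate(self.parent).astype(np.int32),
                child=np.concatenate(self.child).astype(np.int32))
        self.clear()


def _run_recorded(start, config, rng, mut_seed, surface, msat_model, allele_fit,
                  snv_fit, demography, balance_freq_x, start_dist, balance,
                  dmsat, max_gen, seed):
    L = start.sequence_length
    center = L / 2.0
    base_tables = start.ts.dump_tables()
    founder_nodes = start.ts.samples().astype(np.int64)
    focal0 = None if start.focal is None else start.focal.astype(np.int64).copy()

    record = config.mu > 0  # without neutral mutation the ancestry is unobservable
    tables = base_tables.copy()
    buf = _EdgeBuffer()
    cur_nodes = founder_nodes.copy()
    focal = None if focal0 is None else focal0.copy()
    next_id = tables.nodes.num_rows
    gen = 0
    restarts = 0
    trajectory: list[float] = []
    sampled: list[tuple[str, np.ndarray, np.ndarray | None]] = []  # label, nodes, focal states
    stop_generation = None
    converged = True
    target = config.target

    def simplify_now():
        nonlocal tables, cur_nodes, next_id, sampled
        buf.flush(tables)
        keep = [cur_nodes] + [nodes for _, nodes, _ in sampled]
        keep_flat, inverse = np.unique(np.concatenate(keep), return_inverse=True)
        tables.sort()
        node_map = tables.simplify(samples=keep_flat.astype(np.int32),
                                   filter_sites=False)
        remapped = node_map[keep_flat]
        cur_nodes = remapped[inverse[: cur_nodes.size]].astype(np.int64)
        offset = cur_nodes.size
        new_sampled = []
        for label, nodes, fstates in sampled:
            new_sampled.append((label, remapped[inverse[offset: offset + nodes.size]].astype(np.int64), fstates))
            offset += nodes.size
        sampled = new_sampled
        next_id = tables.nodes.num_rows

    def take_sample(label):
        n_ind = cur_nodes.size // 2
        k = config.sample_individuals
        if k > n_ind:
            raise ValueError(f"cannot sample {k} individuals from {n_ind}")
        chosen = rng.choice(n_ind, size=k, replace=False)
        chrom_idx = np.empty(2 * k, dtype=np.int64)
        chrom_idx[0::2], chrom_idx[1::2] = 2 * chosen, 2 * chosen + 1
        fstates = None if focal is None else focal[chrom_idx].copy()
        sampled.append((label, cur_nodes[chrom_idx].copy(), fstates))

    while True:
        n_cur = cur_nodes.size // 2
        if target == "snv":
            freq = focal.mean()
        elif target == "msat":
            freq = np.mean(focal == surface.optimum)
        else:
            freq = math.nan
        if config.record_trajectory:
            trajectory.append(freq)

        if stop_generation is None:
            if target == "snv" and freq >= 1.0:
                stop_generation = gen
            elif target == "msat" and detect_equilibrium(freq, balance_freq_x, n_cur):
                stop_generation = gen
            elif target == "neutral" and gen >= config.run_generations:
                stop_generation = gen
            if stop_generation is not None:
                take_sample("fixation")
                if not config.sample_post_stop or not config.post_stop_offsets:
                    break
        if stop_generation is not None:
            offset = gen - stop_generation
            if offset in config.post_stop_offsets:
                take_sample(f"+{offset}")
            if offset >= max(config.post_stop_offsets):
                break
        if gen >= max_gen:
            converged = False
            if stop_generation is None:
                stop_generation = gen
                take_sample("fixation")
            break

        # --- one generation ---
        n_next = population_size_at(gen, demography)
        w = _survival_probs(focal, target, allele_fit, snv_fit, config.viability) \
            if target != "neutral" else np.ones(n_cur)
        survivors = None
        for _ in range(config.redraw_limit):
            alive = rng.random(n_cur) < w
            if alive.any():
                survivors = np.nonzero(alive)[0]
                break
        if survivors is None:
            raise SimulationBudgetExceeded("no survivors after redraw limit")

        parents = survivors[rng.integers(0, survivors.size, size=2 * n_next)]
        chrom_choice = rng.integers(0, 2, size=2 * n_next)
        first_idx = 2 * parents + chrom_choice
        second_idx = 2 * parents + (1 - chrom_choice)
        cross = rng.random(2 * n_next) < config.r * L
        bp = rng.uniform(0.0, L, size=2 * n_next)

        child_ids = np.arange(next_id, next_id + 2 * n_next, dtype=np.int64)
        next_id += 2 * n_next
        if record:
            buf.node_times.append((2 * n_next, float(-(gen + 1))))
            no_cross = ~cross
            buf.left.append(np.zeros(no_cross.sum()))
            buf.right.append(np.full(no_cross.sum(), L))
            buf.parent.append(cur_nodes[first_idx[no_cross]])
            buf.child.append(child_ids[no_cross])
            if cross.any():
                cbp = bp[cross]
                cchild = child_ids[cross]
                buf.left.append(np.concatenate([np.zeros(cbp.size), cbp]))
                buf.right.append(np.concatenate([cbp, np.full(cbp.size, L)]))
                buf.parent.append(np.concatenate([cur_nodes[first_idx[cross]],
                                                  cur_nodes[second_idx[cross]]]))
                buf.child.append(np.concatenate([cchild, cchild]))
        else:
            no_cross = ~cross

        if focal is not None:
            take_first = no_cross | (bp > center)
            new_focal = np.where(take_first, focal[first_idx], focal[second_idx])
            if target == "msat":
                new_focal = mutate_sizes(new_focal, msat_model, rng)
            focal = new_focal
        cur_nodes = child_ids
        gen += 1

        if target == "snv" and stop_generation is None and focal.sum() == 0:
            restarts += 1
            if restarts > config.restart_limit:
                raise SimulationBudgetExceeded("restart limit exceeded")
            tables = base_tables.copy()
            buf.clear()
            cur_nodes = founder_nodes.copy()
            focal = focal0.copy()
            next_id = tables.nodes.num_rows
            gen = 0
            trajectory.clear()
            sampled.clear()
            continue

        if record and gen % config.simplify_interval == 0:
            simplify_now()

    # finalize: keep only the sampled chromosomes
    if not record:
        samples_out = {}
        for label, nodes, fstates in sampled:
            meta = {"label": label}
            if target == "msat" and fstates is not None:
                meta["msat_allele_sizes"] = fstates
            matrix = np.empty((nodes.size, 0), dtype=np.int8)
            if target == "snv" and fstates is not None and config.include_focal_site \
                    and 0 < fstates.sum() < fstates.size:
                matrix = fstates.astype(np.int8)[:, None]
                positions = np.array([center])
            else:
                positions = np.empty(0)
            samples_out[label] = HaplotypeSample(
                matrix=matrix, positions=positions, sequence_length=L,
                polarized=True, metadata=meta)
        return SimulationResult(
            samples=samples_out, stop_generation=stop_generation,
            restarts=restarts, converged=converged, delta_msat=dmsat,
            balance=balance, start_distribution=start_dist,
            trajectory=np.array(trajectory) if config.record_trajectory else None,
            seed=seed, final_population_size=cur_nodes.size // 2)
    buf.flush(tables)
    all_nodes = [nodes for _, nodes, _ in sampled]
    keep_flat, inverse = np.unique(np.concatenate(all_nodes), return_inverse=True)
    tables.sort()
    node_map = tables.simplify(samples=keep_flat.astype(np.int32))
    remapped = node_map[keep_flat]
    shift = float(gen)
    tables.nodes.time = tables.nodes.time + shift
    tables.mutations.time = tables.mutations.time + shift
    ts = tables.tree_sequence()
    if config.mu > 0 and shift > 0:
        ts = msprime.sim_mutations(ts, rate=config.mu, random_seed=mut_seed,
                                   model=msprime.BinaryMutationModel(),
                                   discrete_genome=False, keep=True,
                                   end_time=shift)
    G = ts.genotype_matrix()
    all_positions = ts.tables.sites.position
    # map each sampled node to its row in the genotype matrix
    ts_samples = ts.samples()
    row_of = {int(node): i for i, node in enumerate(ts_samples)}
    samples_out: dict[str, HaplotypeSample] = {}
    offset = 0
    for label, nodes, fstates in sampled:
        new_nodes = remapped[inverse[offset: offset + nodes.size]]
        offset += nodes.size
        rows = np.array([row_of[int(v)] for v in new_nodes])
        matrix = (G[:, rows] > 0).T.astype(np.int8)
        positions = all_positions.copy()
        meta = {"label": label, "generation_sampled": label}
        if target == "snv" and fstates is not None and config.include_focal_site:
            if 0 < fstates.sum() < fstates.size:
                col = np.searchsorted(positions, center)
                positions = np.insert(positions, col, center)
                matrix = np.insert(matrix, col, fstates.astype(np.int8), axis=1)
        if target == "msat" and fstates is not None:
            meta["msat_allele_sizes"] = fstates
        samples_out[label] = HaplotypeSample(
            matrix=matrix, positions=positions, sequence_length=L,
            polarized=True, metadata=meta)

    return SimulationResult(
        samples=samples_out, stop_generation=stop_generation, restarts=restarts,
        converged=converged, delta_msat=dmsat, balance=balance,
        start_distribution=start_dist,
        trajectory=np.array(trajectory) if config.record_trajectory else None,
        seed=seed, final_population_size=cur_nodes.size // 2)


# ---------------------------------------------------------------------------
# direct engine (literal algorithm; independent cross-check)
# ---------------------------------------------------------------------------

@dataclass
class DirectPopulation:
    """Materialized diploid population: per-chromosome derived-allele
    positions plus focal-locus states."""

    haplotypes: list[np.ndarray]
    focal: np.ndarray | None
    sequence_length: float
    generation: int = 0
    mutation_counts: list[int] = field(default_factory=list)

    @property
    def num_individuals(self) -> int:
        return len(self.haplotypes) // 2

    @classmethod
    def from_start(cls, start: StartState) -> "DirectPopulation":
        return cls(haplotypes=start.haplotype_positions(),
                   focal=None if start.focal is None else start.focal.copy(),
                   sequence_length=start.sequence_length)


def _direct_generation(pop: DirectPopulation, config: SimConfig, rng,
                       target, allele_fit, snv_fit, msat_model, n_next) -> DirectPopulation:
    L = pop.sequence_length
    center = L / 2.0
    n_cur = pop.num_individuals
    focal = pop.focal
    w = _survival_probs(focal, target, allele_fit, snv_fit, config.viability) \
        if target != "neutral" else np.ones(n_cur)
    for _ in range(config.redraw_limit):
        alive = rng.random(n_cur) < w
        if alive.any():
            break
    else:
        raise SimulationBudgetExceeded("no survivors after redraw limit")
    survivors = np.nonzero(alive)[0]
    parents = survivors[rng.integers(0, survivors.size, size=2 * n_next)]
    chrom_choice = rng.integers(0, 2, size=2 * n_next)
    cross = rng.random(2 * n_next) < config.r * L
    bps = rng.uniform(0.0, L, size=2 * n_next)

    new_haps: list[np.ndarray] = []
    new_focal = None if focal is None else np.empty(2 * n_next, dtype=np.int64)
    for t in range(2 * n_next):
        a = 2 * parents[t] + chrom_choice[t]
        b = 2 * parents[t] + 1 - chrom_choice[t]
        if cross[t]:
            bp = bps[t]
            ha, hb = pop.haplotypes[a], pop.haplotypes[b]
            hap = np.concatenate([ha[ha < bp], hb[hb >= bp]])
            if new_focal is not None:
                new_focal[t] = focal[a] if bp > center else focal[b]
        else:
            hap = pop.haplotypes[a]
            if new_focal is not None:
                new_focal[t] = focal[a]
        new_haps.append(hap)

    # neutral mutation: Poisson number of new derived sites per chromosome
    n_mut = rng.poisson(config.mu * L, size=2 * n_next)
    total = int(n_mut.sum())
    pop.mutation_counts.append(total)
    if total:
        for t in np.nonzero(n_mut)[0]:
            new_sites = rng.uniform(0.0, L, size=n_mut[t])
            new_haps[t] = np.sort(np.concatenate([new_haps[t], new_sites]))
    if target == "msat":
        new_focal = mutate_sizes(new_focal, msat_model, rng)
    return DirectPopulation(haplotypes=new_haps, focal=new_focal,
                            sequence_length=L, generation=pop.generation + 1,
                            mutation_counts=pop.mutation_counts)


def sample_population(pop: DirectPopulation, k_individuals: int,
                      rng: np.random.Generator) -> HaplotypeSample:
    """Both chromosomes of ``k`` individuals drawn without replacement."""
    n_ind = pop.num_individuals
    if k_individuals > n_ind:
        raise ValueError(f"cannot sample {k_individuals} of {n_ind} individuals")
    chosen = rng.choice(n_ind, size=k_individuals, replace=False)
    chrom_idx = np.empty(2 * k_individuals, dtype=np.int64)
    chrom_idx[0::2], chrom_idx[1::2] = 2 * chosen, 2 * chosen + 1
    haps = [pop.haplotypes[i] for i in chrom_idx]
    all_pos = np.unique(np.concatenate(haps)) if haps else np.empty(0)
    matrix = np.zeros((len(haps), all_pos.size), dtype=np.int8)
    for row, hap in enumerate(haps):
        matrix[row, np.searchsorted(all_pos, hap)] = 1
    meta = {}
    if pop.focal is not None:
        meta["focal_states"] = pop.focal[chrom_idx].copy()
    return HaplotypeSample(matrix=matrix, positions=all_pos,
                           sequence_length=pop.sequence_length,
                           polarized=True, metadata=meta)


def _run_direct(start, config, rng, mut_seed, surface, msat_model, allele_fit,
                snv_fit, demography, balance_freq_x, start_dist, balance,
                dmsat, max_gen, seed):
    target = config.target
    pop0 = DirectPopulation.from_start(start)
    pop = DirectPopulation(haplotypes=list(pop0.haplotypes),
                           focal=None if pop0.focal is None else pop0.focal.copy(),
                           sequence_length=pop0.sequence_length)
    restarts = 0
    gen = 0
    stop_generation = None
    converged = True
    trajectory: list[float] = []
    samples_out: dict[str, HaplotypeSample] = {}

    def freq_now():
        if target == "snv":
            return pop.focal.mean()
        if target == "msat":
            return float(np.mean(pop.focal == surface.optimum))
        return math.nan

    while True:
        freq = freq_now()
        if config.record_trajectory:
            trajectory.append(freq)
        if stop_generation is None:
            n_cur = pop.num_individuals
            if target == "snv" and freq >= 1.0:
                stop_generation = gen
            elif target == "msat" and detect_equilibrium(freq, balance_freq_x, n_cur):
                stop_generation = gen
            elif target == "neutral" and gen >= config.run_generations:
                stop_generation = gen
            if stop_generation is not None:
                samples_out["fixation"] = sample_population(
                    pop, config.sample_individuals, rng)
                if not config.sample_post_stop or not config.post_stop_offsets:
                    break
        if stop_generation is not None:
            offset = gen - stop_generation
            if offset in config.post_stop_offsets:
                samples_out[f"+{offset}"] = sample_population(
                    pop, config.sample_individuals, rng)
            if offset >= max(config.post_stop_offsets):
                break
        if gen >= max_gen:
            converged = False
            if stop_generation is None:
                stop_generation = gen
                samples_out["fixation"] = sample_population(
                    pop, config.sample_individuals, rng)
            break

        n_next = population_size_at(gen, demography)
        pop = _direct_generation(pop, config, rng, target, allele_fit, snv_fit,
                                 msat_model, n_next)
        gen += 1
        if target == "snv" and stop_generation is None and pop.focal.sum() == 0:
            restarts += 1
            if restarts > config.restart_limit:
                raise SimulationBudgetExceeded("restart limit exceeded")
            pop = DirectPopulation(haplotypes=list(pop0.haplotypes),
                                   focal=pop0.focal.copy(),
                                   sequence_length=pop0.sequence_length)
            gen = 0
            trajectory.clear()
            samples_out.clear()

    return SimulationResult(
        samples=samples_out, stop_generation=stop_generation, restarts=restarts,
        converged=converged, delta_msat=dmsat, balance=balance,
        start_distribution=start_dist,
        trajectory=np.array(trajectory) if config.record_trajectory else None,
        seed=seed, final_population_size=pop.num_individuals)
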