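"""Neutral pre-selection phase: founder haplotypes and focal-locus seeding.

The starting population is drawn from the standard neutral coalescent with
recombination and infinite-sites mutation (via msprime).  The genealogy at the
exact sequence center — where the selected locus sits — is then used to

* seed a microsatellite: the MRCA is assigned a starting allele size
  (default 8, large enough to be modestly mutable) and the size evolves down
  every branch as a continuous-time jump process whose rate is re-evaluated
  after each jump (the rate depends on the current size);
* choose a standing variant: a tree bipartition whose minor side has a leaf
  fraction inside a target frequency interval carries the beneficial SNV; or
* plant a hard-sweep variant on a single random chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import tskit

from .models import MsatMutationModel
from .stats import HaplotypeSample

__all__ = [
    "StartState",
    "NoSuitableBipartition",
    "simulate_neutral_start",
    "seed_microsatellite",
    "choose_standing_variant",
    "seed_hard_sweep_variant",
    "sample_from_tree_sequence",
]

DEFAULT_MRCA_SIZE = 8


class NoSuitableBipartition(RuntimeError):
    """No tree bipartition yields a carrier frequency inside the target range.

    Callers should regenerate the start state (start the replicate over).
    """


@dataclass
class StartState:
    """A neutral founder population ready to enter the selection phase.

    ``ts`` holds both the founder genealogy and the neutral variants (derived
    alleles, infinite sites, continuous positions).  ``focal`` is the
    per-chromosome state of the selected locus at the sequence center:
    microsatellite allele sizes, or 0/1 for an SNV target.
    """

    ts: tskit.TreeSequence
    population_size: int
    mu: float
    r: float
    focal: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def sequence_length(self) -> float:
        return self.ts.sequence_length

    @property
    def num_chromosomes(self) -> int:
        return self.ts.num_samples

    @property
    def focal_position(self) -> float:
        return self.ts.sequence_length / 2.0

    def focal_genealogy(self) -> tskit.Tree:
        """Marginal genealogy at the exact sequence center (branch lengths in
        generations)."""
        return self.ts.at(self.focal_position)

    def focal_genealogy_newick(self) -> str:
        return self.focal_genealogy().as_newick()

    def haplotype_positions(self) -> list[np.ndarray]:
        """Per-chromosome sorted arrays of derived-allele positions (bp)."""
        G = self.ts.genotype_matrix()
        pos = self.ts.tables.sites.position
        out = []
        for j in range(self.ts.num_samples):
            out.append(pos[G[:, j] > 0])
        return out

    def haplotype_sample(self) -> HaplotypeSample:
        G = self.ts.genotype_matrix()
        return HaplotypeSample(
            matrix=(G > 0).T.astype(np.int8),
            positions=self.ts.tables.sites.position.copy(),
            sequence_length=self.ts.sequence_length,
            polarized=True,
            metadata=dict(self.metadata),
        )

    def to_archive(self, directory: str | Path) -> None:
        """Plain-text archive: meta JSON, per-chromosome variant positions,
        focal states, and the focal genealogy in newick."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "population_size": self.population_size,
            "mu": self.mu, "r": self.r,
            "sequence_length": self.sequence_length,
            "num_chromosomes": self.num_chromosomes,
            **self.metadata,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))
        with open(directory / "haplotypes.txt", "w") as fh:
            for positions in self.haplotype_positions():
                fh.write(" ".join(f"{p:.3f}" for p in positions) + "\n")
        if self.focal is not None:
            np.savetxt(directory / "focal.txt", self.focal, fmt="%d")
        (directory / "genealogy.nwk").write_text(self.focal_genealogy_newick())


def simulate_neutral_start(
    num_chromosomes: int,
    sequence_length: float,
    population_size: int,
    mu: float = 2.5e-8,
    r: float = 1.25e-8,
    seed: int | None = None,
    theta: float | None = None,
    rho: float | None = None,
) -> StartState:
    """Neutral coalescent founder population.

    ``theta``/``rho`` (sequence-total 4*N*rate*L values) override ``mu``/``r``
    when given.  ``num_chromosomes`` must be even (diploid founders).
    """
    if num_chromosomes % 2:
        raise ValueError("num_chromosomes must be even (diploids)")
    if sequence_length <= 0:
        raise ValueError("sequence_length must be positive")
    if theta is not None:
        mu = theta / (4.0 * population_size * sequence_length)
    if rho is not None:
        r = rho / (4.0 * population_size * sequence_length)
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1) + 1
    ts = msprime.sim_ancestry(
        samples=num_chromosomes // 2,
        ploidy=2,
        population_size=population_size,
        sequence_length=sequence_length,
        recombination_rate=r,
        random_seed=int(seeds[0]),
    )
    if mu > 0:
        ts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(seeds[1]),
            model=msprime.BinaryMutationModel(), discrete_genome=False,
        )
    return StartState(ts=ts, population_size=population_size, mu=mu, r=r,
                      metadata={"seed": seed, "theta": 4 * population_size * mu * sequence_length,
                                "rho": 4 * population_size * r * sequence_length})


def seed_microsatellite(
    tree: tskit.Tree,
    model: MsatMutationModel,
    rng: np.random.Generator,
    mrca_size: int = DEFAULT_MRCA_SIZE,
) -> np.ndarray:
    """Evolve allele size down a focal genealogy; returns leaf sizes.

    The size performs a continuous-time jump process along each branch: the
    waiting time to the next mutation is exponential with the current size's
    per-generation rate, and the rate is re-evaluated after every jump.
    Leaf values are returned in sample-index order.
    """
    if not model.min_size <= mrca_size <= model.max_size:
        raise ValueError("mrca_size outside allele-size support")
    roots = tree.roots
    if len(roots) != 1:
        raise ValueError("focal genealogy must have a single root")
    n = tree.tree_sequence.num_samples
    leaf_sizes = np.empty(n, dtype=np.int64)
    # iterative DFS carrying the allele size at the top of each branch
    stack = [(roots[0], mrca_size)]
    while stack:
        node, size = stack.pop()
        children = tree.children(node)
        for child in children:
            t = tree.branch_length(child)
            s = size
            remaining = t
            while True:
                rate = model.rate(s)
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait > remaining:
                    break
                remaining -= wait
                s = _step_size(s, model, rng)
            if len(tree.children(child)) == 0:
                leaf_sizes[child] = s
            else:
                stack.append((child, s))
    return leaf_sizes


def _step_size(size: int, model: MsatMutationModel, rng: np.random.Generator) -> int:
    while True:
        step = int(rng.geometric(model.step_p)) * (1 if rng.random() < 0.5 else -1)
        new = size + step
        if model.min_size <= new <= model.max_size:
            return new


def choose_standing_variant(
    tree: tskit.Tree,
    rng: np.random.Generator,
    freq_range: tuple[float, float] = (0.1, 0.15),
) -> np.ndarray:
    """Mark one clade as carrying the beneficial allele B.

    Searches tree bipartitions whose minor-side leaf fraction lies inside
    ``freq_range`` and picks one uniformly at random; returns the carrier
    sample indices.  Raises :class:`NoSuitableBipartition` when no branch
    qualifies, so the caller can regenerate the start state.
    """
    lo, hi = freq_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("freq_range must lie within (0, 0.5]")
    n = tree.tree_sequence.num_samples
    candidates = []
    for node in tree.nodes():
        if node == tree.root:
            continue
        k = tree.num_samples(node)
        minor = min(k, n - k)
        if lo <= minor / n <= hi:
            candidates.append((node, k))
    if not candidates:
        raise NoSuitableBipartition(
            f"no bipartition with minor-side frequency in [{lo}, {hi}]")
    node, k = candidates[rng.integers(len(candidates))]
    below = np.fromiter(tree.samples(node), dtype=np.int64)
    if k <= n - k:
        return below
    mask = np.ones(n, dtype=bool)
    mask[below] = False
    return np.nonzero(mask)[0]


def seed_hard_sweep_variant(num_chromosomes: int, rng: np.random.Generator) -> np.ndarray:
    """0/1 focal states with a single random chromosome carrying allele B."""
    if num_chromosomes < 1:
        raise ValueError("population is empty")
    focal = np.zeros(num_chromosomes, dtype=np.int64)
    focal[rng.integers(num_chromosomes)] = 1
    return focal


def sample_from_tree_sequence(ts: tskit.TreeSequence,
                              metadata: dict | None = None) -> HaplotypeSample:
    """Convert a (mutated) tree sequence into a HaplotypeSample."""
    G = ts.genotype_matrix()
    return HaplotypeSample(
        matrix=(G > 0).T.astype(np.int8),
        positions=ts.tables.sites.position.copy(),
        sequence_length=ts.sequence_length,
        polarized=True,
        metadata=metadata or {},
    )
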