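"""Fitness surfaces and mutation models for selected microsatellites and SNVs.

A microsatellite allele is its repeat count ("allele size").  The fitness
surface is hill-shaped: an optimal size ``x`` has relative fitness 1 and
fitness declines linearly with distance from the optimum at a rate set by the
gradient ``g`` (negative; ``g = -0.01`` means each repeat unit away from the
optimum costs 0.01 of relative fitness).  Genotype fitness is the mean of the
two allele fitnesses (additive model).

Mutation at the microsatellite follows a logistic rate curve in allele size —
slowly mutating short alleles, a sharp rise at intermediate sizes, and a high
plateau for long alleles.  The plateau (maximum rate) is set by the integer
exponent ``phi``: mu_max = 10**(phi - 8), so phi=3 gives 1e-5 and each unit of
phi buys an order of magnitude.  Mutational steps are symmetric in sign with
geometrically distributed magnitude (p = 0.95: 95% of mutations change the
size by one repeat unit).

The deterministic mutation-selection recursion on the bounded allele-size
support yields the equilibrium ("balance") allele-frequency distribution used
both to stop forward simulations and to compute ``delta_msat``, the
frequency-weighted mean |size| distance between a starting allele distribution
and the balance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "MsatFitnessSurface",
    "MsatMutationModel",
    "SnvSelectionModel",
    "AlleleDistribution",
    "allele_fitness",
    "msat_genotype_fitness",
    "snv_genotype_fitness",
    "msat_mutation_rate",
    "draw_mutation",
    "draw_steps",
    "deterministic_balance",
    "delta_msat",
    "BalanceNotConverged",
]


class BalanceNotConverged(RuntimeError):
    """The deterministic mutation-selection recursion failed to converge."""


@dataclass(frozen=True)
class MsatFitnessSurface:
    """Linear hill fitness surface for a microsatellite.

    Parameters
    ----------
    optimum:
        Optimal allele size ``x`` (repeat count); fitness there is exactly 1.
    gradient:
        ``g <= 0``; relative fitness of allele ``i`` is
        ``max(0, 1 + g * |x - i|)``.  ``g = 0`` is neutrality.
    """

    optimum: int
    gradient: float

    def __post_init__(self) -> None:
        if self.gradient > 0:
            raise ValueError("gradient g must be <= 0 (negative for selection)")

    def allele_fitness(self, i):
        """Relative fitness of allele size ``i`` (scalar or array)."""
        i = np.asarray(i)
        w = 1.0 + self.gradient * np.abs(self.optimum - i)
        return np.maximum(w, 0.0) if w.ndim else float(max(w, 0.0))

    def genotype_fitness(self, i, j):
        """Relative fitness of genotype (i, j): mean of the allele fitnesses."""
        return (self.allele_fitness(i) + self.allele_fitness(j)) / 2.0


@dataclass(frozen=True)
class SnvSelectionModel:
    """Additive diallelic model: w(BB)=1, w(Bb)=1-hs, w(bb)=1-s.

    ``B`` is the favored allele.  ``mu_site`` is the per-site, per-generation
    neutral point-mutation rate of the surrounding sequence.
    """

    s: float
    h: float = 0.5
    mu_site: float = 2.5e-8

    def __post_init__(self) -> None:
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("dominance h must be in [0, 1]")

    def genotype_fitness(self, genotype: str) -> float:
        try:
            return {"BB": 1.0, "Bb": 1.0 - self.h * self.s,
                    "bB": 1.0 - self.h * self.s, "bb": 1.0 - self.s}[genotype]
        except KeyError:
            raise ValueError(f"unknown genotype label {genotype!r}") from None

    def fitness_by_count(self) -> np.ndarray:
        """Genotype fitness indexed by the count of B alleles (0, 1, 2)."""
        return np.array([1.0 - self.s, 1.0 - self.h * self.s, 1.0])


@dataclass(frozen=True)
class MsatMutationModel:
    """Logistic allele-size-dependent mutation rate with geometric steps.

    ``rate_scale`` multiplies the whole rate curve and exists for rescaled
    (reduced-N) simulations; at the default 1.0 the curve plateaus exactly at
    ``mu_max = 10**(phi - 8)``.
    """

    phi: int = 5
    step_p: float = 0.95
    rate_midpoint: float = 9.0
    rate_slope: float = 1.0
    mu_min_fraction: float = 0.01
    min_size: int = 1
    max_size: int = 100
    rate_scale: float = 1.0

    @property
    def mu_max(self) -> float:
        return 10.0 ** (self.phi - 8)

    @property
    def mu_min(self) -> float:
        return self.mu_max * self.mu_min_fraction

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.min_size, self.max_size + 1)

    def rate(self, i):
        """Per-generation mutation probability at allele size ``i``."""
        i = np.asarray(i, dtype=float)
        logistic = 1.0 / (1.0 + np.exp(-self.rate_slope * (i - self.rate_midpoint)))
        r = (self.mu_min + (self.mu_max - self.mu_min) * logistic) * self.rate_scale
        return r if r.ndim else float(r)

    def rate_table(self) -> np.ndarray:
        """Rates indexed by allele size 0..max_size (sizes < min_size get 0)."""
        table = np.zeros(self.max_size + 1)
        table[self.min_size:] = self.rate(np.arange(self.min_size, self.max_size + 1))
        return table

    def scaled(self, factor: float) -> "MsatMutationModel":
        return replace(self, rate_scale=self.rate_scale * factor)


def allele_fitness(i, surface: MsatFitnessSurface):
    return surface.allele_fitness(i)


def msat_genotype_fitness(i, j, surface: MsatFitnessSurface):
    return surface.genotype_fitness(i, j)


def snv_genotype_fitness(genotype: str, model: SnvSelectionModel) -> float:
    return model.genotype_fitness(genotype)


def msat_mutation_rate(i, model: MsatMutationModel):
    return model.rate(i)


def draw_steps(n: int, model: MsatMutationModel, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` signed mutational steps (geometric magnitude, symmetric sign)."""
    mag = rng.geometric(model.step_p, size=n)
    sign = rng.integers(0, 2, size=n) * 2 - 1
    return mag * sign


def draw_mutation(i: int, model: MsatMutationModel, rng: np.random.Generator) -> int:
    """Attempt one mutation at allele size ``i``; returns the (possibly new) size.

    With probability ``model.rate(i)`` the allele takes a signed geometric step;
    steps that would leave the size support are redrawn (rejection), which
    preserves step-symmetry at interior sizes.
    """
    if rng.random() >= model.rate(i):
        return i
    return mutate_sizes(np.array([i]), model, rng, force=True)[0]


def mutate_sizes(sizes: np.ndarray, model: MsatMutationModel,
                 rng: np.random.Generator, force: bool = False) -> np.ndarray:
    """Vectorized mutation of an array of allele sizes.

    ``force=True`` mutates every entry (used after the rate Bernoulli has
    already been applied by the caller).
    """
    sizes = np.asarray(sizes).copy()
    if force:
        idx = np.arange(sizes.size)
    else:
        hit = rng.random(sizes.size) < model.rate(sizes)
        idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return sizes
    new = sizes[idx] + draw_steps(idx.size, model, rng)
    bad = (new < model.min_size) | (new > model.max_size)
    while np.any(bad):
        redo = np.nonzero(bad)[0]
        new[redo] = sizes[idx[redo]] + draw_steps(redo.size, model, rng)
        bad = (new < model.min_size) | (new > model.max_size)
    sizes[idx] = new
    return sizes


@dataclass
class AlleleDistribution:
    """Allele-size frequency distribution (sizes ascending, freqs sum to 1)."""

    sizes: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.freqs = np.asarray(self.freqs, dtype=float)
        order = np.argsort(self.sizes)
        self.sizes, self.freqs = self.sizes[order], self.freqs[order]
        if np.any(self.freqs < -1e-12):
            raise ValueError("negative allele frequency")
        total = self.freqs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "AlleleDistribution":
        sizes = np.array(sorted(mapping))
        return cls(sizes, np.array([mapping[s] for s in sizes]))

    @classmethod
    def from_sizes(cls, sizes: np.ndarray) -> "AlleleDistribution":
        """Empirical distribution of an observed vector of allele sizes."""
        uniq, counts = np.unique(np.asarray(sizes, dtype=int), return_counts=True)
        return cls(uniq, counts / counts.sum())

    def frequency(self, size: int) -> float:
        hit = np.nonzero(self.sizes == size)[0]
        return float(self.freqs[hit[0]]) if hit.size else 0.0

    def as_dict(self) -> dict[int, float]:
        return {int(s): float(f) for s, f in zip(self.sizes, self.freqs)}


def _mutation_matrix(model: MsatMutationModel) -> np.ndarray:
    """Column-stochastic size-transition matrix over the full support.

    Matches the simulator's rejection rule: the geometric step distribution is
    renormalized over the signed steps that stay inside the support.
    """
    support = model.support
    k = support.size
    rates = model.rate(support)
    M = np.zeros((k, k))
    p = model.step_p
    # P(step magnitude = m) = p (1-p)^(m-1), split evenly between signs
    max_step = k - 1
    mags = np.arange(1, max_step + 1)
    pmf = p * (1 - p) ** (mags - 1)
    for col, size in enumerate(support):
        dest_weights = np.zeros(k)
        for m, w in zip(mags, pmf):
            if w < 1e-18:
                break
            for dest in (size - m, size + m):
                j = dest - model.min_size
                if 0 <= j < k:
                    dest_weights[j] += 0.5 * w
        z = dest_weights.sum()
        M[:, col] = rates[col] * dest_weights / z if z > 0 else 0.0
        M[col, col] += 1.0 - rates[col]
    return M


def deterministic_balance(
    surface: MsatFitnessSurface,
    model: MsatMutationModel,
    init: AlleleDistribution | None = None,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    exponential: bool = False,
) -> AlleleDistribution:
    """Fixed point of the deterministic selection -> mutation recursion.

    Iterates allele frequencies over the bounded size support, applying
    viability selection (marginal allele fitness under random mating) and then
    the mutation transition matrix, until the L-infinity change per iteration
    drops below ``tol``.  This is the drift-free mutation-selection balance.

    ``exponential=True`` replaces the linear fitness 1 + g|x-i| with its
    compounded form exp(g|x-i|) — the appropriate surface for rescaled
    (reduced-N) simulations, where one scaled generation stands for several
    generations of linear decline.  The two agree to first order in g.
    """
    support = model.support
    p = np.zeros(support.size)
    if init is None:
        p[support == surface.optimum] = 1.0
        if p.sum() == 0:
            raise ValueError("optimum outside allele-size support")
    else:
        for s, f in zip(init.sizes, init.freqs):
            j = s - model.min_size
            if not 0 <= j < support.size:
                raise ValueError(f"allele size {s} outside model support")
            p[j] = f
    if exponential:
        w = np.exp(surface.gradient * np.abs(surface.optimum - support))
    else:
        w = surface.allele_fitness(support)
    M = _mutation_matrix(model)
    for _ in range(max_iter):
        wbar_allele = (w + p @ w) / 2.0  # marginal fitness of each allele
        mean_w = p @ wbar_allele
        if mean_w <= 0:
            raise BalanceNotConverged("population mean fitness fell to zero")
        p_sel = p * wbar_allele / mean_w
        p_new = M @ p_sel
        p_new /= p_new.sum()  # guard against numerical mass leakage
        if np.max(np.abs(p_new - p)) < tol:
            keep = p_new > 1e-15
            return AlleleDistribution(support[keep], p_new[keep] / p_new[keep].sum())
        p = p_new
    raise BalanceNotConverged(f"no fixed point after {max_iter} iterations")


def delta_msat(start: AlleleDistribution, equil: AlleleDistribution) -> float:
    """Frequency-weighted mean |allele size| distance between two distributions.

    ``sum_{x in S} sum_{y in E} |x - y| p_x p_y`` — large values mean the
    population must travel far (in repeat units) from its starting allele
    distribution to reach mutation-selection balance.
    """
    diff = np.abs(start.sizes[:, None] - equil.sizes[None, :])
    return float(start.freqs @ diff @ equil.freqs)
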