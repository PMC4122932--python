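"""Genome scan for anomalous haplotype configurations in phased variant data.

Each chromosome is divided into nonoverlapping windows (default 10 kb) and
the sliding ksk(20)^2 statistic is computed along them.  Significance is
assessed against a simulated neutral null — coalescent replicates of a long
sequence (default 2 Mb) under a generic bottleneck-growth demography with a
uniform prior on recombination rate — using all sliding values of every
replicate (preserving their autocorrelation) and a plug-in empirical FDR
threshold (default 2%).  Significant window sets closer than one detector
footprint are merged into clusters, and a 1-kb-step ksk(1)^2 fine scan
dissects individual hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import msprime
import numpy as np

from .coalescent import sample_from_tree_sequence
from .stats import (
    HaplotypeSample,
    HaplotypeWindow,
    KskProfile,
    fine_scan,
    sliding_ksk,
    window_stats,
)

__all__ = [
    "ScanConfig",
    "GenericDemography",
    "HitCluster",
    "UnphasedGenotypeError",
    "load_phased_windows",
    "load_phased_sample",
    "scan_chromosome",
    "simulate_scan_null",
    "fdr_threshold",
    "cluster_hits",
]

logger = logging.getLogger(__name__)


class UnphasedGenotypeError(ValueError):
    """An unphased genotype was encountered and skipping is disabled."""


@dataclass(frozen=True)
class GenericDemography:
    """Three-phase generic demography for the scan null: constant ancestral
    size, an out-of-equilibrium bottleneck, then exponential growth to the
    present.  Times are generations before present."""

    ancestral_size: float = 14_000.0
    bottleneck_size: float = 1_900.0
    bottleneck_start: float = 3_500.0   # backward time the bottleneck begins
    growth_start: float = 900.0         # backward time growth began
    growth_rate: float = 0.004          # per-generation, forward in time

    def to_msprime(self) -> msprime.Demography:
        demography = msprime.Demography()
        present = self.bottleneck_size * np.exp(self.growth_rate * self.growth_start)
        demography.add_population(name="pop", initial_size=present,
                                  growth_rate=self.growth_rate)
        demography.add_population_parameters_change(
            time=self.growth_start, initial_size=self.bottleneck_size, growth_rate=0)
        demography.add_population_parameters_change(
            time=self.bottleneck_start, initial_size=self.ancestral_size)
        return demography


@dataclass
class ScanConfig:
    """Windowing, null-simulation and thresholding options for a scan."""

    window_bp: float = 10_000.0
    n_windows: int = 20
    fdr: float = 0.02
    null_reps: int = 500
    null_sequence_length: float = 2_000_000.0
    null_sample_chromosomes: int = 170
    mu: float = 2.5e-8
    recomb_prior: tuple[float, float] = (1e-9, 1e-8)
    demography: GenericDemography = field(default_factory=GenericDemography)
    cluster_gap_bp: float = 200_000.0

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.null_sequence_length < self.n_windows * self.window_bp:
            raise ValueError("null sequence shorter than one window set")


@dataclass
class HitCluster:
    """A run of significant ksk values at one genomic location."""

    chrom: str
    start: float
    end: float
    min_value: float
    min_midpoint: float
    n_members: int


def load_phased_sample(vcf_path: str, samples: list[str] | None = None,
                       chrom: str | None = None,
                       skip_unphased: bool = False,
                       region: str | None = None) -> dict[str, HaplotypeSample]:
    """Read phased biallelic SNVs from a VCF into per-chromosome samples.

    Multi-allelic and indel records are skipped and counted (logged).  An
    unphased genotype raises :class:`UnphasedGenotypeError` naming the record
    unless ``skip_unphased`` is set, in which case the site is dropped.
    Coordinates are converted to 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, samples=samples, gts012=False)
    n_ind = len(vcf.samples)
    per_chrom_pos: dict[str, list[int]] = {}
    per_chrom_cols: dict[str, list[np.ndarray]] = {}
    skipped = {"non_snv": 0, "multiallelic": 0, "unphased": 0}
    region_chrom, region_lo, region_hi = None, None, None
    if region:  # filtered in python; plain-text VCFs carry no tabix index
        region_chrom, _, span = region.partition(":")
        if span:
            lo_s, _, hi_s = span.partition("-")
            region_lo, region_hi = int(lo_s), int(hi_s)
    for variant in vcf:
        if chrom is not None and variant.CHROM != chrom:
            continue
        if region_chrom is not None:
            if variant.CHROM != region_chrom:
                continue
            if region_lo is not None and not region_lo <= variant.POS <= region_hi:
                continue
        if len(variant.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(variant.REF) != 1 or len(variant.ALT[0]) != 1 or \
                variant.ALT[0] not in "ACGT":
            skipped["non_snv"] += 1
            continue
        gts = variant.genotype.array()
        if np.any(gts[:, 0] < 0) or np.any(gts[:, 1] < 0):
            skipped["unphased"] += 1  # missing treated like unphasable
            if skip_unphased:
                continue
            raise UnphasedGenotypeError(
                f"missing genotype at {variant.CHROM}:{variant.POS}")
        if not np.all(gts[:, 2] == 1):
            skipped["unphased"] += 1
            if skip_unphased:
                continue
            raise UnphasedGenotypeError(
                f"unphased genotype at {variant.CHROM}:{variant.POS}")
        col = np.empty(2 * n_ind, dtype=np.int8)
        col[0::2] = gts[:, 0]
        col[1::2] = gts[:, 1]
        per_chrom_pos.setdefault(variant.CHROM, []).append(variant.POS - 1)
        per_chrom_cols.setdefault(variant.CHROM, []).append(col)
    if any(skipped.values()):
        logger.info("skipped records: %s", skipped)
    out = {}
    lengths = dict(zip(vcf.seqnames, vcf.seqlens or [])) if vcf.seqlens else {}
    for name, positions in per_chrom_pos.items():
        pos = np.array(positions, dtype=float)
        order = np.argsort(pos, kind="stable")
        matrix = np.stack(per_chrom_cols[name], axis=1)[:, order]
        length = float(lengths.get(name, pos.max() + 1))
        out[name] = HaplotypeSample(
            matrix=matrix, positions=pos[order], sequence_length=length,
            polarized=False,
            metadata={"vcf": vcf_path, "skipped": skipped})
    return out


def load_phased_windows(vcf_path: str, samples: list[str] | None = None,
                        window_bp: float = 10_000.0,
                        skip_unphased: bool = False
                        ) -> dict[str, list[HaplotypeWindow]]:
    """Per-chromosome ordered window lists from a phased VCF."""
    from .stats import windows_from_sample

    out = {}
    for name, sample in load_phased_sample(
            vcf_path, samples=samples, skip_unphased=skip_unphased).items():
        out[name] = windows_from_sample(sample, window_bp)
    return out


def scan_chromosome(windows: list[HaplotypeWindow], n_windows: int = 20,
                    chrom: str | None = None) -> KskProfile:
    """Sliding ksk(n)^2 along one chromosome's nonoverlapping windows."""
    stats_list = [window_stats(w) for w in windows]
    return sliding_ksk(stats_list, n_windows, chrom=chrom)


def simulate_scan_null(cfg: ScanConfig, seed: int,
                       progress: bool = False) -> np.ndarray:
    """Pooled sliding ksk values from neutral replicates under the scan null.

    Every replicate of ``null_sequence_length`` contributes all of its
    sliding values (e.g. 181 for 2 Mb of 10-kb windows with n=20), which
    preserves the autocorrelation among overlapping window sets.
    """
    from .stats import windows_from_sample

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    child = np.random.SeedSequence(seed).spawn(cfg.null_reps)
    demography = cfg.demography.to_msprime()
    values = []
    for i in range(cfg.null_reps):
        r = rng.uniform(*cfg.recomb_prior)
        seeds = child[i].generate_state(2) % (2**31 - 1) + 1
        ts = msprime.sim_ancestry(
            samples=cfg.null_sample_chromosomes // 2, ploidy=2,
            demography=demography,
            sequence_length=cfg.null_sequence_length,
            recombination_rate=r, random_seed=int(seeds[0]))
        ts = msprime.sim_mutations(
            ts, rate=cfg.mu, random_seed=int(seeds[1]),
            model=msprime.BinaryMutationModel(), discrete_genome=False)
        sample = sample_from_tree_sequence(ts)
        stats_list = [window_stats(w)
                      for w in windows_from_sample(sample, cfg.window_bp)]
        values.append(sliding_ksk(stats_list, cfg.n_windows).values)
        if progress and (i + 1) % 50 == 0:
            print(f"  null replicate {i + 1}/{cfg.null_reps}", flush=True)
    return np.sort(np.concatenate(values))


def fdr_threshold(observed: np.ndarray, null: np.ndarray,
                  q: float = 0.02) -> tuple[float | None, np.ndarray]:
    """Plug-in empirical FDR threshold for lower-tail (more negative) values.

    Finds the least-extreme threshold t with
    ``fraction(null <= t) * N_observed / #{observed <= t} <= q`` and flags
    every observed value <= t as significant (pi0 taken as 1, conservative).
    Returns ``(threshold, significant_mask)``; threshold is None (empty mask)
    when no threshold achieves the target.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.sort(np.asarray(null, dtype=float))
    if observed.size == 0 or null.size == 0:
        raise ValueError("observed and null must be non-empty")
    candidates = np.unique(observed)
    null_frac = np.searchsorted(null, candidates, side="right") / null.size
    obs_sorted = np.sort(observed)
    n_below = np.searchsorted(obs_sorted, candidates, side="right")
    fdr = null_frac * observed.size / np.maximum(n_below, 1)
    ok = np.nonzero(fdr <= q)[0]
    if ok.size == 0:
        return None, np.zeros(observed.size, dtype=bool)
    threshold = float(candidates[ok.max()])
    return threshold, observed <= threshold


def cluster_hits(profile: KskProfile, gap_bp: float = 200_000.0) -> list[HitCluster]:
    """Merge significant profile positions closer than ``gap_bp``.

    ``profile.significant`` must be set (e.g. by applying an FDR threshold);
    each cluster reports its extent, member count, and minimum value.
    """
    if profile.significant is None:
        raise ValueError("profile has no significance calls")
    sig = np.nonzero(profile.significant)[0]
    if sig.size == 0:
        return []
    pos = profile.positions[sig]
    vals = profile.values[sig]
    order = np.argsort(pos)
    pos, vals = pos[order], vals[order]
    clusters = []
    start = 0
    for i in range(1, pos.size + 1):
        if i == pos.size or pos[i] - pos[i - 1] >= gap_bp:
            chunk_pos, chunk_vals = pos[start:i], vals[start:i]
            j = int(np.argmin(chunk_vals))
            clusters.append(HitCluster(
                chrom=profile.chrom or "?",
                start=float(chunk_pos[0]), end=float(chunk_pos[-1]),
                min_value=float(chunk_vals[j]),
                min_midpoint=float(chunk_pos[j]),
                n_members=int(i - start)))
            start = i
    return clusters
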