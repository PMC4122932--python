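"""Empirical null distributions and statistical power.

Two null constructions are provided:

* **S-conditioned nulls** — a large set of neutral 10-kb windows is simulated
  with the scaled mutation and recombination rates drawn from uniform priors
  (defaults theta ~ U[2, 25] and rho ~ U[3, 20] per window, reasonable human
  ranges), and each statistic's null distribution is stored separately for
  every observed segregating-site count S.  A window is tested one-tailed
  against the S-matched bin (empirical p = (r+1)/(m+1)); selection on a
  30-kb sample counts as detected when any of its three 10-kb windows is
  significant at alpha = 0.05/3.

* **extreme-value ksk nulls** — per neutral replicate of a long sequence the
  minimum of the sliding ksk(20)^2 profile is retained, and all sliding
  values are pooled (preserving within-replicate autocorrelation).  The
  power driver's default critical value is the Bonferroni form — the
  alpha / (sliding values per replicate) quantile of the pooled values —
  with a per-replicate minima quantile available as an alternative.  A
  selection replicate is detected when its profile minimum falls below the
  critical value.

``power_table`` drives forward simulations for SNV and microsatellite
selection scenarios and reports the detected fraction per scenario and time
point, optionally stratified by delta_msat.  Reduced-scale runs use the
standard rescaling (N -> N/scale, per-generation rates and selection
coefficients * scale), which preserves theta and rho per window, 2Ns, and
sweep footprints in base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import msprime
import numpy as np

from .coalescent import (
    NoSuitableBipartition,
    choose_standing_variant,
    sample_from_tree_sequence,
    seed_hard_sweep_variant,
    seed_microsatellite,
    simulate_neutral_start,
)
from .models import (
    AlleleDistribution,
    MsatFitnessSurface,
    MsatMutationModel,
    SnvSelectionModel,
    deterministic_balance,
)
from .stats import HaplotypeSample, WindowStats, sliding_ksk, window_stats, windows_from_sample
from .wright_fisher import SimConfig, run_selection_phase

__all__ = [
    "THETA_PRIOR",
    "RHO_PRIOR",
    "StudyConditions",
    "ConditionalNull",
    "ExtremeKskNull",
    "Scenario",
    "PowerResult",
    "neutral_sample",
    "build_conditional_null",
    "test_window",
    "detect_selection_3window",
    "extreme_ksk_null",
    "power_table",
    "table1_scenarios",
]

THETA_PRIOR = (2.0, 25.0)  # per 10-kb window
RHO_PRIOR = (3.0, 20.0)

STAT_TAILS = {"D": "lower", "H_FW": "lower", "E": "lower",
              "K": "lower", "H": "lower", "M": "upper"}


@dataclass(frozen=True)
class StudyConditions:
    """Simulation conditions; ``rescaled(scale)`` gives the desk-scale map."""

    population_size: int = 10_000
    mu: float = 2.5e-8
    r: float = 1.25e-8
    sequence_length: float = 1_000_000.0
    window_bp: float = 10_000.0
    sample_chromosomes: int = 100
    mrca_size: int = 8
    optimum_range: tuple[int, int] = (8, 20)
    gradient: float = -0.05
    scale: float = 1.0

    def rescaled(self, scale: float) -> "StudyConditions":
        return replace(
            self,
            population_size=int(round(self.population_size / scale)),
            mu=self.mu * scale,
            r=self.r * scale,
            scale=self.scale * scale,
        )

    @property
    def num_chromosomes(self) -> int:
        return 2 * self.population_size

    @property
    def theta_per_window(self) -> float:
        return 4 * self.population_size * self.mu * self.window_bp

    @property
    def rho_per_window(self) -> float:
        return 4 * self.population_size * self.r * self.window_bp


def neutral_sample(n_chromosomes: int, sequence_length: float, theta: float,
                   rho: float, seed: int) -> HaplotypeSample:
    """One neutral coalescent sample; theta/rho are sequence totals (4NrL)."""
    ne = 10_000
    mu = theta / (4 * ne * sequence_length)
    r = rho / (4 * ne * sequence_length)
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1) + 1
    ts = msprime.sim_ancestry(
        samples=n_chromosomes // 2, ploidy=2, population_size=ne,
        sequence_length=sequence_length, recombination_rate=r,
        random_seed=int(seeds[0]))
    if mu > 0:
        ts = msprime.sim_mutations(ts, rate=mu, random_seed=int(seeds[1]),
                                   model=msprime.BinaryMutationModel(),
                                   discrete_genome=False)
    return sample_from_tree_sequence(ts)


# ---------------------------------------------------------------------------
# S-conditioned nulls and the 3-window test
# ---------------------------------------------------------------------------

@dataclass
class ConditionalNull:
    """Null statistic values binned by the window's segregating-site count."""

    bins: dict[str, dict[int, np.ndarray]]
    reps: int
    theta_prior: tuple[float, float]
    rho_prior: tuple[float, float]
    seed: int | None = None
    min_bin: int = 1000

    def pooled_bin(self, stat: str, S: int) -> np.ndarray:
        """S bin, pooled with neighbors (expanding +-1 alternately) until it
        holds at least ``min_bin`` values or the whole table is used."""
        table = self.bins[stat]
        if not table:
            return np.empty(0)
        chunks = []
        if S in table:
            chunks.append(table[S])
        size = sum(c.size for c in chunks)
        lo = hi = S
        smin, smax = min(table), max(table)
        while size < self.min_bin and (lo > smin or hi < smax):
            lo -= 1
            if lo >= smin and lo in table:
                chunks.append(table[lo])
            hi += 1
            if hi <= smax and hi in table:
                chunks.append(table[hi])
            size = sum(c.size for c in chunks)
        return np.sort(np.concatenate(chunks)) if chunks else np.empty(0)


def build_conditional_null(
    reps: int,
    seed: int,
    theta_prior: tuple[float, float] = THETA_PRIOR,
    rho_prior: tuple[float, float] = RHO_PRIOR,
    window_bp: float = 10_000.0,
    n_chromosomes: int = 100,
    min_bin: int = 1000,
) -> ConditionalNull:
    """Neutral 10-kb windows with prior-drawn theta and rho, binned by S."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    child_seeds = np.random.SeedSequence(seed).spawn(reps)
    values: dict[str, dict[int, list]] = {s: {} for s in STAT_TAILS}
    for i in range(reps):
        theta = rng.uniform(*theta_prior)
        rho = rng.uniform(*rho_prior)
        rep_seed = int(child_seeds[i].generate_state(1)[0] % (2**31 - 1))
        sample = neutral_sample(n_chromosomes, window_bp, theta, rho, rep_seed)
        ws = window_stats(windows_from_sample(sample, window_bp)[0])
        row = {"D": ws.D, "H_FW": ws.H_FW, "E": ws.E,
               "K": ws.K, "H": ws.H, "M": ws.M}
        for stat, val in row.items():
            if np.isnan(val):
                continue
            values[stat].setdefault(ws.S, []).append(val)
    bins = {stat: {S: np.sort(np.array(v)) for S, v in table.items()}
            for stat, table in values.items()}
    return ConditionalNull(bins=bins, reps=reps, theta_prior=theta_prior,
                           rho_prior=rho_prior, seed=seed, min_bin=min_bin)


def test_window(stat_name: str, value: float, S: int, null: ConditionalNull,
                tail: str | None = None, alpha: float = 0.05 / 3) -> bool:
    """One-tailed empirical rank test of one window statistic against the
    S-matched null bin; empirical p = (r+1)/(m+1)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tail is None:
        tail = STAT_TAILS[stat_name]
    if np.isnan(value):
        return False
    bin_values = null.pooled_bin(stat_name, S)
    if bin_values.size == 0:
        return False  # test unavailable; reported as non-significant
    m = bin_values.size
    if tail == "lower":
        r = int(np.searchsorted(bin_values, value, side="right"))
    elif tail == "upper":
        r = m - int(np.searchsorted(bin_values, value, side="left"))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = (r + 1) / (m + 1)
    return p <= alpha


def detect_selection_3window(stats3: list[WindowStats], stat_name: str,
                             null: ConditionalNull, tail: str | None = None,
                             alpha: float = 0.05 / 3) -> bool:
    """Selection detected if any of the three 10-kb windows is significant."""
    if len(stats3) != 3:
        raise ValueError("expected exactly 3 windows")
    return any(
        test_window(stat_name, getattr(ws, stat_name), ws.S, null, tail, alpha)
        for ws in stats3
    )


# ---------------------------------------------------------------------------
# extreme-value ksk(20)^2 null
# ---------------------------------------------------------------------------

@dataclass
class ExtremeKskNull:
    """Null for the most-extreme-sliding-ksk detector.

    ``minima`` holds one value per neutral replicate (the minimum of its
    sliding ksk profile); ``values`` pools every sliding value, preserving
    within-replicate autocorrelation.  Two critical-value conventions:

    * ``critical`` — the configured lower quantile of the per-replicate
      minima (one value per replicate already absorbs within-replicate
      multiplicity);
    * ``critical_bonferroni(alpha)`` — the alpha / (values per replicate)
      quantile of the pooled values, i.e. a per-window-set test at the
      Bonferroni-corrected level.  A replicate whose profile minimum falls
      below it has at least one significant window set.
    """

    minima: np.ndarray
    quantile: float
    n_windows: int
    window_bp: float
    values: np.ndarray | None = None
    values_per_rep: int | None = None

    @property
    def critical(self) -> float:
        return float(np.quantile(self.minima, self.quantile))

    def critical_at(self, quantile: float) -> float:
        return float(np.quantile(self.minima, quantile))

    def critical_bonferroni(self, alpha: float = 0.05) -> float:
        if self.values is None or not self.values_per_rep:
            raise ValueError("pooled values not stored")
        return float(np.quantile(self.values, alpha / self.values_per_rep))


def extreme_ksk_null(
    reps: int,
    seed: int,
    sequence_length: float = 1_000_000.0,
    n_chromosomes: int = 100,
    window_bp: float = 10_000.0,
    n_windows: int = 20,
    theta_prior: tuple[float, float] = THETA_PRIOR,
    rho_prior: tuple[float, float] = RHO_PRIOR,
    quantile: float = 0.05,
    replicate_source=None,
) -> ExtremeKskNull:
    """Collection of per-replicate minima of sliding ksk(n_windows)^2.

    ``theta_prior``/``rho_prior`` are per ``window_bp`` window and drawn once
    per replicate.  ``replicate_source(i) -> HaplotypeSample`` may replace the
    neutral coalescent generator (used for validation).
    """
    windows_per_rep = int(sequence_length // window_bp)
    if windows_per_rep < n_windows:
        raise ValueError("sequence too short for a single n-window set")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    child = np.random.SeedSequence(seed).spawn(reps)
    minima = np.empty(reps)
    pooled = []
    for i in range(reps):
        if replicate_source is not None:
            sample = replicate_source(i)
        else:
            theta = rng.uniform(*theta_prior) * windows_per_rep
            rho = rng.uniform(*rho_prior) * windows_per_rep
            rep_seed = int(child[i].generate_state(1)[0] % (2**31 - 1))
            sample = neutral_sample(n_chromosomes, sequence_length, theta,
                                    rho, rep_seed)
        ws = [window_stats(w) for w in
              windows_from_sample(sample, window_bp)]
        profile = sliding_ksk(ws, n_windows)
        minima[i] = profile.min_value
        pooled.append(profile.values)
    return ExtremeKskNull(minima=np.sort(minima), quantile=quantile,
                          n_windows=n_windows, window_bp=window_bp,
                          values=np.sort(np.concatenate(pooled)),
                          values_per_rep=windows_per_rep - n_windows + 1)


# ---------------------------------------------------------------------------
# power table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One selective scenario (a Table-style row group)."""

    name: str
    target: str  # 'snv' | 'snv_standing' | 'msat'
    s: float | None = None
    h: float = 0.5
    phi: int | None = None
    gradient: float | None = None
    delta_min: float | None = None  # stratify on delta_msat > delta_min
    timepoints: tuple = ("fixation",)


@dataclass
class PowerResult:
    statistic: str
    scenario: str
    timepoint: str
    detected: int
    replicates: int

    @property
    def power(self) -> float:
        return self.detected / self.replicates if self.replicates else float("nan")


def table1_scenarios() -> list[Scenario]:
    """The selective targets of the ksk(20)^2 power table."""
    t = ("fixation", "+250", "+500")
    return [
        Scenario("SNV (s=0.01)", "snv", s=0.01, timepoints=t),
        Scenario("SNV (s=0.05)", "snv", s=0.05, timepoints=t),
        Scenario("Microsatellite (phi=3; all msats)", "msat", phi=3, timepoints=t),
        Scenario("Microsatellite (phi=5; all msats)", "msat", phi=5, timepoints=t),
        Scenario("Microsatellite (phi=3; dmsat>4)", "msat", phi=3, delta_min=4.0, timepoints=t),
        Scenario("Microsatellite (phi=5; dmsat>4)", "msat", phi=5, delta_min=4.0, timepoints=t),
    ]


def _run_one_replicate(scenario: Scenario, conditions: StudyConditions,
                       seed: int, balance_cache: dict,
                       post_offsets: tuple[int, ...]) -> dict:
    """Forward-simulate one replicate; returns per-timepoint ksk minima."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scale = conditions.scale
    n_windows = int(conditions.sequence_length // conditions.window_bp)
    while True:  # regenerate start when no bipartition suits standing variation
        start_seed = int(rng.integers(2**31 - 1))
        start = simulate_neutral_start(
            conditions.num_chromosomes, conditions.sequence_length,
            population_size=conditions.population_size,
            mu=conditions.mu, r=conditions.r, seed=start_seed)
        surface = msat_model = snv_model = None
        balance = None
        if scenario.target == "msat":
            gradient = (scenario.gradient if scenario.gradient is not None
                        else conditions.gradient) * scale
            x = int(rng.integers(conditions.optimum_range[0],
                                 conditions.optimum_range[1] + 1))
            surface = MsatFitnessSurface(optimum=x, gradient=gradient)
            msat_model = MsatMutationModel(phi=scenario.phi, rate_scale=scale)
            key = (scenario.phi, x, gradient)
            if key not in balance_cache:
                balance_cache[key] = deterministic_balance(
                    surface, msat_model, exponential=(scale > 1))
            balance = balance_cache[key]
            start.focal = seed_microsatellite(start.focal_genealogy(),
                                              msat_model, rng,
                                              mrca_size=conditions.mrca_size)
            break
        snv_model = SnvSelectionModel(s=scenario.s * scale, h=scenario.h)
        if snv_model.s > 1:
            raise ValueError("scaled s exceeds 1; reduce the scale factor")
        if scenario.target == "snv":
            start.focal = seed_hard_sweep_variant(start.num_chromosomes, rng)
            break
        try:  # standing variation
            carriers = choose_standing_variant(start.focal_genealogy(), rng)
        except NoSuitableBipartition:
            continue
        start.focal = np.zeros(start.num_chromosomes, dtype=np.int64)
        start.focal[carriers] = 1
        break

    config = SimConfig(
        target="msat" if scenario.target == "msat" else "snv",
        mu=conditions.mu, r=conditions.r,
        sample_individuals=conditions.sample_chromosomes // 2,
        sample_post_stop=bool(post_offsets),
        post_stop_offsets=post_offsets,
        max_generations=int(40 * conditions.population_size),
        viability="exp_best" if (scenario.target == "msat" and scale > 1) else "absolute",
        record_trajectory=False,
    )
    result = run_selection_phase(
        start, config, seed=int(rng.integers(2**31 - 1)), surface=surface,
        msat_model=msat_model, snv_model=snv_model, balance=balance)
    minima = {}
    for label, sample in result.samples.items():
        ws = [window_stats(w) for w in
              windows_from_sample(sample, conditions.window_bp)]
        minima[label] = sliding_ksk(ws, 20).min_value
    return {"minima": minima, "delta_msat": result.delta_msat,
            "converged": result.converged, "restarts": result.restarts}


def power_table(
    scenarios: list[Scenario],
    reps: int,
    seed: int,
    conditions: StudyConditions | None = None,
    null: ExtremeKskNull | None = None,
    null_reps: int = 800,
    critical: float | None = None,
    critical_method: str = "bonferroni",
    progress: bool = False,
) -> list[PowerResult]:
    """Power of the min-sliding-ksk(20)^2 detector for each scenario.

    The critical value defaults to the Bonferroni form (per-window-set test
    at alpha / sets-per-replicate, matching the reported full-scale critical
    value); ``critical_method='minima'`` uses the lower quantile of the
    per-replicate minima instead.  Scenarios sharing target/phi differ only
    in delta_msat stratification, so replicate runs are shared between "all"
    and "delta > cutoff" rows.
    """
    if conditions is None:
        conditions = StudyConditions().rescaled(10.0)
    root = np.random.SeedSequence(seed)
    null_seed, sim_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                           for s in root.spawn(2))
    if critical is None:
        if null is None:
            null = extreme_ksk_null(
                null_reps, null_seed,
                sequence_length=conditions.sequence_length,
                n_chromosomes=conditions.sample_chromosomes,
                window_bp=conditions.window_bp)
        critical = (null.critical_bonferroni() if critical_method == "bonferroni"
                    else null.critical)

    # group scenarios by the underlying simulation settings
    groups: dict[tuple, list[Scenario]] = {}
    for sc in scenarios:
        groups.setdefault((sc.target, sc.s, sc.h, sc.phi, sc.gradient), []).append(sc)

    scale = conditions.scale
    results: list[PowerResult] = []
    sim_root = np.random.SeedSequence(sim_seed)
    for key, members in groups.items():
        timepoints = tuple(dict.fromkeys(tp for sc in members for tp in sc.timepoints))
        post_offsets = tuple(sorted(
            max(1, int(round(int(tp) / scale)))
            for tp in timepoints if tp != "fixation"))
        label_map = {"fixation": "fixation"}
        for tp in timepoints:
            if tp != "fixation":
                label_map[tp] = f"+{max(1, int(round(int(tp) / scale)))}"
        balance_cache: dict = {}
        records = []
        rep_seeds = sim_root.spawn(reps)
        for i in range(reps):
            rec = _run_one_replicate(
                members[0], conditions,
                int(rep_seeds[i].generate_state(1)[0] % (2**31 - 1)),
                balance_cache, post_offsets)
            records.append(rec)
            if progress and (i + 1) % 20 == 0:
                print(f"  {members[0].name}: {i + 1}/{reps}", flush=True)
        for sc in members:
            keep = [r for r in records
                    if sc.delta_min is None
                    or (r["delta_msat"] is not None
                        and r["delta_msat"] > sc.delta_min)]
            for tp in sc.timepoints:
                label = label_map[tp]
                vals = [r["minima"][label] for r in keep if label in r["minima"]]
                detected = int(sum(v < critical for v in vals))
                results.append(PowerResult(
                    statistic="ksk20", scenario=sc.name, timepoint=tp,
                    detected=detected, replicates=len(vals)))
    return results
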