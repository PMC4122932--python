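# Methods

`kskscan` simulates natural selection on a microsatellite — a multiallelic,
highly mutable tandem repeat — embedded in recombining neutral sequence, and
implements the haplotype-configuration statistic ksk(n)² together with the
empirical-null machinery needed to use it as a scan for selection. This note
records the models, the numerical choices, and what the desk-scale test
conditions do and do not demonstrate.

## Selection and mutation models

**Microsatellite fitness.** Alleles are repeat counts. An optimal size `x`
has relative fitness 1 and fitness declines linearly with distance:
`w(a_i) = max(0, 1 + g·|x − i|)` with gradient `g ≤ 0` (`g = −0.01` costs one
percent of fitness per repeat unit). Genotype fitness is the mean of the two
allele fitnesses (additive). The comparison SNV model is the standard
diallelic additive scheme `w(BB)=1, w(Bb)=1−hs, w(bb)=1−s` with `h = 0.5`.

**Microsatellite mutation.** The per-generation mutation probability follows
a logistic curve in allele size: a low floor for short alleles, a sharp rise
at an intermediate size, and a plateau `mu_max = 10^(phi−8)` for long alleles
(`phi = 3 → 1e−5`, each unit of `phi` an order of magnitude). Steps are
symmetric in sign with geometric magnitude (`p = 0.95`: 95% single-step);
steps leaving the size support `[1, 100]` are redrawn, which preserves
symmetry at interior sizes. Defaults for the curve shape are
`rate_midpoint = 9`, `rate_slope = 1.0`, `mu_min = mu_max/100`. The midpoint
and slope are genuinely free choices — the published description fixes only
the plateau and the qualitative shape. `rate_midpoint = 9` was chosen so that
the canonical starting allele (size 8) is modestly mutable: seeding the
founder genealogy then yields a polymorphic locus more often than not, and
mutation–selection equilibrium is reachable for every optimum in `[8, 20]`.
A higher midpoint (e.g. 14) creates a near-mutation-free zone across the
starting sizes, which contradicts the described behaviour of the locus and
makes low-`phi` equilibria effectively unreachable; we verified empirically
that it also degrades every power result. This parameterization remains the
main source of quantitative uncertainty relative to the original study (see
*Known limitations*).

**Mutation–selection balance.** The drift-free recursion — viability
selection via marginal allele fitness under random mating, then the
size-transition matrix of the mutation model (step distribution renormalized
over moves that stay in the support, matching the simulator's rejection
rule) — is iterated to an L∞ fixed-point tolerance of 1e−12 (cap 1e6
iterations). The fixed point is independent of the initialization; we start
at the optimum, which stays well-defined under rescaled gradients.
`delta_msat = Σ_x Σ_y |x−y| p_x p_y` measures the distance between a starting
allele distribution and the balance distribution; large values (> 4) mark
replicates whose selective footprint is strongest.

## Simulation design

**Neutral pre-selection phase.** Founder populations are drawn from the
standard neutral coalescent with recombination and infinite-sites mutation
(msprime; continuous positions, binary derived states). The selected locus
sits at the exact sequence centre; the marginal genealogy there seeds the
microsatellite: allele size 8 at the MRCA evolves down every branch as a
continuous-time jump process whose rate is re-evaluated after each jump.
Standing-variation SNV runs pick a tree bipartition whose minor side has
frequency in [0.1, 0.15] (regenerating the start state when none exists);
hard sweeps place a single copy on one random chromosome.

**Selection phase.** Each generation: (1) every diploid survives with
probability equal to its relative genotypic fitness (a fully-extinct
generation is redrawn); (2) offspring are produced by drawing two uniform
random surviving parents each (selfing allowed), with at most one crossover
per transmitted chromosome at probability `r·L`, breakpoint uniform; (3)
Poisson neutral mutation and a focal-locus mutation attempt; (4) SNV runs
restart from the original start state if the beneficial allele is lost; (5)
stop at fixation (SNV) or when the optimal-allele frequency is within
`1/(2N)` of its deterministic balance frequency (microsatellite), optionally
continuing for post-stop samples. Demographic change (instant bottleneck to
500 diploids with 0.005/generation exponential regrowth, or exponential
decline at −0.003/generation; `N_t = round(N·e^{rt})`) starts at selection
onset. Samples are 50 individuals (100 chromosomes) drawn without
replacement.

**Two engines.** The default engine records transmissions as tskit ancestry
tables (bulk-buffered edges, periodic simplification) and overlays neutral
mutations on the recorded genealogy of the sampled chromosomes only, with
msprime, restricted to the forward-phase time window so founder-era variation
is not double-mutated. Every sampled observable has exactly the distribution
of per-generation mutation at a fraction of the cost. A second, independent
`direct` engine materializes each chromosome's derived-allele positions and
mutates them generation by generation, literally following the numbered
algorithm; the test suite checks distributional agreement between the two.
When the neutral mutation rate is zero the recorded engine skips ancestry
tracking entirely (used for fixation-time checks, where only the focal-locus
trajectory is observable).

## Summary statistics

Per nonoverlapping window (10 kb by default): segregating sites `S`, mean
pairwise differences π, Tajima's `D`, the variance-standardized Fay & Wu
`H_FW` and Zeng `E` (normalizations of Zeng et al. 2006; these require
derived/ancestral polarization and are flagged unavailable otherwise; the raw
`θπ − θH` contrast is also exposed), the number of distinct haplotypes `K`,
haplotype diversity `H = 1 − Σ p_i²` (uncorrected; the choice is isolated in
one function), and the modal-haplotype count `M`. Windows with `S = 0`
report `K = 1, H = 0, M = n` with the SFS statistics undefined.

`ksk(n)² = (1/n) Σ (K_i − S_i)/K_i²` over `n` contiguous windows, placed at
the window-set midpoint and slid one window at a time. An `S = 0` window
contributes `+1`, keeping the statistic defined genome-wide. Strongly
negative values require few but mutually divergent haplotypes — the
signature left when a favoured microsatellite allele recurrently mutates
onto divergent haplotype backgrounds, and (transiently) by the flanks of
strong SNV sweeps. A 1-kb-step ksk(1)² fine scan dissects individual hits;
`pairwise_diff_matrix` exposes the haplotype-network view of a window.

## Nulls, detection, and power

**S-conditioned nulls.** Neutral 10-kb windows (n = 100 chromosomes) are
simulated with θ and ρ drawn per replicate from uniform priors (defaults
θ ∈ [2, 25], ρ ∈ [3, 20] per window — plausible human ranges) and every
statistic's null values are binned by the window's `S`. Bins with fewer than
1000 values pool neighbouring S values (expanding ±1 alternately) for stable
tail quantiles. A window is tested one-tailed with empirical
`p = (r+1)/(m+1)`; selection on a 30-kb sample counts as detected when any
of its three windows is significant at `α = 0.05/3` (D, H_FW, E, K, H lower
tail; M upper tail).

**Extreme-value ksk null.** Per neutral replicate of a long sequence (1 Mb:
81 sliding values) the profile minimum is retained, and all sliding values
are pooled preserving within-replicate autocorrelation. Two critical-value
conventions are provided: a lower quantile of the per-replicate minima, and
the Bonferroni form — the `α/(values per replicate)` quantile of the pooled
values, i.e. a per-window-set test at the multiplicity-corrected level. The
power driver defaults to the Bonferroni form (α = 0.05, per-test level
0.05/81 ≈ 6.2e−4, critical ≈ −0.065 under the default priors): it reproduces
both the reported full-scale critical value (≈ −0.07) and the near-null
detected fraction of weak sweeps, whereas a 5% minima quantile (≈ −0.053)
yields a 5% type-I rate, several-fold higher than the published weak-sweep
row. A replicate is detected when its profile minimum falls below the
critical value.

**Genome scan.** Phased biallelic SNVs are read from VCF (multi-allelic and
indel records skipped and counted; unphased genotypes are a hard error
unless skipping is requested), cut into windows per chromosome, and scanned
with sliding ksk(20)². The scan null simulates 2-Mb neutral replicates (181
sliding values each) under a generic three-phase demography (ancestral size
14,000; bottleneck 1,861 from 3,500 to 900 generations ago; then 0.4%/
generation exponential growth — generic stand-ins, not a fitted human model)
with per-site recombination rate uniform on [1e−9, 1e−8]. Thresholding uses
the plug-in empirical FDR (π₀ = 1, conservative) at q = 2%; significant
midpoints closer than 200 kb (one 20-window footprint) merge into clusters.

## Reduced-scale study conditions

Full-scale conditions are Ne = 10,000 diploids, 1 Mb of sequence,
μ = 2.5e−8 and r = 1.25e−8 per bp (θ = 10, ρ = 5 per 10-kb window), samples
of 100 chromosomes. Desk-scale runs apply the standard rescaling with
λ = 10: N → N/λ, all per-generation rates — neutral μ and r, microsatellite
locus rates, and the selection coefficients s and g — multiplied by λ, time
compressed λ-fold. This preserves θ and ρ per window, 2Ns, the
mutation/selection ratio at the focal locus, and sweep footprints in base
pairs. Because a rescaled gradient of −0.5 makes the *linear* surface clamp
to zero two repeat units from the optimum, scaled microsatellite runs use
the compounded viability `survival = exp(g_s·(d − d_best))` (one scaled
generation standing for λ generations of `(1 − |g|)`-per-step decline,
referenced to the best genotype present since only fitness differences move
allele frequencies); the balance solver uses the matching exponential
surface. At the full scale the linear and compounded rules agree to first
order in g.

Default problem sizes: power analyses run 100 replicates per scenario
against an 800-replicate extreme-value null; the power table covers weak and
strong hard sweeps (s = 0.01, 0.05) and microsatellite selection
(g = −0.05; phi = 3, 5), with delta_msat > 4 stratification, at
fixation/equilibrium and scaled post-stop offsets.

## What the synthetic conditions do not show

The generator emulates the idealized study design: panmictic Wright–Fisher
diploids, uniform recombination, infinite-sites neutral mutation, a single
selected locus at the sequence centre, and perfectly phased, error-free
haplotypes. Real data add phasing error, low-coverage genotype error,
recombination-rate and mutation-rate heterogeneity, population structure,
and uncertain demography — all of which widen the ksk null. Passing tests
therefore demonstrate correctness of the machinery and reproduction of the
simulated operating characteristics, not field performance on a specific
cohort.

## Known limitations

* The exact midpoint, slope and floor of the original logistic rate curve
  are not recoverable; our defaults reproduce the plateau calibration and
  the qualitative shape. The detected fraction for low-mutation-rate
  (phi = 3) microsatellite selection pooled over all optima is the quantity
  most sensitive to this choice: we obtain ≈ 0.70 at equilibrium versus the
  reported ≈ 0.80, with the deficit concentrated in long climbs (optimum far
  from the starting size), and full-scale spot checks show the same
  behaviour, so the gap traces to the rate-curve parameterization rather
  than to rescaling.
* The equilibrium-detection band `1/(2N)` is 10× coarser at desk scale.
* `H` (haplotype diversity) is uncorrected; standardized `H_FW`/`E` follow
  one published normalization among several in use.
* The scan-null demography is a generic bottleneck-growth stand-in; for real
  scans it should be replaced with a fitted model for the cohort analysed.
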