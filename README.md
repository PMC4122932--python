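# kskscan

Forward simulation of natural selection on microsatellites and a
haplotype-configuration scan statistic — **ksk(n)²** — for detecting it in
phased sequence data.

## The problem

Genome-wide scans for selection assume the selected variant follows the
infinite-sites model: it arises once and sweeps on a single haplotype
background. A microsatellite — a 1–6 bp motif repeated in tandem, whose
alleles are repeat counts — violates this assumption by construction: it
mutates by whole repeat units at rates orders of magnitude above point
mutation, with recurrent and back mutation throughout a selective event. A
favoured allele size therefore ends up carried by a *few, mutually
divergent* haplotypes rather than one. Summaries of the site frequency
spectrum (Tajima's D, Fay & Wu's H, Zeng's E) lose most of their power in
this regime; the joint configuration of the number of distinct haplotypes
*K* and segregating sites *S* does not. The statistic

```
ksk(n)² = (1/n) · Σᵢ (Kᵢ − Sᵢ) / Kᵢ²       (n contiguous windows)
```

is strongly negative exactly when K is small while S stays large, and is
used as a sliding 20-window scan (10-kb windows) with an empirical
extreme-value null and FDR-thresholded cluster calling.

The package provides, as a library plus a thin `kskscan` CLI:

* **Models** — the additive hill fitness surface `w(aᵢ) = 1 + g·|x − i|`
  (optimum `x`, gradient `g ≤ 0`), the logistic allele-size-dependent
  mutation-rate curve (plateau `10^(φ−8)`, geometric steps with p = 0.95),
  the SNV comparison model `w(BB)=1, w(Bb)=1−hs, w(bb)=1−s`, the
  deterministic mutation–selection-balance solver, and the footprint
  predictor `Δmsat = Σ Σ |x−y| pₓ p_y`.
* **Simulation** — msprime founder populations with the selected locus at
  the sequence centre (microsatellite seeded down the focal genealogy from
  an MRCA of size 8; hard-sweep or standing-variation SNVs), then an exact
  forward Wright–Fisher selection phase with viability selection,
  single-crossover recombination, restart-on-loss, demographic change, and
  equilibrium/fixation detection. Ancestry is recorded with tskit and
  neutral mutations are overlaid on the sampled genealogy.
* **Statistics** — windowed S, π, D, H_FW, E, K, H, M; sliding ksk(n)²;
  1-kb-step ksk(1)² fine scans; haplotype pairwise-difference matrices.
* **Detection** — S-conditioned empirical nulls with θ/ρ priors and the
  3-window one-tailed test; extreme-value ksk(20)² nulls and the power
  table over sweep and microsatellite scenarios; a VCF genome-scan mode
  with simulated demographic nulls, 2% FDR thresholding and cluster calling.

## Worked example

One reduced-scale hard-sweep replicate, scanned at fixation
(`python examples/sweep_simulation.py`):

```
fixation at generation 45 (1 restarted attempts that lost the allele)
sliding ksk(20)^2: 81 values, min -0.230 at 350 kb
```

The profile minimum of −0.230 is far below the neutral critical value
(≈ −0.065 under the default null): few divergent haplotypes dominate the
swept region, so the replicate is detected. A neutral replicate's minimum
sits near −0.04 and is not called. `examples/scan_vcf.py` runs the full
scan loop — simulate, export phased VCF, reload, sliding scan, FDR
threshold, cluster call — and prints the significant clusters around the
selected locus; `examples/mutation_selection_balance.py` prints a balance
distribution and its Δmsat; `examples/power_mini.py` a miniature power
table.

The same operations are available from the shell:

```bash
kskscan simulate --target msat --seed 1 --out-prefix runs/rep1
kskscan scan --vcf runs/rep1.vcf --seed 2 --out-prefix runs/rep1.scan
kskscan finescan --vcf runs/rep1.vcf --region 1:450001-550000 --out fine.tsv
kskscan power --reps 100 --seed 3 --out power.tsv --fixation-only
```

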