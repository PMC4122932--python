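"""Genome-scan mode on a simulator-exported phased VCF.

Simulates microsatellite selection on a 1-Mb sequence, writes the sampled
haplotypes as a phased VCF, scans it with sliding ksk(20)^2 against a
matched neutral null at a 2% FDR, and prints the significant clusters —
which should overlap the selected locus at 500 kb.
"""

import tempfile
from pathlib import Path

import numpy as np

from kskscan import (
    MsatFitnessSurface,
    MsatMutationModel,
    SimConfig,
    cluster_hits,
    extreme_ksk_null,
    fdr_threshold,
    load_phased_sample,
    run_selection_phase,
    scan_chromosome,
    seed_microsatellite,
    simulate_neutral_start,
    windows_from_sample,
    write_vcf,
)

scale = 10.0
mu, r = 2.5e-8 * scale, 1.25e-8 * scale
start = simulate_neutral_start(2000, 1e6, population_size=1000, mu=mu, r=r, seed=3)
model = MsatMutationModel(phi=5, rate_scale=scale)
surface = MsatFitnessSurface(optimum=14, gradient=-0.05 * scale)
start.focal = seed_microsatellite(start.focal_genealogy(), model,
                                  np.random.default_rng(3))
config = SimConfig(target="msat", mu=mu, r=r, viability="exp_best",
                   max_generations=40_000)
result = run_selection_phase(start, config, seed=4, surface=surface,
                             msat_model=model)
print(f"mutation-selection balance at generation {result.stop_generation}; "
      f"delta_msat = {result.delta_msat:.1f}")

with tempfile.TemporaryDirectory() as tmp:
    vcf_path = Path(tmp) / "replicate.vcf"
    write_vcf(result.samples["fixation"], vcf_path, chrom="1")
    sample = load_phased_sample(str(vcf_path))["1"]
sample.sequence_length = 1e6

profile = scan_chromosome(windows_from_sample(sample, 10_000), 20, chrom="1")
null = extreme_ksk_null(60, seed=5, sequence_length=4e5, n_chromosomes=100,
                        theta_prior=(10.0, 10.0), rho_prior=(5.0, 5.0))
threshold, profile.significant = fdr_threshold(profile.values, null.values,
                                               q=0.02)
print(f"FDR 2% threshold: {threshold if threshold is None else round(threshold, 4)}")
for cl in cluster_hits(profile, gap_bp=200_000):
    print(f"cluster {cl.start/1e3:.0f}-{cl.end/1e3:.0f} kb, "
          f"min ksk(20)^2 = {cl.min_value:.3f} at {cl.min_midpoint/1e3:.0f} kb "
          f"({cl.n_members} window sets)")
print("The selected microsatellite sits at 500 kb.  Significant clusters sit")
print("on or beside it: the statistic is often most negative in the flanking")
print("partial-sweep zones and closer to zero at the swept centre itself.")
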