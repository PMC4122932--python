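"""Genome-scan mode: VCF loading, sliding scan, FDR, clusters, fine scan."""

import numpy as np
import pytest

from kskscan.scan import (
    GenericDemography,
    ScanConfig,
    UnphasedGenotypeError,
    cluster_hits,
    fdr_threshold,
    load_phased_sample,
    load_phased_windows,
    scan_chromosome,
    simulate_scan_null,
)
from kskscan.stats import KskProfile, HaplotypeSample, window_stats, windows_from_sample
from kskscan.vcfio import write_vcf


@pytest.fixture(scope="module")
def simulated_sample():
    from kskscan.power import neutral_sample

    return neutral_sample(40, 1e5, theta=40.0, rho=20.0, seed=77)


class TestVcfRoundTrip:
    def test_matrices_survive_round_trip(self, simulated_sample, tmp_path_factory):
        path = tmp_path_factory.mktemp("vcf") / "sim.vcf"
        write_vcf(simulated_sample, path, chrom="1")
        loaded = load_phased_sample(str(path))["1"]
        assert loaded.matrix.shape == simulated_sample.matrix.shape
        assert np.array_equal(loaded.matrix, simulated_sample.matrix)
        # window statistics identical (positions shift by < 1 bp)
        orig = [window_stats(w) for w in
                windows_from_sample(simulated_sample, 1e4)]
        back = [window_stats(w) for w in windows_from_sample(loaded, 1e4)]
        assert [w.S for w in orig] == [w.S for w in back]
        assert [w.K for w in orig] == [w.K for w in back]

    def test_85_diploids_give_170_chromosomes(self, tmp_path):
        rng = np.random.default_rng(0)
        matrix = rng.integers(0, 2, size=(170, 10)).astype(np.int8)
        sample = HaplotypeSample(matrix=matrix,
                                 positions=np.arange(10) * 100.0 + 50,
                                 sequence_length=2e4)
        path = tmp_path / "ceu_like.vcf"
        write_vcf(sample, path)
        loaded = load_phased_sample(str(path))["1"]
        assert loaded.num_chromosomes == 170

    def test_odd_chromosome_count_rejected(self, tmp_path):
        sample = HaplotypeSample(matrix=np.zeros((3, 1), dtype=np.int8),
                                 positions=np.array([5.0]),
                                 sequence_length=10.0)
        sample.matrix[0, 0] = 1
        with pytest.raises(ValueError):
            write_vcf(sample, tmp_path / "odd.vcf")


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb
"""


def write_lines(path, lines):
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in lines))
    return str(path)


class TestVcfEdgeCases:
    def test_unphased_raises_with_record_name(self, tmp_path):
        path = write_lines(tmp_path / "u.vcf", [
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|0",
            "1\t200\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1|0",
        ])
        with pytest.raises(UnphasedGenotypeError, match="1:200"):
            load_phased_sample(path)

    def test_skip_unphased_option_drops_site(self, tmp_path):
        path = write_lines(tmp_path / "u2.vcf", [
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|0",
            "1\t200\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t1|0",
        ])
        sample = load_phased_sample(path, skip_unphased=True)["1"]
        assert sample.positions.tolist() == [99.0]

    def test_non_snv_records_skipped_and_counted(self, tmp_path):
        path = write_lines(tmp_path / "m.vcf", [
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|0",
            "1\t150\t.\tA\tT,G\t.\tPASS\t.\tGT\t0|1\t2|0",
            "1\t180\t.\tAT\tA\t.\tPASS\t.\tGT\t0|1\t1|0",
        ])
        sample = load_phased_sample(path)["1"]
        assert sample.positions.size == 1
        assert sample.metadata["skipped"]["multiallelic"] == 1
        assert sample.metadata["skipped"]["non_snv"] == 1

    def test_record_order_invariance(self, tmp_path):
        lines = [
            "1\t500\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\t1|0",
            "1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t1|1\t0|0",
            "1\t300\t.\tA\tT\t.\tPASS\t.\tGT\t0|0\t0|1",
        ]
        a = load_phased_sample(write_lines(tmp_path / "a.vcf", lines))["1"]
        b = load_phased_sample(write_lines(tmp_path / "b.vcf", lines[::-1]))["1"]
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.matrix, b.matrix)

    def test_load_phased_windows_shape(self, simulated_sample, tmp_path):
        path = tmp_path / "w.vcf"
        write_vcf(simulated_sample, path)
        windows = load_phased_windows(str(path), window_bp=1e4)["1"]
        assert len(windows) == 10
        assert all(w.n == 40 for w in windows)


class TestScanChromosome:
    def test_value_count(self, simulated_sample):
        windows = windows_from_sample(simulated_sample, 1e4)
        profile = scan_chromosome(windows, n_windows=5)
        assert len(profile) == len(windows) - 4

    def test_appending_trailing_windows_extends_but_preserves(self, simulated_sample):
        windows = windows_from_sample(simulated_sample, 1e4)
        base = scan_chromosome(windows, n_windows=5)
        from kskscan.stats import HaplotypeWindow
        trailing = [HaplotypeWindow(
            matrix=np.zeros((40, 0), dtype=np.int8), positions=np.empty(0),
            interval=(1e5 + i * 1e4, 1e5 + (i + 1) * 1e4)) for i in range(3)]
        extended = scan_chromosome(windows + trailing, n_windows=5)
        assert np.allclose(extended.values[: len(base)], base.values)

    def test_agrees_with_explicit_slice_oracle(self, simulated_sample):
        from kskscan.stats import ksk_stat
        windows = windows_from_sample(simulated_sample, 1e4)
        stats_list = [window_stats(w) for w in windows]
        profile = scan_chromosome(windows, n_windows=4)
        for j in range(len(profile)):
            chunk = stats_list[j: j + 4]
            assert profile.values[j] == pytest.approx(
                ksk_stat([w.K for w in chunk], [w.S for w in chunk]))


class TestFdrThreshold:
    def test_identical_distributions_yield_no_calls(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=2000)
        threshold, sig = fdr_threshold(values, rng.normal(size=2000), q=0.02)
        assert sig.mean() < 0.05

    def test_shifted_observations_all_called(self):
        rng = np.random.default_rng(2)
        null = rng.normal(size=2000)
        observed = rng.normal(size=500) - 30.0
        threshold, sig = fdr_threshold(observed, null, q=0.02)
        assert sig.all()

    def test_labeled_mixture_controls_fdp(self):
        """Realized false-discovery proportion <= q + 2 SE on a known mixture."""
        rng = np.random.default_rng(3)
        fdp = []
        for rep in range(40):
            null = rng.normal(size=4000)
            true_null = rng.normal(size=900)
            signal = rng.normal(loc=-6.0, size=100)
            observed = np.concatenate([true_null, signal])
            labels = np.concatenate([np.ones(900), np.zeros(100)])
            _, sig = fdr_threshold(observed, null, q=0.1)
            if sig.sum():
                fdp.append((labels[sig] == 1).sum() / sig.sum())
        mean_fdp = np.mean(fdp)
        se = np.std(fdp, ddof=1) / np.sqrt(len(fdp))
        assert mean_fdp <= 0.1 + 2 * se

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold(np.empty(0), np.arange(5.0))


def make_profile(positions, values, significant):
    positions = np.asarray(positions, dtype=float)
    return KskProfile(positions=positions, values=np.asarray(values, float),
                      n_windows=20, window_bp=1e4, chrom="1",
                      significant=np.asarray(significant, bool))


class TestClusterHits:
    def test_single_hit_single_cluster(self):
        profile = make_profile([1e5], [-0.2], [True])
        clusters = cluster_hits(profile)
        assert len(clusters) == 1
        assert clusters[0].n_members == 1
        assert clusters[0].min_value == -0.2

    def test_distant_hits_split(self):
        profile = make_profile([1e5, 6e5], [-0.2, -0.3], [True, True])
        assert len(cluster_hits(profile, gap_bp=2e5)) == 2
        assert len(cluster_hits(profile, gap_bp=6e5)) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.uniform(0, 5e6, size=60))
        profile = make_profile(pos, rng.uniform(-0.3, -0.1, size=60),
                               np.ones(60, bool))
        clusters = cluster_hits(profile, gap_bp=2e5)
        reprofile = make_profile([c.min_midpoint for c in clusters],
                                 [c.min_value for c in clusters],
                                 np.ones(len(clusters), bool))
        assert len(cluster_hits(reprofile, gap_bp=2e5)) == len(clusters)

    def test_requires_significance_calls(self):
        profile = KskProfile(np.array([1.0]), np.array([-0.1]), 20, 1e4)
        with pytest.raises(ValueError):
            cluster_hits(profile)


class TestScanNull:
    def test_values_per_replicate_structure(self):
        cfg = ScanConfig(null_reps=2, null_sequence_length=4e5,
                         null_sample_chromosomes=20, mu=2.5e-8)
        values = simulate_scan_null(cfg, seed=5)
        # (40 windows - 19) sliding values per replicate
        assert values.size == 2 * (40 - 19)

    def test_high_theta_null_concentrates_below_zero(self):
        cfg = ScanConfig(null_reps=2, null_sequence_length=3e5,
                         null_sample_chromosomes=60, mu=2.5e-7,
                         demography=GenericDemography(
                             ancestral_size=10_000, bottleneck_size=10_000,
                             growth_rate=0.0))
        values = simulate_scan_null(cfg, seed=6)
        assert np.mean(values < 0) > 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(fdr=1.5)
        with pytest.raises(ValueError):
            ScanConfig(null_sequence_length=1e5, n_windows=20)


class TestEndToEndScan:
    def test_selection_replicate_yields_cluster_near_target(self, tmp_path):
        """A strong microsatellite-selection replicate embedded in neutral
        sequence produces a significant cluster overlapping the locus."""
        from kskscan.coalescent import simulate_neutral_start, seed_microsatellite
        from kskscan.models import MsatFitnessSurface, MsatMutationModel
        from kskscan.wright_fisher import SimConfig, run_selection_phase

        scale = 10.0
        start = simulate_neutral_start(2000, 1e6, population_size=1000,
                                       mu=2.5e-7, r=1.25e-7, seed=41)
        model = MsatMutationModel(phi=5, rate_scale=scale)
        surface = MsatFitnessSurface(optimum=14, gradient=-0.05 * scale)
        rng = np.random.default_rng(8)
        start.focal = seed_microsatellite(start.focal_genealogy(), model, rng)
        cfg = SimConfig(target="msat", mu=2.5e-7, r=1.25e-7,
                        viability="exp_best", max_generations=30_000)
        res = run_selection_phase(start, cfg, seed=42, surface=surface,
                                  msat_model=model)
        sample = res.samples["fixation"]
        path = tmp_path / "sel.vcf"
        write_vcf(sample, path)
        loaded = load_phased_sample(str(path))["1"]
        loaded.sequence_length = 1e6
        windows = windows_from_sample(loaded, 1e4)
        profile = scan_chromosome(windows, n_windows=20, chrom="1")
        # null from matched neutral coalescent replicates
        from kskscan.power import extreme_ksk_null
        null = extreme_ksk_null(40, seed=43, sequence_length=4e5,
                                n_chromosomes=100,
                                theta_prior=(10.0, 10.0), rho_prior=(5.0, 5.0))
        threshold, sig = fdr_threshold(profile.values, null.values, q=0.02)
        profile.significant = sig
        clusters = cluster_hits(profile, gap_bp=2e5)
        assert clusters, "no significant cluster found"
        best = min(clusters, key=lambda c: c.min_value)
        assert best.start - 2e5 <= 5e5 <= best.end + 2e5
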