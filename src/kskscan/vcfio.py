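"""Minimal VCF export of simulated haplotype samples.

Samples are written as phased diploid genotypes (consecutive chromosome
pairs), one pseudo-contig per sample, with REF=A / ALT=T placeholders for the
binary derived/ancestral states.  The files round-trip through standard VCF
readers (the scan module reads them back with cyvcf2).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .stats import HaplotypeSample

__all__ = ["write_vcf"]


def write_vcf(sample: HaplotypeSample, path: str | Path, chrom: str = "1",
              sample_prefix: str = "ind") -> None:
    """Write a haplotype sample as an uncompressed, phased VCF.

    Positions are converted to VCF's 1-based convention; chromosomes 2k and
    2k+1 become the phased genotype of diploid individual k.
    """
    n = sample.num_chromosomes
    if n % 2:
        raise ValueError("need an even number of chromosomes for diploid VCF")
    n_ind = n // 2
    names = [f"{sample_prefix}{i}" for i in range(n_ind)]
    length = int(np.ceil(sample.sequence_length))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        pos_1based = np.floor(sample.positions).astype(np.int64) + 1
        # infinite-sites positions are continuous; keep integer positions unique
        for i in range(1, pos_1based.size):
            if pos_1based[i] <= pos_1based[i - 1]:
                pos_1based[i] = pos_1based[i - 1] + 1
        for col in range(sample.positions.size):
            gt = sample.matrix[:, col]
            fields = "\t".join(f"{gt[2 * k]}|{gt[2 * k + 1]}" for k in range(n_ind))
            fh.write(f"{chrom}\t{pos_1based[col]}\t.\tA\tT\t.\tPASS\t.\tGT\t{fields}\n")
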