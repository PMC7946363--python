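"""Phased-VCF ingest and export for haplotype matrices.

Only biallelic SNPs with phased GT fields are accepted; missing calls
('.') become the missing sentinel. Multiallelic records are rejected at
ingest (split or drop them upstream). Coordinates are 1-based in VCF, as
in the reports; matrices keep 1-based bp positions throughout.
"""

from __future__ import annotations

import numpy as np

from .hapstats import MISSING, HaplotypeMatrix

__all__ = ["read_vcf", "write_vcf"]


def read_vcf(path, chrom: str | None = None) -> dict[str, HaplotypeMatrix]:
    """Read a phased VCF into per-chromosome haplotype matrices.

    Each diploid sample contributes two haplotype rows (``<id>_a`` and
    ``<id>_b``). Returns ``{chrom: HaplotypeMatrix}``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    per_chrom: dict[str, list] = {}
    positions: dict[str, list] = {}
    for var in vcf:
        if chrom is not None and var.CHROM != chrom:
            continue
        if len(var.ALT) != 1 or not var.is_snp:
            raise ValueError(
                f"{var.CHROM}:{var.POS}: only biallelic SNPs are accepted; "
                "split or drop multiallelic records upstream"
            )
        # genotype array: (n_samples, 3) = allele_a, allele_b, phased flag
        geno = np.asarray(var.genotype.array())
        if np.any((geno[:, 2] == 0) & (geno[:, 0] != geno[:, 1])):
            raise ValueError(f"{var.CHROM}:{var.POS}: unphased heterozygote")
        col = geno[:, :2].reshape(-1).astype(np.int8)
        col[col < 0] = MISSING
        per_chrom.setdefault(var.CHROM, []).append(col)
        positions.setdefault(var.CHROM, []).append(var.POS)
    sample_ids = tuple(f"{s}_{ab}" for s in samples for ab in ("a", "b"))
    out = {}
    for c, cols in per_chrom.items():
        out[c] = HaplotypeMatrix(
            alleles=np.array(cols, dtype=np.int8).T,
            positions=np.array(positions[c], dtype=np.int64),
            chrom=c,
            sample_ids=sample_ids,
        )
    return out


def write_vcf(matrix: HaplotypeMatrix, path, contig_length: int | None = None) -> None:
    """Export a haplotype matrix as an uncompressed phased VCF.

    Consecutive haplotype pairs form diploid samples; an odd trailing
    haplotype becomes a haploid-coded sample (second allele '.').
    """
    n = matrix.n_haplotypes
    n_dip, odd = divmod(n, 2)
    names = [f"ind{i}" for i in range(n_dip + odd)]
    length = contig_length or int(matrix.positions[-1]) if matrix.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names) + "\n"
        )
        for j in range(matrix.n_sites):
            col = matrix.alleles[:, j]
            calls = []
            for i in range(n_dip):
                a, b = col[2 * i], col[2 * i + 1]
                calls.append(
                    f"{'.' if a == MISSING else int(a)}|"
                    f"{'.' if b == MISSING else int(b)}"
                )
            if odd:
                a = col[-1]
                calls.append(f"{'.' if a == MISSING else int(a)}|.")
            fh.write(
                f"{matrix.chrom}\t{int(matrix.positions[j])}\t.\tA\tT\t.\tPASS\t.\t"
                "GT\t" + "\t".join(calls) + "\n"
            )
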