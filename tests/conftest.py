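import numpy as np
import pytest

from dogcnv.simulate import GenoSimConfig, simulate_genotypes, study_scale_bundle


@pytest.fixture(scope="session")
def study_bundle():
    """Study-scale synthetic CNV calls + breed metadata + ground truth."""
    return study_scale_bundle(seed=1)


@pytest.fixture(scope="session")
def geno_bundle():
    """Default genotype scenario: 4 dog breeds + wolves, introgression planted."""
    config = GenoSimConfig(seed=5)
    loci, dosages, pop_map, truth = simulate_genotypes(config)
    return config, loci, dosages, pop_map, truth


def write_vcf(path, loci, dosages, aa_field="AA"):
    """Write loci + derived-dosage matrix as a minimal text VCF.

    REF is the ancestral allele and ALT the derived one, so the derived
    dosage equals the ALT dosage; missing dosages become ./. genotypes.
    """
    samples = list(dosages.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={aa_field},Number=1,Type=String,'
                 'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = sorted({loc.chrom for loc in loci})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        mat = dosages.to_numpy()
        order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].pos))
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i in order:
            loc = loci[i]
            gts = [gt_of.get(mat[i, j], "./.") if not np.isnan(mat[i, j]) else "./."
                   for j in range(len(samples))]
            fh.write(f"{loc.chrom}\t{loc.pos + 1}\t.\t{loc.ancestral_allele}\t"
                     f"{loc.derived_allele}\t.\tPASS\t{aa_field}="
                     f"{loc.ancestral_allele}\tGT\t" + "\t".join(gts) + "\n")
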