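"""Optional VCF genotype ingestion (biallelic SNP records, GT field only).

Sample IDs in the VCF are matched to ``subject_id``; calls overwrite or
extend the cohort's genotype mapping.  Requires cyvcf2 (``pip install
gxe[vcf]``).
"""

from __future__ import annotations

from .cohort import CohortData, SnpInfo

__all__ = ["load_genotypes_from_vcf"]


def load_genotypes_from_vcf(cohort: CohortData, vcf_path: str) -> CohortData:
    """Attach genotypes from a VCF to matching subjects, in place.

    Only biallelic SNP records are read; multiallelic or indel records are
    skipped.  Missing GT stays missing.  Returns the cohort for chaining.
    """
    from cyvcf2 import VCF  # lazy: optional dependency

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    by_id = {s.subject_id: s for s in cohort.subjects}
    known = {s.snp_id for s in cohort.snp_catalog}
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        ref, alt = var.REF, var.ALT[0]
        if snp_id not in known:
            cohort.snp_catalog.append(SnpInfo(snp_id, ref, alt))
            known.add(snp_id)
        alleles = (ref, alt)
        for sample, gt in zip(samples, var.genotypes):
            subj = by_id.get(sample)
            if subj is None:
                continue
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                subj.genotypes[snp_id] = None
            else:
                subj.genotypes[snp_id] = (alleles[a], alleles[b])
    return cohort
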