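"""Per-SNP genotyping QC: genotype counts, call rate, MAF, Hardy-Weinberg tests.

HWE is assessed in controls (cases are ascertained on the outcome, so only
the control genotype distribution is expected to follow population
proportions (1-p)^2 : 2p(1-p) : p^2).  The default test is the 1-df Pearson
chi-square; an exact test by full enumeration of the heterozygote count
conditional on the allele counts is available for sparse genotype classes.
SNPs failing a threshold are flagged, never auto-dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .cohort import CohortData, code_codominant

__all__ = ["HWETestResult", "genotype_counts", "hwe_chisq", "hwe_exact", "call_rate", "snp_qc_table"]


@dataclass
class HWETestResult:
    snp_id: str
    counts: tuple[int, int, int]  # (n_AA, n_Aa, n_aa) = (ref hom, het, var hom)
    allele_freq_hat: float  # variant-allele frequency
    chi2: float
    df: int
    p_value: float
    method: str
    flags: list[str] = field(default_factory=list)


def genotype_counts(cohort: CohortData, snp_id: str, subset: str = "controls"):
    """Genotype counts (ref-hom, het, var-hom) over a cohort subset.

    Missing calls are excluded from the counts.  ``subset`` is one of
    ``controls`` (the HWE convention), ``cases`` or ``all``.
    """
    snp = cohort.snp(snp_id)  # raises KeyError for unknown SNP
    if subset not in ("controls", "cases", "all"):
        raise ValueError(f"unknown subset {subset!r}")
    n = [0, 0, 0]
    for s in cohort.subjects:
        if subset == "controls" and s.is_case:
            continue
        if subset == "cases" and not s.is_case:
            continue
        g = code_codominant(s.genotypes.get(snp_id), snp)
        if g is not None:
            n[g] += 1
    return tuple(n)


def hwe_chisq(counts, snp_id: str = "") -> HWETestResult:
    """1-df Pearson chi-square test of HWE genotype proportions.

    Expected counts use the estimated variant-allele frequency
    p-hat = (2 n_aa + n_Aa) / 2n.  Monomorphic SNPs (p-hat 0 or 1) return
    chi2 = 0, p = 1 with a ``monomorphic`` flag.
    """
    n_aa_ref, n_het, n_aa_var = counts
    if min(counts) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa_ref + n_het + n_aa_var
    if n == 0:
        return HWETestResult(snp_id, tuple(counts), float("nan"), 0.0, 1, 1.0,
                             "chi-square", ["no_data"])
    p = (2 * n_aa_var + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return HWETestResult(snp_id, tuple(counts), p, 0.0, 1, 1.0,
                             "chi-square", ["monomorphic"])
    exp = (n * (1 - p) ** 2, n * 2 * p * (1 - p), n * p**2)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, exp))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HWETestResult(snp_id, tuple(counts), p, chi2, 1, pval, "chi-square")


def hwe_exact(counts, snp_id: str = "") -> HWETestResult:
    """Exact HWE test by enumeration of the heterozygote count.

    Conditional on the allele counts, the number of heterozygotes under HWE
    has the distribution P(n_het) ∝ n! / (n_AA! n_Aa! n_aa!) * 2^{n_Aa};
    the two-sided p-value sums the probabilities of all configurations no
    more probable than the observed one.
    """
    n_ref, n_het, n_var = counts
    if min(counts) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_ref + n_het + n_var
    if n == 0:
        return HWETestResult(snp_id, tuple(counts), float("nan"), 0.0, 1, 1.0,
                             "exact", ["no_data"])
    n_minor = min(2 * n_var + n_het, 2 * n_ref + n_het)
    p = (2 * n_var + n_het) / (2 * n)
    if n_minor == 0:
        return HWETestResult(snp_id, tuple(counts), p, 0.0, 1, 1.0,
                             "exact", ["monomorphic"])

    def log_prob(het: int) -> float:
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        return (
            het * math.log(2)
            - math.lgamma(hom_major + 1)
            - math.lgamma(het + 1)
            - math.lgamma(hom_minor + 1)
        )

    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    mx = max(logs.values())
    total = sum(math.exp(v - mx) for v in logs.values())
    probs = {h: math.exp(v - mx) / total for h, v in logs.items()}
    obs = probs[n_het]
    pval = min(1.0, sum(q for q in probs.values() if q <= obs + 1e-12))
    return HWETestResult(snp_id, tuple(counts), p, float("nan"), 1, pval, "exact")


def call_rate(cohort: CohortData, snp_id: str, threshold: float = 0.98):
    """Fraction of subjects with a non-missing call; flagged below threshold."""
    cohort.snp(snp_id)
    total = len(cohort.subjects)
    if total == 0:
        return {"rate": 0.0, "flagged": True}
    called = sum(1 for s in cohort.subjects if s.genotypes.get(snp_id) is not None)
    rate = called / total
    return {"rate": rate, "flagged": rate < threshold}


def snp_qc_table(cohort: CohortData, alpha: float = 0.001,
                 call_threshold: float = 0.98, method: str = "chi-square"):
    """Per-SNP QC rows: counts, MAF, call rate, HWE statistic and flags."""
    rows = []
    test = hwe_chisq if method == "chi-square" else hwe_exact
    for snp in cohort.snp_catalog:
        counts = genotype_counts(cohort, snp.snp_id, subset="controls")
        res = test(counts, snp.snp_id)
        cr = call_rate(cohort, snp.snp_id, threshold=call_threshold)
        flags = list(res.flags)
        if not math.isnan(res.allele_freq_hat) and res.p_value < alpha:
            flags.append("hwe_deviation")
        if cr["flagged"]:
            flags.append("low_call_rate")
        maf = res.allele_freq_hat
        if maf == maf and maf > 0.5:  # report the minor allele frequency
            maf = 1 - maf
        rows.append(
            {
                "snp_id": snp.snp_id,
                "n_ref_hom": counts[0],
                "n_het": counts[1],
                "n_var_hom": counts[2],
                "maf": maf,
                "call_rate": cr["rate"],
                "chi2": res.chi2,
                "p_value": res.p_value,
                "flags": ";".join(flags),
            }
        )
    return rows
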