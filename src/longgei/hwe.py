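"""Founders-only exact Hardy-Weinberg test and pre-scan SNP filtering.

Family data violate the independence assumption of HWE tests, so genotype
counts are taken from founders only (members with no parents in the
pedigree).  The test conditions on the observed allele counts: given n
genotyped founders and n_a copies of the minor allele, the probability of
observing h heterozygotes is

    P(h | n, n_a) = C(n, h) C(n - h, (n_a - h)/2) 2^h / C(2n, n_a) * ...

computed here in log space from factorials; the exact two-sided P-value sums
P(h') over all attainable heterozygote counts h' (same parity as n_a) whose
probability does not exceed that of the observed count.  SNPs with P below a
threshold (default 1e-6, strict inequality) are excluded before scanning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .data import GenotypeTable, PedigreeMember

__all__ = ["HweResult", "founders", "hwe_exact", "filter_snps"]


@dataclass(frozen=True)
class HweResult:
    """Founder genotype counts and exact HWE P-value for one SNP."""

    snp_id: str
    n_AA: int  # major homozygotes
    n_Aa: int  # heterozygotes
    n_aa: int  # minor homozygotes
    p_value: float
    passed: bool
    reason: str = ""


def founders(members: Iterable[PedigreeMember]) -> set[str]:
    """Individuals with both parent ids missing."""
    return {m.individual_id for m in members if m.is_founder}


def _log_prob_het(h: np.ndarray, n: int, na: int) -> np.ndarray:
    """log P(h heterozygotes | n individuals, na minor alleles)."""
    n_min_hom = (na - h) // 2
    n_maj_hom = n - h - n_min_hom
    lf = gammaln  # log Gamma(x+1) = log x!
    return (
        lf(n + 1)
        - lf(h + 1)
        - lf(n_min_hom + 1)
        - lf(n_maj_hom + 1)
        + h * np.log(2.0)
        + lf(na + 1)
        + lf(2 * n - na + 1)
        - lf(2 * n + 1)
    )


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE P-value from genotype counts, conditional on allele counts.

    Symmetric in the homozygote labels; a monomorphic SNP returns 1.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotyped founder is required")
    na = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor-allele copies
    if na == 0:
        return 1.0
    hs = np.arange(na % 2, na + 1, 2)
    hs = hs[(na - hs) // 2 <= n - hs]  # attainable configurations
    logp = _log_prob_het(hs, n, na)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hs, n_Aa)]
    p = float(probs[probs <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def filter_snps(
    genotypes: GenotypeTable,
    members: Sequence[PedigreeMember],
    threshold: float = 1e-6,
) -> tuple[list[str], list[HweResult]]:
    """Keep SNPs whose founders-only exact HWE P-value is >= threshold.

    Exclusion uses strict inequality (P < threshold drops the SNP); SNPs with
    no genotyped founder are excluded with a reason code.
    """
    fset = founders(members)
    idx = [i for i in genotypes.individual_ids if i in fset]
    sub = genotypes.dosages.loc[idx]
    kept: list[str] = []
    results: list[HweResult] = []
    for snp in genotypes.snp_ids:
        d = sub[snp].dropna()
        if len(d) == 0:
            results.append(HweResult(snp, 0, 0, 0, float("nan"), False, "no founder genotypes"))
            continue
        n_aa = int((d == 2).sum())
        n_Aa = int((d == 1).sum())
        n_AA = int((d == 0).sum())
        p = hwe_exact(n_AA, n_Aa, n_aa)
        ok = not (p < threshold)
        results.append(HweResult(snp, n_AA, n_Aa, n_aa, p, ok))
        if ok:
            kept.append(snp)
    return kept, results
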