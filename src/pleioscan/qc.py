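"""Per-SNP quality control: Hardy–Weinberg equilibrium and minor-allele
frequency filters with transparent inclusion–exclusion accounting.

The exact HWE test is the conditional enumeration test: given the observed
allele counts, the number of heterozygotes under HWE follows a known
distribution, and the two-sided p-value is the summed probability of all
heterozygote counts whose probability does not exceed the observed one
(no mid-p correction).  The chi-square alternative is the 1-df Pearson
statistic against HWE expected genotype counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeDataset


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one SNP; ``n_AA`` counts minor-allele homozygotes."""

    n_AA: int
    n_Aa: int
    n_aa: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa, self.n_missing) < 0:
            raise ValueError("genotype counts must be nonnegative")

    @property
    def n_genotyped(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


def counts_from_dosages(dosage: np.ndarray) -> GenotypeCounts:
    """Tally 0/1/2 dosages (NaN = missing) into genotype counts."""
    d = np.asarray(dosage, dtype=float)
    return GenotypeCounts(
        n_AA=int(np.sum(d == 2.0)),
        n_Aa=int(np.sum(d == 1.0)),
        n_aa=int(np.sum(d == 0.0)),
        n_missing=int(np.sum(np.isnan(d))),
    )


def hwe_exact_probs(n_rare: int, n_genotyped: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of heterozygote counts given allele counts.

    Returns ``(het_counts, probs)`` for all feasible heterozygote counts
    (same parity as the rare-allele count).  Probabilities are computed by
    the standard recurrence, normalised to sum to 1.
    """
    if n_rare > n_genotyped:  # rare allele count bounded by 2n
        raise ValueError("rare allele count exceeds what n samples can carry")
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # Unnormalised recurrence upward in het count:
    #   P(h+2)/P(h) = 4*n_AA(h)*n_aa(h) / ((h+2)*(h+1))
    # with n_AA = (n_rare - h)/2 rare homs, n_aa = n - n_AA - h common homs.
    log_probs = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        n_homr = (n_rare - h) // 2
        n_homc = n_genotyped - n_homr - h
        ratio = 4.0 * n_homr * n_homc / ((h + 2.0) * (h + 1.0))
        log_probs[i] = log_probs[i - 1] + np.log(ratio)
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    return hets, probs


def hwe_exact_p(c: GenotypeCounts) -> float:
    """Exact conditional HWE test p-value (two-sided, no mid-p).

    Monomorphic SNPs return 1 by convention.
    """
    n = c.n_genotyped
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_rare = min(2 * c.n_AA + c.n_Aa, 2 * c.n_aa + c.n_Aa)
    if n_rare == 0:
        return 1.0
    hets, probs = hwe_exact_probs(n_rare, n)
    p_obs = probs[hets == c.n_Aa][0]
    # Sum of probabilities <= observed; tiny relative slack absorbs the
    # floating-point noise of the recurrence so the modal config gives 1.
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chisq_p(c: GenotypeCounts) -> float:
    """1-df Pearson chi-square HWE test against expected genotype counts."""
    n = c.n_genotyped
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    p = (2 * c.n_AA + c.n_Aa) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    observed = np.array([c.n_AA, c.n_Aa, c.n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test(c: GenotypeCounts, method: str = "exact") -> float:
    if method == "exact":
        return hwe_exact_p(c)
    if method == "chisq":
        return hwe_chisq_p(c)
    raise ValueError(f"unknown HWE method: {method!r}")


def minor_allele_frequency(c: GenotypeCounts) -> tuple[float, bool]:
    """Frequency of the designated A allele over non-missing genotypes.

    Returns ``(maf, swapped)``: if the designated allele turns out to be
    the major one (frequency > 0.5) the labels are swapped and the swap
    reported, so ``maf <= 0.5`` always.
    """
    n = c.n_genotyped
    if n < 1:
        raise ValueError("MAF undefined: all genotypes missing")
    freq = (2 * c.n_AA + c.n_Aa) / (2 * n)
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


@dataclass
class QCReport:
    """Inclusion–exclusion accounting of a QC pass.

    Satisfies ``n_retained = n_total - n_hwe_fail - n_maf_fail +
    n_both_fail`` by construction; the optional per-SNP ``flags`` table
    carries one row per input SNP.
    """

    n_total: int
    n_hwe_fail: int
    n_maf_fail: int
    n_both_fail: int
    flags: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_hwe_fail - self.n_maf_fail + self.n_both_fail

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_hwe_fail": self.n_hwe_fail,
            "n_maf_fail": self.n_maf_fail,
            "n_both_fail": self.n_both_fail,
            "n_retained": self.n_retained,
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def apply_qc(
    G: GenotypeDataset,
    hwe_threshold: float = 0.01,
    maf_threshold: float = 0.01,
    method: str = "exact",
) -> tuple[GenotypeDataset, QCReport]:
    """Filter SNPs failing HWE or MAF criteria; strict-inequality failures.

    A SNP fails HWE iff ``p < hwe_threshold`` and fails MAF iff
    ``maf < maf_threshold`` (ties are retained).  SNPs with every genotype
    missing have undefined MAF and auto-fail the MAF criterion.  Returns
    the filtered dataset and a :class:`QCReport` whose flags table lists
    ``snp_id, maf, hwe_p, hwe_fail, maf_fail, retained``.
    """
    # threshold 0 disables a filter (strict inequality never fires)
    if not 0.0 <= hwe_threshold < 1.0 or not 0.0 <= maf_threshold < 1.0:
        raise ValueError("thresholds must lie in [0, 1)")
    rows = []
    for j in range(G.n_snps):
        c = counts_from_dosages(G.dosages[:, j])
        snp_id = G.snps["snp_id"].iloc[j]
        if c.n_genotyped == 0:
            rows.append((snp_id, np.nan, np.nan, False, True))
            continue
        maf, _ = minor_allele_frequency(c)
        p = hwe_test(c, method=method)
        rows.append((snp_id, maf, p, p < hwe_threshold, maf < maf_threshold))

    flags = pd.DataFrame(
        rows, columns=["snp_id", "maf", "hwe_p", "hwe_fail", "maf_fail"]
    )
    flags["retained"] = ~(flags["hwe_fail"] | flags["maf_fail"])
    report = QCReport(
        n_total=G.n_snps,
        n_hwe_fail=int(flags["hwe_fail"].sum()),
        n_maf_fail=int(flags["maf_fail"].sum()),
        n_both_fail=int((flags["hwe_fail"] & flags["maf_fail"]).sum()),
        flags=flags,
    )
    filtered = G.subset_snps(flags["retained"].to_numpy())
    return filtered, report
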