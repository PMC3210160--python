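"""HWE testing and SNP filtering: enumeration oracle, asymptotic
agreement, inclusion-exclusion accounting, order independence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pleioscan import GenotypeCounts, QCReport, apply_qc, minor_allele_frequency
from pleioscan.qc import (
    counts_from_dosages,
    hwe_chisq_p,
    hwe_exact_p,
    hwe_exact_probs,
)
from pleioscan.synthgen import SNPSpec, simulate_genotypes


def enumeration_oracle(n_AA, n_Aa, n_aa):
    """Brute-force exact HWE p: enumerate all genotype configurations with
    the observed allele counts, with probabilities from the closed-form
    conditional distribution (multinomial-coefficient formula)."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_rare = min(n_A, 2 * n - n_A)
    configs = []
    for het in range(n_rare % 2, n_rare + 1, 2):
        homr = (n_rare - het) // 2
        homc = n - homr - het
        logp = (
            math.lgamma(n + 1)
            - math.lgamma(homr + 1) - math.lgamma(het + 1) - math.lgamma(homc + 1)
            + het * math.log(2)
        )
        configs.append((het, logp))
    mx = max(lp for _, lp in configs)
    probs = {het: math.exp(lp - mx) for het, lp in configs}
    total = sum(probs.values())
    probs = {het: p / total for het, p in probs.items()}
    p_obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts",
    [(1, 2, 1), (0, 4, 0), (5, 10, 85), (2, 30, 68), (0, 1, 49), (10, 10, 10)],
)
def test_exact_hwe_matches_enumeration_oracle(counts):
    got = hwe_exact_p(GenotypeCounts(*counts))
    want = enumeration_oracle(*counts)
    assert got == pytest.approx(want, rel=1e-9)


def test_modal_configuration_gives_p_one():
    assert hwe_exact_p(GenotypeCounts(1, 2, 1)) == 1.0


def test_all_heterozygote_excess_is_rejected():
    assert hwe_exact_p(GenotypeCounts(0, 200, 0)) < 1e-20


def test_monomorphic_p_is_one_by_convention():
    assert hwe_exact_p(GenotypeCounts(0, 0, 50)) == 1.0
    assert hwe_chisq_p(GenotypeCounts(0, 0, 50)) == 1.0


def test_exact_and_chisq_agree_asymptotically():
    """Balanced large counts near HWE expectations: the two tests agree
    within 0.02."""
    # p = 0.3, n = 1000, counts at expectation
    c = GenotypeCounts(90, 420, 490)
    assert abs(hwe_exact_p(c) - hwe_chisq_p(c)) < 0.02
    # mild disequilibrium
    c2 = GenotypeCounts(100, 400, 500)
    assert abs(hwe_exact_p(c2) - hwe_chisq_p(c2)) < 0.02


@settings(max_examples=100, deadline=None, derandomize=True)
@given(n_rare=st.integers(1, 200), n=st.integers(1, 300))
def test_enumeration_probabilities_sum_to_one(n_rare, n):
    if n_rare > n:  # infeasible allele count for n diploids capped at 2n... keep rare <= n
        n_rare = n
    _, probs = hwe_exact_probs(n_rare, n)
    assert abs(probs.sum() - 1.0) < 1e-12


def test_minor_allele_frequency_cases():
    assert minor_allele_frequency(GenotypeCounts(0, 10, 0)) == (0.5, False)
    # designated allele carried by 2*90+18 = 198 of 220: major, so swap
    maf, swapped = minor_allele_frequency(GenotypeCounts(90, 18, 2))
    assert maf == pytest.approx((18 + 4) / 220) and swapped
    with pytest.raises(ValueError):
        minor_allele_frequency(GenotypeCounts(0, 0, 0, n_missing=5))


def test_maf_label_swap_recorded():
    # designated A allele fixed: frequency 1 -> swap to 0
    maf, swapped = minor_allele_frequency(GenotypeCounts(50, 0, 0))
    assert maf == 0.0 and swapped
    maf2, swapped2 = minor_allele_frequency(GenotypeCounts(0, 0, 50))
    assert maf2 == 0.0 and not swapped2


def test_published_inclusion_exclusion_accounting():
    """The inclusion-exclusion identity on the reported genome-scan
    totals: 909,622 - 17,888 - 202,984 + 618 = 689,368 retained."""
    report = QCReport(909622, 17888, 202984, 618)
    assert report.n_retained == 689368
    assert report.summary()["n_retained"] == 689368


def test_apply_qc_flags_planted_failures_exactly():
    """A panel with planted rare and HWE-violating SNPs: flags must match
    the plant, and the report identity must hold."""
    rng = np.random.default_rng(0)
    n = 500
    good = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
    rare = rng.binomial(2, 0.004, size=(n, 1)).astype(float)  # MAF << 1%
    all_het = np.ones((n, 1))  # gross HWE violation
    rare_het = np.zeros((n, 1))  # one rare het: MAF fail only
    rare_het[0, 0] = 1.0
    dosages = np.hstack([good, rare, all_het, rare_het])

    import pandas as pd

    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(6)],
            "chrom": 1, "pos": np.arange(6) + 1,
            "minor_allele": "A", "major_allele": "G",
        }
    )
    from pleioscan.datatypes import GenotypeDataset

    G = GenotypeDataset(dosages, snps, pd.DataFrame({"sample_id": [str(i) for i in range(n)]}))
    filtered, report = apply_qc(G, 0.01, 0.01)
    flags = report.flags.set_index("snp_id")
    assert not flags.loc[["s0", "s1", "s2"], ["hwe_fail", "maf_fail"]].any().any()
    assert flags.loc["s3", "maf_fail"] and not flags.loc["s3", "hwe_fail"]
    assert flags.loc["s4", "hwe_fail"]
    assert flags.loc["s5", "maf_fail"]
    assert report.n_retained == filtered.n_snps == 3
    assert report.n_retained == (
        report.n_total - report.n_hwe_fail - report.n_maf_fail + report.n_both_fail
    )


def test_qc_thresholds_zero_disable_filters():
    G = simulate_genotypes(100, [SNPSpec("a", 1, 1, 0.05)], seed=1)
    filtered, report = apply_qc(G, hwe_threshold=0.0, maf_threshold=0.0)
    assert report.n_retained == G.n_snps == filtered.n_snps


def test_qc_empty_dataset_yields_empty_report():
    G = simulate_genotypes(50, [SNPSpec("a", 1, 1, 0.3)], seed=1)
    empty = G.subset_snps(np.zeros(1, dtype=bool))
    filtered, report = apply_qc(empty)
    assert report.n_total == 0 and report.n_retained == 0
    assert filtered.n_snps == 0


def test_qc_is_order_independent():
    """Permuting SNP columns permutes the flags but never changes them."""
    specs = [SNPSpec(f"s{j}", 1, j + 1, 0.05 + 0.04 * j) for j in range(8)]
    G = simulate_genotypes(300, specs, seed=5)
    _, rep1 = apply_qc(G)
    perm = np.random.default_rng(1).permutation(8)
    from pleioscan.datatypes import GenotypeDataset

    Gp = GenotypeDataset(
        G.dosages[:, perm],
        G.snps.iloc[perm].reset_index(drop=True),
        G.samples,
    )
    _, rep2 = apply_qc(Gp)
    a = rep1.flags.set_index("snp_id").sort_index()
    b = rep2.flags.set_index("snp_id").sort_index()
    assert a.equals(b)


def test_all_missing_snp_auto_fails():
    import pandas as pd

    from pleioscan.datatypes import GenotypeDataset

    dosages = np.column_stack(
        [np.full(50, np.nan), np.random.default_rng(0).binomial(2, 0.3, 50).astype(float)]
    )
    snps = pd.DataFrame(
        {"snp_id": ["gone", "ok"], "chrom": 1, "pos": [1, 2],
         "minor_allele": "A", "major_allele": "G"}
    )
    G = GenotypeDataset(dosages, snps, pd.DataFrame({"sample_id": [str(i) for i in range(50)]}))
    _, report = apply_qc(G)
    flags = report.flags.set_index("snp_id")
    assert flags.loc["gone", "maf_fail"] and not flags.loc["gone", "retained"]
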