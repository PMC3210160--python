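import numpy as np
import pytest

from pleioscan import synthgen


@pytest.fixture(scope="session")
def small_cohort():
    """600 samples x 50 independent SNPs with one planted shared-effect SNP."""
    specs = synthgen.uniform_snp_panel(50, maf_range=(0.1, 0.5), seed=100)
    G = synthgen.simulate_genotypes(600, specs, seed=101)
    model = synthgen.PhenoModelSpec(residual_corr=0.5, seed=102)
    traits = synthgen.simulate_traits(
        G, [synthgen.EffectSpec("snp7", 0.4, 0.4)], model
    )
    return G, traits


def phased_genotypes(hap_freqs, n, seed):
    """Draw unphased dosage pairs from known two-locus haplotype frequencies.

    Independent of the EM code path: haplotypes are sampled directly and
    collapsed to dosages, so the generating frequencies are ground truth.
    """
    rng = np.random.default_rng(seed)
    hap = rng.choice(4, size=(n, 2), p=np.asarray(hap_freqs, dtype=float))
    g1 = np.isin(hap, (0, 1)).sum(axis=1).astype(float)  # haps carrying A
    g2 = np.isin(hap, (0, 2)).sum(axis=1).astype(float)  # haps carrying B
    return g1, g2
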