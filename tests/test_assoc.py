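"""The bivariate Wilks-lambda F-test and univariate regressions:
brute-force oracle equivalence, exact null distribution, invariances,
scan behaviour on planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan import (
    DegenerateResidualError,
    EffectSpec,
    MonomorphicError,
    PhenoModelSpec,
    fit_bivariate,
    fit_univariate,
    scan,
    threshold_view,
)
from pleioscan.synthgen import simulate_genotypes, simulate_traits, uniform_snp_panel


def brute_force_bivariate(y, x, Z=None):
    """Independent MANOVA likelihood-ratio computation: explicit normal
    equations, determinant formula, exact F conversion."""
    n = len(x)
    X0 = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    X1 = np.column_stack([X0, x])

    def resid_sscp(X):
        B = np.linalg.solve(X.T @ X, X.T @ y)
        R = y - X @ B
        return R.T @ R

    E1, E0 = resid_sscp(X1), resid_sscp(X0)
    lam = np.linalg.det(E1) / np.linalg.det(E0)
    nu_e = n - X1.shape[1]
    F = (1 - lam) / lam * (nu_e - 1) / 2
    return F, float(stats.f.sf(F, 2, nu_e - 1))


def test_bivariate_matches_brute_force_oracle():
    """50 random small instances (n=30, 2 covariates): F and p agree with
    the independent computation to 1e-8 relative."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = 30
        Z = rng.normal(size=(n, 2))
        x = rng.binomial(2, 0.3, n).astype(float)
        if np.ptp(x) == 0:
            continue
        y = rng.normal(size=(n, 2))
        fit = fit_bivariate(y, x, Z)
        F0, p0 = brute_force_bivariate(y, x, Z)
        assert fit.F == pytest.approx(F0, rel=1e-8)
        assert fit.p == pytest.approx(p0, rel=1e-8)


def test_bivariate_matches_statsmodels_manova():
    """Independent cross-check against statsmodels' Wilks-lambda test."""
    from statsmodels.multivariate.manova import MANOVA

    rng = np.random.default_rng(8)
    n = 150
    Z = rng.normal(size=(n, 1))
    x = rng.binomial(2, 0.3, n).astype(float)
    y = rng.normal(size=(n, 2)) + 0.2 * x[:, None]
    df = pd.DataFrame({"y1": y[:, 0], "y2": y[:, 1], "z": Z[:, 0], "x": x})
    tbl = MANOVA.from_formula("y1 + y2 ~ z + x", data=df).mv_test().results["x"]["stat"]
    fit = fit_bivariate(y, x, Z)
    assert fit.wilks_lambda == pytest.approx(tbl.loc["Wilks' lambda", "Value"], rel=1e-10)
    assert fit.p == pytest.approx(tbl.loc["Wilks' lambda", "Pr > F"], rel=1e-8)


def test_orthogonal_dosage_gives_null_projection():
    """x exactly orthogonal to both traits and the covariates: Lambda = 1,
    F = 0, p = 1."""
    n = 40
    rng = np.random.default_rng(9)
    y = rng.normal(size=(n, 2))
    x = rng.normal(size=n)
    # project x out of [1, y1, y2]
    M = np.column_stack([np.ones(n), y])
    x = x - M @ np.linalg.lstsq(M, x, rcond=None)[0]
    fit = fit_bivariate(y, x)
    assert fit.wilks_lambda == pytest.approx(1.0, abs=1e-12)
    assert fit.F == pytest.approx(0.0, abs=1e-10)
    assert fit.p == pytest.approx(1.0, abs=1e-10)


def test_constant_dosage_raises_not_p_one():
    y = np.random.default_rng(0).normal(size=(30, 2))
    with pytest.raises(MonomorphicError):
        fit_bivariate(y, np.ones(30))


def test_duplicated_trait_is_degenerate():
    rng = np.random.default_rng(1)
    y1 = rng.normal(size=50)
    x = rng.binomial(2, 0.3, 50).astype(float)
    with pytest.raises(DegenerateResidualError):
        fit_bivariate(np.column_stack([y1, y1]), x)


def test_univariate_degenerate_perfect_fit():
    x = np.random.default_rng(2).binomial(2, 0.4, 40).astype(float)
    with pytest.raises(DegenerateResidualError):
        fit_univariate(x.copy(), x)  # y = x exactly: zero residual variance


def test_univariate_matches_closed_form():
    rng = np.random.default_rng(3)
    n = 80
    x = rng.binomial(2, 0.3, n).astype(float)
    y = 0.3 * x + rng.normal(size=n)
    fit = fit_univariate(y, x)
    X = np.column_stack([np.ones(n), x])
    b = np.linalg.solve(X.T @ X, X.T @ y)
    r = y - X @ b
    s2 = r @ r / (n - 2)
    se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
    t = b[1] / se
    assert fit.beta == pytest.approx(b[1], rel=1e-10)
    assert fit.se == pytest.approx(se, rel=1e-10)
    assert fit.p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-10)


def test_null_univariate_p_is_uniform():
    """Null simulations: per-seed KS statistic against U(0,1) stays below
    the 95% critical value in >=90% of seeds."""
    n, m = 400, 60
    ok = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        x = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        ps = []
        for j in range(m):
            ps.append(fit_univariate(y, x[:, j]).p)
        d = stats.kstest(ps, "uniform").statistic
        ok += d < 1.358 / np.sqrt(m)  # asymptotic 95% critical value
    assert ok >= 0.9 * n_seeds


def test_bivariate_p_invariant_to_affine_recoordinatisation():
    """Wilks lambda depends on the trait pair only through its span: any
    invertible affine map of the two traits leaves F and p unchanged."""
    rng = np.random.default_rng(5)
    n = 120
    x = rng.binomial(2, 0.3, n).astype(float)
    y = rng.normal(size=(n, 2)) + 0.2 * x[:, None]
    A = np.array([[2.0, -0.7], [0.3, 1.1]])  # invertible
    y2 = y @ A.T + np.array([5.0, -3.0])
    f1, f2 = fit_bivariate(y, x), fit_bivariate(y2, x)
    assert f1.F == pytest.approx(f2.F, rel=1e-8)
    assert f1.p == pytest.approx(f2.p, rel=1e-8)


def test_null_f_mean_matches_exact_distribution():
    """Mean of simulated null F within MC error of df2/(df2-2) for
    F(2, nu_e - 1)."""
    rng = np.random.default_rng(6)
    n, reps = 200, 800
    Fs = []
    for _ in range(reps):
        x = rng.binomial(2, 0.3, n).astype(float)
        y = rng.normal(size=(n, 2))
        Fs.append(fit_bivariate(y, x).F)
    Fs = np.array(Fs)
    df2 = n - 2 - 1
    expected = df2 / (df2 - 2)
    assert abs(Fs.mean() - expected) < 3 * Fs.std() / np.sqrt(reps)


def test_listwise_deletion_and_reported_n():
    rng = np.random.default_rng(10)
    n = 100
    x = rng.binomial(2, 0.4, n).astype(float)
    x[:7] = np.nan
    y = rng.normal(size=(n, 2))
    fit = fit_bivariate(y, x)
    assert fit.n == 93


def test_scan_planted_pleiotropic_snp_ranks_first():
    """A SNP with a shared effect on both traits attains the scan-wide
    minimum bivariate p in >=95% of replicates (beta=0.3 SD, MAF 0.3)."""
    reps, hits = 30, 0
    for seed in range(reps):
        specs = uniform_snp_panel(400, maf_range=(0.1, 0.5), seed=seed)
        G = simulate_genotypes(1000, specs, seed=1000 + seed)
        traits = simulate_traits(
            G,
            [EffectSpec("snp123", 0.3, 0.3)],
            PhenoModelSpec(residual_corr=0.5, seed=2000 + seed),
        )
        res = scan(G, traits, [("trait1", "trait2")])
        best = res.loc[res["p_biv_trait1_trait2"].idxmin(), "snp_id"]
        hits += best == "snp123"
    assert hits >= 0.95 * reps


def test_scan_row_retained_with_reason_on_failure(small_cohort):
    G, traits = small_cohort
    G2 = G.subset_snps(np.arange(G.n_snps) < 5)
    G2.dosages[:, 3] = 0.0  # monomorphic column
    res = scan(G2, traits, [("trait1", "trait2")])
    assert len(res) == 5
    row = res[res["snp_id"] == G2.snps["snp_id"].iloc[3]].iloc[0]
    assert np.isnan(row["p_biv_trait1_trait2"])
    assert "monomorphic" in row["reason"]


def test_scan_null_hit_count_binomial(small_cohort):
    """All-null scan: the number of bivariate p < 1e-3 should be within
    3 SDs of m * 1e-3 (here: effectively zero expected)."""
    specs = uniform_snp_panel(2000, maf_range=(0.1, 0.5), seed=77)
    G = simulate_genotypes(500, specs, seed=78)
    traits = simulate_traits(G, [], PhenoModelSpec(residual_corr=0.5, seed=79))
    res = scan(G, traits, [("trait1", "trait2")])
    k = int((res["p_biv_trait1_trait2"] < 1e-3).sum())
    expect = 2000 * 1e-3
    assert abs(k - expect) <= 3 * np.sqrt(expect * (1 - 1e-3)) + 1


def test_threshold_view_convention(small_cohort):
    G, traits = small_cohort
    res = scan(G, traits, [("trait1", "trait2")])
    view = threshold_view(res, "p_biv_trait1_trait2", 1e-5)
    assert (view["p_biv_trait1_trait2"] < 1e-5).all()
    assert "snp7" in set(view["snp_id"])  # the planted effect is strong
    assert view["p_biv_trait1_trait2"].is_monotonic_increasing
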