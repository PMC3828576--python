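"""Correlation, dispersion, regression and enrichment against independent
oracles (scipy / permutation / closed forms / Fisher)."""

import numpy as np
import pytest
from scipy import stats as sps

from idrmap import (index_of_dispersion, multiple_regression, pearson,
                    star_band, term_enrichment)


def test_pearson_perfect_correlation():
    x = np.array([1.0, 2.0, 5.0, 7.0])
    res = pearson(x, x)
    assert res.r == pytest.approx(1.0) and res.p == 0.0


def test_pearson_matches_scipy(rng):
    for _ in range(50):
        n = int(rng.integers(5, 100))
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = pearson(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref)
        assert res.p == pytest.approx(p_ref, rel=1e-6)


def test_pearson_affine_invariance_and_sign_flip(rng):
    x, y = rng.normal(size=30), rng.normal(size=30)
    base = pearson(x, y).r
    assert pearson(2.5 * x + 1, y).r == pytest.approx(base)
    assert pearson(-2.5 * x + 1, y).r == pytest.approx(-base)
    assert pearson(y, x).r == pytest.approx(base)


def test_pearson_degenerate_input_errors():
    with pytest.raises(ValueError, match="x"):
        pearson([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="y"):
        pearson([1, 2, 3, 4], [2, 2, 2, 2])
    with pytest.raises(ValueError):
        pearson([1, 2], [3, 4])


def test_pearson_p_close_to_permutation_null(rng):
    # moderate-size check; the full 1e5-replicate version runs in acceptance
    n, reps = 10, 20_000
    x, y = rng.normal(size=n), rng.normal(size=n)
    res = pearson(x, y)
    perm_r = np.empty(reps)
    for i in range(reps):
        perm_r[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
    p_perm = np.mean(np.abs(perm_r) >= abs(res.r))
    assert res.p == pytest.approx(p_perm, abs=0.03)


@pytest.mark.parametrize("p,stars", [
    (0.0049, "***"),
    (0.005, "**"),   # strict inequality for ***
    (0.0099, "**"),
    (0.01, "*"),
    (0.049, "*"),
    (0.05, "ns"),
    (0.5, "ns"),
])
def test_star_banding_boundaries(p, stars):
    assert star_band(p) == stars


# ---------------------------------------------------------------------------
# dispersion

def test_dispersion_constant_counts():
    assert index_of_dispersion([5, 5, 5, 5]) == 0.0


def test_dispersion_poisson_near_one(rng):
    counts = rng.poisson(4.0, size=10_000)
    assert 0.95 <= index_of_dispersion(counts) <= 1.05


def test_dispersion_negative_binomial_overdispersed(rng):
    # NB with dispersion k=0.5, mean mu=4: VMR = 1 + mu/k = 9
    k, mu = 0.5, 4.0
    counts = rng.negative_binomial(k, k / (k + mu), size=10_000)
    vmr = index_of_dispersion(counts)
    assert vmr > 1.0
    assert vmr == pytest.approx(1 + mu / k, rel=0.15)


def test_dispersion_invalid_inputs():
    with pytest.raises(ValueError):
        index_of_dispersion([0, 0, 0])
    with pytest.raises(ValueError):
        index_of_dispersion([1.5, 2.0])
    with pytest.raises(ValueError):
        index_of_dispersion([-1, 2])


# ---------------------------------------------------------------------------
# regression

def test_regression_exact_fit_in_gc():
    gc = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
    rec = np.array([1.0, 5.0, 2.0, 8.0, 3.0, 9.0])
    y = 0.5 + 2.0 * gc
    res = multiple_regression(y, gc, rec)
    assert res.multiple_r2 == pytest.approx(1.0)
    assert res.params["gc"] == pytest.approx(2.0)
    assert res.params["rec"] == pytest.approx(0.0, abs=1e-12)


def test_regression_matches_normal_equations_closed_form():
    y = np.array([1.0, 2.0, 2.5, 4.0, 5.5])
    gc = np.array([0.2, 0.4, 0.5, 0.7, 0.9])
    rec = np.array([1.0, 0.5, 2.0, 1.5, 3.0])
    res = multiple_regression(y, gc, rec)
    X = np.column_stack([np.ones(5), gc, rec])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert res.params["intercept"] == pytest.approx(beta[0])
    assert res.params["gc"] == pytest.approx(beta[1])
    assert res.params["rec"] == pytest.approx(beta[2])
    resid = y - X @ beta
    r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    assert res.multiple_r2 == pytest.approx(r2)


def test_regression_recovers_simulated_coefficients(rng):
    # beta_gc=2.0, beta_rec=0.01, noise sd 0.02: within 2 SE in >=95% of runs
    hits = 0
    runs = 200
    for _ in range(runs):
        n = 500
        gc = rng.uniform(0.3, 0.7, size=n)
        rec = rng.gamma(2.0, 2.0, size=n)
        y = 0.1 + 2.0 * gc + 0.01 * rec + rng.normal(0, 0.02, size=n)
        res = multiple_regression(y, gc, rec)
        ok = (abs(res.params["gc"] - 2.0) <= 2 * res.bse["gc"]
              and abs(res.params["rec"] - 0.01) <= 2 * res.bse["rec"])
        hits += ok
    assert hits / runs >= 0.90  # each condition alone holds ~95%


def test_regression_anova_invariant_to_predictor_scaling(rng):
    n = 80
    gc = rng.uniform(0, 1, size=n)
    rec = rng.gamma(2, 2, size=n)
    y = 1 + gc + 0.05 * rec + rng.normal(0, 0.3, size=n)
    a = multiple_regression(y, gc, rec)
    b = multiple_regression(y, 1000 * gc, 0.001 * rec)
    assert a.anova_p["gc"] == pytest.approx(b.anova_p["gc"])
    assert a.anova_p["rec"] == pytest.approx(b.anova_p["rec"])


def test_regression_rank_deficiency_error():
    gc = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    with pytest.raises(ValueError, match="rank"):
        multiple_regression([1, 2, 3, 4, 5], gc, 2 * gc)


# ---------------------------------------------------------------------------
# enrichment

def test_enrichment_study_equals_population():
    pop = {f"g{i}" for i in range(10)}
    ann = {g: {"T1"} if i < 4 else {"T2"} for i, g in enumerate(sorted(pop))}
    results = term_enrichment(pop, pop, ann)
    assert all(r.p_raw == pytest.approx(1.0) for r in results)


def test_enrichment_full_study_term_closed_form():
    # term annotates all n=5 study genes and 10 of 100 population genes
    pop = {f"g{i}" for i in range(100)}
    study = {f"g{i}" for i in range(5)}
    ann = {f"g{i}": {"T"} for i in range(10)}
    (res,) = term_enrichment(study, pop, ann)
    expected = sps.hypergeom.sf(4, 100, 10, 5)
    assert res.p_raw == pytest.approx(expected)
    # closed form: all 5 draws inside the 10 annotated genes
    from math import comb
    assert expected == pytest.approx(comb(10, 5) / comb(100, 5))


def test_enrichment_matches_fisher_one_tail():
    # population 20, term annotates 5, study of 5 overlaps 4
    pop = {f"g{i}" for i in range(20)}
    ann = {f"g{i}": {"T"} for i in range(5)}
    study = {"g0", "g1", "g2", "g3", "g10"}
    (res,) = term_enrichment(study, pop, ann)
    _odds, p_fisher = sps.fisher_exact([[4, 1], [1, 14]], alternative="greater")
    assert res.p_raw == pytest.approx(p_fisher)


def test_enrichment_correction_monotone_and_capped(rng):
    pop = {f"g{i}" for i in range(50)}
    ann = {}
    for i in range(50):
        terms = {f"T{rng.integers(0, 8)}" for _ in range(rng.integers(1, 4))}
        ann[f"g{i}"] = terms
    study = {f"g{i}" for i in range(12)}
    for method in ("bonferroni", "bh"):
        for r in term_enrichment(study, pop, ann, correction=method):
            assert 0 < r.p_raw <= 1
            assert r.p_raw <= r.p_corrected <= 1.0


def test_enrichment_empty_study_error():
    with pytest.raises(ValueError):
        term_enrichment(set(), {"g1"}, {"g1": {"T"}})
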