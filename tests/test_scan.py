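"""Whitening algebra, LOD computation, covariate selection and the scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cimld.imputation import impute_draws
from cimld.lattice import (
    LineMeans,
    arithmetic_means,
    lattice_anova,
    make_simple_lattice,
    simulate_phenotypes,
)
from cimld.ril_sim import build_grid, simulate_ril_genotypes, uniform_map
from cimld.scan import (
    CovariateSet,
    covariates_at,
    lod,
    multi_env_scan,
    run_method_scan,
    select_covariates,
    sigma_inv_sqrt_block,
    whiten,
    whiten_multi,
)


# ---------------------------------------------------------------- whitening

def test_sigma_inv_sqrt_identity_at_zero_delta():
    assert np.allclose(sigma_inv_sqrt_block(5, 0.0), np.eye(5))


@pytest.mark.parametrize("k, delta", [(2, 1.0), (4, 0.5), (14, 10.0)])
def test_sigma_inv_sqrt_squares_to_inverse(k, delta):
    M = sigma_inv_sqrt_block(k, delta)
    Sigma = np.eye(k) + delta * np.ones((k, k))
    assert np.allclose(M @ M @ Sigma, np.eye(k), atol=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(min_value=1, max_value=20), st.floats(min_value=0.0, max_value=50.0))
def test_sigma_inv_sqrt_eigenvalues(k, delta):
    """Closed form agrees with the eigendecomposition oracle."""
    M = sigma_inv_sqrt_block(k, delta)
    eig = np.sort(np.linalg.eigvalsh(M))
    expected = np.sort(np.concatenate([[(1 + k * delta) ** -0.5], np.ones(k - 1)]))
    assert np.allclose(eig, expected, atol=1e-10)
    Sigma = np.eye(k) + delta * np.ones((k, k))
    w, V = np.linalg.eigh(Sigma)
    oracle = (V * w**-0.5) @ V.T
    assert np.allclose(M, oracle, atol=1e-9)


def test_whiten_identity_at_zero_delta(small_trial):
    layout, g, records = small_trial
    wh = whiten(records, layout, 0.0)
    assert np.allclose(wh.y, records.value)
    assert np.allclose(wh.X_base[:, 0], 1.0)


def test_whitened_ols_equals_dense_gls(small_trial):
    """Position test via whitened OLS == explicit GLS (k=3 instance)."""
    layout, g, records = small_trial
    delta = 1.7
    wh = whiten(records, layout, delta)
    rng = np.random.default_rng(0)
    x_line = (rng.random(9) < 0.5).astype(float)
    X0 = wh.X_base
    X1 = np.concatenate([X0, wh.expand_whiten(x_line[:, None])], axis=1)
    rss = []
    for X in (X0, X1):
        beta, *_ = np.linalg.lstsq(X, wh.y, rcond=None)
        r = wh.y - X @ beta
        rss.append(r @ r)
    # dense GLS oracle
    n = records.n
    Z = np.zeros((n, layout.n_blocks))
    Z[np.arange(n), records.rep * 3 + records.block] = 1.0
    Si = np.linalg.inv(np.eye(n) + delta * Z @ Z.T)
    Xr = np.ones((n, 2))
    Xr[:, 1] = records.rep
    X1r = np.concatenate([Xr, x_line[records.line][:, None]], axis=1)
    rss_gls = []
    for X in (Xr, X1r):
        beta = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ records.value)
        r = records.value - X @ beta
        rss_gls.append(r @ Si @ r)
    assert lod(rss[0], rss[1], n) == pytest.approx(
        lod(rss_gls[0], rss_gls[1], n), abs=1e-9
    )


def test_whitened_residuals_are_spherical():
    """Empirical covariance of whitened residuals approximates sigma^2 I."""
    rng = np.random.default_rng(12)
    k, delta, sigma = 4, 3.0, 1.0
    layout = make_simple_lattice(k, rng, randomize=False)
    resids = []
    for _ in range(1000):
        gamma = rng.normal(0, sigma * np.sqrt(delta), layout.n_blocks)
        eps = rng.normal(0, sigma, layout.n_plots)
        rep, block, line = layout.plots.T
        noise = gamma[rep * k + block] + eps
        from cimld._whiten import block_whiten

        resids.append(block_whiten(noise, layout.n_blocks, k, delta))
    cov = np.cov(np.array(resids).T)
    off = cov[~np.eye(cov.shape[0], dtype=bool)]
    assert np.mean(np.abs(off)) < 0.05 * sigma**2
    assert np.allclose(np.diag(cov), sigma**2, atol=0.2)


# ---------------------------------------------------------------------- LOD

def test_lod_values():
    assert lod(3.0, 3.0, 50) == 0.0
    assert lod(10.0, 1.0, 100) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        lod(0.0, 1.0, 10)


def test_lod_equals_gaussian_likelihood_ratio():
    rng = np.random.default_rng(3)
    n = 40
    x = rng.normal(size=n)
    y = 0.4 * x + rng.normal(size=n)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), x])
    rss = []
    ll = []
    for X in (X0, X1):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(r @ r)
        s2 = (r @ r) / n
        ll.append(-n / 2 * (np.log(2 * np.pi * s2) + 1))
    assert lod(rss[0], rss[1], n) == pytest.approx((ll[1] - ll[0]) / np.log(10), abs=1e-9)


# ------------------------------------------------------- covariate selection

def test_select_zero_covariates():
    y = np.arange(6.0)
    C = np.eye(6)
    assert len(select_covariates(y, C, 0)) == 0
    with pytest.raises(ValueError):
        select_covariates(y, C, 7)


def test_select_one_equals_exhaustive_best():
    rng = np.random.default_rng(8)
    y = rng.normal(size=60)
    C = rng.normal(size=(60, 15))
    chosen = select_covariates(y, C, 1).grid_columns[0]
    # brute force best single-column RSS
    best, best_rss = None, np.inf
    for j in range(15):
        X = np.column_stack([np.ones(60), C[:, j]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        if r @ r < best_rss:
            best, best_rss = j, r @ r
    assert chosen == best


def test_first_selected_marker_near_single_qtl(small_map):
    hits = 0
    n_sims = 200
    for s in range(n_sims):
        rng = np.random.default_rng(3000 + s)
        grid = build_grid(small_map)
        geno = simulate_ril_genotypes(grid, 150, rng)
        qtl_col = grid.column_of("C1", 30.0)
        y = 1.0 * geno.matrix[:, qtl_col] + rng.normal(0, 0.8, 150)
        cset = select_covariates(
            y, geno.matrix.astype(float), 1,
            chrom=grid.flat_chrom(), pos=grid.flat_pos(),
        )
        if abs(cset.pos[0] - 30.0) <= 10.0:
            hits += 1
    assert hits / n_sims >= 0.95


# ------------------------------------------------------------------ the scan

@pytest.fixture(scope="module")
def single_qtl_setup():
    gmap = uniform_map(n_chromosomes=1, length=60.0, markers_per_chromosome=7)
    rng = np.random.default_rng(17)
    grid = build_grid(gmap)
    geno = simulate_ril_genotypes(grid, 120, rng)
    qtl_col = grid.column_of("C1", 30.0)
    y = 0.9 * geno.matrix[:, qtl_col] + rng.normal(0, 1.0, 120)
    draws = impute_draws(geno.matrix, gmap, step=2.0, n_draws=5, rng=rng)
    return gmap, geno, y, draws


def test_scan_at_marker_equals_direct_regression(single_qtl_setup):
    """At an observed marker all draws coincide; averaged LOD = single fit."""
    gmap, geno, y, draws = single_qtl_setup
    prof = run_method_scan("rcbd", draws=draws, p=0, means=LineMeans(y, "arithmetic"))
    col = draws.grid.column_of("C1", 30.0)
    x = geno.matrix[:, geno.grid.column_of("C1", 30.0)].astype(float)
    n = len(y)
    X0 = np.ones((n, 1))
    X1 = np.column_stack([np.ones(n), x])
    rss = []
    for X in (X0, X1):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(r @ r)
    assert prof.lod[col] == pytest.approx(lod(rss[0], rss[1], n), abs=1e-9)
    # effect estimate has the simulated sign and scale
    assert prof.effect[col] == pytest.approx(0.9, abs=0.4)


def test_null_scan_rarely_exceeds_fixed_threshold(paper_map):
    """Pure-noise phenotypes: genome-wide max averaged LOD < 2.5 in >=90%."""
    exceed = 0
    n_sims = 100
    grid = build_grid(paper_map)
    for s in range(n_sims):
        rng = np.random.default_rng(5000 + s)
        geno = simulate_ril_genotypes(grid, 196, rng)
        y = rng.normal(0, 1.0, 196)
        draws = impute_draws(geno.matrix, paper_map, step=2.0, n_draws=8, rng=rng)
        prof = run_method_scan("rcbd", draws=draws, p=0,
                               means=LineMeans(y, "arithmetic"))
        if prof.max_lod() >= 2.5:
            exceed += 1
    assert exceed <= 10


def test_cimld_profile_positive_and_window_exclusion(small_trial):
    layout, g, records = small_trial
    vc = lattice_anova(records, layout)
    wh = whiten(records, layout, vc.delta)
    gmap = uniform_map(n_chromosomes=1, length=20.0, markers_per_chromosome=3)
    rng = np.random.default_rng(2)
    geno = simulate_ril_genotypes(build_grid(gmap), 9, rng)
    draws = impute_draws(geno.matrix, gmap, step=5.0, n_draws=4, rng=rng)
    prof = run_method_scan("cimld", draws=draws, p=1, whitened=wh)
    assert np.all(prof.lod >= -1e-9)
    assert prof.covariates is not None and len(prof.covariates) == 1


def test_covariates_at_maps_to_nearest_marker(single_qtl_setup):
    gmap, geno, y, draws = single_qtl_setup
    cset = covariates_at(draws, [("C1", 28.7), ("C1", 29.0)])
    assert cset.pos == (30.0,)  # deduplicated nearest marker


def test_effect_sign_recovery(single_qtl_setup):
    """Sign of the estimated effect matches the simulated sign."""
    gmap, _, _, _ = single_qtl_setup
    grid = build_grid(gmap)
    agree = 0
    n_sims = 60
    for s in range(n_sims):
        rng = np.random.default_rng(7000 + s)
        geno = simulate_ril_genotypes(grid, 120, rng)
        sign = 1.0 if s % 2 == 0 else -1.0
        y = sign * 1.2 * geno.matrix[:, grid.column_of("C1", 30.0)] + rng.normal(0, 1, 120)
        draws = impute_draws(geno.matrix, gmap, step=5.0, n_draws=4, rng=rng)
        prof = run_method_scan("rcbd", draws=draws, p=0, means=LineMeans(y, "x"))
        j = int(np.argmax(prof.lod))
        if np.sign(prof.effect[j]) == sign:
            agree += 1
    assert agree / n_sims >= 0.95


# --------------------------------------------------------------- multi-env

def _two_env_setup(qtl_effects=(1.0, 1.0), seed=0, k=6):
    gmap = uniform_map(n_chromosomes=1, length=60.0, markers_per_chromosome=7)
    rng = np.random.default_rng(seed)
    grid = build_grid(gmap)
    t = k * k
    geno = simulate_ril_genotypes(grid, t, rng)
    x = geno.matrix[:, grid.column_of("C1", 30.0)].astype(float)
    records, layouts, deltas = {}, {}, {}
    for e, eff in enumerate(qtl_effects):
        layout = make_simple_lattice(k, rng)
        g = eff * x
        rec = simulate_phenotypes(g + rng.normal(0, 0.0, t), layout, 0.6, 1.0, 2.0, rng)
        records[f"E{e}"] = rec
        layouts[f"E{e}"] = layout
        deltas[f"E{e}"] = 1.0
    draws = impute_draws(geno.matrix, gmap, step=5.0, n_draws=4, rng=rng)
    return records, layouts, deltas, draws


def test_multi_env_identical_phenotypes_no_interaction():
    records, layouts, deltas, draws = _two_env_setup(seed=5)
    # force identical phenotypes in both environments
    records["E1"] = records["E0"]
    layouts["E1"] = layouts["E0"]
    me = whiten_multi(records, layouts, deltas)
    prof = multi_env_scan(me, draws=draws, p=2)
    assert np.all(prof.lod_ge < 0.1)


def test_multi_env_nested_lod_inequality():
    records, layouts, deltas, draws = _two_env_setup(qtl_effects=(1.0, -0.5), seed=9)
    me = whiten_multi(records, layouts, deltas)
    prof = multi_env_scan(me, draws=draws, p=2)
    assert np.all(prof.lod_join >= prof.lod_g - 1e-6)
    assert np.all(prof.lod_join >= prof.lod_ge - 1e-6)


def test_multi_env_interaction_recovery():
    """Opposite-sign effects by environment put the GxE peak near the locus."""
    hits = 0
    n_sims = 60
    for s in range(n_sims):
        records, layouts, deltas, draws = _two_env_setup(
            qtl_effects=(1.4, -1.4), seed=100 + s, k=8
        )
        me = whiten_multi(records, layouts, deltas)
        prof = multi_env_scan(me, draws=draws, p=2)
        peak = prof.pos[int(np.argmax(prof.lod_ge))]
        if abs(peak - 30.0) <= 10.0:
            hits += 1
    assert hits / n_sims >= 0.8


def test_multi_env_requires_two_envs(small_trial):
    layout, g, records = small_trial
    with pytest.raises(ValueError):
        whiten_multi({"E0": records}, {"E0": layout}, {"E0": 1.0})
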