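"""MLPE pairwise mixed models, model selection, and the highland models."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from landgen import ibr


def _pair_adjacency(pair_index):
    ii, jj = pair_index[:, 0], pair_index[:, 1]
    share = (
        (ii[:, None] == ii[None, :]) | (ii[:, None] == jj[None, :])
        | (jj[:, None] == ii[None, :]) | (jj[:, None] == jj[None, :])
    ).astype(float)
    np.fill_diagonal(share, 0.0)
    return share


def test_rho_zero_profile_equals_ols():
    rng = np.random.default_rng(0)
    pair_index = ibr.full_pair_index(8)
    m = len(pair_index)
    x = rng.standard_normal(m)
    y = 0.3 - 1.2 * x + rng.standard_normal(m)
    ps = ibr._PairStructure(pair_index, 8)
    Xd = np.column_stack([np.ones(m), x])
    _, beta, _, _, _ = ibr.mlpe_loglik(ps, 0.0, y, Xd)
    ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
    np.testing.assert_allclose(beta, ols, atol=1e-8)


def test_loglik_matches_dense_multivariate_normal_oracle():
    rng = np.random.default_rng(1)
    pair_index = ibr.full_pair_index(5)   # 10 pairs
    m = len(pair_index)
    x = rng.standard_normal(m)
    y = 1 + 2 * x + rng.standard_normal(m)
    fit = ibr.mlpe_fit(y, x, pair_index)
    C = np.eye(m) + 2 * fit.rho * _pair_adjacency(pair_index)
    Xd = np.column_stack([np.ones(m), x])
    oracle = multivariate_normal.logpdf(y, Xd @ fit.beta, fit.sigma2 * C)
    assert fit.loglik == pytest.approx(oracle, abs=1e-8)
    # and at a handful of non-optimal rho values
    ps = ibr._PairStructure(pair_index, 5)
    for rho in (0.05, 0.15, 0.2):
        ll, beta, s2, _, _ = ibr.mlpe_loglik(ps, rho, y, Xd)
        Crho = np.eye(m) + 2 * rho * _pair_adjacency(pair_index)
        oracle = multivariate_normal.logpdf(y, Xd @ beta, s2 * Crho)
        assert ll == pytest.approx(oracle, abs=1e-8)


def test_fitted_rho_recovers_simulated_correlation():
    rng = np.random.default_rng(2)
    pair_index = ibr.full_pair_index(40)
    m = len(pair_index)
    chol = np.linalg.cholesky(np.eye(m) + 2 * 0.2 * _pair_adjacency(pair_index))
    rhos = []
    for _ in range(10):
        x = rng.standard_normal(m)
        y = 1 + 2 * x + 0.5 * (chol @ rng.standard_normal(m))
        rhos.append(ibr.mlpe_fit(y, x, pair_index).rho)
    assert 0.15 < np.mean(rhos) < 0.25


def test_loglik_at_fitted_rho_at_least_rho_zero(small_dataset):
    from landgen import landscape, popgen

    geno, _ = small_dataset
    rel = popgen.yang_relatedness(geno)
    geo = landscape.geographic_distance(geno.samples)
    pair_index = ibr.full_pair_index(geno.n_samples)
    fit = ibr.mlpe_fit(rel.condensed(), geo.values, pair_index)
    ps = ibr._PairStructure(pair_index, geno.n_samples)
    Xd = np.column_stack([np.ones(len(geo.values)), geo.values])
    ll0, *_ = ibr.mlpe_loglik(ps, 0.0, rel.condensed(), Xd)
    assert fit.loglik >= ll0 - 1e-9


def test_incomplete_pair_set_is_rejected():
    pair_index = ibr.full_pair_index(6)[:-1]
    with pytest.raises(ValueError, match="complete"):
        ibr.mlpe_fit(np.zeros(len(pair_index)), None, pair_index)


# ---------------------------------------------------------------------------
# AICc arithmetic and model tables


def test_aicc_convention_reproduces_published_value():
    # 3 slopes + intercept + rho + sigma^2 = 6 parameters over 7381 pairs
    assert ibr.aicc_of(14847.40, 6, 7381) == pytest.approx(-29682.79, abs=0.005)
    assert abs(ibr.aicc_of(14847.40, 6, 7381) - (-29682.80)) < 0.02


def test_akaike_weights_from_delta_pair():
    delta = np.array([0.0, 0.28])
    w = np.exp(-delta / 2)
    w = w / w.sum()
    assert w[0] == pytest.approx(0.53, abs=0.005)


def test_dredge_excludes_collinear_pairs_and_ranks():
    rng = np.random.default_rng(3)
    pair_index = ibr.full_pair_index(12)
    m = len(pair_index)
    a = rng.standard_normal(m)
    b = a + 0.1 * rng.standard_normal(m)     # r > 0.9
    y = 1 + a + rng.standard_normal(m)
    mt = ibr.dredge_mlpe(y, {"a": a, "b": b}, pair_index)
    assert len(mt.table) == 3                # null, a, b
    assert not any("a + b" in mdl for mdl in mt.table["model"])
    assert mt.table["delta_aicc"].iloc[0] == 0.0
    assert mt.table["aicc"].is_monotonic_increasing
    assert mt.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)


def test_duplicated_hypothesis_ties_break_lexicographically():
    rng = np.random.default_rng(4)
    pair_index = ibr.full_pair_index(10)
    m = len(pair_index)
    x = rng.standard_normal(m)
    y = x + rng.standard_normal(m)
    mt, winners = ibr.rank_candidate_surfaces(y, {"bb": x, "aa": x}, pair_index)
    assert mt.table["aicc"].iloc[0] == pytest.approx(mt.table["aicc"].iloc[1], abs=1e-9)
    assert mt.table["model"].iloc[0] == "aa"


def test_rank_candidate_surfaces_reports_polarity_winners():
    rng = np.random.default_rng(5)
    pair_index = ibr.full_pair_index(15)
    m = len(pair_index)
    x = rng.standard_normal(m)
    y = 2 * x + 0.3 * rng.standard_normal(m)
    dists = {"elev_raw": x, "elev_inv": -x + 0.5 * rng.standard_normal(m),
             "landcover1994_s_low": 0.9 * x + 0.4 * rng.standard_normal(m),
             "landcover2004_s_low": rng.standard_normal(m)}
    mt, winners = ibr.rank_candidate_surfaces(y, dists, pair_index)
    assert winners["elev"] in {"elev_raw", "elev_inv"}
    assert winners["landcover"] == "landcover1994_s_low"
    assert len(mt.table) == 4


# ---------------------------------------------------------------------------
# LRT and model averaging


def test_lrt_identity_and_bookkeeping():
    rng = np.random.default_rng(6)
    pair_index = ibr.full_pair_index(10)
    m = len(pair_index)
    x = rng.standard_normal((m, 2))
    y = 1 + x[:, 0] + rng.standard_normal(m)
    full = ibr.mlpe_fit(y, x, pair_index, predictor_names=["a", "b"])
    stat, df, p = ibr.lrt(full, full)
    assert stat == 0.0 and p == 1.0
    reduced = ibr.mlpe_fit(y, x[:, :1], pair_index, predictor_names=["a"])
    stat, df, p = ibr.lrt(full, reduced)
    assert df == 1 and stat >= 0.0
    other = ibr.mlpe_fit(y, x[:, 1:], pair_index, predictor_names=["c"])
    with pytest.raises(ValueError, match="nested"):
        ibr.lrt(full, other)


def test_model_average_identity_hand_case_and_convexity():
    rng = np.random.default_rng(7)
    pair_index = ibr.full_pair_index(10)
    m = len(pair_index)
    x = rng.standard_normal(m)
    y = 1 + 2 * x + 0.2 * rng.standard_normal(m)
    fit1 = ibr.mlpe_fit(y, x, pair_index, predictor_names=["a"])
    single = ibr.model_average([fit1])
    row = single[single.predictor == "a"].iloc[0]
    assert row["estimate"] == pytest.approx(fit1.beta[1])

    fit0 = ibr.mlpe_fit(y, None, pair_index)
    avg = ibr.model_average([fit1, fit0], weights=np.array([0.5, 0.5]))
    row = avg[avg.predictor == "a"].iloc[0]
    assert row["estimate"] == pytest.approx(0.5 * fit1.beta[1])

    fit2 = ibr.mlpe_fit(y, np.column_stack([x, rng.standard_normal(m)]),
                        pair_index, predictor_names=["a", "junk"])
    both = ibr.model_average([fit1, fit2])
    est = both[both.predictor == "a"]["estimate"].iloc[0]
    lo = min(fit1.beta[1], fit2.beta[1])
    hi = max(fit1.beta[1], fit2.beta[1])
    assert lo - 1e-12 <= est <= hi + 1e-12


# ---------------------------------------------------------------------------
# highland mixed models


def test_zero_variance_response_gives_null_result():
    df = pd.DataFrame({
        "He_ind": 0.25, "F": np.random.default_rng(8).normal(size=40),
        "area": np.repeat(np.arange(8), 5), "isolation": 1.0,
        "highland_id": np.repeat(np.arange(8), 5),
    })
    res = ibr.lmm_highland(df, responses=("He_ind",))
    assert res["He_ind"]["slopes"] == {"area": 0.0, "isolation": 0.0}
    assert res["He_ind"]["lrt_p"] == {"area": 1.0, "isolation": 1.0}


def test_single_highland_falls_back_to_fixed_intercept():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({
        "He_ind": rng.normal(0.2, 0.05, 30), "F": rng.normal(0, 0.1, 30),
        "area": rng.uniform(0, 1, 30), "isolation": rng.uniform(0, 1, 30),
        "highland_id": 1,
    })
    with pytest.warns(UserWarning, match="single highland"):
        res = ibr.lmm_highland(df, responses=("He_ind",))
    assert np.isfinite(res["He_ind"]["loglik"])


def test_known_area_effect_recovered_on_average():
    rng = np.random.default_rng(10)
    slopes = []
    for rep in range(25):
        rows = []
        for h in range(30):
            area = rng.uniform(0, 2)
            u = rng.normal(0, 0.2)
            for _ in range(6):
                rows.append({"He_ind": 0.2 + 0.5 * area + u + rng.normal(0, 0.3),
                             "area": area, "isolation": rng.uniform(0, 2), "highland_id": h})
        res = ibr.lmm_highland(pd.DataFrame(rows), responses=("He_ind",))
        slopes.append(res["He_ind"]["slopes"]["area"])
    assert 0.4 < np.mean(slopes) < 0.6
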