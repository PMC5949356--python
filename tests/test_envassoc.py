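"""Environmental-variable selection, latent-factor scans, and candidates."""

import numpy as np
import pandas as pd
import pytest

from landgen import envassoc
from landgen.envassoc import AssociationScan

from conftest import make_geno


# ---------------------------------------------------------------------------
# variable selection


def test_constructed_gradients_are_selected_over_noise():
    # like real bioclim tables, each underlying gradient drives a correlated
    # group of variables; the leading axes align with the groups, never with
    # the independent noise columns
    rng = np.random.default_rng(0)
    n = 120
    g1, g2, g3 = rng.standard_normal((3, n))
    cols = {}
    for gname, g, size in [("grad_a", g1, 4), ("grad_b", g2, 3), ("grad_c", g3, 2)]:
        for i in range(size):
            cols[f"{gname}{i + 1}"] = g + 0.2 * rng.standard_normal(n)
    cols["noise1"] = rng.standard_normal(n)
    cols["noise2"] = rng.standard_normal(n)
    table = pd.DataFrame(cols)
    chosen, corr = envassoc.select_env_variables(table, n_axes=3)
    assert all(name.startswith("grad") for name in chosen)
    assert {name[:6] for name in chosen} == {"grad_a", "grad_b", "grad_c"}
    assert len(chosen) == len(set(chosen))


def test_selection_is_without_replacement_and_drops_constant_columns():
    rng = np.random.default_rng(1)
    n = 60
    x = rng.standard_normal(n)
    table = pd.DataFrame({
        "v1": x, "v2": x + 0.01 * rng.standard_normal(n),
        "v3": rng.standard_normal(n), "flat": np.ones(n),
    })
    with pytest.warns(UserWarning, match="constant"):
        chosen, _ = envassoc.select_env_variables(table, n_axes=3)
    assert len(set(chosen)) == 3
    assert "flat" not in chosen


# ---------------------------------------------------------------------------
# latent factor scan


def test_lfmm_same_seed_identical_scan():
    rng = np.random.default_rng(2)
    g = make_geno(rng.binomial(2, 0.4, (50, 80)).astype(np.int8))
    env = rng.standard_normal(50)
    a = envassoc.lfmm_scan(g, env, k=2, seed=9)
    b = envassoc.lfmm_scan(g, env, k=2, seed=9)
    np.testing.assert_array_equal(a.z, b.z)
    np.testing.assert_array_equal(a.z_runs, b.z_runs)


def test_lfmm_null_z_scores_are_standard_normal():
    rng = np.random.default_rng(3)
    L = 800
    g = make_geno(rng.binomial(2, np.tile(rng.uniform(0.2, 0.8, L), (100, 1))).astype(np.int8))
    env = rng.standard_normal(100)
    scan = envassoc.lfmm_scan(g, env, k=2, n_runs=3, seed=0)
    assert abs(np.abs(scan.z).mean() - np.sqrt(2 / np.pi)) < 3 / np.sqrt(L)


def test_lfmm_planted_loci_rank_top():
    from scipy.special import expit, logit

    rng = np.random.default_rng(4)
    n, L = 120, 300
    p_anc = rng.uniform(0.3, 0.7, L)
    p = np.tile(p_anc, (n, 1))
    env = rng.standard_normal(n)
    z_env = (env - env.mean()) / env.std()
    for l in range(8):
        p[:, l] = expit(logit(p_anc[l]) + 1.5 * z_env)
    g = make_geno(rng.binomial(2, p).astype(np.int8))
    scan = envassoc.lfmm_scan(g, env, k=1, n_runs=3, seed=5)
    top = set(np.argsort(-np.abs(scan.z))[:8].tolist())
    assert len(top & set(range(8))) >= 7


def test_lfmm_k_must_be_below_n():
    g = make_geno(np.zeros((5, 10), dtype=np.int8))
    with pytest.raises(ValueError):
        envassoc.lfmm_scan(g, np.arange(5.0), k=5)


# ---------------------------------------------------------------------------
# calibration


def test_lambda_near_one_for_standard_normal_z():
    rng = np.random.default_rng(6)
    z = rng.standard_normal(10_000)
    scan = AssociationScan("x", 1, z[None, :], z, [0])
    envassoc.calibrate_adjust(scan)
    assert 0.95 < scan.lam < 1.05


def test_calibration_is_scale_invariant():
    rng = np.random.default_rng(7)
    z = rng.standard_normal(500)
    a = envassoc.calibrate_adjust(AssociationScan("x", 1, z[None, :], z, [0]))
    b = envassoc.calibrate_adjust(AssociationScan("x", 1, 2 * z[None, :], 2 * z, [0]))
    np.testing.assert_allclose(a.p_adjusted, b.p_adjusted, rtol=1e-10)


def test_lambda_monotone_ranking_matches_p_ranking():
    rng = np.random.default_rng(8)
    z = rng.standard_normal(200)
    scan = envassoc.calibrate_adjust(AssociationScan("x", 1, z[None, :], z, [0]))
    by_z = np.argsort(-np.abs(z))
    by_p = np.argsort(scan.p_adjusted, kind="stable")
    np.testing.assert_array_equal(np.abs(z)[by_z], np.abs(z)[by_p])


def test_degenerate_all_zero_z_raises():
    scan = AssociationScan("x", 1, np.zeros((1, 10)), np.zeros(10), [0])
    with pytest.raises(ValueError):
        envassoc.calibrate_adjust(scan)


# ---------------------------------------------------------------------------
# intersection


def _fake_scan(flags, var, k):
    L = len(flags)
    s = AssociationScan(var, k, np.zeros((1, L)), np.zeros(L), [0])
    s.candidates = np.asarray(flags, dtype=bool)
    s.p_adjusted = np.where(s.candidates, 0.001, 0.5)
    s.q_values = s.p_adjusted
    s.lam = 1.0
    return s


def test_intersection_requires_all_k_values():
    loci = make_geno(np.zeros((2, 4), dtype=np.int8)).loci
    scans = [
        _fake_scan([1, 1, 0, 0], "temp", 2),
        _fake_scan([1, 1, 0, 0], "temp", 3),
        _fake_scan([1, 0, 0, 0], "temp", 4),
    ]
    cs = envassoc.intersect_candidates(scans, loci)
    assert cs.snp_indices.tolist() == [0]


def test_intersection_is_antimonotone_in_k_grid():
    loci = make_geno(np.zeros((2, 6), dtype=np.int8)).loci
    rng = np.random.default_rng(9)
    scans = [_fake_scan(rng.random(6) < 0.5, "v", k) for k in (1, 2, 3)]
    small = envassoc.intersect_candidates(scans, loci)
    large = envassoc.intersect_candidates(scans[:2], loci)
    assert set(small.snp_indices) <= set(large.snp_indices)


def test_provenance_partitions_cover_the_union():
    loci = make_geno(np.zeros((2, 5), dtype=np.int8), contigs=list("aabbc")).loci
    scans = [_fake_scan([1, 0, 1, 0, 0], "temp", 2), _fake_scan([0, 0, 0, 1, 0], "prec", 2)]
    cs = envassoc.intersect_candidates(scans, loci)
    union = set().union(*cs.provenance.values())
    assert union == set(cs.snp_indices.tolist())
    assert cs.contigs == ["a", "b"]
    summary = envassoc.candidate_summary(cs, loci)
    assert summary[summary.source == "union"]["n_snps"].iloc[0] == 3


# ---------------------------------------------------------------------------
# proportion test


def test_published_chi_square_value_reproduced():
    x2, p = envassoc.compare_candidate_proportions(1147, 9625, 3065, 9143)
    assert x2 == pytest.approx(798.19, abs=0.005)
    assert p < 0.001


def test_chi_square_agrees_with_closed_form_on_random_tables():
    from scipy.stats import chi2_contingency

    rng = np.random.default_rng(10)
    for _ in range(20):
        a, b = rng.integers(5, 500, 2)
        ta, tb = a + rng.integers(5, 500), b + rng.integers(5, 500)
        x2, _ = envassoc.compare_candidate_proportions(a, ta, b, tb)
        oracle = chi2_contingency(np.array([[a, ta], [b, tb]]), correction=True).statistic
        assert x2 == pytest.approx(oracle, rel=1e-10)


def test_equal_proportions_give_small_statistic():
    x2_nc, _ = envassoc.compare_candidate_proportions(10, 100, 10, 100, continuity=False)
    assert x2_nc == 0.0
    x2, _ = envassoc.compare_candidate_proportions(10, 100, 10, 100, continuity=True)
    assert 0.0 <= x2 < 0.05


def test_counts_validated():
    with pytest.raises(ValueError):
        envassoc.compare_candidate_proportions(10, 5, 1, 2)
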