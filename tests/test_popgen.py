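"""Diversity statistics, relatedness, and effective population size."""

import itertools

import numpy as np
import pytest

from landgen import popgen, synthdata
from landgen.experiments import tajima_d_oracle
from landgen.genio import MISSING

from conftest import make_geno


# ---------------------------------------------------------------------------
# expected heterozygosity


def test_he_closed_form_at_half_frequency():
    # 5 individuals, allele counts 5/5 over 10 chromosomes
    g = make_geno([[0], [1], [1], [1], [2]])
    he, mean, _ = popgen.expected_heterozygosity(g, n_boot=10)
    assert he[0] == pytest.approx(2 * 0.25 * 10 / 9)
    assert mean == pytest.approx(0.55556, abs=1e-4)


def test_he_monomorphic_locus_is_zero():
    g = make_geno(np.zeros((6, 1), dtype=np.int8))
    he, mean, _ = popgen.expected_heterozygosity(g, n_boot=10)
    assert he[0] == 0.0 and mean == 0.0


def test_he_bootstrap_ci_matches_exhaustive_enumeration():
    g = make_geno([[0, 1, 2], [1, 1, 0], [2, 1, 0], [0, 1, 2]])
    he, _, ci = popgen.expected_heterozygosity(g, n_boot=20000, seed=5)
    # exhaustive bootstrap over the 3^3 equally likely locus resamples
    means = sorted(np.mean([he[list(c)]]) for c in itertools.product(range(3), repeat=3))
    lo, hi = np.quantile(means, [0.025, 0.975])
    achievable = np.unique(np.round(means, 12))
    assert min(abs(ci[0] - v) for v in achievable) < 1e-9
    assert min(abs(ci[1] - v) for v in achievable) < 1e-9
    assert ci[0] <= np.mean(he) <= ci[1]
    assert abs(ci[0] - lo) < np.ptp(means) / 3 and abs(ci[1] - hi) < np.ptp(means) / 3


def test_he_bootstrap_ci_coverage_near_nominal():
    # loci are iid draws with p ~ U(0.1, 0.9); the bootstrap-over-loci CI
    # targets the superpopulation mean E[2p(1-p)]
    rng = np.random.default_rng(0)
    n, L = 30, 60
    true_mean = 2 * (0.25 - (0.9 - 0.1) ** 2 / 12)
    cover = 0
    n_rep = 500
    for rep in range(n_rep):
        p = rng.uniform(0.1, 0.9, L)
        calls = rng.binomial(2, p, size=(n, L)).astype(np.int8)
        _, _, ci = popgen.expected_heterozygosity(make_geno(calls), n_boot=400, seed=rep)
        cover += ci[0] <= true_mean <= ci[1]
    assert abs(cover / n_rep - 0.95) <= 0.03


# ---------------------------------------------------------------------------
# inbreeding


def test_inbreeding_fully_homozygous_individual_is_one():
    rng = np.random.default_rng(0)
    calls = rng.binomial(2, 0.5, size=(30, 50)).astype(np.int8)
    calls[0] = np.where(calls[0] == 1, 0, calls[0])
    f, _, _ = popgen.individual_inbreeding(make_geno(calls), n_boot=10)
    assert f[0] == pytest.approx(1.0)


def test_inbreeding_two_locus_toy_matches_hand_computation():
    # 4 individuals, focal individual heterozygous at both loci
    calls = np.array([[1, 1], [0, 2], [2, 0], [1, 1]], dtype=np.int8)
    g = make_geno(calls)
    f, _, _ = popgen.individual_inbreeding(g, n_boot=10)
    # p = 0.5 at both loci, n = 8 chromosomes: He = 2*0.25*8/7 = 4/7
    e_hom = 2 * (1 - 4 / 7)
    expected = (0 - e_hom) / (2 - e_hom)
    assert f[0] == pytest.approx(expected)
    assert f[0] < 0


# ---------------------------------------------------------------------------
# nucleotide diversity


def test_pi_closed_forms():
    # n = 4 chromosomes, j = 2 -> 2*2*2/(4*3) = 2/3, the maximum for n = 4
    g = make_geno([[1, 0], [1, 0]])
    pi, mean, _ = popgen.nucleotide_diversity(g, n_boot=10)
    assert pi[0] == pytest.approx(2 / 3)
    assert pi[1] == 0.0


def test_pi_equals_mean_pairwise_hamming_over_haplotypes():
    rng = np.random.default_rng(1)
    hap = rng.integers(0, 2, size=(8, 3)).astype(np.int8)   # phased 8 haplotypes
    calls = hap[0::2] + hap[1::2]
    pi, _, _ = popgen.nucleotide_diversity(make_geno(calls), n_boot=10)
    n = hap.shape[0]
    for l in range(3):
        diffs = [
            abs(int(hap[a, l]) - int(hap[b, l]))
            for a, b in itertools.combinations(range(n), 2)
        ]
        assert pi[l] == pytest.approx(np.mean(diffs))


# ---------------------------------------------------------------------------
# Tajima's D


def test_tajimas_d_matches_constant_by_constant_oracle():
    rng = np.random.default_rng(2)
    hap = rng.integers(0, 2, size=(8, 40)).astype(np.int8)
    calls = hap[0::2] + hap[1::2]
    d, _ = popgen.tajimas_d(make_geno(calls), n_boot=10)
    assert d == pytest.approx(tajima_d_oracle(hap), abs=1e-10)


def test_tajimas_d_near_zero_under_neutral_constant_size():
    ds = []
    for r in range(12):
        g = synthdata.simulate_coalescent(30, 150, "constant", seed=40 + r)
        d, _ = popgen.tajimas_d(g, n_boot=10)
        ds.append(d)
    assert abs(np.mean(ds)) < 0.3


def test_tajimas_d_sign_tracks_demography():
    d_bot = np.mean([
        popgen.tajimas_d(synthdata.simulate_coalescent(30, 120, "bottleneck", seed=60 + r), n_boot=5)[0]
        for r in range(4)
    ])
    d_exp = np.mean([
        popgen.tajimas_d(synthdata.simulate_coalescent(30, 120, "expansion", seed=80 + r), n_boot=5)[0]
        for r in range(4)
    ])
    assert d_bot > 0 > d_exp


def test_tajimas_d_undefined_without_segregating_sites():
    d, ci = popgen.tajimas_d(make_geno(np.zeros((5, 4), dtype=np.int8)), n_boot=5)
    assert np.isnan(d)


# ---------------------------------------------------------------------------
# Yang relatedness


def test_yang_single_locus_closed_forms():
    # p = 0.5; opposite homozygotes -> A_jk = -2; heterozygote diagonal -> 0
    g = make_geno([[2], [0], [1], [1]])
    rel = popgen.yang_relatedness(g)
    assert rel.matrix[0, 1] == pytest.approx(-2.0)
    assert rel.matrix[2, 2] == pytest.approx(0.0)


def test_yang_symmetry_and_permutation_consistency(small_dataset):
    geno, _ = small_dataset
    rel = popgen.yang_relatedness(geno)
    np.testing.assert_allclose(rel.matrix, rel.matrix.T, atol=1e-12)
    perm = np.random.default_rng(3).permutation(geno.n_samples)
    rel_p = popgen.yang_relatedness(geno.subset_samples(perm))
    np.testing.assert_allclose(rel_p.matrix, rel.matrix[np.ix_(perm, perm)], atol=1e-12)


def test_diversity_statistics_invariant_to_allele_label_swap(small_dataset):
    geno, _ = small_dataset
    swapped = make_geno(np.where(geno.calls == MISSING, MISSING, 2 - geno.calls))
    for fn in (popgen.expected_heterozygosity, popgen.nucleotide_diversity):
        a = fn(geno, n_boot=10, seed=0)
        b = fn(swapped, n_boot=10, seed=0)
        np.testing.assert_allclose(a[0], b[0], atol=1e-12)
    ra = popgen.yang_relatedness(geno).matrix
    rb = popgen.yang_relatedness(swapped).matrix
    np.testing.assert_allclose(ra, rb, atol=1e-10)


def test_yang_unstructured_row_means_concentrate():
    rng = np.random.default_rng(4)
    calls = rng.binomial(2, rng.uniform(0.2, 0.8, 200), size=(20, 200)).astype(np.int8)
    rel = popgen.yang_relatedness(make_geno(calls))
    off = rel.matrix - np.diag(np.diag(rel.matrix))
    row_means = off.sum(1) / (len(off) - 1)
    assert np.abs(row_means).max() < 3 / np.sqrt(200)


# ---------------------------------------------------------------------------
# Ne


def test_ne_formula_inversion():
    r2d = 1.0 / 300.0
    ne = popgen._ne_from_r2drift(r2d)
    assert ne == pytest.approx((1 / 3 + np.sqrt(1 / 9 - 2.76 * r2d)) / (2 * r2d))
    assert 95 < ne < 100


def test_ne_same_contig_pairs_are_excluded():
    rng = np.random.default_rng(5)
    col = rng.binomial(2, 0.5, size=(40, 1)).astype(np.int8)
    g = make_geno(np.hstack([col, col]), contigs=["tag1", "tag1"], pos=[1, 50])
    est = popgen.ne_ld(g)
    assert est.n_pairs == 0


def test_ne_infinite_when_no_drift_signal():
    assert np.isinf(popgen._ne_from_r2drift(-0.001))
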