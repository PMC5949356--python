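"""Validation experiments on synthetic data with known ground truth.

Each function runs one self-contained study — recovery, calibration, or
power — at desk scale and returns summary metrics.  They are used by the
test suite and by the reproduction script; all randomness flows from the
seed argument.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.linalg import pinvh

from . import ancestry as anc
from . import envassoc, ibr, landscape, popgen, synthdata


# ---------------------------------------------------------------------------
# circuit solver


def circuit_solver_error(seed: int = 0, n_grids: int = 50, max_cells: int = 100) -> dict:
    """Worst-case deviation of the sparse solver from the dense L+ oracle.

    Random rectangular grids of at most ``max_cells`` cells with random
    positive resistances; all pairwise effective resistances among 6 random
    sample cells are compared against the symmetric pseudo-inverse identity
    R_ij = L+_ii + L+_jj - 2 L+_ij.  Also audits the metric axioms.
    """
    import pandas as pd

    from .genio import Raster

    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_triangle = 0.0
    for _ in range(n_grids):
        nr = int(rng.integers(3, 11))
        nc = int(rng.integers(3, max(4, min(10, max_cells // nr)) + 1))
        data = rng.uniform(0.1, 5.0, (nr, nc))
        surface = landscape.ResistanceHypothesis("rand", Raster(data, 0, 0, 1.0), {})
        cells = rng.choice(nr * nc, size=min(6, nr * nc), replace=False)
        rows, cols = np.unravel_index(cells, (nr, nc))
        samples = pd.DataFrame(
            {"x": cols + 0.5, "y": nr - rows - 0.5},
            index=[f"s{i}" for i in range(len(cells))],
        )
        d = landscape.resistance_distance(surface, samples)
        lap, node = landscape._grid_laplacian(data, -9999.0)
        lp = pinvh(lap.toarray())
        nodes = [node[r, c] for r, c in zip(rows, cols)]
        sq = d.square()
        m = len(nodes)
        for i in range(m):
            for j in range(i + 1, m):
                a, b = nodes[i], nodes[j]
                oracle = lp[a, a] + lp[b, b] - 2 * lp[a, b]
                worst = max(worst, abs(oracle - sq[i, j]))
        for i in range(m):
            for j in range(m):
                for k in range(m):
                    worst_triangle = max(worst_triangle, sq[i, j] - (sq[i, k] + sq[k, j]))
    return {"max_abs_error": worst, "max_triangle_violation": worst_triangle}


# ---------------------------------------------------------------------------
# MLPE


def mlpe_recovery(seed: int = 0, n_individuals: int = 40, n_reps: int = 200,
                  rho: float = 0.2, beta1: float = 2.0) -> dict:
    """Slope recovery and CI coverage of the MLPE fit on simulated pairs."""
    rng = np.random.default_rng(seed)
    pair_index = ibr.full_pair_index(n_individuals)
    m = len(pair_index)
    ii, jj = pair_index[:, 0], pair_index[:, 1]
    share = (
        (ii[:, None] == ii[None, :]) | (ii[:, None] == jj[None, :])
        | (jj[:, None] == ii[None, :]) | (jj[:, None] == jj[None, :])
    ).astype(float)
    np.fill_diagonal(share, 0.0)
    chol = np.linalg.cholesky(np.eye(m) + 2 * rho * share)
    betas, covered = [], []
    for _ in range(n_reps):
        x = rng.standard_normal(m)
        y = 1.0 + beta1 * x + 0.5 * (chol @ rng.standard_normal(m))
        fit = ibr.mlpe_fit(y, x, pair_index)
        betas.append(fit.beta[1])
        covered.append(abs(fit.beta[1] - beta1) <= 1.96 * fit.se[1])
    return {
        "mean_beta": float(np.mean(betas)),
        "bias_pct": float(100 * abs(np.mean(betas) - beta1) / beta1),
        "coverage": float(np.mean(covered)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# surface recovery


def surface_recovery(seed: int = 0, n_reps: int = 50, grid_shape=(30, 30)) -> dict:
    """How often the true resistance hypothesis wins the univariate AICc race.

    One landscape and sampling design (spread across the savanna extent);
    per replicate, fresh genotypes from the strong-IBR preset, Yang
    relatedness, and a node-effect-augmented MLPE fit per candidate surface
    (27 hypotheses).
    """
    cfg = synthdata.preset("ibr")
    n = cfg.pop("n_samples")
    bundle = synthdata.generate_landscape(seed=seed, grid_shape=grid_shape,
                                          **synthdata.PRESET_LANDSCAPE["ibr"])
    samples = synthdata.sample_individuals(bundle, n, 10.0, seed=seed + 1, method="spread")
    surfaces = landscape.build_surfaces(bundle, samples)
    dists = {s.name: landscape.resistance_distance(s, samples).values for s in surfaces}
    pair_index = ibr.full_pair_index(n)
    wins = 0
    true_name = None
    for r in range(n_reps):
        geno, truth = synthdata.simulate_genotypes(bundle, samples, seed=seed + 100 + r, **cfg)
        true_name = truth.true_resistance_hypothesis
        y = popgen.yang_relatedness(geno).condensed()
        table, _ = ibr.rank_candidate_surfaces(y, dists, pair_index)
        wins += table.table["model"].iloc[0] == true_name
    return {"win_rate": wins / n_reps, "n_surfaces": len(dists),
            "true_surface": true_name, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# scan calibration and power


def scan_calibration(seed: int = 0, n_z: int = 10_000) -> dict:
    """Genomic inflation factor on standard-normal z-scores."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_z)
    scan = envassoc.AssociationScan("null", 1, z[None, :], z, [seed])
    envassoc.calibrate_adjust(scan)
    return {"lambda": scan.lam, "n_candidates": int(scan.candidates.sum())}


def bh_bruteforce_agreement(seed: int = 0, n_lists: int = 30, L: int = 10,
                            fdr_q: float = 0.05) -> dict:
    """BH step-up flags versus exhaustive search over all rejection sets.

    The brute-force oracle picks the largest subset R of p-values whose
    maximum is at most |R| q / L — the defining property of the BH set.
    """
    import itertools

    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_lists):
        p = np.concatenate([rng.uniform(0, 0.03, 3), rng.uniform(0, 1, L - 3)])
        _, flags = envassoc.bh_adjust(p, fdr_q)
        best: set = set()
        for size in range(L, 0, -1):
            found = None
            for combo in itertools.combinations(range(L), size):
                if max(p[list(combo)]) <= size * fdr_q / L:
                    found = set(combo)
                    break
            if found is not None:
                best = found
                break
        if best != set(np.flatnonzero(flags).tolist()):
            mismatches += 1
    return {"mismatches": mismatches, "n_lists": n_lists}


def scan_fdr_power(seed: int = 0, n_reps: int = 50, n: int = 80, L: int = 300,
                   n_planted: int = 15, beta: float = 1.2, fdr_q: float = 0.05,
                   k_center: int = 2, k_spread: int = 1, n_runs: int = 3) -> dict:
    """Empirical FDR and power of the k-intersected candidate set.

    Structured two-population genotypes with planted environmental effects;
    scans across the k grid are calibrated and intersected as in the full
    pipeline.
    """
    import pandas as pd

    from scipy.special import expit, logit

    from .genio import GenotypeMatrix

    rng = np.random.default_rng(seed)
    loci = pd.DataFrame({"contig": [f"c{i}" for i in range(L)], "pos": 1,
                         "ref": "A", "alt": "T", "qual": 99.0, "n_alt": 1})
    sample_index = pd.Index([f"i{i}" for i in range(n)], name="id")
    fdrs, powers = [], []
    theta = 0.1
    for rep in range(n_reps):
        p_anc = rng.uniform(0.2, 0.8, L)
        a = p_anc * (1 - theta) / theta
        b = (1 - p_anc) * (1 - theta) / theta
        p_cl = rng.beta(a, b, (2, L))
        memb = np.repeat([0, 1], [n // 2, n - n // 2])
        p = p_cl[memb]
        env = rng.standard_normal(n) + 0.5 * memb
        z_env = (env - env.mean()) / env.std()
        planted = rng.choice(L, n_planted, replace=False)
        for l in planted:
            p[:, l] = expit(logit(p_anc[l]) + beta * z_env)
        calls = rng.binomial(2, p).astype(np.int8)
        geno = GenotypeMatrix(pd.DataFrame(index=sample_index), loci, calls)
        scans = []
        for k in range(max(1, k_center - k_spread), k_center + k_spread + 1):
            s = envassoc.lfmm_scan(geno, env, k, n_runs=n_runs, seed=seed + 31 * rep)
            scans.append(envassoc.calibrate_adjust(s, fdr_q))
        found = set(envassoc.intersect_candidates(scans, loci).snp_indices.tolist())
        tp = len(found & set(planted.tolist()))
        fp = len(found) - tp
        fdrs.append(fp / max(len(found), 1))
        powers.append(tp / n_planted)
    return {"fdr": float(np.mean(fdrs)), "power": float(np.mean(powers)),
            "nominal_q": fdr_q, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# ancestry


def choose_k_hits(preset_name: str, k_true: int, seed: int = 0, n_reps: int = 10,
                  n_samples: int = 70, k_max: int = 6, reps: int = 4,
                  grid_shape=(30, 30)) -> dict:
    """Fraction of replicate datasets on which choose_k recovers k_true."""
    from . import genio

    hits = 0
    for r in range(n_reps):
        _, _, geno, _ = synthdata.simulate_preset(
            preset_name, seed=seed + 37 * r, grid_shape=grid_shape, n_samples=n_samples
        )
        qcd, _ = genio.qc_filter(geno)
        best, _, _ = anc.choose_k(qcd, 1, k_max, reps=reps, seed=seed + r)
        hits += best == k_true
    return {"hits": hits, "n_reps": n_reps, "k_true": k_true}


def ancestry_q_rmse(seed: int = 0, n: int = 80, L: int = 600, k: int = 4,
                    theta: float = 0.3) -> dict:
    """Q recovery on well-separated discrete clusters (Balding-Nichols)."""
    import pandas as pd

    from .genio import GenotypeMatrix

    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.2, 0.8, L)
    a = p_anc * (1 - theta) / theta
    b = (1 - p_anc) * (1 - theta) / theta
    p_cl = rng.beta(a, b, (k, L))
    memb = np.repeat(np.arange(k), n // k)
    memb = np.concatenate([memb, np.full(n - len(memb), k - 1)])
    calls = rng.binomial(2, p_cl[memb]).astype(np.int8)
    loci = pd.DataFrame({"contig": [f"c{i}" for i in range(L)], "pos": 1,
                         "ref": "A", "alt": "T", "qual": 99.0, "n_alt": 1})
    geno = GenotypeMatrix(pd.DataFrame(index=[f"i{i}" for i in range(n)]), loci, calls)
    model = anc.snmf_fit(geno, k, seed=seed + 1, init="spectral")
    q_true = np.zeros((n, k))
    q_true[np.arange(n), memb] = 1.0
    q_hat = anc.align_labels(model.Q, q_true)
    return {"rmse": float(np.sqrt(((q_hat - q_true) ** 2).mean())),
            "mean_abs": float(np.abs(q_hat - q_true).mean())}


# ---------------------------------------------------------------------------
# popgen


def ne_recovery(seed: int = 0, n_reps: int = 50, n_e: int = 100, n_sample: int = 50,
                n_loci: int = 400, n_generations: int = 30) -> dict:
    """Median LD-Ne estimate across Wright-Fisher replicates at known Ne."""
    estimates = []
    for r in range(n_reps):
        geno = synthdata.simulate_wright_fisher(
            n_e=n_e, n_sample=n_sample, n_loci=n_loci,
            n_generations=n_generations, seed=seed + r,
        )
        estimates.append(popgen.ne_ld(geno).ne)
    finite = [e for e in estimates if np.isfinite(e)]
    return {"median_ne": float(np.median(estimates)), "true_ne": n_e,
            "n_finite": len(finite), "n_reps": n_reps}


def tajima_d_oracle(haplotypes: np.ndarray) -> float:
    """Independent constant-by-constant Tajima's D on phased haplotypes."""
    n, L = haplotypes.shape
    freqs = haplotypes.sum(axis=0)
    seg = (freqs > 0) & (freqs < n)
    s = int(seg.sum())
    pi_tot = 0.0
    for l in np.flatnonzero(seg):
        j = haplotypes[:, l].sum()
        pi_tot += 2.0 * j * (n - j) / (n * (n - 1))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_tot - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))
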