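"""Ancestry coefficients by sparse nonnegative matrix factorisation.

Genotypes are one-hot encoded over the three diploid classes {0, 1, 2} and
factorised as X ~ Q G with Q (n x k) on the probability simplex per
individual and G (k x 3L) a per-ancestral-population genotype-class
distribution per locus.  The number of ancestral populations k is chosen by
masked cross-entropy: a random fraction of known genotype cells is held out
and the model's predictive log-loss on those cells scores each k.

Optimisation is block projected-gradient descent with exact Lipschitz step
sizes, which guarantees a monotone non-increasing penalised loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix

N_CLASSES = 3


@dataclass
class AncestryModel:
    k: int
    Q: np.ndarray               # n x k, rows on the simplex
    G: np.ndarray               # k x 3L, class triplets sum to 1
    cross_entropy: float        # masked held-out log-loss
    reg_alpha: float
    seed: int
    loss_trace: np.ndarray | None = None

    def assignments(self) -> np.ndarray:
        """Hard cluster per individual (argmax Q, ties to lowest index)."""
        return self.Q.argmax(axis=1)


def _one_hot(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encoding (n, 3L) and the known-cell mask expanded to classes."""
    n, L = calls.shape
    x = np.zeros((n, N_CLASSES * L))
    known = calls != MISSING
    ii, ll = np.nonzero(known)
    x[ii, N_CLASSES * ll + calls[ii, ll]] = 1.0
    w = np.repeat(known, N_CLASSES).reshape(n, N_CLASSES * L).astype(float)
    return x, w


def _project_rows_simplex(q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = q.shape
    u = np.sort(q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(q - theta[:, None], 0.0)


def _project_g(g: np.ndarray) -> np.ndarray:
    """Project each (population, locus) class triplet onto the 3-simplex."""
    k, width = g.shape
    tri = g.reshape(k * (width // N_CLASSES), N_CLASSES)
    return _project_rows_simplex(tri).reshape(k, width)


def _spectral_init(calls: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Near-hard Q start from k-means on leading principal components."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    col = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col, x) - col
    n_comp = min(max(k, 2), min(x.shape) - 1)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    labels = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(pcs).labels_
    q = np.full((calls.shape[0], k), 0.1 / max(k - 1, 1))
    q[np.arange(calls.shape[0]), labels] = 0.9
    return q


def snmf_fit(
    geno: GenotypeMatrix,
    k: int,
    reg_alpha: float = 10.0,
    seed: int = 0,
    mask_fraction: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-6,
    inner_steps: int = 4,
    mask_seed: int | None = None,
    init: str = "random",
) -> AncestryModel:
    """Fit the sparse-NMF ancestry model at a given k.

    Minimises ``||W o (X - QG)||^2 + reg_alpha ||Q||^2`` where W masks
    missing genotypes and a seeded held-out fraction of known cells; the
    held-out cells score the model by cross-entropy.  ``mask_seed`` pins the
    held-out mask independently of the initialisation seed so that fits at
    different k can be scored on the same cells.
    """
    n, L = geno.calls.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of individuals ({n})")
    rng = np.random.default_rng(seed)
    mask_rng = np.random.default_rng(seed if mask_seed is None else mask_seed)
    x, w = _one_hot(geno.calls)

    known = geno.calls != MISSING
    ki, kl = np.nonzero(known)
    n_known = len(ki)
    n_hold = int(round(mask_fraction * n_known))
    hold = mask_rng.choice(n_known, size=n_hold, replace=False) if n_hold else np.array([], int)
    hold_i, hold_l = ki[hold], kl[hold]
    for i, l in zip(hold_i, hold_l):
        w[i, N_CLASSES * l : N_CLASSES * (l + 1)] = 0.0

    # init: Dirichlet rows (or spectral clusters) for Q; G from training
    # class frequencies + noise
    if init == "spectral" and k > 1:
        Q = _spectral_init(geno.calls, k, seed)
    elif init in ("random", "spectral"):
        Q = rng.dirichlet(np.ones(k), size=n)
    else:
        raise ValueError("init must be 'random' or 'spectral'")
    wx = w * x
    freq = wx.reshape(n, L, N_CLASSES).sum(axis=0)
    freq = freq / np.maximum(freq.sum(axis=1, keepdims=True), 1e-12)
    G = np.tile(freq.reshape(1, -1), (k, 1))
    G = _project_g(G + 0.1 * rng.random(G.shape))

    def loss(Q, G):
        r = w * (x - Q @ G)
        return float((r * r).sum() + reg_alpha * (Q * Q).sum())

    prev = loss(Q, G)
    trace = [prev]
    for _ in range(max_iter):
        # Q block: projected gradient, step 1/L with L = 2*lmax(GG') + 2*alpha
        gg = G @ G.T
        lip_q = 2.0 * np.linalg.eigvalsh(gg)[-1] + 2.0 * reg_alpha
        for _ in range(inner_steps):
            grad = -2.0 * ((w * (x - Q @ G)) @ G.T) + 2.0 * reg_alpha * Q
            Q = _project_rows_simplex(Q - grad / lip_q)
        # G block: step 1/L with L = 2*lmax(Q'Q)
        qq = Q.T @ Q
        lip_g = 2.0 * np.linalg.eigvalsh(qq)[-1] + 1e-12
        for _ in range(inner_steps):
            grad = -2.0 * (Q.T @ (w * (x - Q @ G)))
            G = _project_g(G - grad / lip_g)
        cur = loss(Q, G)
        if cur > prev * (1 + 1e-9) + 1e-9:
            raise AssertionError("sNMF loss increased across an iteration")
        trace.append(cur)
        if prev - cur < tol * max(prev, 1e-12):
            prev = cur
            break
        prev = cur

    # held-out cross-entropy
    if n_hold:
        pred = Q @ G
        probs = pred[hold_i[:, None], N_CLASSES * hold_l[:, None] + np.arange(N_CLASSES)]
        probs = np.clip(probs, 1e-9, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
        true_cls = geno.calls[hold_i, hold_l]
        ce = float(-np.log(probs[np.arange(n_hold), true_cls]).mean())
    else:
        ce = np.nan
    return AncestryModel(k=k, Q=Q, G=G, cross_entropy=ce, reg_alpha=reg_alpha,
                         seed=seed, loss_trace=np.array(trace))


def choose_k(
    geno: GenotypeMatrix,
    k_min: int = 1,
    k_max: int = 10,
    reps: int = 10,
    reg_alpha: float = 10.0,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, AncestryModel]:
    """Scan k over a range with replicate seeded fits.

    The per-k score is the minimum held-out cross-entropy across replicates;
    the chosen k is the global minimiser (ties to the smaller k).  Within a
    replicate every k is scored on the same held-out mask (a paired
    comparison); masks differ between replicates.  Returns (best k, the
    entropy table, the best model).
    """
    if k_max > geno.n_samples:
        raise ValueError("k_max exceeds the number of individuals")
    rows, models = [], {}
    for k in range(k_min, k_max + 1):
        for rep in range(reps):
            m = snmf_fit(geno, k, reg_alpha=reg_alpha, seed=seed + 1000 * k + rep,
                         mask_seed=seed + 7919 * rep,
                         init="spectral" if rep == 0 else "random", **fit_kwargs)
            rows.append({"k": k, "rep": rep, "cross_entropy": m.cross_entropy})
            key = (k,)
            if key not in models or m.cross_entropy < models[key].cross_entropy:
                models[key] = m
    table = pd.DataFrame(rows)
    score = table.groupby("k")["cross_entropy"].min()
    best_k = int(score.idxmin())   # idxmin takes the first (smallest k) on ties
    return best_k, table, models[(best_k,)]


def align_labels(Q: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Resolve label switching: greedily match columns of Q to the reference."""
    k = Q.shape[1]
    cost = -(Q.T @ reference)   # negative overlap
    perm = [-1] * k
    used_rows, used_cols = set(), set()
    flat = sorted(((cost[i, j], i, j) for i in range(k) for j in range(reference.shape[1])))
    for _, i, j in flat:
        if i not in used_rows and j not in used_cols:
            perm[j] = i
            used_rows.add(i)
            used_cols.add(j)
    remaining = [i for i in range(k) if i not in used_rows]
    for j in range(k):
        if perm[j] == -1:
            perm[j] = remaining.pop(0)
    return Q[:, perm]


# ---------------------------------------------------------------------------
# FST outlier scan


@dataclass
class OutlierScanResult:
    fst: np.ndarray
    z2: np.ndarray
    lam: float
    p_adjusted: np.ndarray
    q_values: np.ndarray
    candidates: np.ndarray
    k: int

    def to_frame(self, loci: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"fst": self.fst, "z2": self.z2, "p": self.p_adjusted,
                           "q": self.q_values, "candidate": self.candidates})
        if loci is not None:
            df.insert(0, "contig", loci["contig"].to_numpy())
            df.insert(1, "pos", loci["pos"].to_numpy())
        return df


def bh_adjust(p: np.ndarray, fdr_q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg: returns (q-values, rejection flags at fdr_q)."""
    p = np.asarray(p, dtype=float)
    L = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = ranked * L / np.arange(1, L + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    qvals = np.empty(L)
    qvals[order] = np.minimum(q, 1.0)
    # step-up rule
    thresh = np.arange(1, L + 1) * fdr_q / L
    below = np.nonzero(ranked <= thresh)[0]
    flags = np.zeros(L, dtype=bool)
    if len(below):
        flags[order[: below[-1] + 1]] = True
    return qvals, flags


CHI2_1_MEDIAN = 0.4549364


def fst_outlier_scan(
    geno: GenotypeMatrix, ancestry: AncestryModel, fdr_q: float = 0.05
) -> OutlierScanResult:
    """Differentiation outlier scan over the hard ancestry clusters.

    Per locus, the weighted FST across argmax-Q clusters is transformed to
    z^2 = FST (n - k)/(1 - FST), calibrated by the genomic inflation factor
    (median z^2 over the chi-square_{k-1} median), and BH-flagged.
    """
    k = ancestry.k
    if k < 2:
        raise ValueError("differentiation test undefined for k=1")
    groups = ancestry.assignments()
    n, L = geno.calls.shape
    ok = geno.called()
    p_bar_num = np.zeros(L)
    p_bar_den = np.zeros(L)
    within = np.zeros(L)
    p_c = {}
    w_c = {}
    for c in range(k):
        rows = groups == c
        ok_c = ok[rows]
        n_chrom = 2 * ok_c.sum(axis=0)
        alt = np.where(ok_c, geno.calls[rows], 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pc = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)
        p_c[c] = pc
        w_c[c] = n_chrom
        p_bar_num += np.nan_to_num(pc * n_chrom)
        p_bar_den += n_chrom
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = p_bar_num / np.maximum(p_bar_den, 1)
        for c in range(k):
            within += np.nan_to_num(w_c[c] / np.maximum(p_bar_den, 1) * p_c[c] * (1 - p_c[c]))
        total = p_bar * (1 - p_bar)
        fst = np.where(total > 0, 1.0 - within / np.where(total > 0, total, 1.0), 0.0)
    fst = np.clip(fst, 0.0, 1.0 - 1e-12)
    z2 = fst * (n - k) / (1.0 - fst)
    lam = float(np.median(z2) / stats.chi2.median(df=k - 1))
    if lam <= 0:
        raise ValueError("degenerate scan: genomic inflation factor is zero")
    p_adj = stats.chi2.sf(z2 / lam, df=k - 1)
    qvals, flags = bh_adjust(p_adj, fdr_q)
    return OutlierScanResult(fst=fst, z2=z2, lam=lam, p_adjusted=p_adj,
                             q_values=qvals, candidates=flags, k=k)
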