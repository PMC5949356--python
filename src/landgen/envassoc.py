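"""Environmental-association scans and candidate-locus bookkeeping.

The association model is a latent-factor regression: genotype dosages Y
(n x L) are explained by the standardised environmental variable x through
per-locus effects b, while k latent factors U absorb population structure.
The model is fit by alternating ridge minimisation (deterministic given the
seed); per-locus z-scores are combined across replicate runs by the median,
calibrated by the genomic inflation factor, and FDR-controlled by
Benjamini-Hochberg.  Candidates are intersected across a grid of k values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ancestry import CHI2_1_MEDIAN, bh_adjust
from .genio import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# variable selection


def select_env_variables(env_table: pd.DataFrame, n_axes: int = 3) -> tuple[list, pd.DataFrame]:
    """Pick the variable most correlated with each leading PCA axis.

    Columns are standardised, a PCA is run, and for axis a = 1..n_axes the
    variable with the largest |correlation| to the axis scores is selected
    without replacement.  Returns (names, axis-correlation table).
    """
    from sklearn.decomposition import PCA

    num = env_table.select_dtypes(include=[np.number])
    keep = [c for c in num.columns if float(np.std(num[c])) > 0]
    dropped = set(num.columns) - set(keep)
    if dropped:
        warnings.warn(f"constant columns dropped: {sorted(dropped)}")
    if len(keep) < n_axes:
        raise ValueError("fewer numeric variables than requested axes")
    Z = (num[keep] - num[keep].mean()) / num[keep].std(ddof=0)
    pca = PCA(n_components=n_axes)
    scores = pca.fit_transform(Z.to_numpy())
    corr = pd.DataFrame(
        {f"axis{a + 1}": [np.corrcoef(Z[c], scores[:, a])[0, 1] for c in keep] for a in range(n_axes)},
        index=keep,
    )
    corr["variance_explained"] = np.nan
    chosen: list[str] = []
    for a in range(n_axes):
        ranked = corr[f"axis{a + 1}"].abs().sort_values(ascending=False).index
        pick = next(c for c in ranked if c not in chosen)
        chosen.append(pick)
    corr.attrs["variance_explained"] = pca.explained_variance_ratio_[:n_axes].sum()
    return chosen, corr


# ---------------------------------------------------------------------------
# latent factor scan


@dataclass
class AssociationScan:
    env_var: str
    k: int
    z_runs: np.ndarray          # n_runs x L
    z: np.ndarray               # combined (median) z per locus
    seeds: list
    lam: float | None = None
    p_adjusted: np.ndarray | None = None
    q_values: np.ndarray | None = None
    candidates: np.ndarray | None = None
    fdr_q: float | None = None

    def to_frame(self, loci: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"z": self.z})
        for name in ("p_adjusted", "q_values", "candidates"):
            val = getattr(self, name)
            if val is not None:
                df[name] = val
        if loci is not None:
            df.insert(0, "contig", loci["contig"].to_numpy())
            df.insert(1, "pos", loci["pos"].to_numpy())
        return df


def _lfmm_single(
    Y: np.ndarray, known: np.ndarray, x: np.ndarray, k: int,
    ridge: float, rng: np.random.Generator, n_iter: int,
) -> np.ndarray:
    """One alternating-ridge latent-factor fit; returns per-locus z-scores."""
    n, L = Y.shape
    col_mean = np.nanmean(np.where(known, Y, np.nan), axis=0)
    col_mean = np.nan_to_num(col_mean)
    Yc = np.where(known, Y, col_mean[None, :]) - col_mean[None, :]
    U = 0.1 * rng.standard_normal((n, k))
    penalty = np.diag(np.concatenate([[0.0], np.full(k, ridge)]))
    B = None
    for _ in range(n_iter):
        D = np.column_stack([x, U])
        # per-locus joint solve for (b_l, V_l) with ridge on V only
        B = np.linalg.solve(D.T @ D + penalty, D.T @ Yc)  # (k+1, L)
        V = B[1:, :].T                                    # L x k
        b = B[0, :]
        T = Yc - np.outer(x, b)
        U = T @ V @ np.linalg.inv(V.T @ V + ridge * np.eye(k))
        # EM-style reimputation of missing cells
        pred = np.outer(x, b) + U @ V.T
        Yc = np.where(known, Yc, pred)
    D = np.column_stack([x, U])
    G = np.linalg.inv(D.T @ D)
    B = G @ D.T @ Yc
    resid = Yc - D @ B
    dof = max(n - (k + 1) - 1, 1)
    s2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(s2 * G[0, 0], 1e-300))
    return B[0, :] / se


def lfmm_scan(
    geno: GenotypeMatrix,
    env: np.ndarray,
    k: int,
    n_runs: int = 5,
    seed: int = 0,
    ridge: float = 1.0,
    n_iter: int = 50,
    env_name: str = "env",
) -> AssociationScan:
    """Latent-factor association scan of every locus against one variable.

    Runs ``n_runs`` seeded fits (differing in factor initialisation) and
    combines per-locus z-scores by the median across runs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= geno.n_samples:
        raise ValueError("k must be smaller than the number of individuals")
    x = np.asarray(env, dtype=float)
    x = (x - x.mean()) / x.std(ddof=0)
    Y = geno.calls.astype(float)
    known = geno.calls != MISSING
    seeds = [seed + 97 * r for r in range(n_runs)]
    z_runs = np.vstack([
        _lfmm_single(Y, known, x, k, ridge, np.random.default_rng(s), n_iter)
        for s in seeds
    ])
    z = np.median(z_runs, axis=0)
    return AssociationScan(env_var=env_name, k=k, z_runs=z_runs, z=z, seeds=seeds)


def calibrate_adjust(scan: AssociationScan, fdr_q: float = 0.05) -> AssociationScan:
    """Genomic-inflation calibration and BH flags for a scan.

    lambda = median(z^2)/0.4549364; adjusted p is the upper chi-square_1
    tail at z^2/lambda.  Rescaling z leaves adjusted p unchanged.
    """
    z2 = scan.z**2
    lam = float(np.median(z2) / CHI2_1_MEDIAN)
    if lam <= 0:
        raise ValueError("all z-scores are zero: lambda undefined")
    p = stats.chi2.sf(z2 / lam, df=1)
    qvals, flags = bh_adjust(p, fdr_q)
    scan.lam = lam
    scan.p_adjusted = p
    scan.q_values = qvals
    scan.candidates = flags
    scan.fdr_q = fdr_q
    return scan


# ---------------------------------------------------------------------------
# candidate sets


@dataclass
class CandidateSet:
    snp_indices: np.ndarray
    contigs: list
    provenance: dict = field(default_factory=dict)  # source -> set of SNP indices

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)


def intersect_candidates(
    scans: list,
    loci: pd.DataFrame,
    fst_scan=None,
) -> CandidateSet:
    """Combine calibrated scans into the final candidate set.

    Per environmental variable a locus is a candidate only if flagged at
    *every* k in that variable's scan list; the union across variables (and
    the optional FST outlier scan) forms the final set, with per-source
    provenance for Venn-style reporting.  Contigs are rolled up through the
    locus-to-contig map.
    """
    L = len(loci)
    by_var: dict[str, list] = {}
    for s in scans:
        if s.candidates is None:
            raise ValueError(f"scan {s.env_var} (k={s.k}) not calibrated")
        if len(s.candidates) != L:
            raise ValueError("scan locus set inconsistent with the locus table")
        by_var.setdefault(s.env_var, []).append(s)
    provenance = {}
    union = np.zeros(L, dtype=bool)
    for var, var_scans in by_var.items():
        flags = np.ones(L, dtype=bool)
        for s in var_scans:
            flags &= s.candidates
        provenance[var] = set(np.flatnonzero(flags).tolist())
        union |= flags
    if fst_scan is not None:
        if len(fst_scan.candidates) != L:
            raise ValueError("FST scan locus set inconsistent with the locus table")
        provenance["fst"] = set(np.flatnonzero(fst_scan.candidates).tolist())
        union |= fst_scan.candidates
    idx = np.flatnonzero(union)
    contigs = sorted(set(loci["contig"].to_numpy()[idx].tolist()))
    return CandidateSet(snp_indices=idx, contigs=contigs, provenance=provenance)


def compare_candidate_proportions(
    count_a: int, total_a: int, count_b: int, total_b: int,
    continuity: bool = True, arrangement: str = "printed",
) -> tuple[float, float]:
    """Chi-square comparison of candidate-contig counts between two datasets.

    ``arrangement="printed"`` forms the 2x2 table [[count_a, total_a],
    [count_b, total_b]] (candidate counts against totals);
    ``arrangement="conventional"`` uses candidates vs non-candidates.
    Yates continuity correction is applied when ``continuity`` is true.
    """
    if min(count_a, total_a, count_b, total_b) < 0 or count_a > total_a or count_b > total_b:
        raise ValueError("counts must be nonnegative and not exceed totals")
    if arrangement == "printed":
        table = np.array([[count_a, total_a], [count_b, total_b]], dtype=float)
    elif arrangement == "conventional":
        table = np.array(
            [[count_a, total_a - count_a], [count_b, total_b - count_b]], dtype=float
        )
    else:
        raise ValueError("arrangement must be 'printed' or 'conventional'")
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    if (expected < 1).any():
        warnings.warn("expected cell count below 1: chi-square approximation is poor")
    a, b = table[0]
    c, d = table[1]
    if continuity:
        num = n * max(abs(a * d - b * c) - n / 2, 0.0) ** 2
    else:
        num = n * (a * d - b * c) ** 2
    x2 = float(num / (row[0] * row[1] * col[0] * col[1]))
    p = float(stats.chi2.sf(x2, df=1))
    return x2, p


def candidate_summary(
    candidates: CandidateSet, loci: pd.DataFrame
) -> pd.DataFrame:
    """Per-source and total candidate counts at SNP and contig level."""
    contig = loci["contig"].to_numpy()
    rows = []
    for source, snps in sorted(candidates.provenance.items()):
        snps = sorted(snps)
        rows.append({
            "source": source,
            "n_snps": len(snps),
            "n_contigs": len(set(contig[list(snps)])) if snps else 0,
        })
    rows.append({
        "source": "union",
        "n_snps": candidates.n_snps,
        "n_contigs": candidates.n_contigs,
    })
    return pd.DataFrame(rows)
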