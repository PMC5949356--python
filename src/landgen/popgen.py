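"""Genetic-diversity statistics, relatedness, and LD-based effective size.

All statistics work on a :class:`~landgen.genio.GenotypeMatrix` of biallelic
dosages and are invariant to swapping the reference/alternate allele labels.
Confidence intervals are percentile bootstraps over loci (or sites), seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

DEFAULT_N_BOOT = 10_000


def _bootstrap_ci(values: np.ndarray, n_boot: int, seed: int, level: float = 0.95):
    """Percentile bootstrap CI for the mean of per-locus values."""
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return (np.nan, np.nan)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def _chrom_counts(geno: GenotypeMatrix):
    ok = geno.called()
    n_chrom = 2 * ok.sum(axis=0)
    alt = np.where(ok, geno.calls, 0).sum(axis=0)
    return n_chrom, alt


# ---------------------------------------------------------------------------
# diversity


def expected_heterozygosity(
    geno: GenotypeMatrix, n_boot: int = DEFAULT_N_BOOT, seed: int = 0, corrected: bool = True
):
    """Per-locus expected heterozygosity 2p(1-p) * n/(n-1), mean and CI.

    ``n`` counts genotyped chromosomes; loci with fewer than 2 chromosomes
    are excluded.  ``corrected=False`` drops the small-sample factor.
    """
    n_chrom, alt = _chrom_counts(geno)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(n_chrom, 1)
        he = 2 * p * (1 - p)
        if corrected:
            he = he * n_chrom / np.maximum(n_chrom - 1, 1)
    he = np.where(n_chrom >= 2, he, np.nan)
    mean = float(np.nanmean(he)) if np.isfinite(he).any() else np.nan
    ci = _bootstrap_ci(he, n_boot, seed)
    return he, mean, ci


def individual_inbreeding(
    geno: GenotypeMatrix, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
):
    """Method-of-moments inbreeding F per individual, population mean and CI.

    F_j = (O_hom - E_hom) / (L_j - E_hom) where E_hom sums the per-locus
    expected homozygosity 1 - 2p(1-p) n/(n-1) over individual j's genotyped
    loci.  Degenerate individuals (L_j == E_hom) are NaN.
    """
    n_chrom, alt = _chrom_counts(geno)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(n_chrom, 1)
        he = 2 * p * (1 - p) * n_chrom / np.maximum(n_chrom - 1, 1)
    usable = n_chrom >= 2
    ok = geno.called() & usable[None, :]
    e_hom = (ok * (1 - np.nan_to_num(he))).sum(axis=1)
    o_hom = (ok & (geno.calls != 1)).sum(axis=1)
    l_j = ok.sum(axis=1)
    denom = l_j - e_hom
    f = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / np.where(denom == 0, 1, denom), np.nan)
    mean = float(np.nanmean(f))
    # CI by bootstrap over individuals
    ci = _bootstrap_ci(f, n_boot, seed)
    return f, mean, ci


def nucleotide_diversity(
    geno: GenotypeMatrix, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
):
    """Per-site pi = 2 j (n-j) / (n (n-1)), mean over sites and CI."""
    n_chrom, alt = _chrom_counts(geno)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * alt * (n_chrom - alt) / (n_chrom * (n_chrom - 1.0))
    pi = np.where(n_chrom >= 2, pi, np.nan)
    mean = float(np.nanmean(pi)) if np.isfinite(pi).any() else np.nan
    ci = _bootstrap_ci(pi, n_boot, seed)
    return pi, mean, ci


def tajima_constants(n: int) -> dict:
    """The standard normalising constants for Tajima's D at n chromosomes."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(geno: GenotypeMatrix, n_boot: int = DEFAULT_N_BOOT, seed: int = 0):
    """Tajima's D over the segregating sites of the matrix, with bootstrap CI.

    With missing data the constants use the (rounded) mean number of
    genotyped chromosomes across segregating sites.
    """
    n_chrom, alt = _chrom_counts(geno)
    seg = (alt > 0) & (alt < n_chrom) & (n_chrom >= 3)
    s = int(seg.sum())
    if s == 0:
        return np.nan, (np.nan, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = 2.0 * alt * (n_chrom - alt) / (n_chrom * (n_chrom - 1.0))
    pi_site = pi_site[seg]
    n_eff = int(round(n_chrom[seg].mean()))

    def d_of(pi_vals):
        cc = tajima_constants(n_eff)
        s_i = len(pi_vals)
        if s_i == 0:
            return np.nan
        var = cc["e1"] * s_i + cc["e2"] * s_i * (s_i - 1)
        if var <= 0:
            return np.nan
        return (pi_vals.sum() - s_i / cc["a1"]) / np.sqrt(var)

    d = float(d_of(pi_site))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, s, size=(min(n_boot, DEFAULT_N_BOOT), s))
    boots = np.array([d_of(pi_site[row]) for row in idx])
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return d, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# relatedness


@dataclass
class RelatednessMatrix:
    matrix: np.ndarray          # n x n, NaN where undefined
    n_loci_used: np.ndarray     # n x n pair-complete locus counts
    sample_ids: list

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def yang_relatedness(geno: GenotypeMatrix) -> RelatednessMatrix:
    """Genome-wide allele-sharing relationship matrix (Yang-style GRM).

    Off-diagonal A_jk averages (x_j - 2p)(x_k - 2p) / (2p(1-p)) over loci
    genotyped in both individuals; the diagonal uses the inbreeding-corrected
    form so A_jj = 1 + F_j.  Fixed loci (p in {0,1}) are excluded.
    """
    p = geno.allele_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    x = geno.calls[:, poly].astype(float)
    p = p[poly]
    ok = x != MISSING
    denom = 2 * p * (1 - p)

    z = np.where(ok, (x - 2 * p), 0.0) / np.sqrt(denom)
    m = ok.astype(float)
    num = z @ z.T
    counts = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(counts > 0, num / np.maximum(counts, 1), np.nan)

    # diagonal: 1 + mean_l (x^2 - (1+2p)x + 2p^2) / (2p(1-p))
    diag_terms = np.where(ok, (x**2 - (1 + 2 * p) * x + 2 * p**2) / denom, 0.0)
    m_j = ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = np.where(m_j > 0, 1 + diag_terms.sum(axis=1) / np.maximum(m_j, 1), np.nan)
    np.fill_diagonal(a, diag)
    np.fill_diagonal(counts, m_j)
    return RelatednessMatrix(a, counts.astype(int), list(geno.samples.index))


def individual_heterozygosity(geno: GenotypeMatrix) -> np.ndarray:
    """Proportion of heterozygous calls per individual (multilocus H_O)."""
    ok = geno.called()
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(ok.sum(1) > 0, (geno.calls == 1).sum(1) / np.maximum(ok.sum(1), 1), np.nan)


# ---------------------------------------------------------------------------
# effective population size


@dataclass
class NeEstimate:
    ne: float                   # may be inf
    ci: tuple
    maf_min: float
    n_pairs: int
    mean_r2: float
    r2_drift: float


def _r2_expectation(s: float) -> float:
    """Sample-size expectation of composite r^2 under random mating."""
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def _ne_from_r2drift(r2d: float) -> float:
    if r2d <= 0:
        return np.inf
    disc = 1.0 / 9.0 - 2.76 * r2d
    if disc < 0:
        disc = 0.0
    return (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2d)


def ne_ld(geno: GenotypeMatrix, maf_min: float = 0.05) -> NeEstimate:
    """LD effective population size from composite r^2 between unlinked loci.

    Uses squared Pearson correlation of dosages (Burrows composite measure)
    across all pairs of loci on *different* contigs, subtracts the
    sample-size expectation, and inverts the unlinked-locus drift relation.
    CI by delete-one-locus jackknife.
    """
    maf = np.nan_to_num(geno.maf(), nan=0.0)
    keep = maf >= maf_min
    sub = geno.subset_loci(keep)
    if sub.n_loci < 2:
        raise ValueError("fewer than 2 loci pass the MAF screen")
    x = np.ma.masked_equal(sub.calls.astype(float), MISSING)
    r = np.asarray(np.ma.corrcoef(x, rowvar=False).filled(np.nan))
    # Burrows' composite r applies an n/(n-1) factor to the covariance but
    # not the denominator; this is what gives the 1/S + 3.19/S^2 null mean
    okm = sub.called().astype(float)
    pair_n = okm.T @ okm
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (r * pair_n / np.maximum(pair_n - 1, 1)) ** 2
    contigs = sub.loci["contig"].to_numpy()
    diff = contigs[:, None] != contigs[None, :]
    iu = np.triu_indices(sub.n_loci, k=1)
    use = diff[iu] & np.isfinite(r2[iu])
    vals = r2[iu][use]
    n_pairs = int(use.sum())
    if n_pairs == 0:
        return NeEstimate(np.nan, (np.nan, np.nan), maf_min, 0, np.nan, np.nan)
    # sample size: mean pair-complete individuals across used pairs
    ok = sub.called().astype(float)
    s_bar = float(np.mean((ok.T @ ok)[iu][use]))
    mean_r2 = float(vals.mean())
    r2d = mean_r2 - _r2_expectation(s_bar)
    ne = _ne_from_r2drift(r2d)

    # jackknife over loci
    li, lj = iu[0][use], iu[1][use]
    total = vals.sum()
    ne_jack = []
    for l in range(sub.n_loci):
        mask = (li != l) & (lj != l)
        n_l = int(mask.sum())
        if n_l == 0:
            continue
        m = (total - vals[~mask].sum()) / n_l
        ne_jack.append(_ne_from_r2drift(m - _r2_expectation(s_bar)))
    ne_jack = np.array(ne_jack)
    finite = ne_jack[np.isfinite(ne_jack)]
    if len(finite) >= 2 and np.isfinite(ne):
        g = len(finite)
        se = np.sqrt((g - 1) / g * ((finite - finite.mean()) ** 2).sum())
        ci = (max(float(ne - 1.96 * se), 0.0), float(ne + 1.96 * se))
    else:
        lo = float(np.nanmin(ne_jack)) if len(ne_jack) else np.nan
        ci = (lo, np.inf)
    return NeEstimate(float(ne), ci, maf_min, n_pairs, mean_r2, float(r2d))


# ---------------------------------------------------------------------------
# report


def diversity_report(
    geno: GenotypeMatrix,
    populations: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    ne: bool = True,
) -> pd.DataFrame:
    """Per-population diversity table: N, H_E, F, pi, Tajima's D, Ne (with CIs)."""
    if populations is None:
        populations = np.zeros(geno.n_samples, dtype=int)
    populations = np.asarray(populations)
    rows = []
    for pop in np.unique(populations):
        sub = geno.subset_samples(populations == pop)
        _, he, he_ci = expected_heterozygosity(sub, n_boot=n_boot, seed=seed)
        _, f, f_ci = individual_inbreeding(sub, n_boot=n_boot, seed=seed + 1)
        _, pi, pi_ci = nucleotide_diversity(sub, n_boot=n_boot, seed=seed + 2)
        d, d_ci = tajimas_d(sub, n_boot=n_boot, seed=seed + 3)
        row = {
            "population": pop,
            "N": sub.n_samples,
            "He": he, "He_lo": he_ci[0], "He_hi": he_ci[1],
            "F": f, "F_lo": f_ci[0], "F_hi": f_ci[1],
            "pi": pi, "pi_lo": pi_ci[0], "pi_hi": pi_ci[1],
            "TajimaD": d, "TajimaD_lo": d_ci[0], "TajimaD_hi": d_ci[1],
        }
        if ne:
            try:
                est = ne_ld(sub)
                row.update(Ne=est.ne, Ne_lo=est.ci[0], Ne_hi=est.ci[1])
            except ValueError:
                row.update(Ne=np.nan, Ne_lo=np.nan, Ne_hi=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
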