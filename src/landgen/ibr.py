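"""Pairwise mixed models for isolation-by-resistance (MLPE) and model selection.

The MLPE model regresses a pairwise genetic response (here Yang relatedness)
on one or more pairwise distance predictors, with residual correlation 2*rho
between pairs sharing exactly one individual.  Because the pair-sharing
graph is the triangular graph, the implied covariance

    C(rho) = (1 - 4 rho) I + 2 rho B B'

(B the pair-by-individual incidence matrix) admits closed-form inverses and
determinants via Woodbury, so likelihoods are exact and cheap even for tens
of thousands of pairs.  Positive-definiteness requires rho < 1/4.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

RHO_MAX = 0.25 - 1e-6


def full_pair_index(n: int) -> np.ndarray:
    """All C(n,2) ordered pairs (i<j) in condensed order."""
    return np.array([(i, j) for i in range(n) for j in range(i + 1, n)], dtype=np.int64)


@dataclass
class MLPEFit:
    predictors: list
    beta: np.ndarray            # intercept first
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rho: float
    sigma2: float
    loglik: float
    n_pairs: int
    n_individuals: int
    aicc: float
    method: str = "ML"
    response: str = "y"

    @property
    def k_params(self) -> int:
        # slopes + intercept + rho + sigma^2
        return len(self.predictors) + 3

    def summary(self) -> pd.DataFrame:
        names = ["(intercept)"] + list(self.predictors)
        return pd.DataFrame(
            {"predictor": names, "estimate": self.beta, "se": self.se,
             "t_value": self.t, "p_value": self.p, "df": self.n_pairs}
        )


class _PairStructure:
    """Precomputed incidence bookkeeping for one set of individuals."""

    def __init__(self, pair_index: np.ndarray, n: int):
        m = len(pair_index)
        if m != n * (n - 1) // 2:
            raise ValueError("MLPE requires the complete set of C(n,2) pairs")
        self.n = n
        self.m = m
        self.i = pair_index[:, 0]
        self.j = pair_index[:, 1]

    def bt(self, u: np.ndarray) -> np.ndarray:
        """B'u: per-individual sums over incident pairs (columns supported)."""
        u = np.atleast_2d(u.T).T  # (m, q)
        out = np.zeros((self.n, u.shape[1]))
        np.add.at(out, self.i, u)
        np.add.at(out, self.j, u)
        return out


def _quad(ps: _PairStructure, rho: float, U: np.ndarray, W: np.ndarray) -> np.ndarray:
    """U' C(rho)^{-1} W for column blocks U, W using Woodbury."""
    a = 1.0 - 4.0 * rho
    if a <= 0:
        raise ValueError("rho out of the positive-definite range")
    U = U.reshape(ps.m, -1)
    W = W.reshape(ps.m, -1)
    base = U.T @ W
    if rho == 0.0:
        return base
    c = 2.0 * rho / a
    bu = ps.bt(U)
    bw = ps.bt(W)
    # M = alpha I + beta J with alpha = 1 + c(n-2), beta = c
    alpha = 1.0 + c * (ps.n - 2)
    beta = c
    denom = alpha + beta * ps.n
    minv_bw = (bw - (beta / denom) * bw.sum(axis=0, keepdims=True)) / alpha
    return (base - c * (bu.T @ minv_bw)) / a


def _logdet(ps: _PairStructure, rho: float) -> float:
    a = 1.0 - 4.0 * rho
    return float(
        (ps.m - ps.n) * np.log(a)
        + (ps.n - 1) * np.log(a + 2 * rho * (ps.n - 2))
        + np.log(a + 2 * rho * (2 * ps.n - 2))
    )


def mlpe_loglik(ps: _PairStructure, rho: float, y: np.ndarray, X: np.ndarray, method: str = "ML"):
    """Profiled (beta, sigma^2 out) log-likelihood at a given rho."""
    m, p = X.shape
    G = _quad(ps, rho, X, X)
    b = _quad(ps, rho, X, y).ravel()
    beta = np.linalg.solve(G, b)
    r = y - X @ beta
    q = float(_quad(ps, rho, r, r).item())
    ld = _logdet(ps, rho)
    if method == "REML":
        sigma2 = q / (m - p)
        ll = -0.5 * (
            (m - p) * np.log(2 * np.pi * sigma2) + ld
            + np.linalg.slogdet(G)[1] + (m - p)
        )
    else:
        sigma2 = q / m
        ll = -0.5 * (m * np.log(2 * np.pi * sigma2) + ld + m)
    return float(ll), beta, sigma2, G, q


def mlpe_fit(
    y_pairs: np.ndarray,
    X: np.ndarray | pd.DataFrame | None,
    pair_index: np.ndarray,
    method: str = "ML",
    predictor_names: list | None = None,
    response: str = "y",
) -> MLPEFit:
    """Fit an MLPE regression of a pairwise response on distance predictors.

    ``X`` holds the predictor columns (no intercept column; one is added);
    ``pair_index`` is the (m, 2) array of individual indices per pair and
    must cover all C(n,2) pairs.  rho is maximised by bounded 1-D search.
    """
    y = np.asarray(y_pairs, dtype=float)
    if isinstance(X, pd.DataFrame):
        predictor_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    if X is None or X.size == 0:
        X = np.empty((len(y), 0))
        predictor_names = []
    elif X.ndim == 1:
        X = X[:, None]
    if predictor_names is None:
        predictor_names = [f"x{i}" for i in range(X.shape[1])]
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in response or predictors")
    n = int(pair_index.max()) + 1
    ps = _PairStructure(np.asarray(pair_index), n)
    Xd = np.column_stack([np.ones(len(y)), X])

    def neg_profile(rho):
        return -mlpe_loglik(ps, rho, y, Xd, method)[0]

    res = minimize_scalar(neg_profile, bounds=(0.0, RHO_MAX), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(res.x)
    # keep the boundary rho=0 if it is as good (optimizer may sit at interior)
    if neg_profile(0.0) <= res.fun + 1e-10:
        rho = 0.0
    ll, beta, sigma2, G, q = mlpe_loglik(ps, rho, y, Xd, method)
    m, p = Xd.shape
    cov = q / (m - p) * np.linalg.inv(G)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df=m)
    k = X.shape[1] + 3
    aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (m - k - 1)
    return MLPEFit(
        predictors=list(predictor_names), beta=beta, se=se, t=t, p=pvals,
        rho=rho, sigma2=sigma2, loglik=ll, n_pairs=m, n_individuals=n,
        aicc=aicc, method=method, response=response,
    )


def aicc_of(loglik: float, k: int, n: int) -> float:
    """Sample-size-corrected AIC."""
    return -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# model tables


@dataclass
class ModelTable:
    table: pd.DataFrame         # model, loglik, aicc, delta_aicc, weight, best
    fits: list = field(default_factory=list)

    def best_set(self, delta_best: float = 2.0):
        mask = self.table["delta_aicc"] < delta_best
        return self.table[mask], [self.fits[i] for i in np.flatnonzero(mask.to_numpy())]


def _finalize_table(rows, fits) -> ModelTable:
    df = pd.DataFrame(rows)
    order = np.lexsort((df["model"].to_numpy(), df["aicc"].to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    fits = [fits[i] for i in order]
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    w = np.exp(-df["delta_aicc"].to_numpy() / 2)
    df["weight"] = w / w.sum()
    df["best"] = df["delta_aicc"] < 2.0
    return ModelTable(df, fits)


def _node_mean_covariate(condensed: np.ndarray, pair_index: np.ndarray) -> np.ndarray:
    """Sum of the two individuals' mean distances to everyone else."""
    from scipy.spatial.distance import squareform

    m = squareform(np.asarray(condensed, dtype=float))
    row_mean = m.sum(axis=1) / (m.shape[0] - 1)
    return row_mean[pair_index[:, 0]] + row_mean[pair_index[:, 1]]


def rank_candidate_surfaces(
    y_pairs: np.ndarray, distances_by_name: dict, pair_index: np.ndarray,
    node_effects: bool = True,
) -> tuple[ModelTable, dict]:
    """Univariate MLPE screening of resistance hypotheses.

    With ``node_effects`` (the default) each hypothesis' model also carries
    that hypothesis' node-mean covariate (the sum of the pair's mean
    distances to all other individuals).  Genome-wide relationship
    estimates are *relative* to the sample — the estimator centres on
    sample allele frequencies, so the expected relatedness surface is the
    double-centred transform of the underlying kinship — and the node-mean
    term lets each candidate express exactly that structure.  Every model
    has the same parameter count, so the AICc race stays fair.

    Returns the AICc-ranked table plus the screening winners: the best
    land-cover surface overall and the best polarity per continuous
    variable (names ``<var>_raw`` / ``<var>_inv``).
    """
    if len(distances_by_name) < 2:
        raise ValueError("need at least two hypotheses to rank")
    rows, fits = [], []
    for name in sorted(distances_by_name):
        d = np.asarray(distances_by_name[name], dtype=float)
        if node_effects:
            X = np.column_stack([d, _node_mean_covariate(d, pair_index)])
            names = [name, f"{name}__node"]
        else:
            X = d[:, None]
            names = [name]
        fit = mlpe_fit(y_pairs, X, pair_index, predictor_names=names)
        rows.append({"model": name, "loglik": fit.loglik, "aicc": fit.aicc})
        fits.append(fit)
    mt = _finalize_table(rows, fits)

    winners: dict[str, str] = {}
    ranked = mt.table["model"].tolist()
    landcover = [nm for nm in ranked if nm.startswith("landcover")]
    if landcover:
        winners["landcover"] = landcover[0]
    bases = {}
    for nm in ranked:
        if nm.endswith("_raw") or nm.endswith("_inv"):
            base = nm.rsplit("_", 1)[0]
            bases.setdefault(base, nm)   # first occurrence = best AICc
    winners.update(bases)
    return mt, winners


def dredge_mlpe(
    y_pairs: np.ndarray,
    predictors: dict,
    pair_index: np.ndarray,
    collinearity_max: float = 0.6,
    delta_best: float = 2.0,
) -> ModelTable:
    """All-subsets MLPE model selection with a collinearity constraint.

    Enumerates every subset of predictors that contains no pair with
    |Pearson r| >= ``collinearity_max`` between distance vectors, fits each
    by ML, and ranks by AICc with Akaike weights over all fitted models.
    """
    names = sorted(predictors)
    if len(names) > 12:
        raise ValueError("more than 12 predictors: refusing 2^p enumeration")
    vecs = {nm: np.asarray(predictors[nm], dtype=float) for nm in names}
    forbidden = set()
    for a, b in itertools.combinations(names, 2):
        r = np.corrcoef(vecs[a], vecs[b])[0, 1]
        if abs(r) >= collinearity_max:
            forbidden.add((a, b))

    rows, fits = [], []
    any_fit = False
    for size in range(0, len(names) + 1):
        for combo in itertools.combinations(names, size):
            if any((a, b) in forbidden for a, b in itertools.combinations(combo, 2)):
                continue
            X = np.column_stack([vecs[nm] for nm in combo]) if combo else None
            fit = mlpe_fit(y_pairs, X, pair_index, predictor_names=list(combo))
            label = " + ".join(combo) if combo else "(intercept)"
            rows.append({"model": label, "loglik": fit.loglik, "aicc": fit.aicc})
            fits.append(fit)
            if combo:
                any_fit = True
    if not any_fit:
        warnings.warn("all predictor subsets excluded by collinearity; intercept-only model returned")
    mt = _finalize_table(rows, fits)
    mt.table["best"] = mt.table["delta_aicc"] < delta_best
    return mt


def lrt(full: MLPEFit, reduced: MLPEFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML MLPE fits."""
    if full.method != "ML" or reduced.method != "ML":
        raise ValueError("LRT requires ML fits")
    if not set(reduced.predictors) <= set(full.predictors):
        raise ValueError("models are not nested")
    df = len(full.predictors) - len(reduced.predictors)
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < 0:
        warnings.warn(f"negative LRT statistic {stat:.3g} clipped to 0")
        stat = 0.0
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), df, p


def model_average(fits: list, weights: np.ndarray | None = None) -> pd.DataFrame:
    """Full model averaging over a best set of MLPE fits.

    Absent predictors contribute beta = 0; the unconditional SE combines
    within-model variance and between-model spread.
    """
    if len(fits) == 0:
        raise ValueError("empty model set")
    if weights is None:
        aicc = np.array([f.aicc for f in fits])
        delta = aicc - aicc.min()
        weights = np.exp(-delta / 2)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    all_preds = sorted({p for f in fits for p in f.predictors} | {"(intercept)"})
    rows = []
    for pred in all_preds:
        betas, ses = [], []
        for f in fits:
            names = ["(intercept)"] + list(f.predictors)
            if pred in names:
                idx = names.index(pred)
                betas.append(f.beta[idx])
                ses.append(f.se[idx])
            else:
                betas.append(0.0)
                ses.append(0.0)
        betas = np.array(betas); ses = np.array(ses)
        bbar = float(weights @ betas)
        se_u = float(np.sqrt(weights @ (ses**2 + (betas - bbar) ** 2)))
        rows.append({"predictor": pred, "estimate": bbar, "se_unconditional": se_u})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# highland-history mixed models


def lmm_highland(
    indiv_stats: pd.DataFrame,
    responses: tuple = ("He_ind", "F"),
    predictors: tuple = ("area", "isolation"),
    group: str = "highland_id",
) -> dict:
    """Random-intercept models of individual diversity on highland history.

    Per response, fits the full ML mixed model (random intercept per
    highland) and reduced models dropping each predictor; reports slope
    estimates and per-predictor LRT p-values plus basic diagnostics.
    Falls back to OLS with a warning when only one highland is present.
    """
    import statsmodels.formula.api as smf

    data = indiv_stats.dropna(subset=list(responses) + list(predictors) + [group]).copy()
    single_group = data[group].nunique() < 2
    out = {}
    for resp in responses:
        if float(np.var(data[resp])) < 1e-14:
            out[resp] = {
                "slopes": {p: 0.0 for p in predictors},
                "lrt_p": {p: 1.0 for p in predictors},
                "loglik": np.nan, "single_group": single_group,
                "diagnostics": {},
            }
            continue

        def fit(terms):
            rhs = " + ".join(terms) if terms else "1"
            formula = f"{resp} ~ {rhs}"
            if single_group:
                return smf.ols(formula, data=data).fit()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return smf.mixedlm(formula, data=data, groups=data[group]).fit(reml=False)

        if single_group:
            warnings.warn("single highland: random effect unidentifiable, using fixed-intercept model")
        full = fit(list(predictors))
        lrt_p, slopes = {}, {}
        for pred in predictors:
            reduced = fit([p for p in predictors if p != pred])
            stat = max(0.0, 2 * (full.llf - reduced.llf))
            lrt_p[pred] = float(stats.chi2.sf(stat, 1))
            slopes[pred] = float(full.params[pred])
        out[resp] = {
            "slopes": slopes,
            "lrt_p": lrt_p,
            "loglik": float(full.llf),
            "single_group": single_group,
            "diagnostics": {
                "fitted": np.asarray(full.fittedvalues, dtype=float),
                "residuals": np.asarray(data[resp], dtype=float) - np.asarray(full.fittedvalues, dtype=float),
                "predictor_corr": data[list(predictors)].corr().to_numpy(),
            },
        }
    return out
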