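"""Resistance surfaces, circuit-theory distances, and spatial autocorrelograms.

A resistance surface is a raster of per-cell movement costs; each surface is
one quantitative hypothesis about landscape permeability.  Pairwise
effective resistances between sample locations are computed on the grid
graph (8-connected, average-conductance edges, diagonal edges scaled by
1/sqrt(2)) via the graph Laplacian, which reproduces circuit-theory
resistance distances exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from scipy.spatial.distance import pdist

from .genio import Raster

SQRT2 = np.sqrt(2.0)


@dataclass
class ResistanceHypothesis:
    name: str
    raster: Raster
    provenance: dict

    def __post_init__(self):
        data = self.raster.data
        valid = data != self.raster.nodata
        if np.any(data[valid] <= 0):
            raise ValueError(f"surface {self.name}: non-positive resistance cells")


@dataclass
class PairwiseDistances:
    name: str
    values: np.ndarray          # condensed, C(n,2), pair order (i<j)
    sample_ids: list
    units: str

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.values)


# ---------------------------------------------------------------------------
# surface construction


def _rescale_unit(data: np.ndarray, zero_replacement: float) -> np.ndarray:
    """Min-max rescale to (0, 1]; a constant raster maps to all ones."""
    lo, hi = float(np.nanmin(data)), float(np.nanmax(data))
    if hi - lo < 1e-300:
        out = np.ones_like(data, dtype=float)
    else:
        out = (data - lo) / (hi - lo)
    out[out <= 0] = zero_replacement
    return out


def build_surfaces(
    bundle,
    samples: pd.DataFrame,
    classes: tuple = ("montane_savanna", "forest", "mine"),
    low: float = 0.1,
    high: float = 0.9,
    buffer_m: float = 5000.0,
    zero_replacement: float = 0.001,
) -> list[ResistanceHypothesis]:
    """Build the full hypothesis set from a landscape bundle.

    Per land-cover year and main class, two binary surfaces (class low /
    others high, and the inverse); per continuous raster, a raw and an
    inverted min-max-rescaled surface; plus one uniform null at ``low``.
    All surfaces are cropped to the sample bounding box plus ``buffer_m``.
    """
    xmin, xmax = samples["x"].min() - buffer_m, samples["x"].max() + buffer_m
    ymin, ymax = samples["y"].min() - buffer_m, samples["y"].max() + buffer_m

    def crop(r: Raster) -> Raster:
        out = r.crop(xmin, ymin, xmax, ymax)
        for _, s in samples.iterrows():
            try:
                out.cell_index(s["x"], s["y"])
            except ValueError:
                raise ValueError(f"sample {s.name} outside raster after crop")
        return out

    surfaces = []
    for year, lc in sorted(bundle.land_cover_by_year.items()):
        lc_c = crop(lc)
        for cls in classes:
            code = bundle.class_codes[cls]
            is_cls = lc_c.data == code
            for polarity, cls_val, other_val in (("low", low, high), ("high", high, low)):
                data = np.where(is_cls, cls_val, other_val).astype(float)
                data[data <= 0] = zero_replacement
                surfaces.append(
                    ResistanceHypothesis(
                        name=f"landcover{year}_{cls}_{polarity}",
                        raster=Raster(data, lc_c.xllcorner, lc_c.yllcorner, lc_c.cellsize, lc_c.nodata),
                        provenance={"source": f"landcover_{year}", "class": cls, "polarity": polarity},
                    )
                )

    continuous = {"elevation": bundle.elevation, "roughness": bundle.roughness}
    continuous.update(bundle.climate)
    for var, r in continuous.items():
        r_c = crop(r)
        raw = _rescale_unit(r_c.data.astype(float), zero_replacement)
        inv_src = (np.nanmax(r_c.data) + np.nanmin(r_c.data)) - r_c.data.astype(float)
        inv = _rescale_unit(inv_src, zero_replacement)
        for suffix, data in (("raw", raw), ("inv", inv)):
            surfaces.append(
                ResistanceHypothesis(
                    name=f"{var}_{suffix}",
                    raster=Raster(data, r_c.xllcorner, r_c.yllcorner, r_c.cellsize, r_c.nodata),
                    provenance={"source": var, "transform": suffix},
                )
            )

    any_grid = surfaces[0].raster
    surfaces.append(
        ResistanceHypothesis(
            name="null",
            raster=Raster(
                np.full(any_grid.shape, low),
                any_grid.xllcorner, any_grid.yllcorner, any_grid.cellsize, any_grid.nodata,
            ),
            provenance={"source": "uniform", "value": low},
        )
    )
    names = [s.name for s in surfaces]
    if len(set(names)) != len(names):
        raise ValueError("duplicate surface names")
    return surfaces


# ---------------------------------------------------------------------------
# effective resistance


def _grid_laplacian(resistance: np.ndarray, nodata: float, connectivity: int = 8):
    """Sparse Laplacian of the cell graph; returns (L, node index grid)."""
    nrows, ncols = resistance.shape
    valid = (resistance != nodata) & np.isfinite(resistance) & (resistance > 0)
    node = -np.ones((nrows, ncols), dtype=np.int64)
    node[valid] = np.arange(valid.sum())
    n = int(valid.sum())
    cond = np.where(valid, 1.0 / np.where(valid, resistance, 1.0), 0.0)

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offsets += [(1, 1, 1.0 / SQRT2), (1, -1, 1.0 / SQRT2)]
    rows, cols, vals = [], [], []
    for dr, dc, scale in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        ok = valid[r0, c0] & valid[r1, c1]
        a = node[r0, c0][ok]
        b = node[r1, c1][ok]
        w = scale * 0.5 * (cond[r0, c0][ok] + cond[r1, c1][ok])
        rows.append(a); cols.append(b); vals.append(w)
    i = np.concatenate(rows); j = np.concatenate(cols); w = np.concatenate(vals)
    adj = sp.coo_matrix((np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n)).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sp.diags(deg) - adj
    return lap.tocsc(), node


def resistance_distance(
    surface: ResistanceHypothesis, samples: pd.DataFrame, connectivity: int = 8
) -> PairwiseDistances:
    """Pairwise effective resistance between sample locations.

    Nodes are raster cells; edge conductance is the mean of the two cell
    conductances, diagonal neighbours scaled by 1/sqrt(2).  Exact solve via
    sparse LU of the grounded Laplacian, one solve per distinct sample node.
    Pairs in different graph components get ``inf``.
    """
    r = surface.raster
    lap, node = _grid_laplacian(r.data, r.nodata, connectivity)
    n_nodes = lap.shape[0]

    sample_nodes = []
    for sid, s in samples.iterrows():
        row, col = r.cell_index(s["x"], s["y"])
        nd = node[row, col]
        if nd < 0:
            raise ValueError(f"sample {sid} sits on a NODATA cell of {surface.name}")
        sample_nodes.append(int(nd))
    sample_nodes = np.array(sample_nodes)

    adj = sp.diags(lap.diagonal()) - lap
    n_comp, labels = connected_components(adj, directed=False)

    # grounded potentials per component
    pot = {}
    for comp in np.unique(labels[sample_nodes]):
        members = np.flatnonzero(labels == comp)
        ground = members[-1]
        keep = np.ones(n_nodes, dtype=bool)
        keep[labels != comp] = False
        keep[ground] = False
        idx = np.flatnonzero(keep)
        remap = -np.ones(n_nodes, dtype=np.int64)
        remap[idx] = np.arange(len(idx))
        lred = lap[idx][:, idx]
        solver = splu(lred.tocsc())
        for nd in np.unique(sample_nodes[labels[sample_nodes] == comp]):
            rhs = np.zeros(len(idx))
            if nd != ground:
                rhs[remap[nd]] = 1.0
            v = solver.solve(rhs)
            full = np.zeros(n_nodes)
            full[idx] = v
            pot[nd] = full

    m = len(sample_nodes)
    out = []
    for a in range(m):
        for b in range(a + 1, m):
            i, j = sample_nodes[a], sample_nodes[b]
            if labels[i] != labels[j]:
                out.append(np.inf)
            elif i == j:
                out.append(0.0)
            else:
                vi, vj = pot[i], pot[j]
                out.append(float(vi[i] - vi[j] - vj[i] + vj[j]))
    return PairwiseDistances(surface.name, np.array(out), list(samples.index), "effective_resistance")


def geographic_distance(samples: pd.DataFrame) -> PairwiseDistances:
    """Euclidean distances (metres) in the same condensed pair order."""
    xy = samples[["x", "y"]].to_numpy(dtype=float)
    return PairwiseDistances("geographic", pdist(xy), list(samples.index), "m")


# ---------------------------------------------------------------------------
# autocorrelogram


@dataclass
class LoessEnvelope:
    grid: np.ndarray
    fit: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    null_mean: np.ndarray
    n_perm: int
    span: float
    significant_up_to: float    # largest grid distance with contiguous excess


def loess_autocorrelogram(
    relatedness: np.ndarray,
    geo: PairwiseDistances,
    span: float = 0.5,
    n_perm: int = 999,
    seed: int = 0,
    n_grid: int = 100,
) -> LoessEnvelope:
    """LOESS of pairwise relatedness on geographic distance with a null band.

    The null permutes individual labels of the relatedness matrix (rows and
    columns jointly), refits, and takes pointwise 2.5/97.5 percentiles.
    ``significant_up_to`` is the largest grid distance below which the
    observed curve exceeds the upper bound contiguously from the origin.
    """
    import statsmodels.api as sm

    n = relatedness.shape[0]
    iu = np.triu_indices(n, k=1)
    d = geo.values
    if len(d) != len(iu[0]):
        raise ValueError("relatedness and distance pair counts differ")
    if span * len(d) < 3:
        raise ValueError("span too small: fewer than 3 points per neighbourhood; increase span")
    grid = np.linspace(d.min(), d.max(), n_grid)

    def fit_curve(mat):
        y = mat[iu]
        return sm.nonparametric.lowess(y, d, frac=span, xvals=grid)

    obs = fit_curve(relatedness)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_grid))
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = fit_curve(relatedness[np.ix_(perm, perm)])
    lo, hi = np.percentile(null, [2.5, 97.5], axis=0)
    above = obs > hi
    k = 0
    while k < n_grid and above[k]:
        k += 1
    sig = float(grid[k - 1]) if k > 0 else 0.0
    return LoessEnvelope(grid, obs, lo, hi, null.mean(axis=0), n_perm, span, sig)


def envelope_frame(env: LoessEnvelope) -> pd.DataFrame:
    return pd.DataFrame({"distance": env.grid, "fit": env.fit, "lo": env.lo, "hi": env.hi})
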