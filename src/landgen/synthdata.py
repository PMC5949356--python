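"""Synthetic landscapes, sampling designs, and genotypes with known truth.

The generator emulates the statistical structure of a two-species montane
savanna study system: categorical land-cover maps (montane savanna, forest,
mine, other) over several decades where disturbance converts savanna to
mine; elevation, terrain roughness and climate rasters; spatially spaced
sampling of individuals restricted to savanna; and genotypes whose pairwise
structure decays with circuit resistance distance under a known true
surface.  Every simulation parameter is recorded in a :class:`TruthRecord`
so downstream recovery tests can read their target.

Allele-frequency model per locus class:

* neutral-spatial: individual logit-frequencies are a Gaussian field with
  covariance eta^2 * exp(-R_ij / phi), R the true resistance distance;
* cluster: Balding-Nichols(theta) draws around a shared ancestral frequency,
  mixed through spatially smooth ancestry memberships;
* adaptive: logit p_il = logit(p_l) + beta_l * z_i with z the standardised
  environmental value at the individual.

Genotypes are Binomial(2, p); read depth is negative binomial, genotype
quality is a saturating log transform of depth, and calls go missing at a
configurable rate, so the QC filters downstream have real work to do.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit, logit

from .genio import GenotypeMatrix, Raster, write_ascii_grid, write_vcf

CLASS_CODES = {"montane_savanna": 1, "forest": 2, "mine": 3, "other": 4}
DEFAULT_CLASS_WEIGHTS = {"montane_savanna": 0.35, "mine": 0.03, "forest": 0.42, "other": 0.20}
DEFAULT_YEARS = (1994, 2004, 2013)


@dataclass
class LandscapeBundle:
    land_cover_by_year: dict            # year -> categorical Raster
    elevation: Raster
    roughness: Raster
    climate: dict                       # name -> Raster
    class_codes: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def geometry_consistent(self) -> bool:
        rasters = list(self.land_cover_by_year.values()) + [self.elevation, self.roughness] + list(self.climate.values())
        return all(r.same_geometry(rasters[0]) for r in rasters)


@dataclass
class TruthRecord:
    """Ground truth of one simulated dataset; JSON-serialisable."""

    true_resistance_hypothesis: str
    true_class_resistances: dict
    eta2: float
    phi: float
    k_true: int
    theta: float
    adaptive_loci: dict                 # locus index -> {"env": name, "beta": value}
    n_neutral: int
    n_cluster: int
    n_adaptive: int
    missing_rate: float
    depth_mean: float
    depth_dispersion: float
    site_qual_mean: float
    site_qual_sd: float
    seed: int
    cluster_memberships: list | None = None   # n x k_true ancestry truth

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["adaptive_loci"] = {str(k): v for k, v in d["adaptive_loci"].items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["adaptive_loci"] = {int(k): v for k, v in d["adaptive_loci"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# landscape


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def _roughness_from(elevation: np.ndarray) -> np.ndarray:
    """Per-cell standard deviation of elevation in a 3x3 window."""
    m = ndimage.uniform_filter(elevation, size=3, mode="reflect")
    m2 = ndimage.uniform_filter(elevation**2, size=3, mode="reflect")
    return np.sqrt(np.maximum(m2 - m**2, 0.0))


def generate_landscape(
    seed: int = 0,
    grid_shape: tuple = (40, 40),
    cell_size_m: float = 250.0,
    class_weights: dict | None = None,
    years: tuple = DEFAULT_YEARS,
    disturbance_fraction: float = 0.05,
    class_sigma: float | None = None,
) -> LandscapeBundle:
    """Generate a multi-year categorical landscape plus continuous rasters.

    The first-year map is carved from a smooth field correlated with
    elevation (savanna occupies the highest band, as canga does on
    plateaus); each later year converts exactly
    floor(disturbance_fraction x current savanna cells) savanna cells into
    mine, grown as a spatial cluster around a seeded savanna cell.
    """
    if grid_shape[0] < 20 or grid_shape[1] < 20:
        raise ValueError("grid must be at least 20 x 20")
    if not years:
        raise ValueError("need at least one year")
    weights = dict(class_weights or DEFAULT_CLASS_WEIGHTS)
    if abs(sum(weights.values()) - 1.0) > 1e-8:
        raise ValueError("class weights must sum to 1")
    rng = np.random.default_rng(seed)
    nrows, ncols = grid_shape
    sigma = min(grid_shape) / 8.0
    if class_sigma is None:
        class_sigma = sigma

    elev_field = _smooth_field(rng, grid_shape, sigma)
    elevation = 650.0 + 180.0 * elev_field
    # land cover tracks elevation (savanna on plateaus) but is patchier
    lc_field = 0.45 * elev_field + 0.55 * _smooth_field(rng, grid_shape, class_sigma)

    # descending field bands: savanna on top, then mine, forest, other
    order = ["montane_savanna", "mine", "forest", "other"]
    qs = np.cumsum([weights[c] for c in order])
    thresholds = np.quantile(lc_field, 1.0 - qs[:-1])
    lc = np.full(grid_shape, CLASS_CODES[order[-1]], dtype=np.int16)
    upper = np.inf
    for cls, thr in zip(order[:-1], thresholds):
        lc[(lc_field <= upper) & (lc_field > thr)] = CLASS_CODES[cls]
        upper = thr

    geometry = dict(xllcorner=0.0, yllcorner=0.0, cellsize=cell_size_m)
    land_cover = {}
    current = lc.copy()
    for t, year in enumerate(sorted(years)):
        if t > 0:
            current = current.copy()
            sav = np.argwhere(current == CLASS_CODES["montane_savanna"])
            n_convert = int(np.floor(disturbance_fraction * len(sav)))
            if n_convert > 0:
                seed_cell = sav[rng.integers(len(sav))]
                d = np.linalg.norm(sav - seed_cell, axis=1)
                chosen = sav[np.argsort(d, kind="stable")[:n_convert]]
                current[chosen[:, 0], chosen[:, 1]] = CLASS_CODES["mine"]
            if (current == CLASS_CODES["montane_savanna"]).sum() == 0:
                raise ValueError(f"disturbance removed all savanna cells by {year}")
        land_cover[int(year)] = Raster(current.astype(float), **geometry, nodata=-9999)

    x_grad = np.tile(np.linspace(0, 1, ncols), (nrows, 1))
    y_grad = np.tile(np.linspace(1, 0, nrows)[:, None], (1, ncols))
    temperature = 26.0 - 0.006 * elevation + 1.0 * x_grad + 0.3 * _smooth_field(rng, grid_shape, sigma / 2)
    precipitation = 1600.0 + 500.0 * y_grad + 80.0 * _smooth_field(rng, grid_shape, sigma / 2)

    return LandscapeBundle(
        land_cover_by_year=land_cover,
        elevation=Raster(elevation, **geometry, nodata=-9999),
        roughness=Raster(_roughness_from(elevation), **geometry, nodata=-9999),
        climate={
            "temperature": Raster(temperature, **geometry, nodata=-9999),
            "precipitation": Raster(precipitation, **geometry, nodata=-9999),
        },
    )


def label_highlands(land_cover: Raster, savanna_code: int = 1) -> np.ndarray:
    """Connected savanna patches (8-connectivity); 0 = not savanna."""
    labels, _ = ndimage.label(land_cover.data == savanna_code, structure=np.ones((3, 3)))
    return labels


def sample_individuals(
    bundle: LandscapeBundle, n: int, min_spacing_m: float = 10.0, seed: int = 0,
    method: str = "random",
) -> pd.DataFrame:
    """Place n individuals on savanna cells of the earliest-year map.

    Points sit at cell centres (one per cell), all pairwise distances are at
    least ``min_spacing_m``, and ``highland_id`` labels the connected
    savanna patch.  ``method="random"`` accepts shuffled cells greedily;
    ``method="spread"`` is a farthest-point design that distributes the
    samples across the whole savanna extent (a transect-style survey
    covering every major highland).  Raises when the landscape cannot host
    n points, reporting the achievable maximum.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if min_spacing_m < 0:
        raise ValueError("min_spacing_m must be nonnegative")
    rng = np.random.default_rng(seed)
    earliest = bundle.land_cover_by_year[min(bundle.land_cover_by_year)]
    labels = label_highlands(earliest, bundle.class_codes["montane_savanna"])
    cells = np.argwhere(labels > 0)
    rng.shuffle(cells)
    xy = np.array([earliest.cell_center(r, c) for r, c in cells])
    accepted: list = []
    if method == "spread":
        chosen = [int(rng.integers(len(cells)))]
        mind = np.hypot(xy[:, 0] - xy[chosen[0], 0], xy[:, 1] - xy[chosen[0], 1])
        while len(chosen) < n:
            cand = int(np.argmax(mind))
            if mind[cand] < min_spacing_m:
                break
            chosen.append(cand)
            mind = np.minimum(mind, np.hypot(xy[:, 0] - xy[cand, 0], xy[:, 1] - xy[cand, 1]))
        accepted = [tuple(cells[i]) for i in chosen]
        coords = [tuple(xy[i]) for i in chosen]
    elif method == "random":
        coords = []
        for (r, c), (x, y) in zip(cells, xy):
            if coords:
                d = np.hypot(np.array([p[0] for p in coords]) - x, np.array([p[1] for p in coords]) - y)
                if d.min() < min_spacing_m:
                    continue
            accepted.append((r, c))
            coords.append((x, y))
            if len(accepted) == n:
                break
    else:
        raise ValueError("method must be 'random' or 'spread'")
    if len(accepted) < n:
        raise ValueError(
            f"cannot place {n} points at spacing {min_spacing_m} m; achievable maximum here is {len(accepted)}"
        )
    rows = [
        {"id": f"ind{k:04d}", "x": coords[k][0], "y": coords[k][1],
         "highland_id": int(labels[accepted[k][0], accepted[k][1]])}
        for k in range(n)
    ]
    return pd.DataFrame(rows).set_index("id")


def environment_table(
    bundle: LandscapeBundle, samples: pd.DataFrame, n_noise: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Per-sample environmental values extracted at the sample cells."""
    rasters = {"elevation": bundle.elevation, "roughness": bundle.roughness}
    rasters.update(bundle.climate)
    out = {}
    for name, r in rasters.items():
        vals = []
        for _, s in samples.iterrows():
            row, col = r.cell_index(s["x"], s["y"])
            vals.append(float(r.data[row, col]))
        out[name] = vals
    df = pd.DataFrame(out, index=samples.index)
    if n_noise:
        rng = np.random.default_rng(seed)
        for i in range(n_noise):
            df[f"noise{i + 1}"] = rng.standard_normal(len(df))
    return df


# ---------------------------------------------------------------------------
# genotypes


def _true_surface(bundle: LandscapeBundle, class_resistances: dict, year: int):
    from .landscape import ResistanceHypothesis

    lc = bundle.land_cover_by_year[year]
    data = np.full(lc.shape, np.nan)
    for cls, code in bundle.class_codes.items():
        data[lc.data == code] = class_resistances.get(cls, max(class_resistances.values()))
    return ResistanceHypothesis(
        name=f"true_landcover{year}",
        raster=Raster(data, lc.xllcorner, lc.yllcorner, lc.cellsize, lc.nodata),
        provenance={"source": "truth"},
    )


def _spatial_memberships(samples: pd.DataFrame, k: int, rng: np.random.Generator, tau: float):
    """Spatially coherent ancestry memberships summing to 1 per individual.

    Cluster centres come from k-means on the sample coordinates, so the k
    populations occupy distinct regions of comparable size; the decay scale
    tau controls how admixed the margins between them are.
    """
    from sklearn.cluster import KMeans

    xy = samples[["x", "y"]].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
    centers = km.fit(xy).cluster_centers_
    d = np.linalg.norm(xy[:, None, :] - centers[None, :, :], axis=2)
    q = np.exp(-d / tau)
    return q / q.sum(axis=1, keepdims=True)


def simulate_genotypes(
    bundle: LandscapeBundle,
    samples: pd.DataFrame,
    seed: int = 0,
    n_neutral: int = 300,
    n_cluster: int = 100,
    n_adaptive: int = 30,
    eta2: float = 0.5,
    phi: float | None = 3.0,
    phi_scale: float | None = None,
    k_true: int = 1,
    theta: float = 0.15,
    beta: float = 2.0,
    adaptive_env: tuple = ("temperature", "precipitation", "elevation"),
    class_resistances: dict | None = None,
    true_year: int | None = None,
    missing_rate: float = 0.05,
    depth_mean: float = 60.0,
    depth_dispersion: float = 5.0,
    site_qual_mean: float = 90.0,
    site_qual_sd: float = 30.0,
    membership_tau_m: float | None = None,
    snps_per_contig: int = 2,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate genotypes over the three locus layers with known truth.

    ``eta2 = 0`` is the no-structure limit (all individuals share each
    neutral locus's frequency); negative variance parameters are errors.
    """
    if phi is None and phi_scale is None:
        raise ValueError("give phi or phi_scale")
    if eta2 < 0 or (phi is not None and phi <= 0) or theta <= 0:
        raise ValueError("eta2 must be >= 0 and phi, theta > 0")
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    from .landscape import resistance_distance
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(seed)
    n = len(samples)
    class_resistances = dict(class_resistances or {"montane_savanna": 0.1, "forest": 0.9, "mine": 0.9, "other": 0.9})
    year = true_year if true_year is not None else min(bundle.land_cover_by_year)
    surface = _true_surface(bundle, class_resistances, year)
    rdist = resistance_distance(surface, samples)
    R = squareform(rdist.values)
    if phi is None:
        # decay scale tied to this landscape's resistance-distance scale so
        # the exponential covariance stays quasi-linear over the observed range
        phi = float(phi_scale * np.median(rdist.values))

    # layer 1: neutral-spatial logit-normal field
    freqs = []
    if n_neutral:
        cov = eta2 * np.exp(-R / phi)
        if eta2 > 0:
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
        else:
            chol = np.zeros((n, n))
        p_anc = rng.uniform(0.15, 0.85, size=n_neutral)
        z = rng.standard_normal((n, n_neutral))
        logits = logit(p_anc)[None, :] + chol @ z
        freqs.append(expit(logits))

    # layer 2: Balding-Nichols cluster loci through mixed memberships
    Qm = None
    if n_cluster:
        tau = membership_tau_m or 0.05 * max(
            samples["x"].max() - samples["x"].min(), samples["y"].max() - samples["y"].min(), 1.0
        )
        Qm = (np.ones((n, 1)) if k_true == 1 else _spatial_memberships(samples, k_true, rng, tau))
        p_anc = rng.uniform(0.15, 0.85, size=n_cluster)
        a = p_anc * (1 - theta) / theta
        b = (1 - p_anc) * (1 - theta) / theta
        p_cl = rng.beta(a[None, :], b[None, :], size=(k_true, n_cluster))
        freqs.append(Qm @ p_cl)

    # layer 3: adaptive loci tied to environmental gradients
    adaptive_info = {}
    if n_adaptive:
        env = environment_table(bundle, samples)
        z_env = {v: (env[v] - env[v].mean()).to_numpy() / max(env[v].std(ddof=0), 1e-12) for v in adaptive_env}
        p_anc = rng.uniform(0.2, 0.8, size=n_adaptive)
        cols = np.empty((n, n_adaptive))
        offset = n_neutral + n_cluster
        for l in range(n_adaptive):
            var = adaptive_env[l % len(adaptive_env)]
            cols[:, l] = expit(logit(p_anc[l]) + beta * z_env[var])
            adaptive_info[offset + l] = {"env": var, "beta": float(beta)}
        freqs.append(cols)

    p = np.concatenate(freqs, axis=1)
    L = p.shape[1]
    calls = rng.binomial(2, p).astype(np.int8)

    depth = rng.negative_binomial(
        depth_dispersion, depth_dispersion / (depth_dispersion + depth_mean), size=(n, L)
    ).astype(np.int32)
    gq = np.minimum(99, np.round(40.0 * np.log10(1.0 + depth))).astype(np.int32)
    missing = rng.random((n, L)) < missing_rate
    calls[missing] = -1
    depth[missing] = 0
    gq[missing] = 0

    site_qual = np.clip(rng.normal(site_qual_mean, site_qual_sd, size=L), 1.0, None)
    n_contigs = int(np.ceil(L / snps_per_contig))
    contig_of = np.repeat(np.arange(n_contigs), snps_per_contig)[:L]
    pos = np.concatenate([np.arange(1, (contig_of == c).sum() * 40, 40)[: (contig_of == c).sum()] for c in range(n_contigs)])
    loci = pd.DataFrame({
        "contig": [f"contig{c:05d}" for c in contig_of],
        "pos": pos,
        "ref": "A",
        "alt": "T",
        "qual": site_qual,
        "n_alt": 1,
    })
    geno = GenotypeMatrix(samples=samples.copy(), loci=loci, calls=calls, depth=depth, gq=gq)
    truth = TruthRecord(
        true_resistance_hypothesis=f"landcover{year}_montane_savanna_low",
        true_class_resistances=class_resistances,
        eta2=eta2, phi=phi, k_true=k_true, theta=theta,
        adaptive_loci=adaptive_info,
        n_neutral=n_neutral, n_cluster=n_cluster, n_adaptive=n_adaptive,
        missing_rate=missing_rate, depth_mean=depth_mean, depth_dispersion=depth_dispersion,
        site_qual_mean=site_qual_mean, site_qual_sd=site_qual_sd, seed=seed,
        cluster_memberships=None if Qm is None else Qm.tolist(),
    )
    return geno, truth


# ---------------------------------------------------------------------------
# study presets


PRESETS = {
    # panmictic narrow endemic: one population, weak spatial autocorrelation,
    # ~12% of contigs adaptive
    "cavalcantei-like": dict(
        n_samples=122, k_true=1, eta2=0.15, phi=0.5, theta=0.15,
        n_neutral=352, n_cluster=0, n_adaptive=48, beta=1.0,
        missing_rate=0.05, snps_per_contig=2,
    ),
    # widespread congener: four well-separated populations, ~33% of contigs adaptive
    "maurandioides-like": dict(
        n_samples=254, k_true=4, eta2=0.05, phi=0.5, theta=0.3,
        n_neutral=120, n_cluster=520, n_adaptive=320, beta=0.75,
        membership_tau_m=200.0, missing_rate=0.05, snps_per_contig=2,
    ),
    # strong isolation-by-resistance signal for surface-recovery experiments
    "ibr": dict(
        n_samples=35, k_true=1, eta2=1.5, phi=None, phi_scale=6.0, theta=0.15,
        n_neutral=8000, n_cluster=0, n_adaptive=0, beta=0.0,
        missing_rate=0.02, snps_per_contig=1,
    ),
}


# landscape settings that belong to a preset's study design
PRESET_LANDSCAPE = {
    # patchier, interspersed classes so competing resistance hypotheses decorrelate
    "ibr": dict(
        class_sigma=1.5,
        class_weights={"montane_savanna": 0.30, "mine": 0.15, "forest": 0.30, "other": 0.25},
    ),
}


def preset(name: str, **overrides) -> dict:
    """A named study preset (copy), with optional overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = dict(PRESETS[name])
    cfg.update(overrides)
    return cfg


def simulate_preset(name: str, seed: int = 0, grid_shape=(40, 40), **overrides):
    """Generate landscape + samples + genotypes for a named preset."""
    cfg = preset(name, **overrides)
    n_samples = cfg.pop("n_samples")
    bundle = generate_landscape(seed=seed, grid_shape=grid_shape,
                                **PRESET_LANDSCAPE.get(name, {}))
    samples = sample_individuals(bundle, n_samples, min_spacing_m=10.0, seed=seed + 1)
    geno, truth = simulate_genotypes(bundle, samples, seed=seed + 2, **cfg)
    return bundle, samples, geno, truth


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation (drift benchmarks)


def simulate_wright_fisher(
    n_e: int = 100,
    n_sample: int = 50,
    n_loci: int = 400,
    n_generations: int = 30,
    seed: int = 0,
    size_history: list | None = None,
) -> GenotypeMatrix:
    """Discrete Wright-Fisher forward simulation of unlinked diploid loci.

    All loci segregate in the same pedigree (free recombination), so finite
    population size generates the drift LD that the linkage-disequilibrium
    Ne estimator measures.  ``size_history`` optionally lists (generations,
    N) epochs replacing the constant size, e.g. a bottleneck or expansion.
    Each locus gets its own contig, as physically unlinked markers.
    """
    rng = np.random.default_rng(seed)
    epochs = size_history or [(n_generations, n_e)]
    p0 = rng.uniform(0.1, 0.9, size=n_loci)
    n_start = epochs[0][1]
    hap = (rng.random((2 * n_start, n_loci)) < p0).astype(np.int8)
    for gens, size in epochs:
        for _ in range(gens):
            n_par = hap.shape[0] // 2
            mothers = rng.integers(0, n_par, size=size)
            fathers = rng.integers(0, n_par, size=size)
            new = np.empty((2 * size, n_loci), dtype=np.int8)
            pick_m = rng.integers(0, 2, size=(size, n_loci))
            pick_f = rng.integers(0, 2, size=(size, n_loci))
            new[0::2] = hap[2 * mothers + 0, :] * (1 - pick_m) + hap[2 * mothers + 1, :] * pick_m
            new[1::2] = hap[2 * fathers + 0, :] * (1 - pick_f) + hap[2 * fathers + 1, :] * pick_f
            hap = new
    n_ind = hap.shape[0] // 2
    take = rng.choice(n_ind, size=min(n_sample, n_ind), replace=False)
    calls = (hap[2 * take] + hap[2 * take + 1]).astype(np.int8)
    loci = pd.DataFrame({
        "contig": [f"wf{l:05d}" for l in range(n_loci)],
        "pos": 1, "ref": "A", "alt": "T", "qual": 99.0, "n_alt": 1,
    })
    samples = pd.DataFrame(index=pd.Index([f"wf_ind{i:04d}" for i in range(len(take))], name="id"))
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def simulate_coalescent(
    n_sample: int = 40,
    n_loci: int = 300,
    scenario: str = "constant",
    n_e: float = 1000.0,
    seed: int = 0,
    sequence_length: float = 150.0,
    mu: float = 1e-7,
) -> GenotypeMatrix:
    """Coalescent simulation of independent loci under simple demographies.

    Scenarios: ``constant`` size; ``bottleneck`` (recent 20-fold crash,
    removing rare variants, which pushes Tajima's D up); ``expansion``
    (recent 20-fold growth, generating an excess of rare variants, which
    pushes D down).  One biallelic SNP is kept per simulated locus.
    """
    import msprime

    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=n_e)
    if scenario == "bottleneck":
        demography.add_population_parameters_change(time=0.1 * n_e, initial_size=20 * n_e, population="pop")
    elif scenario == "expansion":
        demography.add_population_parameters_change(time=0.1 * n_e, initial_size=n_e / 20, population="pop")
    elif scenario != "constant":
        raise ValueError("scenario must be constant, bottleneck or expansion")

    rng = np.random.default_rng(seed)
    cols = []
    contig_ids = []
    replicates = msprime.sim_ancestry(
        samples={"pop": n_sample}, demography=demography,
        sequence_length=sequence_length, num_replicates=4 * n_loci,
        random_seed=seed + 1,
    )
    for i, ts in enumerate(replicates):
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=int(rng.integers(1, 2**31)))
        for var in mts.variants():
            if len(var.alleles) != 2:
                continue
            gsum = var.genotypes.reshape(n_sample, 2).sum(axis=1)
            if 0 < gsum.sum() < 2 * n_sample:
                cols.append(gsum.astype(np.int8))
                contig_ids.append(f"coal{i:05d}")
                break
        if len(cols) == n_loci:
            break
    calls = np.array(cols, dtype=np.int8).T
    loci = pd.DataFrame({"contig": contig_ids, "pos": 1, "ref": "A", "alt": "T",
                         "qual": 99.0, "n_alt": 1})
    samples = pd.DataFrame(index=pd.Index([f"coal_ind{i:04d}" for i in range(n_sample)], name="id"))
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# fixtures on disk


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_set(
    bundle: LandscapeBundle,
    samples: pd.DataFrame,
    geno: GenotypeMatrix,
    truth: TruthRecord,
    out_dir,
) -> dict:
    """Write the complete text fixture set and a checksum manifest.

    Emits VCF (GT:DP:GQ), sample and environment CSVs, per-year land-cover
    and continuous ASCII rasters, and the truth JSON.  A partial write is
    rolled back before the error propagates.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    try:
        def emit(name, writer):
            path = os.path.join(out_dir, name)
            writer(path)
            written.append(name)

        emit("genotypes.vcf", lambda p: write_vcf(geno, p))
        emit("samples.csv", lambda p: samples.to_csv(p))
        emit("environment.csv", lambda p: environment_table(bundle, samples).to_csv(p))
        for year, lc in bundle.land_cover_by_year.items():
            emit(f"landcover_{year}.asc", lambda p, r=lc: write_ascii_grid(r, p))
        emit("elevation.asc", lambda p: write_ascii_grid(bundle.elevation, p))
        emit("roughness.asc", lambda p: write_ascii_grid(bundle.roughness, p))
        for name, r in bundle.climate.items():
            emit(f"climate_{name}.asc", lambda p, r=r: write_ascii_grid(r, p))
        emit("truth.json", lambda p: open(p, "w").write(truth.to_json()))
    except Exception:
        for name in written:
            try:
                os.remove(os.path.join(out_dir, name))
            except OSError:
                pass
        raise
    manifest = {name: _sha256(os.path.join(out_dir, name)) for name in written}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
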