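"""Configuration-driven orchestration of the full landscape-genomics workflow.

Stage order mirrors the analysis design: simulate (or load) -> QC ->
association/outlier scans on the quality+depth-filtered loci -> neutral-set
derivation (candidates removed, then LD pruning and HWE) -> diversity ->
ancestry -> landscape distances -> IBR model selection -> report.  Scans run
before the neutral diversity statistics because candidate adaptive loci are
excluded from them; the scans themselves use the set filtered only by
quality and depth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import envassoc, genio, ibr, landscape, popgen, synthdata

log = logging.getLogger("landgen")

ALL_STAGES = ("simulate", "qc", "scan", "neutral", "diversity", "landscape", "ibr", "report")


@dataclass
class PipelineConfig:
    preset: str = "cavalcantei-like"
    seed: int = 0
    outdir: str = "landgen_run"
    stages: tuple = ALL_STAGES
    n_samples: int | None = None
    grid_shape: tuple = (40, 40)
    sim: dict = field(default_factory=dict)         # simulate_genotypes overrides
    qc: dict = field(default_factory=dict)          # qc_filter thresholds
    hwe_alpha: float = 1e-4
    ld: dict = field(default_factory=dict)          # ld_prune options
    ancestry: dict = field(default_factory=lambda: {"k_min": 1, "k_max": 6, "reps": 3})
    scan: dict = field(default_factory=lambda: {"fdr_q": 0.05, "n_runs": 3, "k_spread": 2, "n_env": 3})
    landscape: dict = field(default_factory=dict)   # build_surfaces options
    loess: dict = field(default_factory=lambda: {"span": 0.5, "n_perm": 99})
    inputs: dict | None = None                      # vcf/samples/rasters paths

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if not set(cfg.stages) <= set(ALL_STAGES):
            raise ValueError(f"unknown stages: {set(cfg.stages) - set(ALL_STAGES)}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["grid_shape"] = list(self.grid_shape)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def highland_stats(bundle: synthdata.LandscapeBundle) -> pd.DataFrame:
    """Area (m^2) and isolation (m to nearest other patch) per savanna patch."""
    earliest = bundle.land_cover_by_year[min(bundle.land_cover_by_year)]
    labels = synthdata.label_highlands(earliest, bundle.class_codes["montane_savanna"])
    ids = [i for i in np.unique(labels) if i > 0]
    cell = earliest.cellsize
    coords = {}
    for i in ids:
        rc = np.argwhere(labels == i).astype(float)
        coords[i] = rc * cell
    rows = []
    for i in ids:
        area = (labels == i).sum() * cell * cell
        iso = np.inf
        for j in ids:
            if j == i:
                continue
            d = np.sqrt(((coords[i][:, None, :] - coords[j][None, :, :]) ** 2).sum(-1)).min()
            iso = min(iso, float(d))
        rows.append({"highland_id": int(i), "area": float(area),
                     "isolation": iso if np.isfinite(iso) else 0.0})
    return pd.DataFrame(rows).set_index("highland_id")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of key results.

    Every produced file is listed with a checksum in ``manifest.json``.
    ``status.json`` records completed stages so a failed run shows where it
    stopped.
    """
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    with open(out("config_resolved.yaml"), "w") as fh:
        yaml.safe_dump(config.resolved(), fh)

    results: dict = {}
    status = {"completed": [], "timings_s": {}}
    rng_seed = int(config.seed)

    def finish_stage(name, t0):
        status["completed"].append(name)
        status["timings_s"][name] = round(time.time() - t0, 3)
        with open(out("status.json"), "w") as fh:
            json.dump(status, fh, indent=2)
        log.info("stage %s done in %.1fs", name, status["timings_s"][name])

    stages = list(config.stages)

    # --- simulate / load ---------------------------------------------------
    t0 = time.time()
    if config.inputs:
        geno = genio.read_vcf(config.inputs["vcf"])
        samples = pd.read_csv(config.inputs["samples"], index_col=0)
        geno.samples = samples.loc[geno.samples.index]
        bundle = None
        truth = None
        env = pd.read_csv(config.inputs["environment"], index_col=0)
    else:
        overrides = dict(config.sim)
        n_samples = config.n_samples
        cfg = synthdata.preset(config.preset, **overrides)
        if n_samples is not None:
            cfg["n_samples"] = n_samples
        n_samples = cfg.pop("n_samples")
        bundle = synthdata.generate_landscape(seed=rng_seed, grid_shape=tuple(config.grid_shape))
        samples = synthdata.sample_individuals(bundle, n_samples, min_spacing_m=10.0, seed=rng_seed + 1)
        geno, truth = synthdata.simulate_genotypes(bundle, samples, seed=rng_seed + 2, **cfg)
        env = synthdata.environment_table(bundle, samples)
        if "simulate" in stages:
            synthdata.write_fixture_set(bundle, samples, geno, truth, out("inputs"))
    results["n_samples"] = geno.n_samples
    results["n_loci_raw"] = geno.n_loci
    finish_stage("simulate", t0)

    # --- qc ----------------------------------------------------------------
    t0 = time.time()
    qcd, qc_report = genio.qc_filter(geno, **config.qc)
    with open(out("qc_report.json"), "w") as fh:
        fh.write(qc_report.to_json())
    results["qc_report"] = qc_report
    finish_stage("qc", t0)

    # --- ancestry + scans on quality/depth-filtered loci ---------------------
    scan_cfg = dict(config.scan)
    candidates = None
    best_k = 1
    model = None
    t0 = time.time()
    k_best, entropy_table, model = anc.choose_k(
        qcd, seed=rng_seed + 10, **config.ancestry
    )
    best_k = k_best
    entropy_table.to_csv(out("cross_entropy.csv"), index=False)
    pd.DataFrame(model.Q, index=qcd.samples.index).to_csv(out("ancestry_Q.csv"))
    results["best_k"] = best_k
    results["ancestry"] = model

    if "scan" in stages:
        chosen, _ = envassoc.select_env_variables(env, n_axes=min(scan_cfg.get("n_env", 3), env.shape[1]))
        spread = scan_cfg.get("k_spread", 2)
        k_grid = [k for k in range(best_k - spread, best_k + spread + 1) if 1 <= k < qcd.n_samples]
        scans = []
        for var in chosen:
            for k in k_grid:
                s = envassoc.lfmm_scan(
                    qcd, env[var].to_numpy(), k, n_runs=scan_cfg.get("n_runs", 3),
                    seed=rng_seed + 20, env_name=var,
                )
                scans.append(envassoc.calibrate_adjust(s, scan_cfg.get("fdr_q", 0.05)))
        fst_scan = None
        if best_k >= 2:
            fst_scan = anc.fst_outlier_scan(qcd, model, fdr_q=scan_cfg.get("fdr_q", 0.05))
        candidates = envassoc.intersect_candidates(scans, qcd.loci, fst_scan=fst_scan)
        envassoc.candidate_summary(candidates, qcd.loci).to_csv(out("table4_candidates.csv"), index=False)
        venn = pd.DataFrame(
            [{"source": src, "snp_index": i} for src, snps in candidates.provenance.items() for i in sorted(snps)]
        )
        venn.to_csv(out("venn_membership.csv"), index=False)
        results["candidates"] = candidates
        results["scans"] = scans
    else:
        log.warning("scan stage disabled: diversity statistics will include any adaptive loci")
    finish_stage("scan", t0)

    # --- neutral set ---------------------------------------------------------
    t0 = time.time()
    neutral = qcd
    if candidates is not None and candidates.n_snps:
        keep = np.ones(neutral.n_loci, dtype=bool)
        keep[candidates.snp_indices] = False
        neutral = neutral.subset_loci(keep)
    neutral, ld_report = genio.ld_prune(neutral, **config.ld)
    neutral, hwe_report = genio.hwe_filter(neutral, alpha=config.hwe_alpha)
    results["n_loci_neutral"] = neutral.n_loci
    with open(out("neutral_filters.json"), "w") as fh:
        json.dump({"ld": json.loads(ld_report.to_json()), "hwe": json.loads(hwe_report.to_json())}, fh, indent=2)
    finish_stage("neutral", t0)

    # --- diversity -----------------------------------------------------------
    t0 = time.time()
    pops = model.assignments() if best_k > 1 else np.zeros(neutral.n_samples, dtype=int)
    table1 = popgen.diversity_report(neutral, pops, n_boot=500, seed=rng_seed + 30)
    table1.to_csv(out("table1_diversity.csv"), index=False)
    rel = popgen.yang_relatedness(neutral)
    rel.to_frame().to_csv(out("relatedness.csv"))
    results["diversity"] = table1
    results["relatedness"] = rel
    finish_stage("diversity", t0)

    # --- landscape distances ---------------------------------------------------
    t0 = time.time()
    dists = {}
    if bundle is not None and "landscape" in stages:
        surfaces = landscape.build_surfaces(bundle, geno.samples, **config.landscape)
        for s in surfaces:
            dists[s.name] = landscape.resistance_distance(s, geno.samples).values
        geo = landscape.geographic_distance(geno.samples)
        pd.DataFrame(dists).assign(geographic=geo.values).to_csv(out("pairwise_distances.csv"), index=False)
        envlp = landscape.loess_autocorrelogram(
            rel.matrix, geo, span=config.loess.get("span", 0.5),
            n_perm=config.loess.get("n_perm", 99), seed=rng_seed + 40,
        )
        landscape.envelope_frame(envlp).to_csv(out("autocorrelogram.csv"), index=False)
        results["geo"] = geo
        results["autocorrelogram"] = envlp
    finish_stage("landscape", t0)

    # --- IBR -----------------------------------------------------------------
    t0 = time.time()
    if dists and "ibr" in stages:
        pair_index = ibr.full_pair_index(geno.n_samples)
        y = rel.condensed()
        table, winners = ibr.rank_candidate_surfaces(y, dists, pair_index)
        table.table.to_csv(out("univariate_ranking.csv"), index=False)
        chosen = {name: dists[name] for name in set(winners.values())}
        chosen["geographic"] = results["geo"].values
        mt = ibr.dredge_mlpe(y, chosen, pair_index)
        mt.table.to_csv(out("table2_model_selection.csv"), index=False)
        _, best_fits = mt.best_set()
        avg = ibr.model_average(best_fits)
        avg.to_csv(out("table3_model_average.csv"), index=False)
        results["ibr_table"] = mt
        results["ibr_winners"] = winners
        results["model_average"] = avg

        # highland-history mixed models
        if bundle is not None:
            hstats = highland_stats(bundle)
            he_ind = popgen.individual_heterozygosity(neutral)
            f_ind, _, _ = popgen.individual_inbreeding(neutral, n_boot=10)
            indiv = pd.DataFrame({
                "He_ind": he_ind, "F": f_ind,
                "highland_id": geno.samples["highland_id"].to_numpy(),
            }, index=geno.samples.index).join(hstats, on="highland_id")
            results["lmm_highland"] = ibr.lmm_highland(indiv)
            pd.DataFrame(
                [{"response": r, "predictor": p, "slope": v["slopes"][p], "lrt_p": v["lrt_p"][p]}
                 for r, v in results["lmm_highland"].items() for p in v["slopes"]]
            ).to_csv(out("highland_lmm.csv"), index=False)
    finish_stage("ibr", t0)

    # --- report ----------------------------------------------------------------
    t0 = time.time()
    manifest = {}
    for root, _, files in os.walk(config.outdir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            path = os.path.join(root, f)
            manifest[os.path.relpath(path, config.outdir)] = _sha256(path)
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    finish_stage("report", t0)
    return results


def summarize_report(run_dir) -> dict:
    """Collect the report tables from a completed run directory."""
    tables = {}
    gaps = []
    for key, name in [
        ("table1", "table1_diversity.csv"),
        ("table2", "table2_model_selection.csv"),
        ("table3", "table3_model_average.csv"),
        ("table4", "table4_candidates.csv"),
    ]:
        path = os.path.join(run_dir, name)
        if os.path.exists(path):
            tables[key] = pd.read_csv(path)
        else:
            gaps.append(name)
    if gaps:
        tables["missing"] = gaps
    return tables
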