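"""Genotype and raster I/O plus locus quality-control filters.

The central container is :class:`GenotypeMatrix`: individuals x biallelic
loci with dosage calls in {0, 1, 2} (-1 = missing), per-call read depth and
genotype quality, and per-locus metadata (contig, position, alleles, site
quality).  VCF parsing goes through cyvcf2; writing emits plain VCFv4.2
text with ``GT:DP:GQ``.

Rasters use the ESRI ASCII grid format (row 0 = northernmost row).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

# ---------------------------------------------------------------------------
# rasters


@dataclass
class Raster:
    """A single-band raster on a regular grid, row 0 at the north edge.

    Coordinates are projected metres; ``xllcorner``/``yllcorner`` locate the
    south-west corner of the south-west cell, as in the ESRI ASCII header.
    """

    data: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 100.0
    nodata: float = -9999.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.xllcorner, other.xllcorner)
            and math.isclose(self.yllcorner, other.yllcorner)
            and math.isclose(self.cellsize, other.cellsize)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.data.shape[0]
        x = self.xllcorner + (col + 0.5) * self.cellsize
        y = self.yllcorner + (nrows - row - 0.5) * self.cellsize
        return x, y

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Grid cell containing the point (x, y)."""
        nrows = self.data.shape[0]
        col = int((x - self.xllcorner) // self.cellsize)
        row = nrows - 1 - int((y - self.yllcorner) // self.cellsize)
        if not (0 <= row < nrows and 0 <= col < self.data.shape[1]):
            raise ValueError(f"point ({x}, {y}) falls outside the raster")
        return row, col

    def crop(self, xmin: float, ymin: float, xmax: float, ymax: float) -> "Raster":
        """Crop to the smallest cell-aligned window covering the bbox."""
        nrows, ncols = self.data.shape
        c0 = max(0, int((xmin - self.xllcorner) // self.cellsize))
        c1 = min(ncols, int(math.ceil((xmax - self.xllcorner) / self.cellsize)))
        r_lo = max(0, int((ymin - self.yllcorner) // self.cellsize))
        r_hi = min(nrows, int(math.ceil((ymax - self.yllcorner) / self.cellsize)))
        # rows count from the north edge
        i0 = nrows - r_hi
        i1 = nrows - r_lo
        return Raster(
            self.data[i0:i1, c0:c1].copy(),
            xllcorner=self.xllcorner + c0 * self.cellsize,
            yllcorner=self.yllcorner + r_lo * self.cellsize,
            cellsize=self.cellsize,
            nodata=self.nodata,
        )


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:])
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    return Raster(
        data,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: Raster, path) -> None:
    nrows, ncols = raster.data.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.6f}\n")
        fh.write(f"yllcorner {raster.yllcorner:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        np.savetxt(fh, raster.data, fmt="%.8g")


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci with dosages, depth and quality.

    ``samples`` is indexed by sample id and may carry x/y coordinates and a
    highland id.  ``loci`` has columns contig, pos (1-based), ref, alt, qual
    (site Phred).  ``calls`` is (n_samples, n_loci) int8 with -1 = missing.
    """

    samples: pd.DataFrame
    loci: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError("calls shape inconsistent with samples/loci")
        for arr in (self.depth, self.gq):
            if arr is not None and arr.shape != self.calls.shape:
                raise ValueError("depth/gq shape inconsistent with calls")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def called(self) -> np.ndarray:
        return self.calls != MISSING

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per locus (NaN where no calls)."""
        ok = self.called()
        n_chrom = 2 * ok.sum(axis=0)
        alt = np.where(ok, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1 - p)

    def subset_loci(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=self.samples,
            loci=self.loci.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask].reset_index(drop=True),
            calls=self.calls[:, mask],
            depth=None if self.depth is None else self.depth[:, mask],
            gq=None if self.gq is None else self.gq[:, mask],
        )

    def subset_samples(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=self.samples.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask],
            loci=self.loci,
            calls=self.calls[mask, :],
            depth=None if self.depth is None else self.depth[mask, :],
            gq=None if self.gq is None else self.gq[mask, :],
        )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> GenotypeMatrix:
    """Parse a VCF into a GenotypeMatrix (GT required, DP/GQ optional)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    rows, calls, depths, gqs = [], [], [], []
    has_dp = has_gq = True
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append(
            {
                "contig": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "qual": var.QUAL if var.QUAL is not None else np.nan,
                "n_alt": len(var.ALT),
            }
        )
        g = var.gt_types.astype(np.int8)  # gts012: 0,1,2 and 3=unknown
        g[g == 3] = MISSING
        calls.append(g)
        dp = var.format("DP")
        gq = var.format("GQ")
        if dp is None:
            has_dp = False
        else:
            depths.append(np.where(dp < 0, 0, dp).reshape(n))
        if gq is None:
            has_gq = False
        else:
            gqs.append(np.where(gq < 0, 0, gq).reshape(n))
    loci = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "qual", "n_alt"])
    call_mat = np.array(calls, dtype=np.int8).T if calls else np.zeros((n, 0), np.int8)
    return GenotypeMatrix(
        samples=pd.DataFrame(index=pd.Index(sample_ids, name="id")),
        loci=loci,
        calls=call_mat,
        depth=np.array(depths).T.astype(np.int32) if (has_dp and depths) else None,
        gq=np.array(gqs).T.astype(np.int32) if (has_gq and gqs) else None,
    )


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Emit VCFv4.2 text with FORMAT GT:DP:GQ."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for contig in pd.unique(geno.loci["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        cols = "\t".join(str(s) for s in geno.samples.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        depth = geno.depth
        gq = geno.gq
        for l, locus in enumerate(geno.loci.itertuples(index=False)):
            qual = "." if pd.isna(locus.qual) else f"{locus.qual:.2f}"
            fields = []
            for i in range(geno.n_samples):
                dp = "." if depth is None else str(int(depth[i, l]))
                q = "." if gq is None else str(int(gq[i, l]))
                fields.append(f"{gt_str[int(geno.calls[i, l])]}:{dp}:{q}")
            fh.write(
                f"{locus.contig}\t{locus.pos}\t.\t{locus.ref}\t{locus.alt}\t"
                f"{qual}\tPASS\t.\tGT:DP:GQ\t" + "\t".join(fields) + "\n"
            )


# ---------------------------------------------------------------------------
# QC report


@dataclass
class QCReport:
    thresholds: dict
    n_input: int
    stages: list  # (stage name, n removed)
    n_retained: int

    def __post_init__(self):
        removed = sum(n for _, n in self.stages)
        if removed + self.n_retained != self.n_input:
            raise ValueError("QC attrition does not reconcile with input count")

    def to_json(self) -> str:
        return json.dumps(
            {
                "thresholds": self.thresholds,
                "n_input": self.n_input,
                "stages": [{"filter": s, "removed": n} for s, n in self.stages],
                "n_retained": self.n_retained,
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"QC report: {self.n_input} loci in"]
        for s, n in self.stages:
            lines.append(f"  {s:<14} removed {n}")
        lines.append(f"  retained {self.n_retained}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# filters


def qc_filter(
    geno: GenotypeMatrix,
    site_q_min: float = 50.0,
    depth_min: float = 20.0,
    depth_max: float = 200.0,
    maf_min: float = 0.025,
    max_missing: float = 0.30,
    drop_all_het: bool = True,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Locus QC: site quality, mean depth, MAF, missingness, all-het, biallelic.

    Filters are applied in that fixed order and the report records per-stage
    attrition.  The depth rule uses the mean per-call depth across genotyped
    samples at the locus.
    """
    n_input = geno.n_loci
    keep = np.ones(n_input, dtype=bool)
    stages = []

    def apply(name, ok):
        nonlocal keep
        removed = int((keep & ~ok).sum())
        keep &= ok
        stages.append((name, removed))

    qual = geno.loci["qual"].to_numpy(dtype=float)
    apply("site_quality", np.nan_to_num(qual, nan=np.inf) > site_q_min)

    if geno.depth is not None:
        ok_calls = geno.called()
        ncall = ok_calls.sum(axis=0)
        mean_dp = np.where(
            ncall > 0,
            np.where(ok_calls, geno.depth, 0).sum(axis=0) / np.maximum(ncall, 1),
            np.nan,
        )
        good = np.isnan(mean_dp) | ((mean_dp >= depth_min) & (mean_dp <= depth_max))
        apply("depth", good)
    else:
        stages.append(("depth", 0))

    maf = geno.maf()
    apply("maf", np.nan_to_num(maf, nan=0.0) >= maf_min)

    miss = 1.0 - geno.called().mean(axis=0)
    apply("missing", miss <= max_missing)

    if drop_all_het:
        ok_calls = geno.called()
        ncall = ok_calls.sum(axis=0)
        n_het = (geno.calls == 1).sum(axis=0)
        apply("all_het", ~((ncall > 0) & (n_het == ncall)))
    else:
        stages.append(("all_het", 0))

    if biallelic_only and "n_alt" in geno.loci.columns:
        apply("biallelic", geno.loci["n_alt"].to_numpy() <= 1)
    else:
        stages.append(("biallelic", 0))

    out = geno.subset_loci(keep)
    if out.n_loci == 0:
        out.warnings.append("qc_filter retained zero loci")
    report = QCReport(
        thresholds=dict(
            site_q_min=site_q_min, depth_min=depth_min, depth_max=depth_max,
            maf_min=maf_min, max_missing=max_missing,
            drop_all_het=drop_all_het, biallelic_only=biallelic_only,
        ),
        n_input=n_input,
        stages=stages,
        n_retained=out.n_loci,
    )
    return out, report


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test on genotype counts.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.  Monomorphic sites have p = 1 by convention.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_alt + n_het  # minor-ish allele count (either works)
    if n == 0 or n_a == 0 or n_a == 2 * n:
        return 1.0
    n_minor = min(n_a, 2 * n - n_a)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log prob up to a constant: C(n; n_aa, n_het, n_AA) 2^het
    from scipy.special import gammaln

    n_alt_hom = (n_minor - hets) // 2
    n_ref_hom = n - hets - n_alt_hom
    logp = (
        hets * math.log(2)
        - gammaln(n_ref_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_alt_hom + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = min(n_het, n_minor)
    p_obs = prob[hets == obs][0]
    return float(prob[prob <= p_obs * (1 + 1e-12)].sum())


def hwe_filter(geno: GenotypeMatrix, alpha: float = 1e-4) -> tuple[GenotypeMatrix, QCReport]:
    """Remove loci with strong Hardy-Weinberg deviation (exact test p < alpha)."""
    n_input = geno.n_loci
    keep = np.ones(n_input, dtype=bool)
    for l in range(n_input):
        col = geno.calls[:, l]
        p = hwe_exact_pvalue(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        keep[l] = p >= alpha
    out = geno.subset_loci(keep)
    report = QCReport(
        thresholds={"hwe_alpha": alpha},
        n_input=n_input,
        stages=[("hwe", int((~keep).sum()))],
        n_retained=out.n_loci,
    )
    return out, report


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosages, missing pairwise-deleted."""
    x = np.ma.masked_equal(calls.astype(float), MISSING)
    r = np.ma.corrcoef(x, rowvar=False)
    return np.asarray(r.filled(0.0)) ** 2


def ld_prune(
    geno: GenotypeMatrix, r2_max: float = 0.5, window: int = 50, step: int = 5
) -> tuple[GenotypeMatrix, QCReport]:
    """Greedy windowed LD pruning on composite (dosage) r^2.

    Within each window the member of a high-LD pair with the lower MAF is
    dropped (tie: the later position).  Surviving loci have all within-window
    pairwise r^2 below ``r2_max``.
    """
    n_input = geno.n_loci
    keep = np.ones(n_input, dtype=bool)
    maf = np.nan_to_num(geno.maf(), nan=0.0)
    pos = geno.loci["pos"].to_numpy()
    for start in range(0, max(n_input - 1, 1), step):
        idx = np.flatnonzero(keep[start : start + window]) + start
        if len(idx) < 2:
            continue
        r2 = _pairwise_r2(geno.calls[:, idx])
        active = np.ones(len(idx), dtype=bool)
        while True:
            sub = np.where(np.outer(active, active), r2, 0.0)
            np.fill_diagonal(sub, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] < r2_max:
                break
            a, b = idx[i], idx[j]
            if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
                drop_local, drop = i, a
            else:
                drop_local, drop = j, b
            keep[drop] = False
            active[drop_local] = False
    out = geno.subset_loci(keep)
    report = QCReport(
        thresholds={"r2_max": r2_max, "window": window, "step": step},
        n_input=n_input,
        stages=[("ld_prune", int((~keep).sum()))],
        n_retained=out.n_loci,
    )
    return out, report
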