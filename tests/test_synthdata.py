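"""The synthetic-data generator: landscapes, sampling, genotypes, fixtures."""

import numpy as np
import pytest

from landgen import genio, synthdata
from landgen.genio import MISSING


# ---------------------------------------------------------------------------
# landscape generation


def test_fixed_seed_gives_bit_identical_bundles():
    a = synthdata.generate_landscape(seed=5, grid_shape=(25, 25))
    b = synthdata.generate_landscape(seed=5, grid_shape=(25, 25))
    for year in a.land_cover_by_year:
        np.testing.assert_array_equal(a.land_cover_by_year[year].data,
                                      b.land_cover_by_year[year].data)
    np.testing.assert_array_equal(a.elevation.data, b.elevation.data)
    for name in a.climate:
        np.testing.assert_array_equal(a.climate[name].data, b.climate[name].data)


def test_zero_disturbance_keeps_all_years_identical():
    b = synthdata.generate_landscape(seed=6, grid_shape=(22, 22), disturbance_fraction=0.0)
    years = sorted(b.land_cover_by_year)
    for y in years[1:]:
        np.testing.assert_array_equal(b.land_cover_by_year[years[0]].data,
                                      b.land_cover_by_year[y].data)


def test_disturbance_converts_exactly_the_floor_count_of_savanna_cells():
    frac = 0.07
    b = synthdata.generate_landscape(seed=7, grid_shape=(30, 30), disturbance_fraction=frac)
    years = sorted(b.land_cover_by_year)
    sav_code = b.class_codes["montane_savanna"]
    mine_code = b.class_codes["mine"]
    for y0, y1 in zip(years, years[1:]):
        lc0 = b.land_cover_by_year[y0].data
        lc1 = b.land_cover_by_year[y1].data
        changed = lc0 != lc1
        assert np.all(lc0[changed] == sav_code)
        assert np.all(lc1[changed] == mine_code)
        assert changed.sum() == int(np.floor(frac * (lc0 == sav_code).sum()))


def test_flat_elevation_gives_zero_roughness():
    assert np.allclose(synthdata._roughness_from(np.full((15, 15), 7.0)), 0.0)
    assert np.all(synthdata._roughness_from(np.random.default_rng(0).normal(size=(15, 15))) >= 0)


def test_geometry_consistency(small_bundle):
    assert small_bundle.geometry_consistent()
    codes = set(np.unique(small_bundle.land_cover_by_year[1994].data).astype(int))
    assert codes <= set(small_bundle.class_codes.values())


# ---------------------------------------------------------------------------
# sampling


def test_samples_respect_spacing_and_fall_in_savanna(small_bundle, small_samples):
    from scipy.spatial.distance import pdist

    assert pdist(small_samples[["x", "y"]].to_numpy()).min() >= 10.0
    earliest = small_bundle.land_cover_by_year[1994]
    for _, s in small_samples.iterrows():
        r, c = earliest.cell_index(s["x"], s["y"])
        assert earliest.data[r, c] == small_bundle.class_codes["montane_savanna"]


def test_overfull_sampling_reports_achievable_maximum(small_bundle):
    with pytest.raises(ValueError, match="achievable maximum"):
        synthdata.sample_individuals(small_bundle, 10_000, 10.0, seed=0)


def test_highland_labels_match_flood_fill_oracle():
    from landgen.genio import Raster

    rng = np.random.default_rng(8)
    data = (rng.random((10, 10)) < 0.45).astype(float)   # 1 = savanna
    labels = synthdata.label_highlands(Raster(data, 0, 0, 1.0), savanna_code=1)

    # brute-force 8-connected flood fill
    oracle = np.zeros_like(labels)
    nxt = 0
    for sr in range(10):
        for sc in range(10):
            if data[sr, sc] == 1 and oracle[sr, sc] == 0:
                nxt += 1
                stack = [(sr, sc)]
                while stack:
                    r, c = stack.pop()
                    if not (0 <= r < 10 and 0 <= c < 10):
                        continue
                    if data[r, c] != 1 or oracle[r, c] != 0:
                        continue
                    oracle[r, c] = nxt
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            stack.append((r + dr, c + dc))
    # identical partitions (label values may differ)
    for lab in range(1, nxt + 1):
        cells = oracle == lab
        assert len(np.unique(labels[cells])) == 1
    assert (labels > 0).sum() == (oracle > 0).sum()
    assert labels.max() == nxt


# ---------------------------------------------------------------------------
# genotypes


def test_genotype_values_and_truth_bookkeeping(small_dataset):
    geno, truth = small_dataset
    assert set(np.unique(geno.calls)) <= {MISSING, 0, 1, 2}
    assert geno.depth.min() >= 0 and geno.gq.max() <= 99
    assert set(truth.adaptive_loci) <= set(range(geno.n_loci))
    assert truth.n_neutral + truth.n_cluster + truth.n_adaptive == geno.n_loci
    # loci ordered by contig then position
    assert geno.loci.sort_values(["contig", "pos"]).index.tolist() == list(range(geno.n_loci))


def test_simulation_is_deterministic(small_bundle, small_samples):
    a, _ = synthdata.simulate_genotypes(small_bundle, small_samples, seed=3,
                                        n_neutral=30, n_cluster=10, n_adaptive=5)
    b, _ = synthdata.simulate_genotypes(small_bundle, small_samples, seed=3,
                                        n_neutral=30, n_cluster=10, n_adaptive=5)
    np.testing.assert_array_equal(a.calls, b.calls)
    np.testing.assert_array_equal(a.depth, b.depth)


def test_negative_variance_parameters_rejected(small_bundle, small_samples):
    with pytest.raises(ValueError):
        synthdata.simulate_genotypes(small_bundle, small_samples, eta2=-0.1)
    with pytest.raises(ValueError):
        synthdata.simulate_genotypes(small_bundle, small_samples, phi=0.0)


def test_eta2_zero_removes_spatial_relatedness_gradient(small_bundle, small_samples):
    from landgen import landscape, popgen

    geno, _ = synthdata.simulate_genotypes(
        small_bundle, small_samples, seed=9, n_neutral=400, n_cluster=0,
        n_adaptive=0, eta2=0.0, missing_rate=0.0,
    )
    rel = popgen.yang_relatedness(geno).condensed()
    geo = landscape.geographic_distance(small_samples).values
    near = rel[geo <= np.quantile(geo, 0.1)].mean()
    far = rel[geo >= np.quantile(geo, 0.9)].mean()
    assert abs(near - far) < 0.02


def test_adaptive_locus_correlates_with_environment(small_bundle, small_samples):
    geno, truth = synthdata.simulate_genotypes(
        small_bundle, small_samples, seed=10, n_neutral=10, n_cluster=0,
        n_adaptive=6, beta=3.0, missing_rate=0.0,
    )
    env = synthdata.environment_table(small_bundle, small_samples)
    hits = 0
    for idx, info in truth.adaptive_loci.items():
        z = env[info["env"]]
        z = (z - z.mean()) / z.std(ddof=0)
        r = np.corrcoef(geno.calls[:, idx], z)[0, 1]
        hits += abs(r) > 0.3
    assert hits >= 5


def test_preset_adaptive_contig_fractions_mirror_the_two_species():
    for name, lo, hi in [("cavalcantei-like", 0.10, 0.14), ("maurandioides-like", 0.30, 0.37)]:
        cfg = synthdata.preset(name)
        total = cfg["n_neutral"] + cfg["n_cluster"] + cfg["n_adaptive"]
        frac = cfg["n_adaptive"] / total
        assert lo < frac < hi


def test_unknown_preset_raises():
    with pytest.raises(KeyError):
        synthdata.preset("nope")


# ---------------------------------------------------------------------------
# fixtures on disk


def test_fixture_round_trip(tmp_path, small_bundle, small_samples, small_dataset):
    geno, truth = small_dataset
    out = tmp_path / "fix"
    manifest = synthdata.write_fixture_set(small_bundle, small_samples, geno, truth, out)
    back = genio.read_vcf(out / "genotypes.vcf")
    np.testing.assert_array_equal(back.calls, geno.calls)
    truth2 = synthdata.TruthRecord.from_json((out / "truth.json").read_text())
    assert truth2 == truth
    for name, digest in manifest.items():
        assert synthdata._sha256(out / name) == digest
    raster = genio.read_ascii_grid(out / "elevation.asc")
    np.testing.assert_allclose(raster.data, small_bundle.elevation.data, rtol=1e-6)
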