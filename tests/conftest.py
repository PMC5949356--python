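import numpy as np
import pandas as pd
import pytest

from landgen.genio import GenotypeMatrix


def make_geno(calls, depth=None, gq=None, qual=99.0, contigs=None, pos=None):
    """GenotypeMatrix from a plain call array (rows = individuals)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    loci = pd.DataFrame({
        "contig": contigs if contigs is not None else [f"c{l:04d}" for l in range(L)],
        "pos": pos if pos is not None else np.arange(1, L + 1),
        "ref": "A",
        "alt": "T",
        "qual": qual if np.ndim(qual) else np.full(L, qual, dtype=float),
        "n_alt": 1,
    })
    samples = pd.DataFrame(index=pd.Index([f"i{i:03d}" for i in range(n)], name="id"))
    return GenotypeMatrix(
        samples=samples, loci=loci, calls=calls,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def small_bundle():
    from landgen import synthdata

    return synthdata.generate_landscape(seed=11, grid_shape=(30, 30))


@pytest.fixture(scope="session")
def small_samples(small_bundle):
    from landgen import synthdata

    return synthdata.sample_individuals(small_bundle, 25, 10.0, seed=12)


@pytest.fixture(scope="session")
def small_dataset(small_bundle, small_samples):
    from landgen import synthdata

    geno, truth = synthdata.simulate_genotypes(
        small_bundle, small_samples, seed=13,
        n_neutral=120, n_cluster=40, n_adaptive=12,
    )
    return geno, truth
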