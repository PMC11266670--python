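import numpy as np
import pandas as pd
import pytest

from cadpipe import synthetic_data as synth
from cadpipe.genome_io import GenomeAssembly, RegionSet


@pytest.fixture(scope="session")
def assembly():
    return GenomeAssembly({"chr1": 1_000_000, "chr2": 800_000}, name="toy")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240723)


def make_rs(triples, assembly=None, name="rs", **extra):
    """RegionSet from (chrom, start, end) triples."""
    df = pd.DataFrame(triples, columns=["chrom", "start", "end"])
    for k, v in extra.items():
        df[k] = v
    return RegionSet(df, assembly=assembly, name=name)


def random_regions(rng, assembly, n, min_len=50, max_len=2000):
    chroms, starts, ends = [], [], []
    names = assembly.chroms
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, assembly.length(chrom) - length))
        chroms.append(chrom)
        starts.append(start)
        ends.append(start + length)
    return RegionSet.from_arrays(chroms, starts, ends, assembly=assembly)


@pytest.fixture(scope="session")
def noise_free_sim():
    asm = synth.make_genome(2, 1_000_000, seed=7)
    return synth.make_accessibility_timecourse(
        asm, n_loci_per_group=12, flicker_rate=0.0, noise_sd=0.0, seed=3
    )
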