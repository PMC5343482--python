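import numpy as np
import pandas as pd
import pytest

from enhancerscape.synthetic import SyntheticGenomeSpec, plant_sites
from enhancerscape.taglib import TagLibrary


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticGenomeSpec(
        n_chroms=2, chrom_length=1_000_000, n_promoter_sites=30,
        n_distal_sites=60, fraction_sensitive=0.5, background_rate=0.02,
        enrichment_fold=8.0, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return plant_sites(small_spec)


def library_from_tags(tags, chrom_lengths=None, fragment_size=160):
    """Build a TagLibrary from (chrom, pos, strand) or (chrom, pos, strand, n)."""
    tags = list(tags)
    chrom = [t[0] for t in tags]
    pos = [t[1] for t in tags]
    strand = [t[2] for t in tags]
    count = [t[3] if len(t) > 3 else 1 for t in tags]
    return TagLibrary.from_arrays(np.array(chrom), pos, strand, count,
                                  chrom_lengths=chrom_lengths,
                                  fragment_size=fragment_size)


def random_intervals(rng, n, genome_length=100_000, max_len=3000,
                     chrom="chr1"):
    starts = rng.integers(0, genome_length - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + lengths})
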