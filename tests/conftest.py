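import numpy as np
import pandas as pd
import pytest

from regionburden.io import VARIANT_COLUMNS, GenomicInterval
from regionburden.synthetic import PopulationModel, random_common_sites


def make_variants(rows):
    """Build a variant table from (chrom, pos, ref, alt, sample_id[, genotype,
    quality_flag, somatic_status]) tuples."""
    full = []
    for row in rows:
        row = list(row)
        defaults = [1, "pass", "unknown"]
        row = row + defaults[len(row) - 5 :]
        full.append(row)
    df = pd.DataFrame(full, columns=VARIANT_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["genotype"] = df["genotype"].astype(np.int64)
    return df


@pytest.fixture
def small_region():
    return GenomicInterval("chr3", 1_000_001, 1_200_000)  # 200 kb


@pytest.fixture
def small_population(small_region):
    sites = random_common_sites(small_region, 50, seed=11)
    return PopulationModel(region=small_region, common_sites=sites, rare_site_rate=2e-5)
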