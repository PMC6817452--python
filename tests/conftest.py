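import numpy as np
import pandas as pd
import pytest

from mircna import simulate


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: two planted regions, the 17-miRNA panel, few nulls."""
    regions = [
        simulate.RegionSpec("chr8", 88_000_000, 146_000_000, "gain", 0.6, 0.1),
        simulate.RegionSpec("chr14", 38_000_000, 103_500_000, "loss", 0.5, 0.05),
    ]
    return simulate.CohortConfig(
        n_group_a=14,
        n_group_b=12,
        probe_spacing=4_000_000,
        region_specs=regions,
        n_null_mirnas=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    return simulate.generate_cohort(small_config)


@pytest.fixture(scope="session")
def cohort_labels(cohort):
    _, _, clinical, _ = cohort
    return dict(zip(clinical["sample"], clinical["group"]))


def make_probe_track(sample, chrom, ratios, spacing=1000, start=1):
    """Helper: evenly spaced probe table from a log2-ratio vector."""
    positions = start + spacing * np.arange(len(ratios))
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": chrom,
            "position": positions,
            "log2_ratio": list(ratios),
        }
    )
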