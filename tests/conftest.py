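import numpy as np
import pandas as pd
import pytest

from doublehit import BetaMatrix


def make_beta(values, groups=None, batches=None, probe_prefix="cg"):
    """Build a BetaMatrix from a 2-D array with default metadata."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probes = [f"{probe_prefix}{i:05d}" for i in range(n_probes)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    groups = groups or ["case_FTDALS"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2)
    batches = batches or ["batch0"] * n_samples
    meta = pd.DataFrame({"group": groups, "batch": batches},
                        index=pd.Index(samples, name="sample_id"))
    return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples), meta)


def make_annotation(probes, **overrides):
    """Clean autosomal genic annotation for the given probes."""
    n = len(probes)
    ann = pd.DataFrame(
        {
            "chromosome": ["1"] * n,
            "position": np.arange(1000, 1000 + n * 10, 10),
            "gene_symbol": [f"GENE{i:05d}" for i in range(n)],
            "region_class": ["Body"] * n,
            "island_relation": ["open_sea"] * n,
            "snp_maf": [np.nan] * n,
            "control_probe": [False] * n,
            "blacklist": [False] * n,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    for col, vals in overrides.items():
        ann[col] = vals
    return ann


@pytest.fixture
def small_beta():
    rng = np.random.default_rng(7)
    return make_beta(rng.uniform(0.2, 0.8, size=(20, 10)))
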