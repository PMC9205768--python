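import numpy as np
import pandas as pd
import pytest

from twinclock.synthetic import SimulationParams, write_reference_fixture


@pytest.fixture(scope="session")
def reference_fasta(tmp_path_factory):
    """Small CpG-rich reference fixture shared across tests."""
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    write_reference_fixture(path, length_bp=20_000, cpg_density=0.02, seed=42)
    return path


@pytest.fixture
def twin_params():
    return SimulationParams(rate_per_year=2.5, t_mrca_true=0.8,
                            sampling_age_a=40.0, sampling_age_b=40.0, seed=3)


def planted_records_2d(seed, spec=(((1.0, 1.0), 120), ((1.0, 0.0), 100), ((0.0, 1.0), 100)),
                       depth_mean=40, purity=0.95):
    """Binomial reads from planted 2-D CCF clusters (twin A x twin B)."""
    rng = np.random.default_rng(seed)
    rows = []
    denom = purity * 2 + 2 * (1 - purity)
    for (ca, cb), n in spec:
        for _ in range(n):
            da = max(1, rng.poisson(depth_mean))
            db = max(1, rng.poisson(depth_mean))
            rows.append(dict(
                chrom="c", pos=len(rows) + 1, ref="C", alt="T",
                alt_a=rng.binomial(da, ca * purity / denom), depth_a=da,
                alt_b=rng.binomial(db, cb * purity / denom), depth_b=db,
                cn_total=2, truth_a=ca, truth_b=cb))
    return pd.DataFrame(rows)


def planted_records_1d(seed, spec, depth_mean=40):
    """Planted 1-D clusters at purity 1, diploid (expected VAF = CCF / 2)."""
    rng = np.random.default_rng(seed)
    rows = []
    for ccf, n in spec:
        for _ in range(n):
            d = max(1, rng.poisson(depth_mean))
            rows.append(dict(chrom="c", pos=len(rows) + 1, ref="C", alt="T",
                             alt_a=rng.binomial(d, ccf / 2), depth_a=d,
                             alt_b=0, depth_b=depth_mean, cn_total=2))
    return pd.DataFrame(rows)
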