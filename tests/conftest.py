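import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from modstoich.pileup import SITE_KEY, SiteTable

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def make_site_table(rows, tau=0.99, sample="") -> SiteTable:
    """Build a SiteTable from (chrom, pos0, strand, n_mod, n_canon, n_fail)."""
    df = pd.DataFrame(
        rows, columns=SITE_KEY + ["n_mod", "n_canon", "n_fail"]
    )
    return SiteTable(df, sample=sample, tau=tau).finalize()


def binomial_site_table(f_true, coverage, rng, tau=0.99) -> SiteTable:
    """Measurement-model site table: n_mod ~ Binomial(cov, f), no
    basecaller error. The independent route used to study pure sampling
    noise at fixed coverage."""
    f = np.asarray(f_true, dtype=float)
    cov = np.broadcast_to(np.asarray(coverage, dtype=int), f.shape)
    n_mod = rng.binomial(cov, f)
    rows = [
        ("chr1", 10 * i, "+", int(m), int(c - m), 0)
        for i, (m, c) in enumerate(zip(n_mod, cov))
    ]
    return make_site_table(rows, tau=tau)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_calls():
    """Ten calls at one site: 6 confident-mod, 3 confident-canon, 1 fail."""
    probs = [0.999] * 6 + [0.001] * 3 + [0.60]
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(10)],
            "chrom": "chr1",
            "pos0": 100,
            "strand": "+",
            "p_mod": probs,
        }
    )
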