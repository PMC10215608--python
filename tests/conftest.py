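import numpy as np
import pandas as pd
import pytest

from ovisweep.panel import HIGH, LOW, GenotypePanel


def random_panel(n_sites=50, n_samples=20, missing_rate=0.0, seed=0,
                 contig="chr1", pos_span=1_000_000):
    """Random biallelic panel split evenly into high/low groups."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, pos_span + 1), size=n_sites,
                             replace=False))
    p = rng.uniform(0.05, 0.95, size=n_sites)
    g = rng.binomial(2, p[:, None], size=(n_sites, n_samples)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n_sites, n_samples)) < missing_rate
        g[mask] = -1
    samples = [f"s{i:03d}" for i in range(n_samples)]
    groups = {s: (HIGH if i < n_samples // 2 else LOW)
              for i, s in enumerate(samples)}
    sites = pd.DataFrame({"contig": contig, "pos": pos,
                          "ref": "A", "alt": "G"})
    return GenotypePanel(sites=sites, genotypes=g, samples=samples,
                         groups=groups)


@pytest.fixture
def make_panel():
    return random_panel
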