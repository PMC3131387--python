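import numpy as np
import pytest

from lgtscreen.core import Domain, TaxonRecord


@pytest.fixture
def toy_taxonomy() -> dict[str, TaxonRecord]:
    """Five-group taxonomy matching the synthetic generator's label scheme."""
    recs = {}
    layout = [
        ("ARC", Domain.ARCHAEA, "Archaea", 4, 0.50),
        ("ALP", Domain.BACTERIA, "Alphaproteobacteria", 6, 0.55),
        ("MYX", Domain.BACTERIA, "Myxococcales", 6, 0.72),
        ("OTH", Domain.BACTERIA, "OtherBacteria", 8, 0.50),
        ("EUK", Domain.EUKARYOTA, "Eukaryota", 8, 0.45),
    ]
    for prefix, domain, group, count, gc in layout:
        for i in range(1, count + 1):
            tid = f"{prefix}{i:02d}"
            recs[tid] = TaxonRecord(tid, tid, domain, group, gc)
    return recs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
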