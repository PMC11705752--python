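import pandas as pd
import pytest

from promomethyl import make_site_table
from promomethyl.methylation import ReadCallSet


@pytest.fixture
def two_site_table():
    """One region, two CpGs on chr1 at 100 and 150."""
    return make_site_table([("chr1", 100, "r1"), ("chr1", 150, "r1")])


@pytest.fixture
def readset_factory(two_site_table):
    """Build a ReadCallSet for the two-site region from call strings."""

    def _build(calls, sample="S1", sites=None, tallies=None):
        sites = two_site_table if sites is None else sites
        reads = pd.DataFrame(
            {
                "sample_id": sample,
                "region_id": "r1",
                "read_id": [f"read{i}" for i in range(len(calls))],
                "calls": list(calls),
            }
        )
        return ReadCallSet(reads=reads, sites=sites, non_cpg_tallies=tallies)

    return _build
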