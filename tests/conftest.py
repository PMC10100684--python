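import numpy as np
import pandas as pd
import pytest

from plankweb.otu import OtuTable, SampleMetadata


def make_table(counts, taxon_ids=None, sample_ids=None, domain=None):
    counts = np.asarray(counts)
    taxon_ids = taxon_ids or [f"t{i}" for i in range(counts.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(counts.shape[1])]
    frame = pd.DataFrame(counts, index=taxon_ids, columns=sample_ids)
    dom = pd.Series(domain, index=frame.index) if domain is not None else None
    return OtuTable(frame, domain=dom)


@pytest.fixture
def small_table():
    # 4 taxa x 3 samples with unequal totals
    return make_table(
        [[5, 0, 2], [3, 1, 2], [1, 1, 0], [1, 2, 0]],
    )


@pytest.fixture
def uniform_table():
    return make_table([[10, 10], [10, 10], [10, 10], [10, 10]])


@pytest.fixture
def metadata_factory():
    def make(sample_ids, salinity, temperature=None, region=None):
        n = len(sample_ids)
        frame = pd.DataFrame(
            {
                "salinity": salinity,
                "temperature": temperature if temperature is not None else [4.0] * n,
                "region": region if region is not None else ["all"] * n,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return SampleMetadata(frame)

    return make
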