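import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from symevol.parallelism import GeneTable

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_genes():
    """Ten genes on two replicons with assorted lengths."""
    return GeneTable(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "length": [300, 900, 1500, 600, 1200, 450, 750, 3000, 150, 2100],
                "replicon": ["chr"] * 6 + ["plasmid"] * 4,
            }
        )
    )


def make_mutation_row(lineage="B", replicon="chr", position=100, ref="A", alt="T",
                      gene_id="g0", mutation_type="nonsynonymous", **freqs):
    row = {
        "lineage": lineage, "replicon": replicon, "position": position,
        "ref": ref, "alt": alt, "gene_id": gene_id, "mutation_type": mutation_type,
    }
    row.update(freqs)
    return row
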