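import numpy as np
import pandas as pd
import pytest

from coregdom.simulate import SimulationConfig, default_planted_domains


def make_gene_table(tss_list, chrom="chr1", expressed=None, **fc_cols):
    """Minimal gene table from TSS coordinates (plus-strand, 10 kb bodies)."""
    n = len(tss_list)
    if expressed is None:
        expressed = [True] * n
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": list(tss_list),
            "end": [t + 10_000 for t in tss_list],
            "strand": "+",
            "gene_id": [f"{chrom}_g{i + 1}" for i in range(n)],
            "tss": list(tss_list),
            "expressed": expressed,
        }
    )
    defaults = {
        "log2fc_2h": 0.0, "log2fc_12h": 0.0, "log2fc_12v2": 0.0,
        "p": 1.0, "p_adj": 1.0,
    }
    defaults.update(fc_cols)
    for col, val in defaults.items():
        df[col] = val
    return df


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=11,
        n_chromosomes=2,
        genes_per_chromosome=200,
        planted_domains=default_planted_domains(8),
        motif_enrichment_spec={"AP1": {"FC>=4": 10.0}},
        n_enhancers=400,
    )


@pytest.fixture
def fc_grid():
    """Dense log2FC grid crossing the rule boundaries, with both a
    significant and a non-significant p."""
    vals = [-2.0, -1.5, -0.5, 0.0, 0.5, 1.5, 2.0]
    rows = [
        (a, b, c, p)
        for a in vals for b in vals for c in vals for p in (0.01, 0.5)
    ]
    return pd.DataFrame(rows, columns=["fc2", "fc12", "fc12v2", "p"])
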