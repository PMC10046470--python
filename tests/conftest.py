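import numpy as np
import pandas as pd
import pytest

from hma_kit import synthetic


@pytest.fixture(scope="session")
def panel60():
    """Small deterministic panel shared across test modules."""
    return synthetic.generate_panel(synthetic.PanelSpec(n_cell_lines=60, seed=1))


@pytest.fixture(scope="session")
def methylome60(panel60):
    spec = synthetic.MethylomeSpec(n_probes=800, n_regions=150,
                                   probes_per_region=4, planted_dmr_count=20,
                                   seed=2)
    return synthetic.generate_methylome(spec, panel60)


@pytest.fixture(scope="session")
def omics60(panel60):
    spec = synthetic.OmicsSpec(n_genes=300, planted_marker_count=10,
                               confounded_gene_count=10, seed=3)
    return synthetic.generate_omics(spec, panel60)


@pytest.fixture()
def classes_lineage(panel60):
    rec = panel60.records.set_index("cell_line")
    return rec["response_class"], rec["hematopoietic"].astype(int)
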