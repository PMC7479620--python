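import numpy as np
import pandas as pd
import pytest

import hemopipe as hp


@pytest.fixture(scope="session")
def small_cohort():
    """A small 3-subtype cohort with mito genes and ambient barcodes."""
    cfg = hp.SynthConfig(
        n_cells=400,
        n_genes=300,
        n_subtypes=3,
        seed=7,
        n_ambient_barcodes=300,
        ambient_depth_factor=0.02,
        stress_gene_count=10,
    )
    return cfg, *hp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """2000-cell cohort: 6 subtypes, two near-duplicate pairs forming coarse
    groups A and B, one singleton group C, and one uncorrelated noise
    subtype N (emulating a contaminating cell type)."""
    cfg = hp.SynthConfig(
        n_cells=2000,
        n_genes=1000,
        n_subtypes=6,
        subtype_proportions=(0.2, 0.2, 0.15, 0.15, 0.15, 0.15),
        supergroup_map={0: "A", 1: "A", 2: "B", 3: "B", 4: "C", 5: "N"},
        noise_subtypes=(5,),
        seed=3,
    )
    return cfg, *hp.generate_cohort(cfg)


@pytest.fixture
def subtype_labels():
    def make(truth, adata):
        return pd.Series(
            [f"s{t}" for t in truth.cell_subtype], index=adata.obs_names
        )

    return make
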