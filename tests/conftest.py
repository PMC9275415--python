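import numpy as np
import pandas as pd
import pytest

from spliceprm import gene_models, synthetic_data


@pytest.fixture(scope="session")
def toy_graph():
    return gene_models.as5_toy_graph()


@pytest.fixture(scope="session")
def toy_proteoforms(toy_graph):
    return gene_models.as5_proteoforms(toy_graph)


@pytest.fixture(scope="session")
def assay():
    """Default PRM assay for the example gene (frozen peptide factors)."""
    return synthetic_data.build_prm_assay(seed=0)


@pytest.fixture(scope="session")
def exact_assay():
    """Assay with unit recovery factors, for noiseless identity checks."""
    return synthetic_data.build_prm_assay(seed=0, peptide_cv=0.0)


@pytest.fixture(scope="session")
def peptide_info(assay):
    return synthetic_data.assay_peptide_info(assay)


@pytest.fixture(scope="session")
def nrxn3_protein_map(peptide_info):
    """Constitutive peptides report total gene-level protein."""
    return {
        p: "NRXN3"
        for p in peptide_info.loc[
            peptide_info["specificity"] == "constitutive", "peptide"
        ]
    }
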