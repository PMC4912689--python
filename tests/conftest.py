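import warnings

import numpy as np
import pandas as pd
import pytest

from alascan.datamodel import AffinityEstimate, FitStatus
from alascan.simulate import NoiseModel, generate_panel, wild_type_truth, WT_PKI


@pytest.fixture(scope="session")
def wt_camp_dataset():
    """One wild-type cAMP study at the default design (seed 7)."""
    truth = wild_type_truth(pathways=("cAMP",))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_panel(truth, NoiseModel(seed=7))


@pytest.fixture(scope="session")
def true_binding():
    """AffinityEstimates fixed to the generator's true pKi values."""
    return {l: AffinityEstimate(pki=p, sem_pki=0.0, status=FitStatus.ok)
            for l, p in WT_PKI.items()}


def make_response_frame(conc, responses_by_exp, ligand="GLP-1", pathway="cAMP",
                        construct="WT"):
    """Tidy response table from {experiment_id: y-array} over one grid."""
    rows = []
    for exp_id, y in responses_by_exp.items():
        for c, v in zip(conc, y):
            rows.append((construct, ligand, pathway, exp_id, 1, c, v))
    return pd.DataFrame(rows, columns=[
        "construct_id", "ligand_id", "pathway_id", "experiment_id",
        "replicate_id", "concentration", "response"])
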