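import pandas as pd
import pytest

from tnfipredict.config import NRF2_GENES
from tnfipredict.io import load_table2_fixture
from tnfipredict.qpcr import FoldChangeProfile
from tnfipredict.synthetic import SimulationConfig, simulate_cohort

BAND = (0.94, 1.06)


@pytest.fixture(scope="session")
def table2():
    """Packaged validation cohort: ({patient_id: status}, clinical records)."""
    return load_table2_fixture()


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Small noiseless concordant cohort: activators at 1.5, suppressed
    non-activators at 0.85 so every call is decisive."""
    config = SimulationConfig(
        n_activators=5,
        n_nonactivators=5,
        effect_size_activator=1.5,
        effect_size_nonactivator=0.85,
        ratio_cv=0.0,
        dropout_prob=0.0,
        seed=7,
    )
    return simulate_cohort(config)


def make_profile(cd36=None, nrf2=None, sample_id="s1"):
    """Profile with the given CD36 ratio and Nrf2 ratios (None = not evaluable)."""
    ratios, evaluable = {}, {}
    if cd36 is not None:
        ratios["CD36"] = cd36
    evaluable["CD36"] = cd36 is not None
    nrf2 = nrf2 if nrf2 is not None else {}
    for gene in NRF2_GENES:
        if gene in nrf2 and nrf2[gene] is not None:
            ratios[gene] = nrf2[gene]
            evaluable[gene] = True
        elif gene in nrf2:
            evaluable[gene] = False
    return FoldChangeProfile(sample_id=sample_id, ratios=ratios, evaluable=evaluable)


def ct_rows(sample_id, condition, gene, cts):
    return [
        dict(sample_id=sample_id, condition=condition, gene=gene, replicate=i + 1, ct=ct)
        for i, ct in enumerate(cts)
    ]


def small_ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "replicate", "ct"])
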