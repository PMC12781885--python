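import numpy as np
import pytest

from pforge.features import FeatureTable, extract_features, reduce_features, toy_energy_matrix
from pforge.io import NucSequence
from pforge.pssm import PSSM
from pforge.synth import gen_control_promoter


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_pssm():
    return PSSM("uniform", np.full((6, 4), 0.25))


@pytest.fixture
def onehot_pssm():
    freq = np.zeros((4, 4))
    for i, b in enumerate("ACGT"):
        freq[i, i] = 1.0
    return PSSM("acgt", freq)


@pytest.fixture(scope="session")
def control_promoter():
    return gen_control_promoter(120, np.random.default_rng(7))


@pytest.fixture(scope="session")
def variant_panel(control_promoter):
    """80 variants of the control with 4 random substitutions each."""
    rng = np.random.default_rng(11)
    variants = [control_promoter]
    for i in range(80):
        s = list(control_promoter.seq)
        for j in rng.integers(10, 110, size=4):
            alt = [b for b in "ACGT" if b != s[j]]
            s[j] = alt[rng.integers(3)]
        variants.append(NucSequence(f"v{i:02d}", "".join(s), control_promoter.anchor))
    return variants


@pytest.fixture(scope="session")
def feature_table(variant_panel, control_promoter):
    table = extract_features(
        variant_panel,
        control_promoter,
        energy_matrix=toy_energy_matrix(),
        chimera_reference=[control_promoter],
        tss=0,
    )
    return reduce_features(table)


@pytest.fixture(scope="session")
def feature_table_no_control(feature_table):
    ids = [v for v in feature_table.values.index if v != "control"]
    return FeatureTable(feature_table.values.loc[ids], feature_table.categories)
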