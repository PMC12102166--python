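import numpy as np
import pytest

from sinetkit.synthetic import CloneSpec, example_signature_set, simulate_paired_tumor


@pytest.fixture(scope="session")
def sigset():
    return example_signature_set()


@pytest.fixture(scope="session")
def paired_sim(sigset):
    """Paired tumor with shared + two private clones at study-like settings.

    Depth 80, purities 0.6 / 0.8, SBS3-like exposure 0 in the shared clone
    and 0.30 in the private clones.
    """
    clones = [
        CloneSpec("shared", 1000, 1.0, 1.0, np.array([0.5, 0.5, 0.0])),
        CloneSpec("primary_private", 1000, 1.0, 0.0, np.array([0.35, 0.35, 0.30])),
        CloneSpec("metastasis_private", 1000, 0.0, 1.0, np.array([0.35, 0.35, 0.30])),
    ]
    pair, truth = simulate_paired_tumor(
        clones, tcc_primary=0.6, tcc_metastasis=0.8, mean_depth=80,
        signatures=sigset, seed=11,
    )
    return pair, truth
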