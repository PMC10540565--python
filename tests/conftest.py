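import numpy as np
import pytest

from utrmpra import motifs, synthetic


@pytest.fixture(scope="session")
def small_utrome():
    return synthetic.gen_utrome(6, (250, 450), gc=0.45, seed=11)


@pytest.fixture(scope="session")
def fixed_resources():
    return [motifs.MotifResource("PAS_AAUAAA", "PAS"),
            motifs.MotifResource("M6A_RRACH", "M6A")]


@pytest.fixture(scope="session")
def full_resources():
    """PAS + m6A + one PWM + one miRNA seed."""
    rng = np.random.default_rng(5)
    raw = rng.dirichlet(np.ones(4) * 0.3, size=7).T  # 4 x 7, peaked columns
    return [
        motifs.MotifResource("PAS_AAUAAA", "PAS"),
        motifs.MotifResource("M6A_RRACH", "M6A"),
        motifs.MotifResource("RBP_TEST", "RBP_PWM", "synthetic", matrix=raw),
        motifs.MotifResource("miR_test", "MIRNA_SEED", pattern="GAGGUAG"),
    ]


@pytest.fixture(scope="session")
def mutation_set(small_utrome):
    muts, truth = synthetic.gen_mutations(small_utrome, 40, seed=21)
    return muts, truth
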