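import numpy as np
import pytest

from fgarray import ProbeRecord, ScoringParams, SimulationParams, TargetRecord, generate_panel


@pytest.fixture(scope="session")
def scoring():
    return ScoringParams()


@pytest.fixture
def probe20():
    return ProbeRecord("p20", "ACGTACGTACGTACGTACGT", ("cA",))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_probe(rng, length=None, name="P", group="AOA", clades=("c",)):
    if length is None:
        length = int(rng.integers(18, 29))
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return ProbeRecord(name, seq, clades, array_group=group)


def embed(probe_seq, rng, flank=20):
    left = "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return left + probe_seq + right


@pytest.fixture(scope="session")
def small_panel():
    """Deterministic engineered panel: 4 probes x 5 targets each."""
    params = SimulationParams(seed=42, n_probes=4, noise_cv=0.0)
    return params, *generate_panel(params)
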