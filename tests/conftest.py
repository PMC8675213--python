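import numpy as np
import pytest

import navkit as nk
from navkit.protocols import protocol_preset

CONDITIONS = [("WT", 22), ("L1624Q", 22), ("WT", 37), ("L1624Q", 37)]


@pytest.fixture(scope="session")
def protocols():
    """The four standard protocols at the default 50 kHz sampling."""
    return {name: protocol_preset(name)
            for name in ("activation", "ssfi", "recovery", "persistent")}


@pytest.fixture(scope="session")
def coarse_protocols():
    """Faster 20 kHz variants for bulk cohort tests."""
    return {name: protocol_preset(name, sample_interval=0.05)
            for name in ("activation", "ssfi", "recovery", "persistent")}


@pytest.fixture(scope="session")
def clean_suites(protocols):
    """Noise-free single-cell protocol suites for all four conditions."""
    out = {}
    for gen, temp in CONDITIONS:
        phen = nk.default_phenotype(gen, temp)
        out[(gen, temp)] = {
            name: nk.simulate_protocol(phen, proto, capacitance=15.0)
            for name, proto in protocols.items()}
    return out


@pytest.fixture(scope="session")
def wt_neuron():
    return nk.build_neuron(nk.wt_variant())


@pytest.fixture(scope="session")
def lq_neuron():
    return nk.build_neuron(nk.lq_variant())
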