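import numpy as np
import pytest

from signet import (
    NeuralSignature,
    NeuronParams,
    PlasticityParams,
    SimulationConfig,
    StimulusEntry,
    run_simulation,
)


def make_config(
    rows=6,
    cols=6,
    duration=2000,
    seed=7,
    p=0.05,
    TH=50,
    RP=50,
    AP=200,
    g=1,
    M=400,
    L=4,
    gap=24,
    signature_spikes=6,
    stimuli=(),
    **kw,
):
    return SimulationConfig(
        duration=duration,
        seed=seed,
        rows=rows,
        cols=cols,
        neuron=NeuronParams(p=p, TH=TH, RP=RP, AP=AP),
        plasticity=PlasticityParams(
            M=M, L=L, gap=gap, pattern_len=signature_spikes - 1
        ),
        g=g,
        signature_spikes=signature_spikes,
        stimuli=tuple(stimuli),
        **kw,
    )


@pytest.fixture
def config_factory():
    return make_config


@pytest.fixture(scope="session")
def driven_small_record():
    """A 6x6 driven run with active recognition, recorded at stride 1.

    Shared by analysis and network tests; the low learning threshold
    (L=2) guarantees fingerprint recognition events within 4000 steps.
    """
    cfg = make_config(
        rows=6,
        cols=6,
        duration=4000,
        seed=11,
        L=2,
        stimuli=[StimulusEntry(period=100, cell=14, g_e=50)],
    )
    return run_simulation(
        cfg, frame_stride=1, label_stride=1, record_raster=True
    )


@pytest.fixture
def fixed_signatures():
    def make(n, isis=(2, 3, 4, 5, 6)):
        return tuple(NeuralSignature(isis) for _ in range(n))

    return make
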