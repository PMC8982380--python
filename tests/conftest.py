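import numpy as np
import pytest

from acvu import synth


@pytest.fixture(scope="session")
def control_animal():
    """One rendered negative-control animal (noisy, default settings)."""
    spec = synth.sample_animal(synth.negative_control(), seed=123, animal_id="ctrl")
    stack, record = synth.render_animal(spec)
    return stack, record


@pytest.fixture()
def four_nuclei():
    """Four well-separated nuclei with fixed totals, for noise-free renders."""
    centers = [(12.0, 16.0, 8.0), (24.0, 16.0, 8.0), (12.0, 32.0, 8.0), (24.0, 32.0, 8.0)]
    totals = [20000.0, 1500.0, 8000.0, 3000.0]
    nuclei = []
    for cell, center, gfp in zip(synth.ROLES, centers, totals):
        nuclei.append(
            synth.NucleusTruth(
                cell_id=cell,
                sister_id=synth.SISTER_OF[cell],
                center=center,
                radius=2.5,
                true_gfp_total=gfp,
                true_mcherry_total=30000.0,
            )
        )
    return nuclei


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
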