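import numpy as np
import pytest

import tcspcmcr as tm
from tcspcmcr.axes import ExponentialModel, InstrumentResponse


@pytest.fixture(scope="session")
def axis():
    return tm.make_axis()


@pytest.fixture(scope="session")
def irf(axis):
    return tm.make_irf(axis=axis)


@pytest.fixture(scope="session")
def delta_irf(axis):
    """All IRF mass in the first bin: convolution becomes the identity."""
    counts = np.zeros(axis.n_bins)
    counts[0] = 1.0
    return InstrumentResponse(axis=axis, counts=counts, fwhm=axis.bin_width,
                              t0=axis.centers[0])


def single_species(lifetimes, amplitudes, ph=4.0, name="species"):
    return tm.SpeciesDefinition(
        name,
        ExponentialModel(np.asarray(amplitudes, float), np.asarray(lifetimes, float)),
        {ph: 1.0},
    )


@pytest.fixture(scope="session")
def acidic_species():
    """Four-term folded-state regime: dominant ~30 ps quenched component."""
    return single_species([3.01, 0.88, 0.18, 0.03], [1.75, 2.59, 7.93, 87.73])


@pytest.fixture(scope="session")
def control_species():
    """Unfolded control-strand regime: three lifetimes, pH-invariant."""
    return single_species([1.88, 0.80, 0.20], [20.0, 30.0, 50.0], ph=7.0)


def simulate_group(species, irf, n_traces=7, seed=0, peak=30_000, ph=4.0):
    """n wavelength-replicate traces of one species mixture."""
    return [
        tm.simulate_trace(
            [(species, 1.0)], irf, peak, seed=(seed, 0, i),
            ph=ph, wavelength=560.0 + 5 * i, sequence_id="test",
        )
        for i in range(n_traces)
    ]
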