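import numpy as np
import pytest

import metfref as m


@pytest.fixture(scope="session")
def audiological_freqs() -> tuple[float, ...]:
    return m.AUDIOLOGICAL_GRID.frequencies_hz


@pytest.fixture(scope="session")
def small_population():
    """Gaussian population: 4 groups x 1 method x 12 specimens."""
    spec = m.PopulationSpec(n_groups=4, n_methods=1, n_tb_per_cell=12,
                            seed=42)
    return m.sample_population(spec)


@pytest.fixture(scope="session")
def excitation_spec():
    """Hannover-style multisine plan: all audiological tones on exact
    bins of a 1024-point block at 25.6 kHz (25 Hz bin width)."""
    return m.ExcitationSpec(
        frequencies_hz=m.AUDIOLOGICAL_GRID.frequencies_hz,
        sample_rate_hz=25600.0, block_size=1024, n_averages=20)


@pytest.fixture()
def simple_curve():
    ref = m.packaged_reference("displacement")
    return m.METFCurve(
        tb_id="TB1", group="Dresden", method="A", unit="displacement",
        points={f: s.mean_db for f, s in ref.stats.items()})
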