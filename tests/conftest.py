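import numpy as np
import pytest

from pharmsel import synthetic


@pytest.fixture
def dr_spec():
    """Clean 8-point operational-model dose-response spec."""
    return synthetic.DoseResponseSpec(
        basal=5.0, em=100.0, log_ka=-7.0, log_tau=0.5,
        conc_grid=tuple(np.linspace(-10.0, -4.0, 8)),
        n_replicates=3, noise_sd=0.0, seed=11,
    )


@pytest.fixture
def two_site_spec():
    return synthetic.BindingCurveSpec(
        mode="competition_two_site", top=100.0, bottom=0.0,
        p_ic50_high=9.0, p_ic50_low=6.0, fraction_high=0.6,
        conc_grid=tuple(np.linspace(-12.0, -3.0, 15)), noise_sd=0.0, seed=2,
    )


@pytest.fixture
def markov_spec():
    return synthetic.MarkovTraceSpec(
        n_frames=4000, dt=0.25,
        p_open_to_closed=0.02, p_closed_to_open=0.01,
        open_state_emissions={"chi1_n652": (20.0, 10.0), "d_tm3_tm6_ic": (12.0, 0.3)},
        closed_state_emissions={"chi1_n652": (170.0, 10.0), "d_tm3_tm6_ic": (8.0, 0.3)},
        features=("chi1_n652", "d_tm3_tm6_ic"),
        burn_in_ns=50.0, seed=5, initial_state="open",
    )
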