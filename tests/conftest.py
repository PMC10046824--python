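import pytest

import calodose as cd

#: Published best-fit response parameters, per 100 mA*s.
TABLE_PARAMS = cd.CT_FIT_PARAMS

#: Five per-cycle reference chamber doses of the megavolt linearity experiment, Gy.
SIX_MV_DOSES = cd.REFERENCE_DOSES.six_mv_ic_doses

CT_SETTINGS = list(cd.REFERENCE_DOSES.ct_current_settings)


@pytest.fixture(scope="session")
def cp_room():
    """Polystyrene heat capacity at 24.5 degC (297.65 K), J/(kg K)."""
    return cd.heat_capacity(297.65)


@pytest.fixture(scope="session")
def ct_schedule():
    """CT regime: ten 2 s scans every 10 s, sampled at 0.25 s, 10 s lead-in."""
    return cd.IrradiationSchedule(t_open=2.0, period=10.0, n_cycles=10, t_start=10.0, dt=0.25)


@pytest.fixture(scope="session")
def sixmv_schedule():
    """Megavolt regime: twenty 60 s on / 60 s off cycles, sampled at 1 s."""
    return cd.IrradiationSchedule(t_open=60.0, period=120.0, n_cycles=20, t_start=60.0, dt=1.0)


@pytest.fixture(scope="session")
def table_params():
    return TABLE_PARAMS


@pytest.fixture(scope="session")
def staircase_params():
    """Pure slow staircase: no fast term, effectively lossless slow term."""
    return cd.TransientParams(k1=0.0, k2=0.016, tau1=1.4, tau2=1e9)


@pytest.fixture(scope="session")
def ideal_ct_staircase(ct_schedule, staircase_params):
    """Noiseless lossless staircase record over the CT schedule (with lead-in)."""
    return cd.forward_waveform(
        staircase_params, cd.DriftParams(), ct_schedule, t0=0.0
    )
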