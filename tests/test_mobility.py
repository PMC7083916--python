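"""ATD fitting, stepped-field CCS and resolving-power arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import simms2 as s
from simms2.errors import FitError
from simms2.mobility import (
    ATD,
    DEFAULT_CONFIG,
    InstrumentConfig,
    fit_atd,
    peak_to_peak_resolution,
    reduced_mobility,
    simulate_atd,
)


def test_instrument_config_rejects_nonpositive():
    with pytest.raises(ValueError):
        InstrumentConfig(drift_length_m=-1.0)
    with pytest.raises(ValueError):
        InstrumentConfig(pressure_torr=0.0)


def test_atd_validation():
    with pytest.raises(ValueError):
        ATD(np.array([1.0, 1.0, 2.0]), np.zeros(3), 50.0)
    with pytest.raises(ValueError):
        ATD(np.array([1.0, 2.0, 3.0]), np.array([1.0, -2.0, 1.0]), 50.0)


# -- ATD fitting --------------------------------------------------------

def test_noiseless_gaussian_recovered_exactly():
    atd = simulate_atd([(4.20, 0.30, 500.0)], 60.0)
    (peak,) = fit_atd(atd)
    assert peak.centroid_ms == pytest.approx(4.20, abs=1e-6)
    assert peak.fwhm_ms == pytest.approx(0.30, abs=1e-6)


def test_two_separated_gaussians_in_centroid_order():
    atd = simulate_atd([(5.0, 0.2, 800.0), (5.6, 0.2, 400.0)], 60.0)
    peaks = fit_atd(atd)
    assert len(peaks) == 2
    assert peaks[0].centroid_ms < peaks[1].centroid_ms
    assert peaks[0].area > peaks[1].area


def test_noisy_centroid_within_a_tenth_percent(rng):
    atd = simulate_atd([(6.0, 0.25, 1000.0)], 60.0,
                       intensity_noise=0.01, rng=rng)
    (peak,) = fit_atd(atd)
    assert abs(peak.centroid_ms - 6.0) / 6.0 < 1e-3


def test_flat_trace_is_an_error():
    t = np.linspace(0, 10, 100)
    with pytest.raises(FitError):
        fit_atd(ATD(t, np.ones_like(t), 50.0))


# -- stepped-field fit --------------------------------------------------

def test_noiseless_series_recovers_mobility_exactly():
    series = s.simulate_stepped_field(242.0, 1, 1100.0, t0_ms=0.25)
    res = s.stepped_field_fit(series)
    K_true = s.mobility_from_ccs(242.0, 1, 1100.0, DEFAULT_CONFIG)
    assert res.K == pytest.approx(K_true, rel=1e-9)
    assert res.r_squared == pytest.approx(1.0, abs=1e-9)
    assert res.t0_ms == pytest.approx(0.25, abs=1e-6)


def test_r_squared_survives_realistic_timing_noise():
    series = s.simulate_stepped_field(242.0, 1, 1100.0, noise=0.001, seed=7)
    res = s.stepped_field_fit(series)
    assert res.r_squared >= 0.9999


def test_two_point_series_is_an_exact_line():
    series = s.simulate_stepped_field(300.0, 2, 2000.0, voltages=(60.0, 110.0),
                                      t0_ms=0.4)
    res = s.stepped_field_fit(series)
    assert res.t0_ms == pytest.approx(0.4, abs=1e-9)
    assert res.r_squared == 1.0


def test_duplicate_voltages_collapse_with_warning():
    base = s.simulate_stepped_field(242.0, 1, 1100.0, voltages=(50.0, 80.0))
    dup = s.SteppedFieldSeries(base.atds + (base.atds[0],), mz=1100.0, charge=1)
    with pytest.warns(UserWarning):
        res = s.stepped_field_fit(dup)
    assert res.ccs_A2 is None and res.K > 0


# -- Mason-Schamp -------------------------------------------------------

def test_ccs_example_value():
    # K0 = 4.0 cm^2/Vs at 298 K; value frozen from an independent
    # numeric evaluation of the Mason-Schamp expression
    cfg = InstrumentConfig(temperature_K=298.0, pressure_torr=760.0)
    K = 4.0e-4 / ((cfg.pressure_torr / 760.0) * (273.15 / cfg.temperature_K))
    assert reduced_mobility(K, cfg) == pytest.approx(4.0e-4, rel=1e-12)
    assert s.ccs_from_mobility(K, 1, 416.05, cfg) == pytest.approx(
        134.63, abs=0.01
    )


def test_ccs_scaling_laws():
    cfg = DEFAULT_CONFIG
    base = s.ccs_from_mobility(0.05, 1, 416.05, cfg)
    assert s.ccs_from_mobility(0.10, 1, 416.05, cfg) == pytest.approx(
        base / 2, rel=1e-12
    )
    assert s.ccs_from_mobility(0.05, 2, 416.05, cfg) == pytest.approx(
        base * 2, rel=1e-12
    )


def test_mobility_ccs_inverse_pair():
    K = s.mobility_from_ccs(242.0, 1, 1100.0, DEFAULT_CONFIG)
    assert s.ccs_from_mobility(K, 1, 1100.0, DEFAULT_CONFIG) == pytest.approx(
        242.0, rel=1e-12
    )


# -- resolving power ----------------------------------------------------

def test_required_resolving_power_linearity():
    rp = s.required_resolving_power(0.02, 0.75)
    assert s.required_resolving_power(0.04, 0.75) == pytest.approx(rp / 2)
    assert s.required_resolving_power(0.02, 1.5) == pytest.approx(rp * 2)
    with pytest.raises(ValueError):
        s.required_resolving_power(0.0, 0.75)


def test_plate_number_identity_point_and_monotone():
    assert s.plate_number(1.0 / (2 * math.sqrt(2 * math.log(2)))) == (
        pytest.approx(1.0)
    )
    rps = [10.0, 20.0, 40.0]
    ns = [s.plate_number(r) for r in rps]
    assert ns[0] < ns[1] < ns[2]


def test_two_percent_isomers_at_rp64_resolve_at_three_quarters():
    """Closed loop: simulate the two-isomer ATD at the resolving power
    the arithmetic demands and measure the fitted resolution."""
    rp = s.required_resolving_power(0.02, 0.75)
    t = 8.0
    atd = simulate_atd(
        [(t, t / rp, 1000.0), (t * 1.02, t * 1.02 / rp, 1000.0)], 60.0
    )
    p1, p2 = fit_atd(atd)
    assert peak_to_peak_resolution(p1, p2) == pytest.approx(0.75, abs=0.02)


# -- simulator round trips ---------------------------------------------

def test_zero_noise_full_pipeline_round_trip():
    series = s.simulate_stepped_field(242.0, 1, 1100.0)
    res = s.ccs_from_series(series)
    assert res.ccs_A2 == pytest.approx(242.0, rel=1e-6)


def test_noisy_round_trip_within_half_percent():
    series = s.simulate_stepped_field(242.0, 1, 1100.0, noise=0.001, seed=7)
    res = s.ccs_from_series(series)
    assert abs(res.ccs_A2 - 242.0) / 242.0 < 0.005


def test_ccs_independent_of_voltage_subset():
    full = s.simulate_stepped_field(350.0, 2, 1500.0)
    ref = s.ccs_from_series(full).ccs_A2
    for sub in [(0, 1), (2, 5), (0, 3, 7)]:
        series = s.SteppedFieldSeries(
            tuple(full.atds[i] for i in sub), mz=750.0, charge=2
        )
        assert s.ccs_from_series(series).ccs_A2 == pytest.approx(ref, rel=1e-9)


def test_replicate_summary():
    vals = [241.0, 242.0, 243.0]
    rep = s.replicate_ccs(vals)
    assert rep.ccs_A2 == pytest.approx(242.0)
    assert rep.replicates == 3
    assert rep.deviation == pytest.approx(1.0 / 242.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    ccs=st.floats(100.0, 600.0),
    z=st.integers(1, 3),
    mass=st.floats(300.0, 3000.0),
    noise=st.sampled_from([0.0, 0.001, 0.002]),
)
def test_parameter_recovery_property(ccs, z, mass, noise):
    series = s.simulate_stepped_field(ccs, z, mass, noise=noise, seed=42)
    res = s.ccs_from_series(series)
    if noise == 0.0:
        assert res.ccs_A2 == pytest.approx(ccs, rel=1e-6)
    else:
        assert abs(res.ccs_A2 - ccs) / ccs < 3 * noise + 1e-4
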