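"""Synthetic weather and trial generators: determinism, structure, recovery."""

import datetime as dt

import numpy as np
import pytest

from chiagrow import (
    ANTUMAPU,
    INTIHUASI,
    accumulate_gdd,
    apply_deficit_effect,
    double_logistic,
    fit_double_logistic,
    generate_plant_data,
    generate_weather,
    irrigation_design,
    sowing_date_design,
)
from chiagrow.dlogistic import DoubleLogisticCoefficients
from chiagrow.synth import SiteProfile, _allocation

from dataclasses import replace


def test_zero_noise_tmean_on_sinusoid():
    quiet = replace(ANTUMAPU, noise_sd=0.0)
    days = generate_weather(quiet, dt.date(2011, 1, 10), 5, seed=0)
    for d in days:
        doy = d.date.timetuple().tm_yday
        clim = quiet.mean_temp + quiet.amplitude * np.cos(
            2 * np.pi * (doy - quiet.peak_doy) / 365.25
        )
        assert d.tmean == pytest.approx(clim)


def test_weather_deterministic_per_seed():
    a = generate_weather(ANTUMAPU, dt.date(2011, 1, 1), 30, seed=9)
    b = generate_weather(ANTUMAPU, dt.date(2011, 1, 1), 30, seed=9)
    c = generate_weather(ANTUMAPU, dt.date(2011, 1, 1), 30, seed=10)
    assert a == b
    assert a != c


def test_annual_mean_matches_site_climate():
    """A full year at the warm-temperate site averages near 14 degC."""
    means = []
    for seed in range(5):
        days = generate_weather(ANTUMAPU, dt.date(2011, 1, 1), 365, seed=seed)
        means.append(np.mean([d.tmean for d in days]))
    assert abs(np.mean(means) - 14.0) < 0.5


def test_site_profile_validation():
    with pytest.raises(ValueError):
        SiteProfile(
            name="bad", latitude=0.0, mean_temp=10.0, amplitude=-1.0, noise_sd=0.5,
            diurnal_range=10.0, mean_u2=2.0, mean_rh=60.0, rn_mean=10.0, rn_amplitude=5.0,
        )


def _thermal_for(design, seed=3):
    first = min(t.sowing_date for t in design.treatments)
    n = max(
        (t.sowing_date - first).days + design.season_days for t in design.treatments
    ) + 1
    weather = generate_weather(design.site, first, n, seed=seed)
    return {
        t.label: accumulate_gdd(weather, start_date=t.sowing_date)
        for t in design.treatments
    }


def test_trial_layouts_match_design():
    """SD: 2 treatments x 5 replicates; IT: 2 x 6; harvests per cadence."""
    for design, blocks in ((sowing_date_design(), 5), (irrigation_design(), 6)):
        plants = generate_plant_data(design, _thermal_for(design), seed=1)
        assert plants["treatment"].nunique() == 2
        assert plants["block"].nunique() == blocks
        assert plants["plant_id"].nunique() == 10
        harvests = design.harvest_das()
        assert sorted(plants["das"].unique()) == harvests
        assert len(plants) == 2 * blocks * 10 * len(harvests)
        assert harvests[0] == design.first_harvest_das


def test_plant_data_deterministic():
    design = irrigation_design()
    thermal = _thermal_for(design)
    a = generate_plant_data(design, thermal, seed=4)
    b = generate_plant_data(design, thermal, seed=4)
    assert a.equals(b)


def test_organ_masses_sum_to_total():
    design = sowing_date_design()
    plants = generate_plant_data(design, _thermal_for(design), seed=2)
    total = plants[["dm_leaf_g", "dm_stem_g", "dm_root_g", "dm_inflo_g"]].sum(axis=1)
    assert (total > 0).all()
    # allocation fractions always sum to one
    for add in (0.0, 300.0, 700.0, 1200.0):
        assert _allocation(add, 900.0, 1300.0).sum() == pytest.approx(1.0)
        assert (_allocation(add, 900.0, 1300.0) >= 0).all()


def test_zero_noise_observations_on_truth_curve():
    design = irrigation_design()
    quiet = replace(
        design,
        treatments=tuple(
            replace(t, biomass_sd=0.0, leaf_area_sd=0.0) for t in design.treatments
        ),
    )
    thermal = _thermal_for(quiet)
    plants = generate_plant_data(quiet, thermal, seed=0)
    for trt in quiet.treatments:
        sub = plants[plants["treatment"] == trt.label]
        total = sub[["dm_leaf_g", "dm_stem_g", "dm_root_g", "dm_inflo_g"]].sum(axis=1)
        truth = double_logistic(sub["add"].to_numpy(), trt.biomass)
        on_curve = truth > 0.01  # floored where the truth dips non-positive
        np.testing.assert_allclose(total[on_curve], truth[on_curve], rtol=1e-9)


def test_fit_recovers_growth_inflection_within_two_percent():
    """Full-cycle SD1 observations at the published noise magnitude recover S."""
    c = sowing_date_design().treatments[0].biomass
    t = np.arange(0.0, 1401.0, 25.0)
    rng = np.random.default_rng(8)
    recovered = []
    for _ in range(5):
        y = double_logistic(t, c) + rng.normal(0, 0.4906, t.size)
        fit = fit_double_logistic(t, y, restarts=8, seed=1)
        recovered.append(fit.coefficients.s)
    assert abs(np.median(recovered) - c.s) / c.s < 0.02


def test_doubling_noise_roughly_doubles_residual():
    c = sowing_date_design().treatments[0].biomass
    t = np.arange(0.0, 1401.0, 25.0)
    rmses = []
    for sd in (0.5, 1.0):
        vals = []
        for seed in range(4):
            rng = np.random.default_rng(100 + seed)
            y = double_logistic(t, c) + rng.normal(0, sd, t.size)
            vals.append(fit_double_logistic(t, y, restarts=6, seed=2).rmse)
        rmses.append(np.mean(vals))
    assert rmses[1] / rmses[0] == pytest.approx(2.0, rel=0.35)


def test_deficit_effect_scales_range():
    design = irrigation_design()
    b, l = design.treatments[0].biomass, design.treatments[0].leaf_area
    b0, l0 = apply_deficit_effect(b, l, 0.0, 0.0)
    assert b0 == b and l0 == l
    b54, l43 = apply_deficit_effect(b, l, 0.54, 0.43)
    assert b54.y_max - b54.y_min == pytest.approx(0.46 * (b.y_max - b.y_min))
    assert l43.y_max - l43.y_min == pytest.approx(0.57 * (l.y_max - l.y_min))
    assert (b54.y_min, b54.s, b54.a, b54.m_s, b54.m_a) == (
        b.y_min, b.s, b.a, b.m_s, b.m_a
    )


def test_deficit_effect_integrated_ratio():
    """Season integrals of the curve-minus-floor scale exactly with 1 - r."""
    b = DoubleLogisticCoefficients(0.0, 40.0, 0.02, 500.0, 0.03, 900.0)
    l = DoubleLogisticCoefficients(0.0, 1000.0, 0.02, 450.0, 0.03, 900.0)
    b2, _ = apply_deficit_effect(b, l, 0.54, 0.0)
    t = np.linspace(0, 1200, 5000)
    full = np.trapezoid(double_logistic(t, b) - b.y_min, t)
    reduced = np.trapezoid(double_logistic(t, b2) - b2.y_min, t)
    assert reduced / full == pytest.approx(0.46, rel=1e-6)


def test_deficit_effect_validation():
    design = irrigation_design()
    b, l = design.treatments[0].biomass, design.treatments[0].leaf_area
    with pytest.raises(ValueError):
        apply_deficit_effect(b, l, 1.0, 0.2)
    with pytest.raises(ValueError):
        apply_deficit_effect(b, l, 0.2, -0.1)


def test_cadence_band_enforced():
    design = sowing_date_design()
    with pytest.raises(ValueError):
        replace(design, cadence_days=20)


def test_intihuasi_flowering_near_reported_thermal_time():
    """The calibrated desert climatology puts flowering (70 DAS) near 499 ADD."""
    design = irrigation_design()
    thermal = _thermal_for(design, seed=0)
    add_flowering = thermal["IT1"].das_to_add(70.0)
    assert add_flowering == pytest.approx(499.0, rel=0.08)
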