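"""Empirical machinery: growth-rate and IMP functions, moult bookkeeping,
stage switching."""

import datetime as dt

import numpy as np
import pytest

import krillgrowth as kg
from krillgrowth.base import KrillState, MoultClock
from krillgrowth.empirical import moult_step
from krillgrowth.engine import EnvDay
from krillgrowth.params import RegistryError, get_parameters


def _env(date, sst=0.0, chl=1.0, ice=False):
    return EnvDay(date=date, sst=sst, chl=chl, poc=50 * chl,
                  photoperiod=18.0, ice=ice)


# --------------------------------------------------------------------------
# parameter registry
# --------------------------------------------------------------------------

def test_registry_loads_and_every_coefficient_is_cited():
    reg = kg.load_registry()
    assert ("atkinson2006", "juvenile") in reg
    assert ("kawaguchi2006", "all krill") in reg
    for ps in reg.values():
        assert ps.source
        for name in ps.coefficients:
            assert ps.citations[name], f"{ps.model_id}/{name} lacks citation"


def test_registry_rejects_uncited_coefficient(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text(
        "model: x\nstage: juvenile\nsource: s\n"
        "coefficients:\n  a: {value: 1.0, units: ''}\n")
    from krillgrowth.params import load_parameter_file
    with pytest.raises(RegistryError, match="citation"):
        load_parameter_file(bad)


def test_registry_rejects_unknown_stage_label(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text(
        "model: x\nstage: larva\nsource: s\n"
        "coefficients:\n  a: {value: 1.0, citation: c}\n")
    from krillgrowth.params import load_parameter_file
    with pytest.raises(RegistryError, match="stage"):
        load_parameter_file(bad)


# --------------------------------------------------------------------------
# Atkinson growth-rate function
# --------------------------------------------------------------------------

def test_atkinson_dgr_matches_double_transcription_oracle():
    """Second, literal-arithmetic evaluation of the juvenile fit at
    (26 mm, 0 degC, 1 mg chl m-3)."""
    expected = (-0.158 + 0.00674 * 26 - 0.000101 * 26 ** 2
                + 0.385 * 1.0 / (0.321 + 1.0) + 0.00811 * 0 - 0.0115 * 0 ** 2)
    got = kg.atkinson_dgr(26.0, 0.0, 1.0,
                          get_parameters("atkinson2006", "juvenile"))
    assert got == pytest.approx(expected, abs=1e-12)
    assert got == pytest.approx(0.2404098743, abs=1e-9)


def test_atkinson_dgr_non_decreasing_in_chlorophyll():
    params = get_parameters("atkinson2006", "juvenile")
    chl = np.linspace(0, 10, 500)
    for sst in (-2.0, 0.0, 3.0):
        rates = kg.atkinson_dgr(26.0, sst, chl, params)
        assert (np.diff(rates) >= -1e-12).all()


def test_atkinson_dgr_juvenile_summer_peak_exceeds_threshold():
    params = get_parameters("atkinson2006", "juvenile")
    sst = np.linspace(-2, 4, 200)[:, None]
    chl = np.linspace(0, 5, 200)[None, :]
    assert kg.atkinson_dgr(26.0, sst, chl, params).max() >= 0.3


def test_atkinson_dgr_rejects_negative_chl_and_unknown_stage():
    with pytest.raises(ValueError):
        kg.atkinson_dgr(26.0, 0.0, -1.0,
                        get_parameters("atkinson2006", "juvenile"))
    with pytest.raises(RegistryError):
        get_parameters("atkinson2006", "adult male")


# --------------------------------------------------------------------------
# intermoult-period functions
# --------------------------------------------------------------------------

def test_kawaguchi_imp_thirty_days_at_zero_degrees():
    assert kg.kawaguchi_imp(0.0) == pytest.approx(30.0)


def test_kawaguchi_imp_monotonically_decreasing():
    T = np.linspace(-2, 5, 300)
    imps = kg.kawaguchi_imp(T)
    assert (np.diff(imps) < 0).all()
    assert (imps > 0).all()


def test_tarling_imp_ten_days_for_35mm_female_at_zero_degrees():
    params = get_parameters("tarling2006", "adult female")
    assert kg.tarling_imp(0.0, 35.0, params) == pytest.approx(10.0)


def test_imp_ratio_kawaguchi_to_tarling_near_three():
    params = get_parameters("tarling2006", "adult female")
    ratio = kg.kawaguchi_imp(0.0) / kg.tarling_imp(0.0, 35.0, params)
    assert 2.5 <= ratio <= 3.5


def test_tarling_female_imp_lengthens_above_half_degree():
    params = get_parameters("tarling2006", "adult female")
    assert (kg.tarling_imp(1.5, 35.0, params)
            > kg.tarling_imp(0.5, 35.0, params))
    T = np.linspace(0.5, 4.0, 100)
    assert (np.diff(kg.tarling_imp(T, 35.0, params)) > 0).all()


def test_tarling_juvenile_imp_interior_maximum_near_three_degrees():
    params = get_parameters("tarling2006", "juvenile")
    T = np.linspace(-2, 5, 701)
    imps = kg.tarling_imp(T, 26.0, params)
    assert T[np.argmax(imps)] == pytest.approx(3.0, abs=0.1)
    assert imps.max() > imps[0] and imps.max() > imps[-1]


def test_tarling_imp_rejects_unsupported_stage():
    with pytest.raises(ValueError, match="stage"):
        kg.tarling_imp(0.0, 35.0, get_parameters("atkinson2006", "all krill"))


# --------------------------------------------------------------------------
# stage switching
# --------------------------------------------------------------------------

@pytest.mark.parametrize("length,model,expected", [
    (34.9, "atkinson2006", "juvenile"),
    (35.0, "atkinson2006", "all krill"),
    (34.9, "tarling2006", "juvenile"),
    (35.0, "tarling2006", "adult female"),
    (35.0, "wiedenmann2008", "all krill"),
])
def test_stage_select_switches_at_35mm(length, model, expected):
    assert kg.stage_select(length, model) == expected


def test_stage_select_rejects_nonpositive_length():
    with pytest.raises(ValueError):
        kg.stage_select(0.0, "atkinson2006")


# --------------------------------------------------------------------------
# generic moult step
# --------------------------------------------------------------------------

def _moult_state(date, length=26.0, imp=10):
    return KrillState(length_mm=length, date=date, stage="juvenile",
                      extras={"clock": MoultClock(duration_days=imp)})


def test_moult_step_zero_increment_when_dgr_is_zero():
    d0 = dt.date(2013, 11, 1)
    state = _moult_state(d0, imp=3)
    for i in range(3):
        state = moult_step(state, _env(d0 + dt.timedelta(days=i)),
                           imp_fn=lambda T, L, s: 3,
                           increment_fn=lambda L, T, F, s: 0.0)
    assert state.extras["moulted"]
    assert state.length_mm == 26.0


def test_moult_step_constant_forcing_matches_daily_accumulation_oracle():
    """With increment = rate*IMP, a 10-day moult cycle equals summing an
    equivalent daily-rate model."""
    rate = 0.12
    d0 = dt.date(2013, 11, 1)
    state = _moult_state(d0, imp=10)
    for i in range(20):
        state = moult_step(state, _env(d0 + dt.timedelta(days=i)),
                           imp_fn=lambda T, L, s: 10,
                           increment_fn=lambda L, T, F, s: rate * 10)
    assert state.length_mm == pytest.approx(26.0 + 20 * rate)


def test_moult_step_lengths_are_stepwise_constant_between_moults():
    d0 = dt.date(2013, 11, 1)
    state = _moult_state(d0, imp=7)
    lengths, moults = [], []
    for i in range(21):
        state = moult_step(state, _env(d0 + dt.timedelta(days=i)),
                           imp_fn=lambda T, L, s: 7,
                           increment_fn=lambda L, T, F, s: 1.0)
    # three moults of +1 mm, constant in between
    assert state.length_mm == pytest.approx(29.0)


def test_moult_step_ice_days_extend_the_imp():
    """Three interleaved ice days in a 10-day IMP postpone the moult to
    day 13."""
    d0 = dt.date(2013, 11, 1)
    state = _moult_state(d0, imp=10)
    ice_days = {2, 5, 8}
    moult_day = None
    for i in range(15):
        state = moult_step(state, _env(d0 + dt.timedelta(days=i),
                                       ice=i in ice_days),
                           imp_fn=lambda T, L, s: 10,
                           increment_fn=lambda L, T, F, s: 1.0)
        if state.extras["moulted"]:
            moult_day = i + 1
            break
    assert moult_day == 13
    clock_means_days = 10  # env means cover exactly the non-ice days
    assert state.length_mm == pytest.approx(27.0)


def test_moult_step_running_means_cover_only_elapsed_days():
    d0 = dt.date(2013, 11, 1)
    state = _moult_state(d0, imp=4)
    temps = [1.0, 2.0, 3.0, 6.0]
    seen = {}
    for i, T in enumerate(temps):
        state = moult_step(state, _env(d0 + dt.timedelta(days=i), sst=T),
                           imp_fn=lambda T, L, s: 4,
                           increment_fn=lambda L, T, F, s: seen.setdefault(
                               "mean_sst", T) * 0.0)
    assert seen["mean_sst"] == pytest.approx(np.mean(temps))


def test_moult_step_rejects_date_mismatch():
    d0 = dt.date(2013, 11, 1)
    state = _moult_state(d0)
    with pytest.raises(ValueError, match="mismatch"):
        moult_step(state, _env(d0 + dt.timedelta(days=3)),
                   imp_fn=lambda T, L, s: 10,
                   increment_fn=lambda L, T, F, s: 0.0)


def test_doubling_moult_frequency_doubles_cumulative_growth():
    """Identical positive increments, IMP 5 vs IMP 10, over 40 days."""
    d0 = dt.date(2013, 11, 1)
    finals = {}
    for imp in (5, 10):
        state = _moult_state(d0, imp=imp)
        for i in range(40):
            state = moult_step(state, _env(d0 + dt.timedelta(days=i)),
                               imp_fn=lambda T, L, s, imp=imp: imp,
                               increment_fn=lambda L, T, F, s: 0.5)
        finals[imp] = state.length_mm - 26.0
    assert finals[5] == pytest.approx(2 * finals[10])


# --------------------------------------------------------------------------
# composite-model consistency
# --------------------------------------------------------------------------

@pytest.mark.parametrize("model_id", ["tarling2006", "wiedenmann2008"])
def test_composite_effective_rate_equals_increment_over_imp(models, model_id):
    """Under constant forcing the trajectory's per-cycle rate equals the
    increment at IMP-mean conditions divided by the IMP (= daily_rate)."""
    import pandas as pd
    model = models[model_id]
    sst, chl = 1.0, 2.0
    dates = pd.date_range("2013-11-01", periods=130, freq="D")
    forcing = kg.forcing.make_forcing_frame(
        dates, np.full(len(dates), sst), np.full(len(dates), chl), -60.7)
    traj = kg.simulate_trajectory(model, forcing, kg.SimulationConfig(
        start="2013-11-01", end="2014-03-10"))
    moults = traj[traj["moulted"]]
    assert len(moults) >= 2
    # one whole cycle: from the first moult to the second
    first, second = moults.index[0], moults.index[1]
    eff = ((traj.loc[second, "length_mm"] - traj.loc[first, "length_mm"])
           / (second - first))
    # length stays at the first-moult value throughout the cycle; the only
    # discrepancy vs daily_rate is the whole-day rounding of the IMP clock
    expected = model.daily_rate(traj.loc[first, "length_mm"], sst, chl)
    assert eff == pytest.approx(expected, rel=0.06)
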