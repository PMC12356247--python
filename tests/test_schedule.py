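"""Schedule construction: timing landmarks, weights, rounding, invariants."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from srnmr import (
    AcqParams,
    Schedule,
    ScheduleError,
    build_schedule,
    first_zero_crossing,
    ideal_weight,
    residual_correction_vector,
    scan_budget,
    switch_time,
)


@pytest.mark.parametrize(
    "j_hz, expected_ms, tol_ms",
    [
        (38.0, 13.1, 0.1),   # methyl 1J_CC landmark
        (35.0, 14.3, 0.1),   # 1J(CA,CB) landmark
        (50.0, 10.0, 1e-9),  # exact closed form 1/(2*50)
    ],
)
def test_first_zero_crossing(j_hz, expected_ms, tol_ms):
    assert first_zero_crossing(j_hz) * 1e3 == pytest.approx(expected_ms, abs=tol_ms)


def test_first_zero_crossing_rejects_nonpositive_j():
    with pytest.raises(ScheduleError):
        first_zero_crossing(0.0)
    with pytest.raises(ScheduleError):
        first_zero_crossing(-35.0)


def test_zero_crossing_matches_root_finder():
    """1/(2J) agrees with an independent scalar root of cos(pi*J*t) to 1e-9 s."""
    for j in (35.0, 38.0, 61.7):
        root = brentq(lambda t: math.cos(math.pi * j * t), 1e-6, 1.2 / j, xtol=1e-12)
        assert abs(first_zero_crossing(j) - root) < 1e-9


def test_switch_time_landmarks(hsqc_params, hnca_params):
    # published: 9.1 ms (HSQC: 13.1 - 2*1 - 2) and 12.3 ms (HNCA)
    assert switch_time(hsqc_params) * 1e3 == pytest.approx(9.1, abs=0.1)
    assert switch_time(hnca_params) * 1e3 == pytest.approx(12.3, abs=0.1)


def test_switch_time_limit_case():
    """delta_A -> 0, margin -> 0: switch time approaches the crossing itself."""
    p = AcqParams(j_hz=40.0, delta_a_s=0.0, delta_b_s=1e-3, switch_margin_s=1e-9,
                  t1_max_s=30e-3, n_increments=8)
    assert switch_time(p) == pytest.approx(first_zero_crossing(40.0), abs=1e-8)


def test_switch_time_configuration_error():
    # J so large the crossing sits inside the delays: no legal switch time
    p = AcqParams(j_hz=500.0, delta_a_s=1e-3, delta_b_s=3e-3,
                  t1_max_s=10e-3, n_increments=8)
    with pytest.raises(ScheduleError, match="switch time"):
        switch_time(p)


class TestIdealWeight:
    def test_t1_zero(self, hnca_params):
        w, sign, delta = ideal_weight(0.0, hnca_params)
        assert w == pytest.approx(1.0, abs=1e-4)
        assert sign == 1 and delta == "A"

    def test_before_switch(self, hnca_params):
        # direct scalar evaluation: 1/cos(pi*35*(9.0ms + 2*10us))
        w, sign, delta = ideal_weight(9.0e-3, hnca_params)
        expected = 1.0 / math.cos(math.pi * 35.0 * 9.02e-3)
        assert w == pytest.approx(expected, rel=1e-12)
        assert w == pytest.approx(1.83, abs=0.01)
        assert sign == 1 and delta == "A"

    def test_after_switch_sign_flips(self, hnca_params):
        w, sign, delta = ideal_weight(12.3e-3, hnca_params)
        assert delta == "B"
        expected = 1.0 / abs(math.cos(math.pi * 35.0 * (12.3e-3 + 4e-3)))
        assert w == pytest.approx(expected, rel=1e-12)
        assert w == pytest.approx(4.6, abs=0.1)
        assert sign == -1

    def test_cap_after_1_over_j(self, hnca_params):
        # t_eff beyond 1/J = 28.57 ms: scans no longer boosted
        w, sign, _ = ideal_weight(30e-3, hnca_params)
        assert w == 1.0 and sign == -1

    def test_no_cap_mode(self, hnca_params):
        from dataclasses import replace
        p = replace(hnca_params, boost_cap="no-cap")
        w, _, _ = ideal_weight(30e-3, p)
        assert w == pytest.approx(1.0 / abs(math.cos(math.pi * 35.0 * 34e-3)), rel=1e-12)
        assert w > 1.0

    def test_out_of_range_t1(self, hnca_params):
        with pytest.raises(ScheduleError):
            ideal_weight(50e-3, hnca_params)


class TestBuildSchedule:
    def test_conventional_fixed_point(self, hnca_params):
        sched = build_schedule(hnca_params, "conventional")
        assert np.all(sched.n_scans == 4)
        assert np.all(sched.ideal_weight == 1.0)
        assert np.all(sched.phase_sign == 1)
        assert np.all(sched.delta_used == "A")
        assert scan_budget(sched).total_scans == 4 * 200

    def test_uniform_strictly_increasing_grid(self, hnca_sr_schedule):
        t1 = hnca_sr_schedule.t1_s
        steps = np.diff(t1)
        assert np.all(steps > 0)
        assert np.allclose(steps, steps[0], rtol=1e-9)

    def test_rounding_example(self, hnca_sr_schedule):
        # row nearest t1 = 12.2 ms sits in the delta_A branch:
        # weight ~4.44 -> n = round(4*4.44) = 18, residual ~0.987
        i = int(np.argmin(np.abs(hnca_sr_schedule.t1_s - 12.2e-3)))
        t1 = hnca_sr_schedule.t1_s[i]
        assert hnca_sr_schedule.delta_used[i] == "A"
        w = 1.0 / math.cos(math.pi * 35.0 * (t1 + 2e-5))
        assert hnca_sr_schedule.ideal_weight[i] == pytest.approx(w, rel=1e-12)
        assert hnca_sr_schedule.n_scans[i] == round(4 * w)
        assert hnca_sr_schedule.residual[i] == pytest.approx(4 * w / round(4 * w))

    def test_skip_region_exhaustive(self, hnca_sr_schedule, hsqc_sr_schedule):
        for sched in (hnca_sr_schedule, hsqc_sr_schedule):
            zc = first_zero_crossing(sched.params.j_hz)
            margin = sched.params.switch_margin_s
            gap = np.abs(sched.t_eff_s - zc)
            assert np.all(gap >= margin - 1e-9), "t_eff inside the skipped window"

    def test_bookkeeping_identity(self, hnca_sr_schedule):
        # base * weight = n_scans * residual, exactly, per row
        s = hnca_sr_schedule
        assert np.allclose(
            s.params.base_scans * s.ideal_weight, s.n_scans * s.residual, rtol=1e-12
        )

    def test_phase_sign_matches_cosine(self, hnca_sr_schedule, hsqc_sr_schedule):
        for s in (hnca_sr_schedule, hsqc_sr_schedule):
            c = np.cos(np.pi * s.params.j_hz * s.t_eff_s)
            assert np.all(s.phase_sign * c >= 0)

    def test_n_scans_floor_and_residual_band(self, hnca_sr_schedule):
        s = hnca_sr_schedule
        assert np.all(s.n_scans >= s.params.base_scans)
        assert np.all((s.residual > 0.5) & (s.residual < 2.0))

    def test_multiple_of_k_rounding(self):
        p = AcqParams(j_hz=35.0, delta_a_s=10e-6, delta_b_s=2e-3, t1_max_s=38e-3,
                      n_increments=64, base_scans=4,
                      rounding_mode="nearest-multiple-of-k", round_multiple=4)
        sched = build_schedule(p, "SR")
        assert np.all(sched.n_scans % 4 == 0)
        assert np.all(sched.n_scans >= 4)

    def test_degenerate_no_crossing_reached(self):
        # J*t1max < 1/2: the grid ends before the switch; weights grow
        # monotonically and no delta_B row exists
        p = AcqParams(j_hz=20.0, delta_a_s=1e-4, delta_b_s=3e-3, t1_max_s=10e-3,
                      n_increments=32)
        sched = build_schedule(p, "SR")
        assert np.all(sched.delta_used == "A")
        assert np.all(np.diff(sched.ideal_weight) > 0)
        assert np.all(sched.phase_sign == 1)

    def test_unknown_mode_rejected(self, hnca_params):
        with pytest.raises(ScheduleError):
            build_schedule(hnca_params, "hybrid")


def test_scan_budget_hnca_mean():
    """Default-convention SR-HNCA budget: the mean scans per increment is a
    reported quantity (convention-dependent; see docs/methods.md)."""
    p = AcqParams(j_hz=35.0, delta_a_s=10e-6, delta_b_s=2e-3, t1_max_s=38e-3,
                  n_increments=200, base_scans=4)
    b = scan_budget(build_schedule(p, "SR"))
    assert b.mean_scans > 4.0
    assert b.time_ratio_vs_conventional == pytest.approx(b.mean_scans / 4.0)


def test_scan_budget_single_increment():
    p = AcqParams(j_hz=35.0, delta_a_s=10e-6, delta_b_s=2e-3, t1_max_s=1e-4,
                  n_increments=2, base_scans=4)
    b = scan_budget(build_schedule(p, "SR"))
    assert b.total_scans == 8 and b.mean_scans == 4.0


def test_residual_correction_vector(hnca_sr_schedule):
    vec = residual_correction_vector(hnca_sr_schedule)
    s = hnca_sr_schedule
    assert np.allclose(vec, 4 * s.ideal_weight / s.n_scans, rtol=1e-12)
    # capped-tail rows and weight-1 rows correct by exactly 1
    tail = s.t_eff_s > 1.0 / 35.0
    assert np.all(vec[tail] == 1.0)


def test_tsv_and_json_round_trip(tmp_path, hnca_sr_schedule):
    tsv = tmp_path / "sched.tsv"
    hnca_sr_schedule.to_tsv(tsv)
    first = tsv.read_bytes()
    hnca_sr_schedule.to_tsv(tsv)
    assert tsv.read_bytes() == first, "TSV export must be bit-reproducible"
    header = first.decode().splitlines()[0]
    assert header.startswith("# ") and '"j_hz": 35.0' in header

    js = tmp_path / "sched.json"
    hnca_sr_schedule.to_json(js)
    back = Schedule.from_json(js)
    assert np.array_equal(back.n_scans, hnca_sr_schedule.n_scans)
    assert np.allclose(back.t_eff_s, hnca_sr_schedule.t_eff_s)
    assert back.params == hnca_sr_schedule.params
    assert back.mode == "SR"


def test_schedule_tsv_golden(tmp_path):
    """Tiny schedule matches the frozen golden export byte for byte."""
    from pathlib import Path

    p = AcqParams(j_hz=35.0, delta_a_s=10e-6, delta_b_s=2e-3, t1_max_s=38e-3,
                  n_increments=8, base_scans=4)
    out = tmp_path / "tiny.tsv"
    build_schedule(p, "SR").to_tsv(out)
    golden = Path(__file__).parent / "data" / "tiny_schedule_golden.tsv"
    assert out.read_text() == golden.read_text()


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    j=st.floats(10.0, 80.0),
    da_ms=st.floats(0.0, 1.5),
    db_extra_ms=st.floats(2.0, 4.0),
    t1max_ms=st.floats(5.0, 60.0),
    n=st.integers(2, 64),
    base=st.integers(1, 8),
)
def test_schedule_invariants_property(j, da_ms, db_extra_ms, t1max_ms, n, base):
    """Any buildable SR schedule satisfies the row invariants."""
    params = AcqParams(
        j_hz=j,
        delta_a_s=da_ms * 1e-3,
        delta_b_s=(da_ms + db_extra_ms) * 1e-3,
        t1_max_s=t1max_ms * 1e-3,
        n_increments=n,
        base_scans=base,
    )
    try:
        sched = build_schedule(params, "SR")
    except ScheduleError:
        return  # legal refusal (e.g. no positive switch time)
    zc = first_zero_crossing(j)
    assert np.all(np.abs(sched.t_eff_s - zc) >= params.switch_margin_s - 1e-9)
    c = np.cos(np.pi * j * sched.t_eff_s)
    assert np.all(sched.phase_sign * c >= 0)
    assert np.all(sched.n_scans >= base)
    assert np.allclose(base * sched.ideal_weight, sched.n_scans * sched.residual)
    assert np.all((sched.residual > 0.5) & (sched.residual < 2.0))
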