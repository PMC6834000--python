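"""Epoch segmentation, frozen fixed points and the two certificates."""

import math

import numpy as np
import pytest

import tvcoupling as tv
from conftest import ALPHA, AMPLITUDE, OMEGA, SQRT2


# -- frozen fixed points ----------------------------------------------------

def test_fixed_points_symmetric_case():
    fp = tv.frozen_fixed_points(0.0, 1.0)
    assert fp.eta_star == pytest.approx(0.0)
    assert fp.eta_star2 == pytest.approx(math.pi)


def test_fixed_points_reference_values():
    """Checked against an independent bisection root of Omega = K sin(eta)."""
    from scipy.optimize import brentq

    K = AMPLITUDE
    root = brentq(lambda e: OMEGA - K * math.sin(e), -math.pi / 2, math.pi / 2)
    fp = tv.frozen_fixed_points(OMEGA, ALPHA)
    assert fp.eta_star == pytest.approx(root, abs=1e-10)
    assert fp.eta_star == pytest.approx(0.770890, abs=1e-5)
    assert fp.eta_star2 == pytest.approx(2.370702, abs=1e-5)
    # stability: restoring derivative negative at eta*, positive at eta**
    assert -K * math.cos(fp.eta_star) < 0 < -K * math.cos(fp.eta_star2)


def test_fixed_points_require_locking_condition():
    with pytest.raises(tv.PreconditionError):
        tv.frozen_fixed_points(1.08, (1.08 - 1e-9) / SQRT2)


# -- segmentation -----------------------------------------------------------

def constant_track(value=3.0, duration=200.0, h=0.01):
    n = int(duration / h) + 1
    return tv.PhaseTrack(0.0, h, np.full(n, value), "psi")


def test_constant_track_single_locked_epoch():
    seg = tv.segment_epochs(constant_track(), slope_threshold=0.1)
    assert seg.intervals == [(0.0, 200.0, "locked")]


def test_linear_drift_single_slipping_epoch():
    track = tv.PhaseTrack(0.0, 0.01, OMEGA * np.arange(20001) * 0.01, "psi")
    seg = tv.segment_epochs(track, slope_threshold=OMEGA / 10)
    assert [lab for *_, lab in seg.intervals] == ["slipping"]


def test_segmentation_tiles_and_alternates(main_run):
    seg = tv.segment_epochs(main_run)
    labels = [lab for *_, lab in seg.intervals]
    assert all(a != b for a, b in zip(labels, labels[1:]))
    for (a, b, _), (c, _, _) in zip(seg.intervals, seg.intervals[1:]):
        assert b == pytest.approx(c)
    assert seg.intervals[0][0] == main_run.t0
    assert seg.intervals[-1][1] == pytest.approx(main_run.t_end)


def test_segmentation_constant_shift_invariance_and_idempotence(main_run):
    sub = main_run.window(0.0, 1500.0)
    seg = tv.segment_epochs(sub)
    shifted = tv.PhaseTrack(sub.t0, sub.h, sub.values + 123.0, "psi")
    assert tv.segment_epochs(shifted).intervals == seg.intervals
    assert tv.segment_epochs(sub).intervals == seg.intervals  # deterministic


def test_segmentation_epochs_follow_schedule(main_run):
    """Locked epochs sit inside the slow plateaus, slips cover fast spans."""
    seg = tv.segment_epochs(main_run)
    assert len(seg.locked) == 5
    for start, end in seg.locked:
        n = round(start // 1000)
        assert start >= n * 1000 - 50
        assert end <= n * 1000 + 490 + 50
    for n in range(5):
        fast = (n * 1000 + 500, n * 1000 + 990)
        assert any(a <= fast[0] and b >= fast[1] for a, b in seg.slipping)


def test_segmentation_parameter_validation():
    with pytest.raises(ValueError):
        tv.segment_epochs(constant_track(h=1.0), window=0.5)
    with pytest.raises(ValueError):
        tv.segment_epochs(constant_track(duration=5.0), window=10.0)


# -- drift rate -------------------------------------------------------------

def test_drift_rate_trivial_cases():
    t = np.arange(0, 100.0, 0.01)
    assert tv.drift_rate(tv.PhaseTrack(0, 0.01, 2 * t, "psi"), 10, 90) == \
        pytest.approx(2.0)
    assert tv.drift_rate(tv.PhaseTrack(0, 0.01, np.full(t.size, 5.0), "psi"),
                         10, 90) == pytest.approx(0.0, abs=1e-12)


# -- averaging bounds -------------------------------------------------------

def test_bound_constants_reference_value():
    b = tv.averaging_bounds(OMEGA, ALPHA, 100.0)
    assert b.kappa0 == pytest.approx(2 * math.pi * AMPLITUDE / 100, rel=1e-12)
    assert b.kappa0 == pytest.approx(0.097389, abs=1e-6)
    assert b.kappa == pytest.approx(
        AMPLITUDE * 2 * math.pi * (OMEGA + AMPLITUDE) / 100, rel=1e-12)


def test_bounds_shrink_with_faster_winding():
    b1 = tv.averaging_bounds(OMEGA, ALPHA, 10.0, 10.0)
    b2 = tv.averaging_bounds(OMEGA, ALPHA, 100.0, 10.0)
    b3 = tv.averaging_bounds(OMEGA, ALPHA, 100.0, 100.0)
    assert b2.kappa0 < b1.kappa0
    assert b2.kappa < b1.kappa
    assert b3.kappa < b2.kappa
    assert tv.averaging_bounds(OMEGA, ALPHA, 1e12, 1e6).kappa == \
        pytest.approx(0.0, abs=1e-5)


def test_bounds_require_valid_rates():
    with pytest.raises(tv.PreconditionError):
        tv.averaging_bounds(OMEGA, ALPHA, -1.0)
    with pytest.raises(tv.PreconditionError):
        tv.averaging_bounds(OMEGA, ALPHA, 10.0, K2=2.0)  # K2 <= sqrt(2 pi)


# -- fast-winding certificate ----------------------------------------------

def test_fast_drift_certificate_reference_rates():
    reports = {}
    for k in (100.0, 1000.0):
        sched = tv.ConstantRateSchedule(alpha=ALPHA, rate=k)
        p = tv.SystemParams(schedule=sched, Omega=OMEGA)
        reports[k] = tv.certify_fast_drift(p, duration=100.0)
    assert all(r.passed and r.margin <= 1e-9 for r in reports.values())
    # faster winding hugs the free drift more tightly
    assert reports[1000.0].max_deviation < reports[100.0].max_deviation


def test_fast_drift_certificate_random_sweep():
    rng = np.random.default_rng(2024)
    for _ in range(4):
        Omega = rng.uniform(-2, 2)
        alpha = rng.uniform(0.2, 1.5)
        k = 10 * max(abs(Omega), SQRT2 * alpha) * rng.uniform(1, 5)
        sched = tv.ConstantRateSchedule(alpha=alpha, rate=k)
        p = tv.SystemParams(schedule=sched, Omega=Omega)
        rep = tv.certify_fast_drift(p, duration=60.0)
        assert rep.margin <= 1e-9


def test_fast_drift_zero_coupling_exact():
    sched = tv.ConstantRateSchedule(alpha=0.0, rate=50.0)
    p = tv.SystemParams(schedule=sched, Omega=OMEGA)
    rep = tv.certify_fast_drift(p, duration=20.0, K1=50.0)
    # zero coupling leaves only float rounding in psi0 + Omega*t
    assert rep.max_deviation == pytest.approx(0.0, abs=1e-9)


def test_fast_drift_requires_fast_constant_schedule(main_schedule):
    p = tv.SystemParams(schedule=main_schedule, Omega=OMEGA)
    with pytest.raises(tv.PreconditionError):
        tv.certify_fast_drift(p, duration=10.0)
    slow = tv.SystemParams(
        schedule=tv.ConstantRateSchedule(alpha=ALPHA, rate=5.0), Omega=OMEGA)
    with pytest.raises(tv.PreconditionError):
        tv.certify_fast_drift(slow, duration=10.0, K1=10.0)


# -- slow-driving certificate ----------------------------------------------

def test_slow_tolerance_recipe_is_admissible():
    """eps0 stays below the gap of F on the approach arc; T0 is finite."""
    eps0, T0 = tv.slow_drive_tolerance(OMEGA, ALPHA, 0.0, 0.2)
    K = AMPLITUDE
    fp = tv.frozen_fixed_points(OMEGA, ALPHA)
    edge = min(OMEGA - K * math.sin(fp.eta_star - 0.1),
               K * math.sin(fp.eta_star + 0.1) - OMEGA)
    assert 0 < eps0 < min(OMEGA, edge)
    assert 0 < T0 < 1000


def test_slow_containment_frozen_and_slow_drive():
    frozen = tv.SystemParams(
        schedule=tv.ConstantRateSchedule(alpha=ALPHA, rate=0.0), Omega=OMEGA)
    rep = tv.certify_slow_containment(frozen, 0.2)
    assert rep.passed and rep.first_violation is None

    eps0, T0 = tv.slow_drive_tolerance(OMEGA, ALPHA, 0.0, 0.2)
    slow = tv.SystemParams(
        schedule=tv.ConstantRateSchedule(alpha=ALPHA, rate=eps0 / 2),
        Omega=OMEGA)
    rep = tv.certify_slow_containment(slow, 0.2, duration=T0 + 150.0)
    assert rep.passed
    assert rep.max_deviation_after_T0 < 0.1  # inside the 0.1-radius ball


def test_slow_containment_rejects_fast_schedule():
    fast = tv.SystemParams(
        schedule=tv.ConstantRateSchedule(alpha=ALPHA, rate=1.0), Omega=OMEGA)
    with pytest.raises(tv.PreconditionError):
        tv.certify_slow_containment(fast, 0.2, duration=50.0)


def test_slow_containment_excludes_unstable_start():
    fp = tv.frozen_fixed_points(OMEGA, ALPHA)
    p = tv.SystemParams(
        schedule=tv.ConstantRateSchedule(alpha=ALPHA, rate=0.0), Omega=OMEGA,
        psi0=fp.eta_star2)
    with pytest.raises(tv.PreconditionError):
        tv.certify_slow_containment(p, 0.2, duration=10.0)


def test_report_summarises_epochs(main_run):
    from tvcoupling.fixtures import format_report

    sub = main_run.window(0.0, 1500.0)
    seg = tv.segment_epochs(sub)
    summary = tv.report(sub, seg)
    assert summary["n_epochs"] == len(seg.intervals)
    assert summary["n_locked"] >= 1
    locked = [e for e in summary["epochs"] if e["label"] == "locked"]
    assert abs(locked[0]["drift_rate"]) < 0.108
    text = format_report(summary)
    assert "locked" in text and "slipping" in text
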