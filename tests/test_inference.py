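"""Estimators, goodness of fit, and sweep machinery on controlled inputs."""

import numpy as np
import pytest

import loopfork as lf
from loopfork.inference import _boundary_position


def _profile(vals, genome, bin_size=10_000, kind="MFA"):
    return lf.Profile1D(np.asarray(vals, dtype=float), bin_size, genome.length, kind=kind)


def _analytic_t0(genome, f, bin_size=10_000):
    n = int(np.ceil(genome.length / bin_size))
    centers = lf.Profile1D(np.zeros(n), bin_size, genome.length).bin_centers_signed()
    u = np.abs(centers) / (genome.length / 2)
    return _profile(1 + f * (1 - u), genome, bin_size)


# -- fork speed -------------------------------------------------------------


def test_fork_speed_on_noiseless_fronts(genome59):
    # sharp fronts moving at exactly 66 kb/min
    n = 404
    prof = []
    for t in (10.0, 15.0, 20.0):
        vals = np.ones(n)
        centers = lf.Profile1D(np.zeros(n), 10_000, genome59.length).bin_centers_signed()
        vals[np.abs(centers) <= 66_000 * t] = 2.0
        prof.append((t, _profile(vals, genome59)))
    assert lf.estimate_fork_speed(prof) == pytest.approx(66.0, abs=1.0)


def test_fork_speed_zero_when_frozen(genome59):
    vals = np.ones(404)
    centers = lf.Profile1D(np.zeros(404), 10_000, genome59.length).bin_centers_signed()
    vals[np.abs(centers) <= 800_000] = 2.0
    tc = [(t, _profile(vals.copy(), genome59)) for t in (20.0, 25.0, 30.0)]
    assert lf.estimate_fork_speed(tc) == pytest.approx(0.0, abs=1e-9)


def test_fork_speed_needs_two_points_and_a_boundary(genome59):
    vals = np.ones(404)
    with pytest.raises(ValueError):
        lf.estimate_fork_speed([(10.0, _profile(vals, genome59))])
    flat = [(t, _profile(vals, genome59)) for t in (10.0, 20.0)]
    with pytest.raises(ValueError):
        lf.estimate_fork_speed(flat)


def test_boundary_position_interpolates():
    dist = np.arange(0, 100_000, 10_000, dtype=float)
    vals = np.where(dist < 45_000, 2.0, 1.0)
    b = _boundary_position(dist, vals, plateau_frac=0.3)
    assert 40_000 <= b <= 50_000


# -- pre-existing fraction --------------------------------------------------


def test_pre_existing_fraction_flat_and_analytic(genome59):
    flat = _profile(np.ones(404), genome59)
    assert lf.estimate_pre_existing_fraction(flat) == pytest.approx(0.0, abs=1e-12)
    assert lf.estimate_pre_existing_fraction(_analytic_t0(genome59, 0.18)) \
        == pytest.approx(0.18, abs=0.002)
    assert lf.estimate_pre_existing_fraction(_analytic_t0(genome59, 0.40)) \
        == pytest.approx(0.40, abs=0.005)


# -- initiation fraction ----------------------------------------------------


def test_initiation_fraction_extremes(genome59):
    # all cells initiated, none pre-existing
    n = 404
    centers = lf.Profile1D(np.zeros(n), 10_000, genome59.length).bin_centers_signed()
    mid = np.where(np.abs(centers) <= 1_000_000, 2.0, 1.0)
    t0 = np.ones(n)
    assert lf.estimate_initiation_fraction(_profile(mid, genome59), _profile(t0, genome59)) \
        == pytest.approx(1.0)
    # none initiated
    assert lf.estimate_initiation_fraction(_profile(t0, genome59), _profile(t0, genome59)) \
        == pytest.approx(0.0)


def test_initiation_fraction_rejects_unscaled_profiles(genome59):
    counts = _profile(np.full(404, 1000.0), genome59)
    with pytest.raises(ValueError):
        lf.estimate_initiation_fraction(counts, counts)


# -- motor speed & delay ----------------------------------------------------


def test_motor_speed_two_point_slope():
    tc = [(10.0, 715_000.0), (15.0, 1_072_000.0)]
    assert lf.estimate_motor_speed(tc) == pytest.approx(71.4, abs=0.1)
    flat = [(10.0, 500_000.0), (20.0, 500_000.0)]
    assert lf.estimate_motor_speed(flat) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        lf.estimate_motor_speed([(10.0, 1.0)])


def test_bypass_delay_arithmetic():
    d1 = lf.estimate_bypass_delay(1_000_000, 871_000, 71.0)
    assert d1.minutes == pytest.approx(129 / 71.0)
    assert d1.rounded_min == 2
    d2 = lf.estimate_bypass_delay(1_000_000, 817_000, 71.0)
    assert d2.rounded_min == 3
    assert lf.estimate_bypass_delay(500_000, 500_000, 71.0).minutes == 0.0
    with pytest.raises(ValueError):
        lf.estimate_bypass_delay(400_000, 500_000, 71.0)


# -- goodness of fit --------------------------------------------------------


def test_gof_score_properties(genome59):
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.5, 2.0, 404)
    ref = _profile(vals, genome59, kind="OCCUPANCY")
    same = _profile(vals * 3.7, genome59, kind="OCCUPANCY")  # common rescaling
    assert lf.gof_score(same, ref) == pytest.approx(0.0, abs=1e-15)
    perm = _profile(np.roll(vals, 37), genome59, kind="OCCUPANCY")
    assert lf.gof_score(perm, ref) > 0
    with pytest.raises(ValueError):
        lf.gof_score(ref, ref, mask=np.zeros(404, dtype=bool))


def test_gof_mask_excludes_parS_and_zeros(genome59):
    vals = np.ones(404)
    vals[7] = 0.0
    prof = _profile(vals, genome59, kind="OCCUPANCY")
    mask = lf.make_gof_mask(genome59, prof)
    assert not mask[7]
    parS_bin = int(lf.deg_to_bp(-59.0, genome59) % genome59.length // 10_000)
    assert not mask[parS_bin]
    assert mask.sum() > 390


# -- sweeps -----------------------------------------------------------------


def test_degenerate_collision_sweep(genome59):
    ref = _profile(np.ones(404), genome59, kind="OCCUPANCY")

    def sim(tu, tb):
        return ref

    res = lf.sweep_collision_params(sim, np.array([30.0]), np.array([120.0]), ref)
    assert res.best_params == {"tau_unload": 30.0, "tau_bypass": 120.0}
    assert res.best_score == 0.0
    assert res.annotations["best_in_fast_unload_region"]
    assert len(res.to_table()) == 1


def test_memory_sweep_zero_reference_prefers_grid_minimum(chase_scenario):
    sc = chase_scenario
    parS = lf.deg_to_bp(-59.0, sc.genome)
    ref = lf.simulate_arc2(sc.smc_params, 66.0, 0.0, sc.protocol, sc.genome,
                           n_pairs=200, seed=4, sample_time=25.0)

    def run(tm, t):
        return lf.simulate_arc2(sc.smc_params, 66.0, tm, sc.protocol, sc.genome,
                                n_pairs=150, seed=5, sample_time=t)

    res = lf.sweep_fork_memory(run, np.array([0.0, 300.0, 700.0, 1100.0]),
                               np.array([25.0]), ref, parS)
    assert res.best_params["t_memory"] == 0.0
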