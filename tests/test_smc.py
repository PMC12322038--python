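"""Loop-extrusion engine: loading, motion, memory, collisions, arc-2 model."""

from dataclasses import asdict

import numpy as np
import pytest

import loopfork as lf
from loopfork.smc import BYPASS_OFFSET, Encounter, Outcome


# -- block resolution -------------------------------------------------------


def test_resolve_block_symmetric_clocks():
    params = lf.SMCParams(tau_unload=60.0, tau_bypass=60.0)
    rng = np.random.default_rng(1)
    kind, wait = lf.resolve_block(params, rng, size=50_000)
    assert wait.mean() == pytest.approx(30.0, rel=0.03)
    assert (kind == Outcome.UNLOAD).mean() == pytest.approx(0.5, abs=0.01)


def test_resolve_block_single_rule_models():
    rng = np.random.default_rng(2)
    unload = lf.SMCParams(engagement_model="unload_only", tau_unload=30.0)
    kind, wait = lf.resolve_block(unload, rng, size=50_000)
    assert (kind == Outcome.UNLOAD).all()
    assert wait.mean() == pytest.approx(30.0, rel=0.03)
    block = lf.SMCParams(engagement_model="block_only")
    k1, w1 = lf.resolve_block(block, rng, size=100)
    assert (k1 == Outcome.BLOCK).all() and np.isinf(w1).all()
    bypass = lf.SMCParams(engagement_model="bypass_only", tau_bypass=120.0)
    k2, w2 = lf.resolve_block(bypass, rng, size=50_000)
    assert (k2 == Outcome.BYPASS).all()
    assert w2.mean() == pytest.approx(120.0, rel=0.03)


def test_detect_encounter_orientations():
    # motor toward ori meeting the leftward fork: opposite directions
    assert lf.detect_encounter(-900_000, -1_010_000, -1, -1_000_000, -1_000_000, -1) \
        is Encounter.HEAD_TO_TAIL
    assert lf.detect_encounter(-1_050_000, -990_000, +1, -1_000_000, -995_000, -1) \
        is Encounter.HEAD_ON
    assert lf.detect_encounter(-900_000, -950_000, -1, -1_000_000, -1_005_000, -1) \
        is Encounter.NONE


# -- motor speed and memory -------------------------------------------------


def test_motor_speed_direction_and_memory():
    p = lf.SMCParams(v_to_ter=71.5, v_to_ori=49.0, t_memory=700.0)
    # on unreplicated DNA (infinite age) base speeds apply
    assert lf.motor_speed(-500_000, -1, p) == 71.5     # left arm, ter-directed
    assert lf.motor_speed(-500_000, +1, p) == 49.0     # left arm, ori-directed
    assert lf.motor_speed(+500_000, +1, p) == 71.5     # right arm, ter-directed
    # linear ramp midpoint
    assert lf.motor_speed(-500_000, -1, p, age_seconds=350.0) == pytest.approx(71.5 / 2)
    # exactly at a fresh fork position: zero
    assert lf.motor_speed(-500_000, -1, p, age_seconds=0.0) == 0.0


def test_memory_factor_limits():
    assert lf.memory_factor(np.inf, 700.0) == 1.0
    assert lf.memory_factor(-np.inf, 700.0) == 1.0
    assert lf.memory_factor(350.0, 0.0) == 1.0  # disabled
    assert lf.memory_factor(1400.0, 700.0) == 1.0
    assert lf.memory_factor(70.0, 700.0) == pytest.approx(0.1)


def test_memory_time_formulation_equals_distance_formulation():
    # for a constant-speed fork the ramp in age equals a ramp in distance
    # over t_memory * v_fork behind the fork
    v_f = 66.0 * 1000 / 60.0  # bp/s
    t_mem = 700.0
    zone = t_mem * v_f
    dist = np.linspace(0, 1.2 * zone, 50)
    m_time = lf.memory_factor(dist / v_f, t_mem)
    m_dist = np.clip(dist / zone, 0, 1)
    assert np.allclose(m_time, m_dist)


# -- loading ----------------------------------------------------------------


def test_loading_requires_active_environment(genome59, rep_params):
    prot = lf.g1_arrest_protocol(iptg_time=None, sample_times=(10.0,))
    res = lf.simulate_joint(prot, rep_params, lf.SMCParams(), genome59,
                            n_cells=20, seed=1)
    assert res.snapshots[0].smc.pos_ccw.size == 0


def test_loading_targets_parS(genome59, rep_params):
    prot = lf.g1_arrest_protocol(iptg_time=0.0, sample_times=(10.0,))
    res = lf.simulate_joint(prot, rep_params, lf.SMCParams(), genome59,
                            n_cells=30, seed=2)
    snap = res.snapshots[0].smc
    parS = lf.deg_to_bp(-59.0, genome59)
    assert (snap.load_pos == parS).mean() > 0.90


def test_bound_count_never_exceeds_pool(g1_control_result):
    for snap in g1_control_result.snapshots:
        per_cell = np.bincount(snap.smc.cell, minlength=snap.smc.n_cells)
        assert per_cell.max() <= 40


# -- control zipping --------------------------------------------------------


def test_control_zipping_extent_matches_measured_scale(g1_control_result, genome1):
    # 10 min of extrusion after the 5-min loading lag: ~715 kb per arm,
    # to be compared with the measured ~730 kb within 10%
    snap = g1_control_result.at(15.0)
    cmap = lf.compute_contact_map(snap.smc, genome1)
    ccw, cw = lf.zipping_extent(cmap, lf.deg_to_bp(-1.0, genome1))
    for ext in (ccw, cw):
        assert abs(ext - 730_000) / 730_000 < 0.10


def test_control_extent_grows_at_motor_speed(g1_control_result, genome1):
    tc = []
    for snap in g1_control_result.snapshots:
        cmap = lf.compute_contact_map(snap.smc, genome1)
        tc.append((snap.time_min, lf.zipping_extent(cmap, lf.deg_to_bp(-1.0, genome1))))
    speed = lf.estimate_motor_speed(tc)
    assert speed == pytest.approx(71.5, abs=2.0)


# -- collisions in the joint simulator --------------------------------------


def test_block_only_pins_motors_at_stalled_fork(one_sided_snapshots):
    snap = one_sided_snapshots["block_only"]
    live = snap.forks.initiated & ~snap.forks.completed(lf.GenomeSpec.from_degrees([-59.0]))
    fork = np.full(live.size, np.nan)
    fork[live] = snap.forks.left_pos[live]
    ref = fork[snap.smc.cell]
    at_fork = np.abs(snap.smc.pos_ccw - ref) < 10_000
    assert np.nanmean(at_fork) > 0.4


def test_unloading_depletes_bound_complexes(one_sided_snapshots):
    n_unload = len(one_sided_snapshots["unload_only"].smc.cell)
    n_block = len(one_sided_snapshots["block_only"].smc.cell)
    assert n_unload < n_block


def test_no_fork_crossing_without_bypass(one_sided_scenario):
    """Any motor strictly past its cell's live fork must either have a
    logged bypass or have loaded there (background loading)."""
    sc = one_sided_scenario
    params = lf.SMCParams(**{**asdict(sc.smc_params), "background_weight": 0.0})
    res = lf.simulate_joint(sc.protocol, sc.rep_params, params, sc.genome,
                            n_cells=40, seed=3, sample_times=(sc.sample_times[-1],),
                            collect_events=True)
    snap = res.snapshots[0]
    live = snap.forks.initiated & ~snap.forks.completed(sc.genome)
    fork = np.full(live.size, np.nan)
    fork[live] = snap.forks.left_pos[live]
    margin = BYPASS_OFFSET + 2_000
    parS = lf.deg_to_bp(-59.0, sc.genome)
    fork_past_parS = fork[snap.smc.cell] < parS
    beyond = (snap.smc.pos_ccw < fork[snap.smc.cell] - margin) & fork_past_parS
    ev = res.events
    bypassed = set(zip(ev.loc[(ev.kind == "bypass") & (ev.motor == "ccw"), "cell"],
                       ev.loc[(ev.kind == "bypass") & (ev.motor == "ccw"), "smc"]))
    assert bypassed, "scenario should produce bypass events"
    for cell in snap.smc.cell[np.nan_to_num(beyond).astype(bool)]:
        assert any(c == cell for c, _ in bypassed)


def test_bypass_transparency_limit(one_sided_scenario):
    # tau_bypass -> 0: trajectories indistinguishable from a no-replisome control
    sc = one_sided_scenario
    t_sample = sc.sample_times[-1]
    transparent = lf.SMCParams(**{**asdict(sc.smc_params),
                                  "engagement_model": "bypass_only", "tau_bypass": 1e-9})
    res = lf.simulate_joint(sc.protocol, sc.rep_params, transparent, sc.genome,
                            n_cells=60, seed=42, sample_times=(t_sample,))
    ctrl_prot = lf.g1_arrest_protocol(iptg_time=sc.protocol.iptg_time,
                                      sample_times=(t_sample,))
    ctrl = lf.simulate_joint(ctrl_prot, sc.rep_params, sc.smc_params, sc.genome,
                             n_cells=60, seed=42, sample_times=(t_sample,))
    parS = lf.deg_to_bp(-59.0, sc.genome)
    ext_t = lf.zipping_extent(lf.compute_contact_map(res.snapshots[0].smc, sc.genome), parS)
    ext_c = lf.zipping_extent(lf.compute_contact_map(ctrl.snapshots[0].smc, sc.genome), parS)
    assert abs(ext_t[0] - ext_c[0]) <= 20_000
    assert abs(ext_t[1] - ext_c[1]) <= 20_000


def test_head_on_pushback_moves_blocked_motor_with_fork(genome59):
    """A motor blocked head-on by a moving fork is carried backward."""
    rep = lf.ReplisomeParams(f_pre=0.0, t_init_mean=0.0, v30=66.0, v42=66.0, p_stall=0.0)
    smc = lf.SMCParams(engagement_model="block_only", k_load=10.0, n_smc=5,
                       tau_dissoc=1e9)
    prot = lf.synchronized_protocol(iptg_time=-10.0, sample_times=(6.0, 9.0))
    # loading active from t=-5; motors extrude from parS (-661 kb) before
    # initiation; the ori-directed (cw) motor meets the leftward fork head-on
    res = lf.simulate_joint(prot, rep, smc, genome59, n_cells=15, seed=8,
                            sample_times=(6.0, 9.0), collect_events=True)
    ev = res.events
    assert (ev.kind == "block_head_on").any()
    s6, s9 = res.snapshots
    # blocked cw motors coincide with the fork and move left with it
    f6 = s6.forks.left_pos[s6.smc.cell]
    at_fork6 = np.abs(s6.smc.pos_cw - f6) < 1.0
    assert at_fork6.any()
    f9 = s9.forks.left_pos[s9.smc.cell]
    at_fork9 = np.abs(s9.smc.pos_cw - f9) < 1.0
    assert at_fork9.any()
    assert np.median(s9.forks.left_pos) < np.median(s6.forks.left_pos)


def test_joint_simulation_reproducible(one_sided_scenario):
    sc = one_sided_scenario
    t = sc.sample_times[1]
    runs = []
    for _ in range(2):
        res = lf.simulate_joint(sc.protocol, sc.rep_params, sc.smc_params, sc.genome,
                                n_cells=15, seed=99, sample_times=(t,))
        runs.append(res.snapshots[0])
    assert np.array_equal(runs[0].smc.pos_ccw, runs[1].smc.pos_ccw)
    assert np.array_equal(runs[0].forks.left_pos, runs[1].forks.left_pos)


# -- arc-2 reduced model ----------------------------------------------------


def test_arc2_zero_memory_tracks_fork(chase_scenario):
    sc = chase_scenario
    pts = lf.simulate_arc2(sc.smc_params, 66.0, 0.0, sc.protocol, sc.genome,
                           n_pairs=200, seed=1, sample_time=25.0)
    fork = -66.0 * 1000 / 60.0 * 25.0 * 60.0  # bp
    # chasing motors loaded well before the sample reach and track the fork
    lead = np.quantile(pts[:, 0], 0.05)
    assert abs(lead - fork) < 15_000


def test_arc2_memory_creates_lag_behind_fork(chase_scenario):
    sc = chase_scenario
    pts = lf.simulate_arc2(sc.smc_params, 66.0, 700.0, sc.protocol, sc.genome,
                           n_pairs=200, seed=1, sample_time=25.0)
    fork = -66.0 * 1000 / 60.0 * 25.0 * 60.0
    lead = np.quantile(pts[:, 0], 0.05)
    assert lead - fork > 300_000  # arc 2 stays well behind the replisome


def test_arc2_resolved_memory_behind_old_stalled_fork(chase_scenario):
    """Once a stalled fork is older than t_memory, chasers cross it at full
    speed: kinematics match the unhindered prediction."""
    sc = chase_scenario
    prot = lf.g1_arrest_protocol(hpura_time=15.0, sample_times=())
    t_mem = 700.0
    sample = 45.0
    pts = lf.simulate_arc2(sc.smc_params, 66.0, t_mem, prot, sc.genome,
                           n_pairs=400, seed=2, sample_time=sample)
    # fork stalled at 15 min (990 kb); memory resolved by minute 15 + 700/60.
    # Motors loaded near the end of the window see no slowdown anywhere:
    # the latest-loaded decile should sit at parS - v_ter * elapsed.
    parS = lf.deg_to_bp(-59.0, sc.genome)
    v_ter = sc.smc_params.v_to_ter * 1000 / 60.0
    # identify pairs by their ori-side motor (constant 49 kb/min, no fork on
    # its path for a long stretch): elapsed = d_cw / v_ori
    v_ori = sc.smc_params.v_to_ori * 1000 / 60.0
    elapsed = (pts[:, 1] - parS) / v_ori
    recent = elapsed < 10 * 60.0
    expected = parS - v_ter * elapsed[recent]
    assert np.abs(pts[recent, 0] - expected).max() < 5_000
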