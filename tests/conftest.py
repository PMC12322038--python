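"""Shared fixtures.

Heavy ensemble simulations are session-scoped and reused across unit,
property, and acceptance tests so the suite stays fast while every check
runs on honest stochastic output.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pytest

import loopfork as lf


@pytest.fixture(scope="session")
def genome59() -> lf.GenomeSpec:
    return lf.GenomeSpec.from_degrees([-59.0])


@pytest.fixture(scope="session")
def genome1() -> lf.GenomeSpec:
    return lf.GenomeSpec.from_degrees([-1.0])


@pytest.fixture(scope="session")
def rep_params() -> lf.ReplisomeParams:
    return lf.ReplisomeParams()


@pytest.fixture(scope="session")
def g1_control_result(genome1, rep_params):
    """No-replication control: symmetric 71.5 kb/min motors, loading induced
    at T=0, sampled at 15/20/25 min (300 cells)."""
    prot = lf.g1_arrest_protocol(iptg_time=0.0, sample_times=(15.0, 20.0, 25.0))
    smc = lf.SMCParams(v_to_ori=71.5)
    return lf.simulate_joint(prot, rep_params, smc, genome1, n_cells=300, seed=101)


@pytest.fixture(scope="session")
def one_sided_scenario():
    return lf.make_scenario("one_sided_head_to_tail")


@pytest.fixture(scope="session")
def one_sided_snapshots(one_sided_scenario):
    """Final-time snapshots of the one-sided head-to-tail scenario under each
    engagement model, plus a fork-free control and a reference occupancy
    generated with the combined (30 s, 120 s) clocks at a different seed."""
    sc = one_sided_scenario
    t_sample = sc.sample_times[-1]

    def run(model, seed, protocol=None, n_cells=60, collect=False):
        params = lf.SMCParams(**{**asdict(sc.smc_params), "engagement_model": model})
        return lf.simulate_joint(
            protocol or sc.protocol, sc.rep_params, params, sc.genome,
            n_cells=n_cells, seed=seed, sample_times=(t_sample,),
            collect_events=collect,
        )

    ctrl_prot = lf.g1_arrest_protocol(iptg_time=sc.protocol.iptg_time, sample_times=(t_sample,))
    out = {
        "ref_occupancy": lf.compute_occupancy(
            run("combined", seed=5, n_cells=80).snapshots[0].smc, sc.genome
        ),
        "control": run("combined", seed=42, protocol=ctrl_prot).snapshots[0],
        "control2": run("combined", seed=9, protocol=ctrl_prot).snapshots[0],
    }
    for model in ("combined", "bypass_only", "block_only", "unload_only"):
        res = run(model, seed=42, collect=True)
        out[model] = res.snapshots[0]
        out[model + "_events"] = res.events
    return out


@pytest.fixture(scope="session")
def residence_events(genome1, rep_params):
    """Long no-collision run with the event log, for residence-time checks:
    250 cells x 40 complexes over 90 min (~4.5 dissociation lifetimes)."""
    prot = lf.g1_arrest_protocol(iptg_time=0.0, sample_times=(90.0,))
    res = lf.simulate_joint(prot, rep_params, lf.SMCParams(), genome1,
                            n_cells=250, seed=7, collect_events=True)
    return res.events


@pytest.fixture(scope="session")
def chase_scenario():
    return lf.make_scenario("chase_moving_forks")
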