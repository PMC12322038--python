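"""Synthetic datasets with known ground truth, and named scenario fixtures.

Each scenario bundles a genome (parS placement), an experimental protocol
(temperature window gating initiation, IPTG gating SMC loading, HPUra
stalling forks), replication and extrusion parameters, and sample times —
one per canonical experimental design:

``g1_control``              loading induced in G1-arrested cells; no forks.
``induced_free_forks``      loading induced at the onset of a synchronized
                            round; forks run freely (MFA time course).
``constitutive_moving_forks`` constitutive loading at parS −27°; moving
                            forks collide head-on, then are chased.
``two_sided_head_to_tail``  parS −1°: both motors catch stalled forks.
``one_sided_head_to_tail``  parS −59°: forks stalled after passing parS;
                            only the terminus-directed motor collides.
``head_on_stalled``         parS −59°: forks stalled before reaching parS.
``head_on_moving``          parS −59°, induced loading, forks keep moving.
``chase_moving_forks``      parS −59°, constitutive loading, moving forks
                            (the fork-chasing arc condition).

Read sampling is multinomial (no overdispersion): at the 5–10 kb bins used
for comparisons, counting noise is small; an overdispersion hook can be
layered on the returned counts if needed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .genome import GenomeSpec
from .observables import (
    ContactMap,
    Profile1D,
    compute_contact_map,
    compute_mfa,
    compute_occupancy,
)
from .protocol import Protocol, g1_arrest_protocol, synchronized_protocol
from .replisome import ReplisomeParams
from .smc import SMCParams, simulate_joint


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    genome: GenomeSpec
    protocol: Protocol
    rep_params: ReplisomeParams
    smc_params: SMCParams
    sample_times: tuple[float, ...]
    constitutive_loading: bool = False


def _fork_arrival_time(rep: ReplisomeParams, distance_bp: float, window: float = 15.0) -> float:
    """Minutes after initiation for a fork to reach ``distance_bp`` from the
    origin under the two-temperature elongation schedule (30 °C for the
    permissive window, 42 °C after)."""
    kb = distance_bp / 1000.0
    d30 = rep.v30 * window
    if kb <= d30:
        return kb / rep.v30
    return window + (kb - d30) / rep.v42


def _symmetric(smc: SMCParams) -> SMCParams:
    """Equal per-motor speeds, as appropriate for origin-proximal parS."""
    return SMCParams(**{**asdict(smc), "v_to_ori": smc.v_to_ter})


def make_scenario(
    name: str,
    rep_params: ReplisomeParams | None = None,
    smc_params: SMCParams | None = None,
    genome_length: int | None = None,
) -> ScenarioConfig:
    """Build one of the named scenario fixtures (optionally overriding
    parameters, e.g. for sweeps)."""
    rep = rep_params or ReplisomeParams()
    smc = smc_params or SMCParams()
    kw = {} if genome_length is None else {"length": genome_length}

    if name == "g1_control":
        genome = GenomeSpec.from_degrees([-59.0], **kw)
        samples = (0.0, 15.0, 20.0, 25.0)
        return ScenarioConfig(
            name, genome, g1_arrest_protocol(iptg_time=0.0, sample_times=samples),
            rep, smc, samples,
        )
    if name == "induced_free_forks":
        genome = GenomeSpec.from_degrees([-59.0], **kw)
        samples = (0.0, 15.0, 30.0, 45.0, 60.0)
        return ScenarioConfig(
            name, genome, synchronized_protocol(iptg_time=0.0, sample_times=samples),
            rep, smc, samples,
        )
    if name == "constitutive_moving_forks":
        genome = GenomeSpec.from_degrees([-27.0], **kw)
        samples = (0.0, 10.0, 15.0, 20.0, 25.0, 35.0)
        return ScenarioConfig(
            name, genome, synchronized_protocol(sample_times=samples),
            rep, smc, samples, constitutive_loading=True,
        )
    if name == "two_sided_head_to_tail":
        genome = GenomeSpec.from_degrees([-1.0], **kw)
        t0 = 15.0  # HPUra + IPTG when the permissive window closes
        samples = tuple(t0 + d for d in (15.0, 20.0, 25.0, 30.0))
        return ScenarioConfig(
            name, genome,
            synchronized_protocol(iptg_time=t0, hpura_time=t0, sample_times=samples),
            rep, _symmetric(smc), samples,
        )
    if name == "one_sided_head_to_tail":
        genome = GenomeSpec.from_degrees([-59.0], **kw)
        # stall once the leftward fork is well past the parS site (~1169 kb)
        t0 = round(_fork_arrival_time(rep, 1_169_000.0), 2)
        samples = tuple(t0 + d for d in (0.0, 15.0, 20.0, 25.0))
        return ScenarioConfig(
            name, genome,
            synchronized_protocol(iptg_time=t0, hpura_time=t0, sample_times=samples),
            rep, smc, samples,
        )
    if name == "head_on_stalled":
        genome = GenomeSpec.from_degrees([-59.0], **kw)
        # stall before the fork reaches the parS site (−59° ≈ −661 kb)
        t0 = round(_fork_arrival_time(rep, 450_000.0), 2)
        samples = tuple(t0 + d for d in (0.0, 15.0, 20.0, 25.0))
        return ScenarioConfig(
            name, genome,
            synchronized_protocol(iptg_time=t0, hpura_time=t0, sample_times=samples),
            rep, smc, samples,
        )
    if name == "head_on_moving":
        genome = GenomeSpec.from_degrees([-59.0], **kw)
        samples = (15.0, 20.0, 25.0, 30.0, 40.0)
        return ScenarioConfig(
            name, genome, synchronized_protocol(iptg_time=0.0, sample_times=samples),
            rep, smc, samples,
        )
    if name == "chase_moving_forks":
        genome = GenomeSpec.from_degrees([-59.0], **kw)
        samples = (10.0, 15.0, 20.0, 25.0, 30.0, 40.0)
        return ScenarioConfig(
            name, genome, synchronized_protocol(sample_times=samples),
            rep, smc, samples, constitutive_loading=True,
        )
    raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIO_NAMES)}")


SCENARIO_NAMES = (
    "g1_control",
    "induced_free_forks",
    "constitutive_moving_forks",
    "two_sided_head_to_tail",
    "one_sided_head_to_tail",
    "head_on_stalled",
    "head_on_moving",
    "chase_moving_forks",
)


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------


def sample_profile_reads(profile: Profile1D, depth: int, seed: int) -> Profile1D:
    """Multinomial read counts with per-bin probabilities ∝ profile values."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    p = np.clip(profile.values, 0.0, None).astype(float)
    total = p.sum()
    if total <= 0 or depth == 0:
        counts = np.zeros(profile.n_bins)
    else:
        counts = rng.multinomial(int(depth), p / total).astype(float)
    return Profile1D(counts, profile.bin_size, profile.genome_length, kind="COUNTS",
                     normalization=f"sampled from {profile.kind}")


def sample_hic_counts(cmap: ContactMap, depth: int, seed: int) -> ContactMap:
    """Multinomial contact counts drawn on the upper triangle, symmetrized."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    n = cmap.n_bins
    iu = np.triu_indices(n)
    p = np.clip(cmap.matrix[iu], 0.0, None)
    total = p.sum()
    out = np.zeros((n, n))
    if total > 0 and depth > 0:
        counts = rng.multinomial(int(depth), p / total).astype(float)
        out[iu] = counts
        out = out + np.triu(out, k=1).T
    return ContactMap(out, cmap.bin_size, cmap.genome_length, normalization="counts")


def normalize_mfa_counts(counts: Profile1D, baseline_quantile: float = 0.1) -> Profile1D:
    """Rescale a read-count MFA track onto the copy-number scale by setting
    the mean of the lowest-``baseline_quantile`` bins to 1 (the unreplicated
    baseline).  Requires that part of the genome is still unreplicated."""
    vals = counts.values.astype(float)
    if vals.sum() <= 0:
        raise ValueError("empty count track")
    k = max(1, int(counts.n_bins * baseline_quantile))
    base = np.sort(vals)[:k].mean()
    if base <= 0:
        raise ValueError("baseline bins have zero coverage; increase depth")
    return Profile1D(vals / base, counts.bin_size, counts.genome_length, kind="MFA",
                     normalization="counts/baseline")


# ---------------------------------------------------------------------------
# dataset bundles
# ---------------------------------------------------------------------------


def generate_dataset(
    scenario: ScenarioConfig,
    depth_mfa: int = 2_000_000,
    depth_chip: int = 2_000_000,
    depth_hic: int = 5_000_000,
    seed: int = 0,
    outdir: str | Path = ".",
    n_cells: int = 200,
    bin_size: int = 10_000,
) -> dict:
    """Run the joint simulation for a scenario and write a file bundle.

    Per sample time: a read-sampled MFA bedGraph, a read-sampled occupancy
    bedGraph and a contact-count sparse matrix, plus ``manifest.json``
    recording every ground-truth parameter and seed.  Byte-identical
    across runs with the same arguments.  Returns the manifest dict.
    """
    from . import io as lfio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = simulate_joint(
        scenario.protocol, scenario.rep_params, scenario.smc_params, scenario.genome,
        n_cells=n_cells, seed=seed, sample_times=scenario.sample_times,
        constitutive_loading=scenario.constitutive_loading,
    )
    files: dict[str, dict[str, str]] = {}
    for k, snap in enumerate(res.snapshots):
        t = snap.time_min
        tag = f"t{t:g}"
        mfa = compute_mfa(snap.forks, scenario.genome, bin_size)
        occ = compute_occupancy(snap.smc, scenario.genome, bin_size)
        hic = compute_contact_map(snap.smc, scenario.genome, bin_size)
        mfa_c = sample_profile_reads(mfa, depth_mfa, seed=seed * 1000 + 3 * k + 1)
        occ_c = sample_profile_reads(occ, depth_chip, seed=seed * 1000 + 3 * k + 2)
        hic_c = sample_hic_counts(hic, depth_hic, seed=seed * 1000 + 3 * k + 3)
        paths = {
            "mfa": str(outdir / f"{scenario.name}_{tag}_mfa.bedgraph"),
            "occupancy": str(outdir / f"{scenario.name}_{tag}_occupancy.bedgraph"),
            "hic": str(outdir / f"{scenario.name}_{tag}_hic.triplet.tsv"),
        }
        lfio.write_bedgraph(mfa_c, paths["mfa"])
        lfio.write_bedgraph(occ_c, paths["occupancy"])
        lfio.write_matrix_triplet(hic_c, paths["hic"])
        files[tag] = paths

    manifest = {
        "scenario": scenario.name,
        "seed": seed,
        "n_cells": n_cells,
        "bin_size": bin_size,
        "depths": {"mfa": depth_mfa, "chip": depth_chip, "hic": depth_hic},
        "truth": {
            "genome_length": scenario.genome.length,
            "parS_bp": [s.pos for s in scenario.genome.parS_sites],
            "replisome": asdict(scenario.rep_params),
            "smc": asdict(scenario.smc_params),
            "constitutive_loading": scenario.constitutive_loading,
            "sample_times_min": list(scenario.sample_times),
        },
        "files": files,
    }
    with open(outdir / f"{scenario.name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
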