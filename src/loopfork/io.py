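"""Plain-text file formats: bedGraph tracks, contact matrices, snapshot
tables, run configuration and provenance.

Tracks are standard bedGraph (chrom, 0-based half-open start/end, value) on
a single circular sequence; metadata (genome length, bin size, kind,
normalization) travels in ``#`` header comments so a round trip restores
the full :class:`~loopfork.observables.Profile1D`.  Matrices are written
both as dense TSV and as a sparse upper-triangle triplet format, again with
a commented header.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .observables import ContactMap, Profile1D

CHROM = "chromosome"


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(profile: Profile1D, path: str | Path) -> None:
    """Write a binned track as bedGraph; the last bin is clipped to the
    genome length so intervals tile [0, L) exactly."""
    path = Path(path)
    bs, L = profile.bin_size, profile.genome_length
    with open(path, "w") as fh:
        fh.write(f"# genome_length={L} bin_size={bs} kind={profile.kind}\n")
        fh.write(f"# normalization={profile.normalization}\n")
        fh.write(f'track type=bedGraph name="{profile.kind}"\n')
        for i, v in enumerate(profile.values):
            start = i * bs
            end = min((i + 1) * bs, L)
            fh.write(f"{CHROM}\t{start}\t{end}\t{v:.10g}\n")


def read_bedgraph(path: str | Path) -> Profile1D:
    """Read a bedGraph written by :func:`write_bedgraph` (or compatible).

    Raises a ``ValueError`` naming the offending line on malformed rows or
    overlapping intervals.  Missing intervals read back as zeros.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            if line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                start, end, val = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            rows.append((start, end, val))

    if "genome_length" not in meta or "bin_size" not in meta:
        raise ValueError(f"{path}: missing genome_length/bin_size header metadata")
    L, bs = int(meta["genome_length"]), int(meta["bin_size"])
    n_bins = int(np.ceil(L / bs))
    values = np.zeros(n_bins)
    seen = np.zeros(n_bins, dtype=bool)
    last_end = None
    for lineno_like, (start, end, val) in enumerate(rows):
        if last_end is not None and start < last_end:
            raise ValueError(f"{path}: overlapping intervals at start={start}")
        last_end = end
        b = start // bs
        if seen[b]:
            raise ValueError(f"{path}: duplicate interval for bin {b}")
        seen[b] = True
        values[b] = val
    return Profile1D(values, bs, L, kind=meta.get("kind", "OCCUPANCY"),
                     normalization=meta.get("normalization", "raw"))


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------


def _matrix_header(cmap: ContactMap) -> str:
    return (
        f"# genome_length={cmap.genome_length} bin_size={cmap.bin_size} "
        f"normalization={cmap.normalization}\n"
    )


def write_matrix_dense(cmap: ContactMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_matrix_header(cmap))
        np.savetxt(fh, cmap.matrix, fmt="%.8g", delimiter="\t")


def read_matrix_dense(path: str | Path) -> ContactMap:
    meta = _read_header(path)
    mat = np.loadtxt(path, comments="#", delimiter="\t")
    return ContactMap(mat, int(meta["bin_size"]), int(meta["genome_length"]),
                      normalization=meta.get("normalization", "raw"))


def write_matrix_triplet(cmap: ContactMap, path: str | Path) -> None:
    """Sparse text format: upper-triangle (bin_i, bin_j, value) rows, i <= j."""
    iu = np.triu_indices(cmap.n_bins)
    vals = cmap.matrix[iu]
    nz = vals != 0
    with open(path, "w") as fh:
        fh.write(_matrix_header(cmap))
        fh.write(f"# n_bins={cmap.n_bins} format=triplet_upper\n")
        for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{v:.8g}\n")


def read_matrix_triplet(path: str | Path) -> ContactMap:
    meta = _read_header(path)
    n = int(meta["n_bins"])
    mat = np.zeros((n, n))
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["i", "j", "value"])
    i = df["i"].to_numpy(dtype=int)
    j = df["j"].to_numpy(dtype=int)
    v = df["value"].to_numpy(dtype=float)
    mat[i, j] = v
    off = i != j
    mat[j[off], i[off]] = v[off]
    return ContactMap(mat, int(meta["bin_size"]), int(meta["genome_length"]),
                      normalization=meta.get("normalization", "raw"))


def _read_header(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line.lstrip("# ").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    return meta


# ---------------------------------------------------------------------------
# snapshot tables
# ---------------------------------------------------------------------------


def write_fork_table(snapshots, path: str | Path) -> None:
    """Fork snapshots (list of (time, ForkEnsemble)) as one tidy CSV."""
    frames = []
    for t, state in snapshots:
        df = state.to_table()
        df["time_min"] = t
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fork_table(path: str | Path):
    """Read a fork table back into a list of (time, ForkEnsemble)."""
    from .replisome import ForkEnsemble

    df = pd.read_csv(path)
    out = []
    for t, grp in df.groupby("time_min", sort=True):
        grp = grp.sort_values("cell")
        n = len(grp)
        out.append(
            (
                float(t),
                ForkEnsemble(
                    initiated=grp["initiated"].to_numpy(bool),
                    pending_delay=np.full(n, np.nan),
                    left_pos=grp["left_pos"].to_numpy(float),
                    right_pos=grp["right_pos"].to_numpy(float),
                    left_stalled=grp["left_stalled"].to_numpy(bool),
                    right_stalled=grp["right_stalled"].to_numpy(bool),
                    pre_existing=grp["pre_existing"].to_numpy(bool),
                    time_min=float(t),
                ),
            )
        )
    return out


def write_smc_table(snapshots, path: str | Path) -> None:
    """SMC snapshots (list of SMCSnapshot) as one tidy CSV."""
    frames = [s.to_table() for s in snapshots]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_smc_table(path: str | Path):
    from .smc import SMCSnapshot

    df = pd.read_csv(path)
    out = []
    for t, grp in df.groupby("time_min", sort=True):
        out.append(
            SMCSnapshot(
                time_min=float(t),
                cell=grp["cell"].to_numpy(int),
                load_pos=grp["load_pos"].to_numpy(float),
                pos_ccw=grp["pos_ccw"].to_numpy(float),
                pos_cw=grp["pos_cw"].to_numpy(float),
                n_cells=int(grp["cell"].max()) + 1 if len(grp) else 0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# run config + provenance
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    scenario: str
    outdir: str
    seed: int
    overrides: dict | None = None

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "outdir": self.outdir,
            "seed": self.seed,
            "overrides": self.overrides or {},
        }


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(outdir: str | Path, config: dict, wall_time_s: float | None = None) -> Path:
    """Record what produced the contents of ``outdir``: config, its hash,
    package version, and wall time."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "config": config,
        "config_hash": config_hash(config),
        "loopfork_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "wall_time_s": wall_time_s,
    }
    path = outdir / "provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, default=str)
        fh.write("\n")
    return path
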