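"""Forward models from ensemble snapshots to the three measurement types.

Marker-frequency analysis (MFA) is the per-bin mean copy number over cells
(2 inside the replicated interval, 1 outside).  ChIP-like occupancy is a
kernel-smoothed density of bound motor positions plus loading sites,
normalized reads-per-million style.  Contact maps combine a Gaussian-smeared
density of (motor_ccw, motor_cw) anchor pairs — the loop/zipping layer —
with a power-law distance-decay background, optionally balanced by
iterative proportional fitting.

Geometric feature extractors: :func:`zipping_extent` walks the secondary
diagonal of a contact map outward from the loading site and reports the
per-arm end of detectable signal; :func:`arc_speed_ratio` fits the relative
displacement of the two anchors to obtain the inter-arm speed ratio that
sets the tilt of the secondary diagonal / arc.

All 1-D tracks and matrices live on a circular binning of the genome in
0-based linear coordinates with the origin at position 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .genome import GenomeSpec, wrap_coord
from .replisome import ForkEnsemble
from .smc import SMCSnapshot


@dataclass
class Profile1D:
    """Binned 1-D genomic track on the circular genome.

    ``values[i]`` covers linear coordinates [i*bin_size, (i+1)*bin_size);
    the origin sits at the start of bin 0.
    """

    values: np.ndarray
    bin_size: int
    genome_length: int
    kind: str = "OCCUPANCY"  # MFA | OCCUPANCY | RATIO | COUNTS
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = int(np.ceil(self.genome_length / self.bin_size))
        if self.values.size != expect:
            raise ValueError(f"expected {expect} bins, got {self.values.size}")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_centers_signed(self) -> np.ndarray:
        """Signed (origin-centred) coordinates of bin centers."""
        lin = (np.arange(self.n_bins) + 0.5) * self.bin_size
        return wrap_coord(lin, self.genome_length)

    def rebin(self, out_bin: int) -> "Profile1D":
        """Average-rebin to a coarser bin size (must be a multiple)."""
        if out_bin == self.bin_size:
            return Profile1D(self.values.copy(), self.bin_size, self.genome_length, self.kind, self.normalization)
        if out_bin % self.bin_size:
            raise ValueError("out_bin must be a multiple of bin_size")
        f = out_bin // self.bin_size
        n_out = int(np.ceil(self.n_bins / f))
        padded = self.values
        if self.n_bins % f:  # wrap the circular tail into the last coarse bin
            padded = np.concatenate([self.values, self.values[: n_out * f - self.n_bins]])
        vals = padded.reshape(n_out, f).mean(axis=1)
        return Profile1D(vals, out_bin, self.genome_length, self.kind, self.normalization)

    def window_mean(self, center: float, halfwidth: float) -> float:
        """Mean value over bins whose center lies within ``halfwidth`` of the
        signed coordinate ``center`` (circular)."""
        from .genome import circular_distance

        g = GenomeSpec(length=self.genome_length)
        d = circular_distance(self.bin_centers_signed(), center, g)
        sel = d <= halfwidth
        if not sel.any():
            raise ValueError("window contains no bins")
        return float(self.values[sel].mean())


@dataclass
class ContactMap:
    """Binned symmetric contact-frequency matrix on the circular genome."""

    matrix: np.ndarray
    bin_size: int
    genome_length: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.T, atol=tol * max(1.0, self.matrix.max())))

    def balanced(self, n_iter: int = 50, tol: float = 1e-4) -> "ContactMap":
        """Iterative proportional fitting to equal row sums, preserving
        symmetry and total mass."""
        m = self.matrix.copy()
        total = m.sum()
        for _ in range(n_iter):
            rows = m.sum(axis=1)
            rows[rows == 0] = 1.0
            scale = np.sqrt(rows / rows[rows > 0].mean())
            m = m / scale[:, None] / scale[None, :]
            r = m.sum(axis=1)
            r = r[r > 0]
            if r.size and (r.max() - r.min()) / r.mean() < tol:
                break
        if m.sum() > 0:
            m *= total / m.sum()
        return ContactMap(m, self.bin_size, self.genome_length, normalization="balanced")

    def expected_by_distance(self) -> np.ndarray:
        """Mean contact per circular bin-distance (the distance-decay curve)."""
        n = self.n_bins
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :])
        d = np.minimum(d, n - d).ravel()
        sums = np.bincount(d, weights=self.matrix.ravel(), minlength=n // 2 + 1)
        cnts = np.bincount(d, minlength=n // 2 + 1)
        return sums[: n // 2 + 1] / np.maximum(cnts[: n // 2 + 1], 1)


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------


def compute_mfa(forks: ForkEnsemble, genome: GenomeSpec, bin_size: int = 10_000) -> Profile1D:
    """Population MFA: per-bin mean copy number (values in [1, 2])."""
    if forks.n_cells == 0:
        raise ValueError("empty ensemble")
    n_bins = int(np.ceil(genome.length / bin_size))
    centers = wrap_coord((np.arange(n_bins) + 0.5) * bin_size, genome.length)
    copy = forks.copy_number(centers)  # (n_cells, n_bins)
    return Profile1D(copy.mean(axis=0), bin_size, genome.length, kind="MFA")


def compute_occupancy(
    smc: SMCSnapshot,
    genome: GenomeSpec,
    bin_size: int = 10_000,
    footprint_sd: float = 5_000.0,
    include_load_sites: bool = True,
) -> Profile1D:
    """ChIP-like occupancy: smoothed density of bound motor positions (plus
    loading sites), normalized to reads-per-million equivalent."""
    n_bins = int(np.ceil(genome.length / bin_size))
    positions = [smc.pos_ccw, smc.pos_cw]
    if include_load_sites:
        positions.append(smc.load_pos)
    pos = np.concatenate(positions) if positions else np.empty(0)
    lin = np.asarray(pos) % genome.length
    counts, _ = np.histogram(lin, bins=n_bins, range=(0, n_bins * bin_size))
    vals = counts.astype(float)
    if footprint_sd > 0 and vals.any():
        vals = gaussian_filter1d(vals, sigma=footprint_sd / bin_size, mode="wrap")
    total = vals.sum()
    if total > 0:
        vals = vals * 1e6 / total
    return Profile1D(vals, bin_size, genome.length, kind="OCCUPANCY", normalization="rpm")


def profile_ratio(
    a: Profile1D,
    b: Profile1D,
    out_bin: int = 5_000,
    pseudocount: float | None = None,
) -> Profile1D:
    """log2((a+eps)/(b+eps)) rebinned to ``out_bin``.

    The pseudocount defaults to 1e-6 of the mean level of the two tracks,
    guarding empty bins without distorting occupied ones.
    """
    if a.genome_length != b.genome_length or a.bin_size != b.bin_size:
        raise ValueError("profiles must share genome and binning")
    ar, br = a.rebin(out_bin), b.rebin(out_bin)
    if pseudocount is None:
        pseudocount = 1e-6 * max((ar.values.mean() + br.values.mean()) / 2.0, 1e-300)
    vals = np.log2((ar.values + pseudocount) / (br.values + pseudocount))
    return Profile1D(vals, out_bin, a.genome_length, kind="RATIO", normalization=f"log2, eps={pseudocount:g}")


def compute_contact_map(
    smc: SMCSnapshot,
    genome: GenomeSpec,
    bin_size: int = 10_000,
    background_exponent: float = 1.0,
    background_s0: float = 30_000.0,
    loop_weight: float = 5.0,
    kernel_sd: float = 10_000.0,
    balance: bool = False,
) -> ContactMap:
    """Forward Hi-C model: loop layer from anchor pairs + distance-decay background.

    The loop layer is the Gaussian-smeared, symmetrized density of
    (motor_ccw, motor_cw) pairs normalized to unit mass; the background is
    ``(s0 + circular distance)^(−background_exponent)`` normalized to unit
    mass; the map is ``background + loop_weight × loops``.
    """
    n = int(np.ceil(genome.length / bin_size))
    idx = np.arange(n)
    dbin = np.abs(idx[:, None] - idx[None, :])
    dbin = np.minimum(dbin, n - dbin).astype(float)
    bg = (background_s0 + dbin * bin_size) ** (-background_exponent)
    bg /= bg.sum()

    mat = bg.copy()
    if smc.pos_ccw.size:
        i = (np.asarray(smc.pos_ccw) % genome.length // bin_size).astype(int) % n
        j = (np.asarray(smc.pos_cw) % genome.length // bin_size).astype(int) % n
        loops = np.zeros((n, n))
        np.add.at(loops, (i, j), 1.0)
        loops = loops + loops.T
        if kernel_sd > 0:
            loops = gaussian_filter(loops, sigma=kernel_sd / bin_size, mode="wrap")
        s = loops.sum()
        if s > 0:
            loops /= s
        mat = mat + loop_weight * loops
    cmap = ContactMap(mat, bin_size, genome.length, normalization="raw")
    return cmap.balanced() if balance else cmap


# ---------------------------------------------------------------------------
# feature extractors
# ---------------------------------------------------------------------------


def zipping_extent(
    cmap: ContactMap,
    load_pos: float,
    intensity_threshold_frac: float = 0.2,
    proximal_bins: int = 10,
    miss_run: int = 3,
    subtract_expected: bool = True,
) -> tuple[float, float] | None:
    """Per-arm extent of the secondary diagonal through ``load_pos``.

    Walks the anti-diagonal outward from the loading position, greedily
    following the local ridge (one bin of tilt per step, so arcs are
    tracked as well as perpendicular diagonals), on the
    observed-minus-expected map.  The end is the last step whose ridge
    intensity stays at or above ``intensity_threshold_frac`` times the
    median intensity of the proximal segment; ``miss_run`` consecutive
    sub-threshold steps terminate the walk.  Returns (ccw_extent_bp,
    cw_extent_bp), or None when no diagonal is detectable.
    """
    n = cmap.n_bins
    m = cmap.matrix
    if subtract_expected:
        exp = cmap.expected_by_distance()
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :])
        d = np.minimum(d, n - d)
        m = np.clip(m - exp[d], 0.0, None)
    p = int((load_pos % cmap.genome_length) // cmap.bin_size) % n

    ks = np.arange(1, n // 2)
    shifts = np.zeros(len(ks) + 1, dtype=int)
    intens = np.zeros(len(ks) + 1)
    intens[0] = m[p, p]
    for t, k in enumerate(ks, start=1):
        best_val, best_s = -np.inf, shifts[t - 1]
        for s in (shifts[t - 1] - 1, shifts[t - 1], shifts[t - 1] + 1):
            i = (p - k + s) % n
            j = (p + k + s) % n
            v = m[i, j]
            if v > best_val:
                best_val, best_s = v, s
        shifts[t] = best_s
        intens[t] = best_val

    prox = intens[1 : 1 + proximal_bins]
    med = float(np.median(prox))
    if med <= 0:
        return None
    thr = intensity_threshold_frac * med
    end_t, misses = 0, 0
    for t in range(1, len(intens)):
        if intens[t] >= thr:
            end_t, misses = t, 0
        else:
            misses += 1
            if misses >= miss_run:
                break
    if end_t == 0:
        return None
    k_end, s_end = int(ks[end_t - 1]), int(shifts[end_t])
    ccw = (k_end - s_end) * cmap.bin_size
    cw = (k_end + s_end) * cmap.bin_size
    return float(max(ccw, 0)), float(max(cw, 0))


def arc_speed_ratio(points: np.ndarray, load_pos: float) -> float:
    """Relative speed of the two motors from arc/anchor geometry.

    ``points`` is an (n, 2) array of (pos_ccw, pos_cw) signed positions.
    Displacements are measured from the loading site: the counter-clockwise
    motor's displacement is regressed on the clockwise motor's (least
    squares through the origin), so the returned slope is
    v_ccw / v_cw.  A ratio of 1 means a perpendicular secondary diagonal;
    < 1 means the counter-clockwise side is the slower arm (the arc tilts
    toward it); 0 means that side does not advance at all.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (ccw, cw) arc points")
    d_ccw = load_pos - pts[:, 0]  # ccw motor decreases its coordinate
    d_cw = pts[:, 1] - load_pos
    denom = float(np.sum(d_cw * d_cw))
    if denom <= 0:
        raise ValueError("degenerate arc: clockwise displacements are all zero")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate arc: all points identical")
    return float(np.sum(d_ccw * d_cw) / denom)
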