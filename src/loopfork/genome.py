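"""Circular chromosome geometry and the signed, origin-centred coordinate system.

The chromosome is a circle of ``length`` base pairs with the replication
origin (*oriC*) at coordinate 0 and the terminus at ±length/2.  Signed
coordinates are used throughout the simulators: positive positions lie on
the right replichore (clockwise, + degrees on the standard circular map),
negative positions on the left replichore.  −180° and +180° name the same
locus, the terminus.  File output converts to ordinary 0-based half-open
linear coordinates on [0, length) with the origin at position 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default chromosome length in bp (B. subtilis PY79 scale).  The degree /
#: kb arithmetic of the system is only approximately linear on the real
#: assembly, so the length is configurable rather than pinned to it.
DEFAULT_LENGTH = 4_033_000

#: parS angles (degrees from oriC) carried by wild-type B. subtilis:
#: five origin-proximal sites and four origin-distal sites.
WT_PARS_DEGREES = (-1.0, -3.0, -4.0, -5.0, 4.0, 17.0, 42.0, 91.0, -27.0)


@dataclass(frozen=True)
class ParSSite:
    """A condensin loading site: signed bp position and loading weight (≥ 0)."""

    pos: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"parS loading weight must be >= 0, got {self.weight}")


@dataclass(frozen=True)
class GenomeSpec:
    """Circular chromosome: length, origin at 0, parS sites with loading weights."""

    length: int = DEFAULT_LENGTH
    parS_sites: tuple[ParSSite, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"genome length must be > 0, got {self.length}")
        half = self.length / 2
        for site in self.parS_sites:
            if not (-half < site.pos <= half):
                raise ValueError(
                    f"parS position {site.pos} outside (-{half}, {half}]"
                )

    @classmethod
    def from_degrees(
        cls,
        angles: tuple[float, ...] | list[float],
        weights: tuple[float, ...] | list[float] | None = None,
        length: int = DEFAULT_LENGTH,
    ) -> "GenomeSpec":
        """Build a genome whose parS sites are given as map angles."""
        if weights is None:
            weights = [1.0] * len(angles)
        if len(weights) != len(angles):
            raise ValueError("angles and weights must have equal length")
        sites = tuple(
            ParSSite(pos=deg_to_bp(a, length=length), weight=w)
            for a, w in zip(angles, weights)
        )
        return cls(length=length, parS_sites=sites)

    @property
    def terminus(self) -> float:
        return self.length / 2

    # -- coordinate helpers -------------------------------------------------

    def wrap(self, x):
        """Map arbitrary bp coordinates onto the signed range (−L/2, L/2]."""
        return wrap_coord(x, self.length)

    def to_linear(self, x):
        """Signed coordinate → 0-based linear coordinate on [0, L)."""
        return np.asarray(x) % self.length


def deg_to_bp(angle: float, genome: GenomeSpec | None = None, *, length: int | None = None) -> int:
    """Convert a map angle in [−180, 180] to a signed bp coordinate.

    bp = angle/360 × length, rounded to the nearest integer.  Inverse of
    :func:`bp_to_deg` up to that rounding.
    """
    if length is None:
        length = genome.length if genome is not None else DEFAULT_LENGTH
    if not -180.0 <= angle <= 180.0:
        raise ValueError(f"angle {angle} outside [-180, 180]")
    return int(round(angle / 360.0 * length))


def bp_to_deg(pos: float, genome: GenomeSpec | None = None, *, length: int | None = None) -> float:
    """Convert a signed bp coordinate to a map angle in (−180, 180]."""
    if length is None:
        length = genome.length if genome is not None else DEFAULT_LENGTH
    pos = wrap_coord(pos, length)
    return float(pos) / length * 360.0


def wrap_coord(x, length: int):
    """Map bp coordinates onto the signed range (−L/2, L/2] (array-safe)."""
    arr = np.asarray(x, dtype=float)
    half = length / 2
    out = (arr + half) % length - half
    # the fold above yields [-L/2, L/2); move the -L/2 representative to +L/2
    out = np.where(out == -half, half, out)
    if np.isscalar(x) or getattr(x, "ndim", 1) == 0:
        return float(out)
    return out


def circular_distance(a, b, genome: GenomeSpec) -> float | np.ndarray:
    """Shortest arc distance between two coordinates on the circle (≤ L/2)."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % genome.length
    out = np.minimum(d, genome.length - d)
    if np.isscalar(a) and np.isscalar(b):
        return float(out)
    return out
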