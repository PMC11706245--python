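"""Window-conditioned average structures and inter-base-pair pitch.

An average structure is the independent per-coordinate arithmetic mean of all
trajectory snapshots whose CV triple lies inside a representative window
(default: the bound state at (4.5, 4.5, 4.5) with half-width = half a bin).
Base-pair centers are midpoints of the designated particle pair per position
(the two beads of a position on the coarse-grained tier; the two C1' atoms on
imported full-atom structures), and the inter-base-pair pitch is the
Euclidean distance between consecutive centers.

Because averaging is independent per coordinate, it can be skewed where
conformational fluctuations are large; particles whose coordinate standard
deviation exceeds a threshold are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import Snapshot, Trajectory

#: Default per-particle coordinate standard deviation (angstrom) above which
#: the skew flag is raised.
SKEW_THRESHOLD = 1.5

#: Particle pairing on the coarse-grained tier: codon bead i with anticodon
#: bead i+3.
DEFAULT_PAIRS = ((0, 3), (1, 4), (2, 5))


@dataclass(frozen=True)
class WindowSpec:
    """Representative CV coordinates with an inclusive half-width per axis."""

    center: tuple[float, float, float] = (4.5, 4.5, 4.5)
    half_width: tuple[float, float, float] = (0.25, 0.25, 0.25)
    grid_range: tuple[float, float] = (4.0, 9.0)

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in np.atleast_1d(self.center))
        hw = np.atleast_1d(self.half_width).astype(float)
        if hw.size == 1:
            hw = np.repeat(hw, 3)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "half_width", tuple(hw))
        if len(c) != 3 or len(self.half_width) != 3:
            raise ValueError("window needs three center coordinates")
        if any(h <= 0 for h in self.half_width):
            raise ValueError("half widths must be positive")
        lo, hi = self.grid_range
        for x, h in zip(c, self.half_width):
            if x - h < lo - 1e-9 or x + h > hi + 1e-9:
                raise ValueError(
                    f"window {c} +/- {self.half_width} extends outside the grid "
                    f"range [{lo}, {hi}]"
                )

    def contains(self, cv: np.ndarray) -> bool:
        cv = np.asarray(cv, dtype=float)
        c = np.asarray(self.center)
        h = np.asarray(self.half_width)
        return bool(np.all(cv >= c - h) and np.all(cv <= c + h))


@dataclass(frozen=True)
class AverageStructure:
    """Mean particle coordinates over the selected snapshots."""

    coords: np.ndarray  # (n_particles, 3)
    n_snapshots: int
    names: tuple
    coord_std: np.ndarray  # (n_particles, 3)
    skew_flags: np.ndarray  # (n_particles,) bool
    window: WindowSpec | None = None
    pairs: tuple = DEFAULT_PAIRS

    def __post_init__(self) -> None:
        if self.n_snapshots < 1:
            raise ValueError("an average structure needs at least one snapshot")


@dataclass(frozen=True)
class PitchResult:
    """Base-pair centers (ordered by codon position) and consecutive pitches."""

    centers: np.ndarray  # (3, 3)
    pitch_12: float
    pitch_23: float

    def __post_init__(self) -> None:
        if self.pitch_12 < 0 or self.pitch_23 < 0:
            raise ValueError("pitches are distances and must be >= 0")


def select_snapshots(traj: Trajectory, window: WindowSpec) -> list[Snapshot]:
    """Snapshots whose CVs satisfy the window condition on all three axes.

    Bounds are inclusive on both sides.  An empty selection raises, naming
    the requested window and the nearest populated CV point.
    """
    c = np.asarray(window.center)
    h = np.asarray(window.half_width)
    inside = np.all((traj.cv >= c - h) & (traj.cv <= c + h), axis=1)
    picked = np.flatnonzero(inside)
    if picked.size == 0:
        if len(traj) == 0:
            raise ValueError("trajectory is empty")
        nearest = traj.cv[np.argmin(np.linalg.norm(traj.cv - c, axis=1))]
        raise ValueError(
            f"no snapshots in window {window.center} +/- {window.half_width}; "
            f"nearest populated CV point is {np.round(nearest, 3).tolist()}"
        )
    return [traj.snapshot(int(i)) for i in picked]


def _kabsch(moving: np.ndarray, ref: np.ndarray) -> np.ndarray:
    mc = moving - moving.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, sign]) @ vt
    return mc @ rot + ref.mean(axis=0)


def average_structure(
    snapshots: Sequence[Snapshot],
    window: WindowSpec | None = None,
    skew_threshold: float = SKEW_THRESHOLD,
    superpose: bool = False,
) -> AverageStructure:
    """Independent arithmetic mean of each coordinate of each particle.

    ``superpose`` optionally rigid-body fits every snapshot onto the first
    before averaging (off by default: the production analysis averages raw
    coordinates in the complex frame, accepting the documented skew caveat).
    """
    if len(snapshots) == 0:
        raise ValueError("no snapshots to average")
    names = snapshots[0].names
    stack = np.array([s.coords for s in snapshots])
    if superpose and len(snapshots) > 1:
        stack = np.array([_kabsch(c, stack[0]) for c in stack])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)
    flags = np.any(std > skew_threshold, axis=1)
    return AverageStructure(
        coords=mean,
        n_snapshots=len(snapshots),
        names=tuple(names),
        coord_std=std,
        skew_flags=flags,
        window=window,
    )


def base_pair_centers(structure: AverageStructure) -> np.ndarray:
    """Midpoint of the designated particle pair for each base-pair position."""
    centers = np.empty((3, 3))
    n = structure.coords.shape[0]
    for pos, (i, j) in enumerate(structure.pairs, start=1):
        if i >= n or j >= n:
            raise ValueError(
                f"structure lacks the designated particle pair for position {pos}"
            )
        centers[pos - 1] = 0.5 * (structure.coords[i] + structure.coords[j])
    return centers


def inter_pair_pitch(centers: np.ndarray) -> PitchResult:
    """Distances between consecutive base-pair centers (1-2 and 2-3)."""
    centers = np.asarray(centers, dtype=float)
    if centers.shape != (3, 3):
        raise ValueError("expected three 3D base-pair centers")
    p12 = float(np.linalg.norm(centers[1] - centers[0]))
    p23 = float(np.linalg.norm(centers[2] - centers[1]))
    return PitchResult(centers=centers, pitch_12=p12, pitch_23=p23)
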