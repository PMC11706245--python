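"""Adaptive biasing force engine over the three base-pair distances.

The collective-variable space is binned on a regular grid (default
4.0-9.0 angstrom, bin width 0.5, i.e. 10x10x10 = 1000 bins).  During a biased
run the engine accumulates, per bin, the visit count N(b) and the sum S(b) of
the instantaneous generalized force -dU/dd_i, and applies the ramped running
mean as the bias:

    F_bias(b) = -min(1, N(b)/N_full) * S(b) / N(b)

which progressively flattens the landscape so rarely visited regions become
accessible.  Bins are half-open [lo, lo+w) except the last, which is closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .system import SystemSpec, DynamicsSpec
from . import _kernels
from .dynamics import Trajectory, _embed_cv_coords, BEAD_NAMES

#: Marker returned by :func:`bin_index` for a CV point outside the grid.
OUT_OF_RANGE = None


@dataclass(frozen=True)
class GridSpec:
    """Regular binning of one CV dimension, applied identically to all three."""

    lower: float = 4.0
    upper: float = 9.0
    width: float = 0.5

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        n = (self.upper - self.lower) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"bin width {self.width} does not evenly divide "
                f"[{self.lower}, {self.upper}]"
            )

    @property
    def nbins(self) -> int:
        return int(round((self.upper - self.lower) / self.width))

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.nbins
        return (n, n, n)

    @property
    def edges(self) -> np.ndarray:
        return self.lower + self.width * np.arange(self.nbins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.lower + self.width * (np.arange(self.nbins) + 0.5)


def make_grid(lower: float = 4.0, upper: float = 9.0, width: float = 0.5) -> GridSpec:
    """Validated grid constructor; rejects non-commensurate widths outright."""
    return GridSpec(lower=float(lower), upper=float(upper), width=float(width))


def bin_index(grid: GridSpec, cv: Sequence[float]):
    """Map a CV triple to its (i, j, k) bin, or ``None`` if out of range.

    Half-open bins; a coordinate exactly at the upper bound maps into the
    last (closed) bin.  Total on finite inputs — never raises for
    out-of-range values.
    """
    d = np.asarray(cv, dtype=float)
    if d.shape != (3,):
        raise ValueError("cv must be three distances")
    if not np.all(np.isfinite(d)):
        raise ValueError(f"non-finite cv {d}")
    n = grid.nbins
    idx = []
    for x in d:
        if x < grid.lower or x > grid.upper:
            return OUT_OF_RANGE
        i = int((x - grid.lower) / grid.width)
        idx.append(min(i, n - 1))
    return tuple(idx)


@dataclass
class ABFState:
    """Persistent sampler state: per-bin visit counts and force sums."""

    grid: GridSpec
    counts: np.ndarray = None  # int64, (n, n, n)
    force_sum: np.ndarray = None  # float64, (n, n, n, 3), kJ/mol/angstrom
    n_full: int = 200
    total_steps: int = 0
    discarded: int = 0
    bias_applied: bool = True

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(self.grid.shape, dtype=np.int64)
        if self.force_sum is None:
            self.force_sum = np.zeros(self.grid.shape + (3,), dtype=np.float64)
        if self.counts.shape != self.grid.shape:
            raise ValueError("counts shape does not match grid")
        if self.force_sum.shape != self.grid.shape + (3,):
            raise ValueError("force_sum shape does not match grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.isfinite(self.force_sum)):
            raise ValueError("force_sum must be finite")
        if self.n_full < 1:
            raise ValueError("n_full must be >= 1")

    def copy(self) -> "ABFState":
        return ABFState(
            grid=self.grid,
            counts=self.counts.copy(),
            force_sum=self.force_sum.copy(),
            n_full=self.n_full,
            total_steps=self.total_steps,
            discarded=self.discarded,
            bias_applied=self.bias_applied,
        )

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        """Write the state to a single self-describing .npz archive."""
        meta = {
            "lower": self.grid.lower,
            "upper": self.grid.upper,
            "width": self.grid.width,
            "n_full": self.n_full,
            "total_steps": self.total_steps,
            "discarded": self.discarded,
            "bias_applied": self.bias_applied,
        }
        np.savez(path, counts=self.counts, force_sum=self.force_sum,
                 meta=np.bytes_(json.dumps(meta).encode()))

    @classmethod
    def load(cls, path) -> "ABFState":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            grid = GridSpec(meta["lower"], meta["upper"], meta["width"])
            return cls(
                grid=grid,
                counts=z["counts"].copy(),
                force_sum=z["force_sum"].copy(),
                n_full=int(meta["n_full"]),
                total_steps=int(meta["total_steps"]),
                discarded=int(meta["discarded"]),
                bias_applied=bool(meta["bias_applied"]),
            )


def abf_accumulate(state: ABFState, cv: Sequence[float], force: Sequence[float]) -> ABFState:
    """Record one instantaneous-force sample into the running estimator.

    Out-of-range samples leave the accumulators untouched and increment the
    discard counter.  Mutates and returns ``state``.
    """
    f = np.asarray(force, dtype=float)
    if f.shape != (3,) or not np.all(np.isfinite(f)):
        raise ValueError(f"instantaneous force must be three finite components, got {force}")
    b = bin_index(state.grid, cv)
    if b is OUT_OF_RANGE:
        state.discarded += 1
    else:
        state.counts[b] += 1
        state.force_sum[b] += f
    state.total_steps += 1
    return state


def abf_bias_force(state: ABFState, cv: Sequence[float]) -> np.ndarray:
    """Ramped bias force at a CV point: ``-min(1, N/N_full) * S/N`` per component.

    Zero for unvisited or out-of-range bins, so the bias magnitude never
    exceeds the current mean-force estimate.
    """
    b = bin_index(state.grid, cv)
    if b is OUT_OF_RANGE:
        return np.zeros(3)
    n = state.counts[b]
    if n == 0:
        return np.zeros(3)
    ramp = min(1.0, n / state.n_full)
    return -ramp * state.force_sum[b] / n


def mean_force_grid(state: ABFState) -> np.ma.MaskedArray:
    """Per-bin mean force S(b)/N(b) as a masked (n, n, n, 3) field.

    Unvisited bins are masked.
    """
    n = state.counts[..., None].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mf = state.force_sum / n
    mask = np.broadcast_to(state.counts[..., None] == 0, mf.shape)
    return np.ma.MaskedArray(np.where(mask, 0.0, mf), mask=mask)


# ---------------------------------------------------------------------------
# Biased sampling runs
# ---------------------------------------------------------------------------

@dataclass
class ABFRun:
    """Output bundle of :func:`run_abf`."""

    state: ABFState
    trajectory: Trajectory
    cv_series: np.ndarray  # columns: step, d1, d2, d3, U
    checkpoints: list  # list[(step, ProbabilityGrid)]


def run_abf(
    spec: SystemSpec,
    dyn: DynamicsSpec,
    grid: GridSpec | None = None,
    n_full: int = 200,
    checkpoint_fractions: Sequence[float] = (),
    burn_in_fraction: float = 0.05,
    histogram_reset_fraction: float = 0.1,
    bias: bool = True,
    start: Sequence[float] | None = None,
) -> ABFRun:
    """Run ABF-biased overdamped Langevin dynamics on the direct-CV tier.

    The unbiased burn-in (``burn_in_fraction`` of the steps) is discarded from
    the accumulators.  ``checkpoint_fractions`` request probability-grid
    snapshots (for the convergence statistic L) at those fractions of the
    accumulation phase.  Identical spec + dyn (seed included) reproduce the
    run bit-for-bit.

    ``histogram_reset_fraction`` applies the standard ABF histogram reset:
    after that fraction of the accumulation phase, per-bin counts are capped
    at ``n_full`` while the learned mean forces are retained.  Early samples
    — collected before the bias had flattened the landscape and therefore
    piled up in the wells — then stop dominating the final histogram, while
    the bias force carries on from its converged estimate.  Set to 0 to
    disable.
    """
    from .pmf import probability_from_state  # local import: pmf layers above abf

    if spec.tier != "direct-cv":
        raise ValueError("run_abf operates on the direct-CV tier")
    grid = grid or GridSpec()
    state = ABFState(grid=grid, n_full=n_full, bias_applied=bias)
    rng = np.random.default_rng(dyn.seed)
    pos = np.array(start if start is not None else spec.potential.d0, dtype=float)
    prev_noise = rng.standard_normal(3)

    kt = spec.kt
    mob = dyn.timestep / dyn.friction
    noise_scale = np.sqrt(2.0 * kt * mob)
    pars = spec.potential.as_arrays()

    n_burn = int(round(burn_in_fraction * dyn.n_steps))
    n_acc = dyn.n_steps - n_burn
    check_steps = sorted({int(round(f * n_acc)) for f in checkpoint_fractions if f > 0})
    reset_step = int(round(histogram_reset_fraction * n_acc)) if bias else 0

    n_frames = (dyn.n_steps + dyn.stride - 1) // dyn.stride
    cv_out = np.empty((n_frames, 5), dtype=np.float64)

    def _segment(n_steps: int, step0: int, accumulate: bool) -> None:
        chunk = 200_000
        done = 0
        while done < n_steps:
            m = min(chunk, n_steps - done)
            noise = rng.standard_normal((m, 3))
            bad = _kernels.abf_chunk(
                pos, noise,
                pars["eps"], pars["a"], pars["d0"], pars["j12"], pars["j23"],
                pars["sigma"], pars["kappa"], pars["dw"],
                pars["wall_on"].astype(np.uint8),
                np.uint8(spec.jacobian), kt, mob, noise_scale,
                dyn.range_low, dyn.range_high, dyn.boundary_stiffness,
                grid.lower, grid.width, grid.nbins,
                state.counts, state.force_sum,
                np.uint8(bias and accumulate), np.uint8(accumulate),
                n_full, cv_out, dyn.stride, step0 + done,
                _discard, prev_noise,
            )
            if bad >= 0:
                raise FloatingPointError(
                    f"dynamics diverged (non-finite coordinate) at step {bad}"
                )
            done += m

    def _reset_histogram() -> None:
        visited = state.counts > 0
        capped = np.minimum(state.counts, n_full)
        mean = np.zeros_like(state.force_sum)
        mean[visited] = state.force_sum[visited] / state.counts[visited, None]
        state.counts = np.where(visited, capped, 0)
        state.force_sum = mean * state.counts[..., None]

    _discard = np.zeros(1, dtype=np.int64)
    _segment(n_burn, 0, accumulate=False)
    prev = 0
    checkpoints = []
    boundaries = sorted(set(check_steps) | ({reset_step} if 0 < reset_step < n_acc else set()))
    for cs in boundaries:
        _segment(cs - prev, n_burn + prev, accumulate=True)
        prev = cs
        state.total_steps = n_burn + prev
        state.discarded = int(_discard[0])
        if cs in check_steps:
            checkpoints.append((n_burn + cs, probability_from_state(state.copy(), spec,
                                                                    checkpoint_step=n_burn + cs)))
        if cs == reset_step:
            _reset_histogram()
    _segment(n_acc - prev, n_burn + prev, accumulate=True)
    state.total_steps = dyn.n_steps
    state.discarded = int(_discard[0])

    steps = cv_out[:, 0].astype(int)
    coords = _embed_cv_coords(cv_out[:, 1:4])
    traj = Trajectory(
        steps=steps,
        coords=coords,
        cv=cv_out[:, 1:4].copy(),
        energy=cv_out[:, 4].copy(),
        names=list(BEAD_NAMES),
        metadata={"seed": dyn.seed, "spec_hash": spec.spec_hash(),
                  "tier": spec.tier, "preset": spec.name, "biased": bias},
    )
    return ABFRun(state=state, trajectory=traj, cv_series=cv_out, checkpoints=checkpoints)
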