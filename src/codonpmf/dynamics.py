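"""Langevin dynamics for the coarse-grained triplet system.

Two tiers share the same potential (see :mod:`codonpmf.system`):

* ``direct-cv`` — overdamped (Brownian) dynamics directly on the three
  base-pair distances.  The stationary density is exactly
  ``exp(-U/kT)`` (times ``d^2`` per coordinate when the Jacobian flag is on),
  so the quadrature oracle can validate every estimator.
* ``cartesian-beads`` — six beads in 3D, bead pair (i, i+3) realizing the
  i-th base-pair distance, integrated with the underdamped BAOAB scheme.
  With friction and temperature set to zero BAOAB reduces to velocity
  Verlet, which the energy-conservation test exploits.

One-sided harmonic restraints just outside the sampled range [4, 9] angstrom
keep the coordinates near the grid; their energy is excluded from reported U.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .system import (
    DynamicsSpec,
    SystemSpec,
    potential_energy,
    potential_gradient,
)
from . import _kernels

#: Particle labels: codon positions 1-3, then anticodon positions 1-3.
BEAD_NAMES = ["cod1", "cod2", "cod3", "ant1", "ant2", "ant3"]

#: Helical rise used to embed direct-CV states as 3D bead coordinates (a
#: visualization convention, roughly one base-pair step of an RNA duplex).
EMBED_RISE = 3.4


def _embed_cv_coords(cv: np.ndarray) -> np.ndarray:
    """Embed CV triples (n, 3) as bead coordinates (n, 6, 3).

    Codon bead i sits on the z axis at height ``EMBED_RISE * i``; the paired
    anticodon bead sits at distance ``d_i`` along x, so the recomputed pair
    distances equal the CVs exactly.
    """
    cv = np.atleast_2d(np.asarray(cv, dtype=float))
    n = cv.shape[0]
    coords = np.zeros((n, 6, 3))
    for i in range(3):
        coords[:, i, 2] = EMBED_RISE * i
        coords[:, i + 3, 2] = EMBED_RISE * i
        coords[:, i + 3, 0] = cv[:, i]
    return coords


@dataclass(frozen=True)
class Snapshot:
    """One trajectory frame: particle coordinates plus instantaneous CVs."""

    step: int
    coords: np.ndarray  # (n_particles, 3), angstrom
    cv: np.ndarray  # (3,)
    names: tuple = tuple(BEAD_NAMES)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        cv = np.asarray(self.cv, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "cv", cv)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_particles, 3)")
        if cv.shape != (3,):
            raise ValueError("cv must have three components")
        if coords.shape[0] == 6:
            d = np.linalg.norm(coords[:3] - coords[3:], axis=1)
            if np.max(np.abs(d - cv)) > 1e-9:
                raise ValueError(
                    "snapshot CV values disagree with recomputed pair distances: "
                    f"{cv} vs {d}"
                )


@dataclass
class Trajectory:
    """Time-ordered frames with per-frame CV values and potential energy."""

    steps: np.ndarray  # (n_frames,)
    coords: np.ndarray  # (n_frames, n_particles, 3)
    cv: np.ndarray  # (n_frames, 3)
    energy: np.ndarray  # (n_frames,) potential, kJ/mol
    names: list = field(default_factory=lambda: list(BEAD_NAMES))
    kinetic: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.steps)

    def snapshot(self, i: int) -> Snapshot:
        return Snapshot(step=int(self.steps[i]), coords=self.coords[i],
                        cv=self.cv[i], names=tuple(self.names))

    def __iter__(self):
        return (self.snapshot(i) for i in range(len(self)))

    @classmethod
    def concatenate(cls, parts: Sequence["Trajectory"]) -> "Trajectory":
        if not parts:
            raise ValueError("no trajectories to concatenate")
        first = parts[0]
        if any(p.names != first.names for p in parts):
            raise ValueError("trajectories have mismatched particle names")
        kin = None
        if all(p.kinetic is not None for p in parts):
            kin = np.concatenate([p.kinetic for p in parts])
        return cls(
            steps=np.concatenate([p.steps for p in parts]),
            coords=np.concatenate([p.coords for p in parts]),
            cv=np.concatenate([p.cv for p in parts]),
            energy=np.concatenate([p.energy for p in parts]),
            names=list(first.names),
            kinetic=kin,
            metadata=dict(first.metadata),
        )


BiasFn = Callable[[np.ndarray], np.ndarray]


def run_langevin(
    spec: SystemSpec,
    dyn: DynamicsSpec,
    bias: BiasFn | None = None,
    potential_override: tuple[Callable, Callable] | None = None,
    start: Sequence[float] | None = None,
) -> Trajectory:
    """Simulate the system; returns frames every ``dyn.stride`` steps.

    ``bias`` is an optional callback mapping the CV triple to a
    three-component external force (kJ/mol/angstrom) along the CVs.
    ``potential_override`` is an optional ``(energy_fn, gradient_fn)`` pair on
    the CVs replacing the system potential (used by calibration tests).
    Identical spec + dyn (seed included) give a bit-identical trajectory.
    """
    if spec.tier == "direct-cv":
        if bias is None and potential_override is None:
            return _run_direct_fast(spec, dyn, start)
        return _run_direct_python(spec, dyn, bias, potential_override, start)
    return _run_beads(spec, dyn, bias, potential_override, start)


def _boundary_force(d: np.ndarray, dyn: DynamicsSpec) -> np.ndarray:
    f = np.zeros(3)
    lo, hi, k = dyn.range_low, dyn.range_high, dyn.boundary_stiffness
    below = d < lo
    above = d > hi
    f[below] = 2.0 * k * (lo - d[below])
    f[above] = -2.0 * k * (d[above] - hi)
    return f


def _metadata(spec: SystemSpec, dyn: DynamicsSpec, biased: bool) -> dict:
    return {"seed": dyn.seed, "spec_hash": spec.spec_hash(), "tier": spec.tier,
            "preset": spec.name, "biased": biased}


def _run_direct_fast(spec: SystemSpec, dyn: DynamicsSpec, start) -> Trajectory:
    pars = spec.potential.as_arrays()
    rng = np.random.default_rng(dyn.seed)
    pos = np.array(start if start is not None else spec.potential.d0, dtype=float)
    prev_noise = rng.standard_normal(3)
    kt = spec.kt
    mob = dyn.timestep / dyn.friction
    noise_scale = np.sqrt(2.0 * kt * mob)
    n_frames = (dyn.n_steps + dyn.stride - 1) // dyn.stride
    cv_out = np.empty((n_frames, 5))
    counts = np.zeros((1, 1, 1), dtype=np.int64)
    force_sum = np.zeros((1, 1, 1, 3))
    discard = np.zeros(1, dtype=np.int64)
    chunk = 200_000
    done = 0
    while done < dyn.n_steps:
        m = min(chunk, dyn.n_steps - done)
        noise = rng.standard_normal((m, 3))
        bad = _kernels.abf_chunk(
            pos, noise,
            pars["eps"], pars["a"], pars["d0"], pars["j12"], pars["j23"],
            pars["sigma"], pars["kappa"], pars["dw"],
            pars["wall_on"].astype(np.uint8),
            np.uint8(spec.jacobian), kt, mob, noise_scale,
            dyn.range_low, dyn.range_high, dyn.boundary_stiffness,
            dyn.range_low, dyn.range_high - dyn.range_low, 1,
            counts, force_sum, np.uint8(0), np.uint8(0),
            1, cv_out, dyn.stride, done, discard, prev_noise,
        )
        if bad >= 0:
            raise FloatingPointError(f"dynamics diverged at step {bad}")
        done += m
    return Trajectory(
        steps=cv_out[:, 0].astype(int),
        coords=_embed_cv_coords(cv_out[:, 1:4]),
        cv=cv_out[:, 1:4].copy(),
        energy=cv_out[:, 4].copy(),
        names=list(BEAD_NAMES),
        metadata=_metadata(spec, dyn, biased=False),
    )


def _run_direct_python(spec, dyn, bias, potential_override, start) -> Trajectory:
    rng = np.random.default_rng(dyn.seed)
    pos = np.array(start if start is not None else spec.potential.d0, dtype=float)
    kt = spec.kt
    mob = dyn.timestep / dyn.friction
    noise_scale = np.sqrt(2.0 * kt * mob)
    if potential_override is not None:
        energy_fn, grad_fn = potential_override
    else:
        energy_fn = lambda d: potential_energy(spec, d)
        grad_fn = lambda d: potential_gradient(spec, d)
    frames = []
    prev_noise = rng.standard_normal(3)
    for step in range(dyn.n_steps):
        if step % dyn.stride == 0:
            frames.append((step, pos.copy(), energy_fn(pos)))
        f = -np.asarray(grad_fn(pos), dtype=float)
        if spec.jacobian:
            f += 2.0 * kt / pos
        f += _boundary_force(pos, dyn)
        if bias is not None:
            f += np.asarray(bias(pos), dtype=float)
        noise = rng.standard_normal(3)
        pos = pos + mob * f + 0.5 * noise_scale * (prev_noise + noise)
        prev_noise = noise
        if not np.all(np.isfinite(pos)):
            raise FloatingPointError(f"dynamics diverged at step {step}")
    steps = np.array([s for s, _, _ in frames])
    cv = np.array([p for _, p, _ in frames])
    energy = np.array([u for _, _, u in frames])
    return Trajectory(
        steps=steps, coords=_embed_cv_coords(cv), cv=cv, energy=energy,
        names=list(BEAD_NAMES), metadata=_metadata(spec, dyn, biased=bias is not None),
    )


def _pair_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sep = coords[:3] - coords[3:]
    d = np.linalg.norm(sep, axis=1)
    unit = sep / d[:, None]
    return d, unit


def _bead_forces(d, unit, grad_fn, dyn, bias) -> np.ndarray:
    fd = -np.asarray(grad_fn(d), dtype=float)
    fd += _boundary_force(d, dyn)
    if bias is not None:
        fd += np.asarray(bias(d), dtype=float)
    forces = np.zeros((6, 3))
    for i in range(3):
        forces[i] = fd[i] * unit[i]
        forces[i + 3] = -fd[i] * unit[i]
    return forces


def _run_beads(spec, dyn, bias, potential_override, start) -> Trajectory:
    rng = np.random.default_rng(dyn.seed)
    if potential_override is not None:
        energy_fn, grad_fn = potential_override
    else:
        energy_fn = lambda d: potential_energy(spec, d)
        grad_fn = lambda d: potential_gradient(spec, d)
    kt = spec.kt
    dt, gamma, m = dyn.timestep, dyn.friction, dyn.mass
    if start is not None:
        coords = np.array(start, dtype=float).reshape(6, 3)
    else:
        coords = _embed_cv_coords(np.asarray(spec.potential.d0))[0].copy()
    vel = rng.standard_normal((6, 3)) * np.sqrt(kt / m)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(kt / m * (1.0 - c1 * c1), 0.0))
    d, unit = _pair_geometry(coords)
    forces = _bead_forces(d, unit, grad_fn, dyn, bias)
    frames = []
    for step in range(dyn.n_steps):
        if step % dyn.stride == 0:
            ke = 0.5 * m * float(np.sum(vel**2))
            frames.append((step, coords.copy(), d.copy(), energy_fn(d), ke))
        vel = vel + 0.5 * dt * forces / m
        coords = coords + 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.standard_normal((6, 3))
        coords = coords + 0.5 * dt * vel
        d, unit = _pair_geometry(coords)
        forces = _bead_forces(d, unit, grad_fn, dyn, bias)
        vel = vel + 0.5 * dt * forces / m
        if not np.all(np.isfinite(coords)):
            raise FloatingPointError(f"dynamics diverged at step {step}")
    return Trajectory(
        steps=np.array([f[0] for f in frames]),
        coords=np.array([f[1] for f in frames]),
        cv=np.array([f[2] for f in frames]),
        energy=np.array([f[3] for f in frames]),
        names=list(BEAD_NAMES),
        kinetic=np.array([f[4] for f in frames]),
        metadata=_metadata(spec, dyn, biased=bias is not None),
    )
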