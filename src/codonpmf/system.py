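"""Coarse-grained triplet base-pairing system: potentials, codon presets, specs.

The model resolves one codon:anticodon triplet by its three base-pair
distances d1, d2, d3 (angstrom).  The energy (kJ/mol) is

    U(d1, d2, d3) = sum_i well_i(d_i) + stack(d1, d2) + stack(d2, d3) + wall(d)

with

* ``well_i``   — a Morse well ``eps_i * ((1 - exp(-a_i (d - d0_i)))^2 - 1)``,
  minimum ``-eps_i`` at ``d0_i``, approaching zero at large separation.  The
  depth encodes how well the codon base at that position pairs with the
  initiator-tRNA anticodon base (Watson-Crick match deep, mismatch shallow).
* ``stack``    — a negative bivariate Gaussian on adjacent base-pair distances,
  ``-J * exp(-((d_i - d0_i)^2 + (d_j - d0_j)^2) / (2 sigma^2))``, rewarding
  simultaneous closure of neighbouring pairs.  Pseudouridine (psi) at the
  second codon position raises ``J12`` and ``J23`` (its A:psi pair stacks more
  strongly than A:U).
* ``wall``     — a one-sided harmonic ``kappa * (d_w - d_i)^2`` for
  ``d_i < d_w`` on wall-enabled positions (position 1 in the shipped presets),
  standing in for the steric discrimination by the eIF1 beta-hairpin residue
  N34 against bulky or methylated first codon bases.  "_noeIF1" preset
  variants set ``kappa = 0``.

Energies are kJ/mol, distances angstrom, kB = 0.0083145 kJ/mol/K so that
kB*T at the default 310 K is about 2.577 kJ/mol.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083145

_Triple = tuple[float, float, float]


@dataclass(frozen=True)
class PotentialSpec:
    """Parameters of the triplet pairing potential.

    Attributes
    ----------
    epsilon : tuple of float
        Per-position Morse well depths (kJ/mol), >= 0.
    steepness : tuple of float
        Per-position Morse steepness a_i (1/angstrom), > 0.
    d0 : tuple of float
        Per-position equilibrium pairing distances (angstrom), in (4, 9).
    j12, j23 : float
        Stacking coupling strengths between adjacent pairs (kJ/mol).
    sigma : float
        Stacking Gaussian width (angstrom), > 0.
    kappa : float
        Steric-wall stiffness (kJ/mol/angstrom^2), >= 0.
    wall_onset : float
        Wall onset distance d_w (angstrom); the wall acts where d < d_w.
    wall_enabled : tuple of bool
        Which positions carry the steric wall (shipped presets: position 1).
    """

    epsilon: _Triple
    steepness: _Triple = (1.1, 1.1, 1.1)
    d0: _Triple = (5.0, 5.0, 5.0)
    j12: float = 4.0
    j23: float = 4.0
    sigma: float = 0.8
    kappa: float = 0.0
    wall_onset: float = 5.4
    wall_enabled: tuple[bool, bool, bool] = (True, False, False)

    def __post_init__(self) -> None:
        eps = tuple(float(x) for x in self.epsilon)
        a = tuple(float(x) for x in self.steepness)
        d0 = tuple(float(x) for x in self.d0)
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "steepness", a)
        object.__setattr__(self, "d0", d0)
        object.__setattr__(self, "wall_enabled", tuple(bool(x) for x in self.wall_enabled))
        if len(eps) != 3 or len(a) != 3 or len(d0) != 3 or len(self.wall_enabled) != 3:
            raise ValueError("per-position parameters must have length 3")
        if any(e < 0 for e in eps):
            raise ValueError("well depths epsilon must be >= 0")
        if any(x <= 0 for x in a):
            raise ValueError("well steepness must be > 0")
        if any(not (4.0 < x < 9.0) for x in d0):
            raise ValueError("equilibrium distances d0 must lie in (4.0, 9.0)")
        if self.sigma <= 0:
            raise ValueError("stacking width sigma must be > 0")
        if self.kappa < 0:
            raise ValueError("wall stiffness kappa must be >= 0")

    def as_arrays(self) -> dict[str, np.ndarray | float]:
        """Plain-array view consumed by the numeric kernels."""
        return {
            "eps": np.asarray(self.epsilon, dtype=np.float64),
            "a": np.asarray(self.steepness, dtype=np.float64),
            "d0": np.asarray(self.d0, dtype=np.float64),
            "j12": float(self.j12),
            "j23": float(self.j23),
            "sigma": float(self.sigma),
            "kappa": float(self.kappa),
            "dw": float(self.wall_onset),
            "wall_on": np.asarray(self.wall_enabled, dtype=np.bool_),
        }


@dataclass(frozen=True)
class SystemSpec:
    """A simulatable system: potential + thermodynamic settings.

    ``tier`` selects the representation: ``"direct-cv"`` runs overdamped
    Langevin dynamics directly on (d1, d2, d3) (exact Boltzmann oracle
    available); ``"cartesian-beads"`` simulates six beads in 3D, one bead pair
    per collective variable, with an underdamped BAOAB integrator.

    ``jacobian`` applies the d^2 density-of-states weighting of a radial
    distance coordinate.  Off by default in the direct-CV tier (the PMF then
    equals U exactly); turn it on to emulate radial-distance statistics.
    """

    potential: PotentialSpec
    tier: str = "direct-cv"
    temperature: float = 310.0
    kb: float = KB
    jacobian: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.tier not in ("direct-cv", "cartesian-beads"):
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kt(self) -> float:
        """Thermal energy kB*T in kJ/mol."""
        return self.kb * self.temperature

    def spec_hash(self) -> str:
        """Short stable hash of the full parameterization (for manifests)."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class DynamicsSpec:
    """Langevin integration settings (reduced time units).

    ``boundary_stiffness`` is the one-sided harmonic restraint applied outside
    the sampled range [4.0, 9.0] angstrom on each coordinate; its energy is
    excluded from reported U.  The default timestep (with the default
    friction, a mobility of 1e-3) balances sampling efficiency against
    integrator bias for the shipped presets under the averaged-noise
    overdamped scheme.
    """

    timestep: float = 2e-3
    friction: float = 2.0
    mass: float = 1.0
    n_steps: int = 100_000
    seed: int = 0
    boundary_stiffness: float = 400.0
    stride: int = 100
    range_low: float = 4.0
    range_high: float = 9.0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


# ---------------------------------------------------------------------------
# Potential evaluation (reference numpy implementation; the hot Langevin/ABF
# loop uses the numba twin in _kernels.py, which is tested against this one).
# ---------------------------------------------------------------------------

def _check_cv(cv: Sequence[float]) -> np.ndarray:
    d = np.asarray(cv, dtype=np.float64)
    if d.shape != (3,):
        raise ValueError("cv must be three distances")
    if not np.all(np.isfinite(d)):
        raise ValueError(f"non-finite cv {d}")
    if np.any(d <= 0):
        raise ValueError(f"cv distances must be positive, got {d}")
    return d


def potential_energy(spec: SystemSpec | PotentialSpec, cv: Sequence[float]) -> float:
    """Energy U(d1, d2, d3) in kJ/mol (boundary restraints excluded)."""
    pot = spec.potential if isinstance(spec, SystemSpec) else spec
    d = _check_cv(cv)
    eps = np.asarray(pot.epsilon)
    a = np.asarray(pot.steepness)
    d0 = np.asarray(pot.d0)
    e = np.exp(-a * (d - d0))
    u = float(np.sum(eps * ((1.0 - e) ** 2 - 1.0)))
    s2 = 2.0 * pot.sigma**2
    x = d - d0
    u -= pot.j12 * math.exp(-(x[0] ** 2 + x[1] ** 2) / s2)
    u -= pot.j23 * math.exp(-(x[1] ** 2 + x[2] ** 2) / s2)
    for i in range(3):
        if pot.wall_enabled[i] and d[i] < pot.wall_onset:
            u += pot.kappa * (pot.wall_onset - d[i]) ** 2
    return u


def potential_gradient(spec: SystemSpec | PotentialSpec, cv: Sequence[float]) -> np.ndarray:
    """Analytic gradient (dU/dd1, dU/dd2, dU/dd3) in kJ/mol/angstrom."""
    pot = spec.potential if isinstance(spec, SystemSpec) else spec
    d = _check_cv(cv)
    eps = np.asarray(pot.epsilon)
    a = np.asarray(pot.steepness)
    d0 = np.asarray(pot.d0)
    e = np.exp(-a * (d - d0))
    g = 2.0 * eps * (1.0 - e) * a * e
    sig2 = pot.sigma**2
    x = d - d0
    e12 = math.exp(-(x[0] ** 2 + x[1] ** 2) / (2.0 * sig2))
    e23 = math.exp(-(x[1] ** 2 + x[2] ** 2) / (2.0 * sig2))
    g[0] += pot.j12 * e12 * x[0] / sig2
    g[1] += pot.j12 * e12 * x[1] / sig2
    g[1] += pot.j23 * e23 * x[1] / sig2
    g[2] += pot.j23 * e23 * x[2] / sig2
    for i in range(3):
        if pot.wall_enabled[i] and d[i] < pot.wall_onset:
            g[i] += -2.0 * pot.kappa * (pot.wall_onset - d[i])
    return g


# ---------------------------------------------------------------------------
# Codon presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonPreset:
    """A named codon parameterization (name + potential)."""

    name: str
    potential: PotentialSpec


# First codon base pairs the anticodon 3'-terminal U, second base pairs A,
# third base pairs C.  Depths (kJ/mol): cognate pairs are deep; a first-base
# mismatch is shallow, graded C > G > U by how close the geometry can get to a
# paired arrangement; second/third mismatches for ACG/AUU are shallow too.
# The scale keeps per-bin energy variation at a few kT so the 0.5-angstrom
# binning resolves the landscape.
_DEPTH1 = {"A": 10.0, "C": 5.0, "G": 4.2, "U": 4.0, "mC": 5.0}
_DEPTH2 = {"U": 10.0, "Ψ": 10.0, "C": 4.0}
_DEPTH3 = {"G": 10.0, "U": 3.8}

# eIF1 present: an A first base is stabilized (bonus depth); non-A first bases
# meet the N34 steric wall, stiffness graded by base bulk, 5mC bulkiest.
_EIF1_BONUS_A = 2.5
_WALL_KAPPA = {"A": 0.0, "C": 3.0, "G": 6.0, "U": 6.0, "mC": 12.0}

_J_PLAIN = 4.0
_J_PSI = 7.0  # psi:A stacks more strongly than U:A

_CODONS: dict[str, tuple[str, str, str]] = {
    "AUG": ("A", "U", "G"),
    "CUG": ("C", "U", "G"),
    "GUG": ("G", "U", "G"),
    "UUG": ("U", "U", "G"),
    "ACG": ("A", "C", "G"),
    "AUU": ("A", "U", "U"),
    "CΨG": ("C", "Ψ", "G"),
    "GΨG": ("G", "Ψ", "G"),
    "mCUG": ("mC", "U", "G"),
}

_ALIASES = {"CpsiG": "CΨG", "GpsiG": "GΨG", "CpsiG_noeIF1": "CΨG_noeIF1",
            "GpsiG_noeIF1": "GΨG_noeIF1"}

# Diagnostic (non-codon) systems: "flat" (U = 0, the analytic null) and
# "smooth" (shallow wide wells, gentle enough that bin-center values resolve
# the landscape) used to validate the estimators.
_VALIDATION = {"flat", "smooth"}


def _build_potential(bases: tuple[str, str, str], eif1: bool) -> PotentialSpec:
    b1, b2, b3 = bases
    eps1 = _DEPTH1[b1] + (_EIF1_BONUS_A if (eif1 and b1 == "A") else 0.0)
    j = _J_PSI if b2 == "Ψ" else _J_PLAIN
    kappa = _WALL_KAPPA[b1] if eif1 else 0.0
    return PotentialSpec(
        epsilon=(eps1, _DEPTH2[b2], _DEPTH3[b3]),
        j12=j,
        j23=j,
        kappa=kappa,
        wall_enabled=(True, False, False),
    )


def list_presets() -> list[str]:
    """Names of all shipped presets (each codon plus its "_noeIF1" variant)."""
    names = list(_CODONS)
    names += [f"{n}_noeIF1" for n in _CODONS]
    return names


def load_preset(
    name: str,
    overrides: Mapping[str, object] | None = None,
    temperature: float = 310.0,
    tier: str = "direct-cv",
    jacobian: bool = False,
) -> SystemSpec:
    """Build the SystemSpec for a named codon preset.

    ``name`` is a codon (e.g. ``"AUG"``, ``"CΨG"``, ``"mCUG"``) or its
    ``"_noeIF1"`` variant (eIF1/eIF1A removed: steric wall off, no first-base
    stabilization).  ASCII aliases ``CpsiG``/``GpsiG`` are accepted.
    ``overrides`` replaces individual :class:`PotentialSpec` fields.
    """
    name = _ALIASES.get(name, name)
    eif1 = True
    base = name
    if name.endswith("_noeIF1"):
        eif1 = False
        base = name[: -len("_noeIF1")]
    if base not in _CODONS and base not in _VALIDATION:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(list_presets())} "
            f"(plus diagnostic systems: {', '.join(sorted(_VALIDATION))})"
        )
    if base == "flat":
        pot = PotentialSpec(epsilon=(0.0, 0.0, 0.0), j12=0.0, j23=0.0, kappa=0.0)
    elif base == "smooth":
        pot = PotentialSpec(epsilon=(3.0, 3.0, 3.0), steepness=(0.6, 0.6, 0.6),
                            d0=(6.0, 6.0, 6.0), j12=2.0, j23=2.0, sigma=1.2,
                            kappa=0.0)
    else:
        pot = _build_potential(_CODONS[base], eif1)
    if overrides:
        valid = {f.name for f in dataclasses.fields(PotentialSpec)}
        bad = set(overrides) - valid
        if bad:
            raise KeyError(f"unknown potential override(s) {sorted(bad)}; valid: {sorted(valid)}")
        pot = dataclasses.replace(pot, **dict(overrides))
    return SystemSpec(potential=pot, tier=tier, temperature=temperature,
                      jacobian=jacobian, name=name)
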