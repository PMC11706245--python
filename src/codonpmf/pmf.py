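"""Probability -> free-energy pipeline over the CV grid.

Implements the estimator chain used to score codon:anticodon pairing:
normalized P(d1, d2, d3); G = -kB*T ln P + const; 2D reductions by
marginalization; region free energies with the bound window
4.0 <= d_i <= 6.0 and unbound window 7.0 <= d_i <= 9.0 (all three
coordinates simultaneously; the 6-7 angstrom shell belongs to neither);
Delta_G_binding = G_bound - G_unbound; pairing penalties
DeltaDelta_G = Delta_G - Delta_G(AUG); the convergence statistic
L(tau1, tau2) = sum_b (P(b; tau1) - P(b; tau2))^2; and five-trial averaging
of P before any downstream free energy is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.sparse
import scipy.sparse.linalg

from .abf import ABFState, GridSpec, mean_force_grid
from .system import SystemSpec

#: Sentinel carried in FreeEnergyGrid.values at masked (never-visited) bins.
MASK_SENTINEL = np.nan

BOUND_WINDOW = ((4.0, 6.0), (4.0, 6.0), (4.0, 6.0))
UNBOUND_WINDOW = ((7.0, 9.0), (7.0, 9.0), (7.0, 9.0))


@dataclass(frozen=True)
class ProbabilityGrid:
    """Normalized probability over the 3D CV grid."""

    grid: GridSpec
    p: np.ndarray
    provenance: str = "histogram"
    checkpoint_step: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != self.grid.shape:
            raise ValueError(f"p shape {p.shape} does not match grid {self.grid.shape}")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        total = p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {total:.12f})")


@dataclass(frozen=True)
class FreeEnergyGrid:
    """G over the grid, min-shifted to zero; masked bins carry NaN."""

    grid: GridSpec
    values: np.ndarray  # kJ/mol; NaN where masked
    occupied: np.ndarray  # bool, True where G is defined
    kt: float

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape or self.occupied.shape != self.grid.shape:
            raise ValueError("grid shape mismatch")
        if self.occupied.any():
            lo = np.nanmin(self.values[self.occupied])
            if abs(lo) > 1e-9:
                raise ValueError("free energy must be min-shifted to zero")


@dataclass(frozen=True)
class BindingResult:
    """Bound/unbound region free energies and their difference."""

    g_bound: float
    g_unbound: float
    delta_g: float
    grid: GridSpec
    kt: float
    bound_window: tuple = BOUND_WINDOW
    unbound_window: tuple = UNBOUND_WINDOW
    n_trials: int = 1
    name: str = ""


@dataclass(frozen=True)
class ConvergenceRecord:
    """Squared-probability-error statistic between two checkpoints."""

    tau1: float
    tau2: float
    l_value: float


@dataclass(frozen=True)
class Reduced2D:
    """A 2D free-energy surface G(d_i, d_j) from marginalized probability."""

    grid: GridSpec
    axes: tuple[int, int]  # 1-based kept coordinates
    g: np.ndarray  # (n, n), NaN at zero-probability bins
    p: np.ndarray  # marginal probability


# ---------------------------------------------------------------------------
# Gradient integration (shared by the mean-force route and bias unweighting)
# ---------------------------------------------------------------------------

def _integrate_gradient(grid: GridSpec, vec_field: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Solve grad(A) = vec_field on the masked grid, least squares.

    ``vec_field`` is (n, n, n, 3); the finite-difference gradient between
    adjacent occupied bins (spacing = bin width) is matched to the midpoint
    average of the field.  Raises on a disconnected mask.
    """
    lbl, ncomp = scipy.ndimage.label(mask)
    if ncomp == 0:
        raise ValueError("mask is empty; nothing to integrate")
    if ncomp > 1:
        sizes = scipy.ndimage.sum_labels(np.ones_like(lbl), lbl, index=range(1, ncomp + 1))
        raise ValueError(
            f"occupancy mask is disconnected: {ncomp} components with sizes "
            f"{[int(s) for s in sizes]}"
        )
    idx = -np.ones(grid.shape, dtype=int)
    occ = np.argwhere(mask)
    idx[tuple(occ.T)] = np.arange(len(occ))
    rows, cols, data, rhs = [], [], [], []
    w = grid.width
    eq = 0
    for axis in range(3):
        shift = np.zeros(3, dtype=int)
        shift[axis] = 1
        for b in occ:
            nb = b + shift
            if np.any(nb >= grid.nbins):
                continue
            j = idx[tuple(nb)]
            if j < 0:
                continue
            i = idx[tuple(b)]
            rows += [eq, eq]
            cols += [j, i]
            data += [1.0, -1.0]
            rhs.append(w * 0.5 * (vec_field[tuple(b)][axis] + vec_field[tuple(nb)][axis]))
            eq += 1
    # anchor the undetermined constant
    rows.append(eq)
    cols.append(0)
    data.append(1.0)
    rhs.append(0.0)
    eq += 1
    mat = scipy.sparse.csr_matrix((data, (rows, cols)), shape=(eq, len(occ)))
    sol = scipy.sparse.linalg.lsqr(mat, np.asarray(rhs), atol=1e-12, btol=1e-12,
                                   iter_lim=20000)[0]
    out = np.full(grid.shape, MASK_SENTINEL)
    out[tuple(occ.T)] = sol
    return out


# ---------------------------------------------------------------------------
# Probability estimation
# ---------------------------------------------------------------------------

def probability_from_state(
    state: ABFState, spec: SystemSpec, checkpoint_step: int | None = None
) -> ProbabilityGrid:
    """Reconstruct the unbiased P from the sampler state.

    For a biased run, each bin's visit count is reweighted by
    ``exp(-A_bias(b) / kT)`` where ``A_bias`` integrates the applied bias
    force field (at its final ramp level) over the grid; for an unbiased run
    the result is exactly the raw normalized histogram.
    """
    total = int(state.counts.sum())
    if total == 0:
        raise ValueError("sampler state is empty (no in-range samples)")
    counts = state.counts.astype(float)
    if state.bias_applied:
        mask = state.counts > 0
        mf = mean_force_grid(state)
        ramp = np.minimum(1.0, counts / state.n_full)[..., None]
        bias_force = -ramp * mf.filled(0.0)
        a_bias = _integrate_gradient(state.grid, bias_force, mask)
        a_bias = a_bias - np.nanmin(a_bias)
        weight = np.zeros_like(counts)
        weight[mask] = np.exp(-a_bias[mask] / spec.kt)
        p = counts * weight
        provenance = "histogram-reweighted"
    else:
        p = counts
        provenance = "histogram"
    p = p / p.sum()
    if checkpoint_step is not None:
        provenance = f"checkpoint@{checkpoint_step}"
    return ProbabilityGrid(grid=state.grid, p=p, provenance=provenance,
                           checkpoint_step=checkpoint_step)


def free_energy_from_probability(P: ProbabilityGrid, kt: float) -> FreeEnergyGrid:
    """G(b) = -kT ln P(b), min-shifted to zero; zero-probability bins masked."""
    occupied = P.p > 0
    values = np.full(P.grid.shape, MASK_SENTINEL)
    with np.errstate(divide="ignore"):
        values[occupied] = -kt * np.log(P.p[occupied])
    if occupied.any():
        values[occupied] -= values[occupied].min()
    return FreeEnergyGrid(grid=P.grid, values=values, occupied=occupied, kt=kt)


def probability_from_free_energy(G: FreeEnergyGrid) -> ProbabilityGrid:
    """Inverse map P proportional to exp(-G/kT) over occupied bins."""
    p = np.zeros(G.grid.shape)
    p[G.occupied] = np.exp(-G.values[G.occupied] / G.kt)
    p /= p.sum()
    return ProbabilityGrid(grid=G.grid, p=p, provenance="gradient-derived")


def free_energy_from_mean_force(state: ABFState, kt: float) -> FreeEnergyGrid:
    """Integrate the negative mean force into G on the occupied bins.

    Solves for the G whose discrete gradient best matches -<F> over the
    (connected) occupancy mask, then min-shifts to zero.
    """
    mask = state.counts > 0
    mf = mean_force_grid(state)
    values = _integrate_gradient(state.grid, -mf.filled(0.0), mask)
    values[mask] -= values[mask].min()
    return FreeEnergyGrid(grid=state.grid, values=values, occupied=mask, kt=kt)


# ---------------------------------------------------------------------------
# Reductions and region free energies
# ---------------------------------------------------------------------------

_PAIRS = {(1, 2): 2, (1, 3): 1, (2, 3): 0}


def reduce_to_2d(P: ProbabilityGrid, pair: tuple[int, int], kt: float) -> Reduced2D:
    """Marginalize P over the dropped coordinate, then take -kT ln.

    ``pair`` names the kept coordinates, 1-based: (1, 2), (1, 3) or (2, 3).
    The marginal is computed on probabilities (never by averaging G).
    """
    pair = tuple(pair)
    if pair not in _PAIRS:
        raise ValueError(f"pair must be one of {sorted(_PAIRS)}, got {pair}")
    p2 = P.p.sum(axis=_PAIRS[pair])
    g = np.full(p2.shape, MASK_SENTINEL)
    nz = p2 > 0
    with np.errstate(divide="ignore"):
        g[nz] = -kt * np.log(p2[nz])
    if nz.any():
        g[nz] -= g[nz].min()
    return Reduced2D(grid=P.grid, axes=pair, g=g, p=p2)


def _window_bin_slices(grid: GridSpec, window) -> tuple[slice, ...]:
    sl = []
    for dim, (lo, hi) in enumerate(window):
        if not (lo < hi):
            raise ValueError(f"degenerate window on coordinate {dim + 1}: ({lo}, {hi})")
        flo = (lo - grid.lower) / grid.width
        fhi = (hi - grid.lower) / grid.width
        if abs(flo - round(flo)) > 1e-9 or abs(fhi - round(fhi)) > 1e-9:
            raise ValueError(
                f"window ({lo}, {hi}) on coordinate {dim + 1} is not aligned to "
                f"bin edges (grid {grid.lower}..{grid.upper} step {grid.width})"
            )
        i0 = int(round(flo))
        i1 = int(round(fhi))
        i0 = max(i0, 0)
        i1 = min(i1, grid.nbins)
        sl.append(slice(i0, i1))
    return tuple(sl)


def region_free_energy(P: ProbabilityGrid, window, kt: float) -> float:
    """Free energy of a CV region: -kT ln of the region's total probability.

    ``window`` is one (lo, hi) interval per coordinate, aligned to bin edges;
    only bins fully inside all three intervals contribute.
    """
    total = float(P.p[_window_bin_slices(P.grid, window)].sum())
    if total <= 0.0:
        raise ValueError(f"window {window} captures zero probability")
    return float(-kt * np.log(total))


def binding_free_energy(
    P: ProbabilityGrid,
    kt: float,
    n_trials: int = 1,
    name: str = "",
) -> BindingResult:
    """Delta_G_binding = G_bound - G_unbound with the standard windows."""
    gb = region_free_energy(P, BOUND_WINDOW, kt)
    gu = region_free_energy(P, UNBOUND_WINDOW, kt)
    return BindingResult(g_bound=gb, g_unbound=gu, delta_g=gb - gu,
                         grid=P.grid, kt=kt, n_trials=n_trials, name=name)


def pairing_penalty(result, reference) -> float:
    """DeltaDelta_G = Delta_G - Delta_G(reference); positive = weaker pairing.

    When both arguments are :class:`BindingResult`, the grids, windows, kT
    and trial counts must match; plain floats are subtracted directly.
    """
    if isinstance(result, BindingResult) and isinstance(reference, BindingResult):
        for attr in ("grid", "bound_window", "unbound_window", "kt", "n_trials"):
            a, b = getattr(result, attr), getattr(reference, attr)
            if a != b:
                raise ValueError(
                    f"mismatched {attr} between result ({a}) and reference ({b})"
                )
        return result.delta_g - reference.delta_g
    return float(result) - float(reference)


# ---------------------------------------------------------------------------
# Convergence and trial averaging
# ---------------------------------------------------------------------------

def convergence_error(P1: ProbabilityGrid, P2: ProbabilityGrid) -> ConvergenceRecord:
    """L(tau1, tau2) = sum over all bins of (P1 - P2)^2 (symmetric, >= 0)."""
    if P1.grid != P2.grid:
        raise ValueError(f"grid mismatch: {P1.grid} vs {P2.grid}")
    l_value = float(np.sum((P1.p - P2.p) ** 2))
    return ConvergenceRecord(
        tau1=P1.checkpoint_step if P1.checkpoint_step is not None else np.nan,
        tau2=P2.checkpoint_step if P2.checkpoint_step is not None else np.nan,
        l_value=l_value,
    )


def average_trials(grids: list[ProbabilityGrid]) -> ProbabilityGrid:
    """Arithmetic per-bin mean of trial probability grids, renormalized.

    Downstream binding free energies are computed from this averaged P (not
    from averaging per-trial free energies).
    """
    if not grids:
        raise ValueError("need at least one probability grid")
    g0 = grids[0].grid
    if any(P.grid != g0 for P in grids):
        raise ValueError("probability grids use different grids")
    mean = np.mean([P.p for P in grids], axis=0)
    drift = abs(mean.sum() - 1.0)
    if drift > 1e-9:
        warnings.warn(f"trial-average normalization drift {drift:.2e}; renormalizing")
    mean /= mean.sum()
    return ProbabilityGrid(grid=g0, p=mean, provenance=f"trial-average({len(grids)})")
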