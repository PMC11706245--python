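"""File formats: OpenDX volumetric grids, TSV series/tables, extended XYZ, PDB.

Conventions
-----------
* OpenDX grids carry bin-center positions (origin = first bin center,
  delta = bin width).  Masked bins are written as ``nan`` (the documented
  sentinel) and survive a round trip.  Values are written with 17 significant
  digits so a write/read cycle is bitwise lossless.
* CV time series are TSV with header ``step d1 d2 d3 U``.
* Trajectories are extended XYZ; the comment line carries the step index and
  instantaneous CVs (``step=N d1=... d2=... d3=...``).
* Average structures go through PDB (via biotite); coarse-grained beads are
  written as C1' pseudo-atoms of residues 1-3 on chain C (codon) and chain A
  (anticodon), so the C1'-midpoint base-pair-center rule applies uniformly to
  toy and imported structures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from gridData import Grid as _DXGrid

import biotite.structure as bst
import biotite.structure.io.pdb as bst_pdb

from .abf import GridSpec
from .dynamics import Trajectory, BEAD_NAMES
from .structure import AverageStructure, DEFAULT_PAIRS, PitchResult


# ---------------------------------------------------------------------------
# OpenDX
# ---------------------------------------------------------------------------

def write_opendx(path, values: np.ndarray, grid: GridSpec) -> None:
    """Write a (n, n, n) scalar field on the CV grid as OpenDX text."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} does not match grid {grid.shape}")
    n = grid.nbins
    origin = grid.lower + grid.width / 2.0
    with open(path, "w") as fh:
        fh.write("# OpenDX scalar field on the CV grid (bin centers)\n")
        fh.write(f"object 1 class gridpositions counts {n} {n} {n}\n")
        fh.write(f"origin {origin!r} {origin!r} {origin!r}\n")
        fh.write(f"delta {grid.width!r} 0 0\n")
        fh.write(f"delta 0 {grid.width!r} 0\n")
        fh.write(f"delta 0 0 {grid.width!r}\n")
        fh.write(f"object 2 class gridconnections counts {n} {n} {n}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} data follows\n"
        )
        flat = values.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.17g}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_opendx(path) -> tuple[np.ndarray, GridSpec]:
    """Read an OpenDX grid back into (values, GridSpec).

    The grid must be cubic with equal spacing on all axes and commensurate
    with its extent; malformed headers are reported with the offending line.
    """
    _validate_dx_header(path)
    g = _DXGrid(str(path))
    delta = np.diag(np.atleast_2d(g.delta)) if np.ndim(g.delta) > 1 else np.asarray(g.delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError(f"{path}: anisotropic grid spacing {delta} is not supported")
    width = float(delta[0])
    shape = g.grid.shape
    if len(set(shape)) != 1:
        raise ValueError(f"{path}: non-cubic grid {shape} is not supported")
    origin = float(np.asarray(g.origin)[0])
    lower = origin - width / 2.0
    upper = lower + width * shape[0]
    try:
        spec = GridSpec(lower=lower, upper=upper, width=width)
    except ValueError as exc:
        raise ValueError(f"{path}: header grid is not commensurate: {exc}") from exc
    return g.grid.astype(np.float64), spec


def _validate_dx_header(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object"):
                parts = s.split()
                if "gridpositions" in parts and "counts" in parts:
                    counts = parts[parts.index("counts") + 1:]
                    if len(counts) != 3 or not all(c.isdigit() for c in counts):
                        raise ValueError(
                            f"{path}:{lineno}: malformed gridpositions counts: {s!r}"
                        )
                    return
                raise ValueError(
                    f"{path}:{lineno}: expected 'object 1 class gridpositions counts', "
                    f"got {s!r}"
                )
            raise ValueError(f"{path}:{lineno}: unexpected header line {s!r}")
    raise ValueError(f"{path}: no gridpositions header found")


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

CV_COLUMNS = ["step", "d1", "d2", "d3", "U"]


def write_cv_series(path, cv_series: np.ndarray) -> None:
    """Write a CV time series (columns step d1 d2 d3 U) as TSV."""
    df = pd.DataFrame(cv_series, columns=CV_COLUMNS)
    df["step"] = df["step"].astype(np.int64)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cv_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(CV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: CV series is missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Extended XYZ trajectories
# ---------------------------------------------------------------------------

def write_xyz(path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        n_particles = traj.coords.shape[1]
        for i in range(len(traj)):
            fh.write(f"{n_particles}\n")
            d = [float(x) for x in traj.cv[i]]
            fh.write(
                f"step={int(traj.steps[i])} d1={d[0]!r} d2={d[1]!r} d3={d[2]!r}\n"
            )
            for name, xyz in zip(traj.names, traj.coords[i]):
                fh.write(f"{name} {float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}\n")


def read_xyz(path) -> Trajectory:
    steps, coords, cvs, names = [], [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        meta = dict(kv.split("=", 1) for kv in lines[i + 1].split())
        steps.append(int(meta["step"]))
        cvs.append([float(meta["d1"]), float(meta["d2"]), float(meta["d3"])])
        frame = []
        frame_names = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            frame_names.append(parts[0])
            frame.append([float(x) for x in parts[1:4]])
        if names is None:
            names = frame_names
        coords.append(frame)
        i += 2 + n
    steps = np.asarray(steps)
    coords = np.asarray(coords)
    cvs = np.asarray(cvs)
    energy = np.full(len(steps), np.nan)
    return Trajectory(steps=steps, coords=coords, cv=cvs, energy=energy,
                      names=list(names or BEAD_NAMES))


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

_TOY_RES = [("C", 1), ("C", 2), ("C", 3), ("A", 1), ("A", 2), ("A", 3)]


def write_structure_pdb(path, structure: AverageStructure) -> None:
    """Write an average structure as PDB (beads become C1' pseudo-atoms)."""
    n = structure.coords.shape[0]
    atoms = bst.AtomArray(n)
    atoms.coord = np.asarray(structure.coords, dtype=np.float32)
    if n == 6:
        atoms.atom_name = np.array(["C1'"] * 6)
        atoms.chain_id = np.array([c for c, _ in _TOY_RES])
        atoms.res_id = np.array([r for _, r in _TOY_RES])
        atoms.res_name = np.array(["BED"] * 6)
    else:
        atoms.atom_name = np.array([str(x)[:4] for x in structure.names])
        atoms.chain_id = np.array(["X"] * n)
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.array(["UNK"] * n)
    atoms.element = np.array(["C"] * n)
    pdb = bst_pdb.PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_structure_pdb(path) -> AverageStructure:
    """Load a PDB and map it onto the base-pair-center convention.

    Expects C1' atoms on three codon residues (chain C, or the first chain)
    and three anticodon residues (chain A, or the second chain); a missing
    C1' raises an error naming the base-pair position.
    """
    pdb = bst_pdb.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    chains = list(dict.fromkeys(atoms.chain_id))
    if len(chains) < 2:
        raise ValueError(f"{path}: need codon and anticodon chains, found {chains}")
    cod_chain, ant_chain = ("C", "A") if {"C", "A"} <= set(chains) else chains[:2]
    picked = []
    for pos in (1, 2, 3):
        for chain in (cod_chain, ant_chain):
            sel = atoms[(atoms.chain_id == chain) & (atoms.atom_name == "C1'")]
            res_ids = sorted(set(sel.res_id))
            if len(res_ids) < pos:
                raise ValueError(
                    f"{path}: no C1' atom for base-pair position {pos} "
                    f"(chain {chain})"
                )
    cod_sel = atoms[(atoms.chain_id == cod_chain) & (atoms.atom_name == "C1'")]
    ant_sel = atoms[(atoms.chain_id == ant_chain) & (atoms.atom_name == "C1'")]
    coords = np.concatenate([cod_sel.coord[:3], ant_sel.coord[:3]]).astype(float)
    return AverageStructure(
        coords=coords,
        n_snapshots=1,
        names=tuple(BEAD_NAMES),
        coord_std=np.zeros((6, 3)),
        skew_flags=np.zeros(6, dtype=bool),
        pairs=DEFAULT_PAIRS,
    )


def write_pitch_tsv(path, pitch: PitchResult) -> None:
    rows = [{"quantity": "pitch_12", "value": pitch.pitch_12},
            {"quantity": "pitch_23", "value": pitch.pitch_23}]
    for i, c in enumerate(pitch.centers, start=1):
        rows.append({"quantity": f"center_{i}",
                     "value": " ".join(f"{float(x)!r}" for x in c)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
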