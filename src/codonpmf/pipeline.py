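"""End-to-end orchestration: presets -> ABF trials -> free energies -> report.

For every configured preset the pipeline runs the configured number of ABF
trials (trial t uses seed ``master + t``), averages the per-trial probability
grids, and derives the free-energy landscape, its three 2D reductions, the
binding free energy and its penalty against the reference codon (AUG), the
convergence statistic across checkpoints, and the bound-state average
structure with inter-base-pair pitch.

Everything is deterministic for a fixed config: report numerical content
(JSON-lines, TSV, OpenDX) is byte-identical across reruns; wall-clock
timestamps live only in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .abf import GridSpec, run_abf
from .config import RunConfig
from .dynamics import Trajectory
from .fileio import write_cv_series, write_opendx, write_structure_pdb
from .pmf import (
    average_trials,
    binding_free_energy,
    convergence_error,
    free_energy_from_probability,
    pairing_penalty,
    reduce_to_2d,
)
from .structure import (
    WindowSpec,
    average_structure,
    base_pair_centers,
    inter_pair_pitch,
    select_snapshots,
)
from .system import DynamicsSpec, load_preset

logger = logging.getLogger("codonpmf.pipeline")


@dataclass(frozen=True)
class RunManifest:
    """Provenance block embedded next to every pipeline output."""

    config_hash: str
    package_version: str
    presets: tuple[str, ...]
    grid: dict
    seeds: dict
    steps: int
    trials: int
    checkpoints: tuple[float, ...]
    created: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_manifest(config: RunConfig) -> RunManifest:
    return RunManifest(
        config_hash=_config_hash(config),
        package_version=__version__,
        presets=tuple(config.presets),
        grid=dict(config.grid),
        seeds={p: [config.seed + t for t in range(config.trials)]
               for p in config.presets},
        steps=config.steps,
        trials=config.trials,
        checkpoints=tuple(config.checkpoints),
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )


def _run_preset(name: str, config: RunConfig, grid: GridSpec):
    spec = load_preset(
        name,
        overrides=config.preset_overrides.get(name),
        temperature=config.temperature,
        jacobian=config.jacobian,
    )
    dyn_kwargs = dict(config.dynamics)
    abf_kwargs = dict(config.abf)
    trials = []
    for t in range(config.trials):
        dyn = DynamicsSpec(n_steps=config.steps, seed=config.seed + t, **dyn_kwargs)
        run = run_abf(
            spec, dyn, grid,
            n_full=int(abf_kwargs.get("n_full", 200)),
            burn_in_fraction=float(abf_kwargs.get("burn_in_fraction", 0.05)),
            checkpoint_fractions=config.checkpoints if t == 0 else (),
        )
        logger.info(
            "stage=abf preset=%s trial=%d seed=%d steps=%d samples=%d discarded=%d",
            name, t, dyn.seed, config.steps, int(run.state.counts.sum()),
            run.state.discarded,
        )
        trials.append(run)
    return spec, trials


def _preset_report(name: str, spec, trials, config: RunConfig, reference=None):
    from .pmf import probability_from_state

    kt = spec.kt
    p_trials = [probability_from_state(r.state, spec) for r in trials]
    p_avg = average_trials(p_trials)
    g = free_energy_from_probability(p_avg, kt)
    reductions = {pair: reduce_to_2d(p_avg, pair, kt) for pair in ((1, 2), (1, 3), (2, 3))}
    binding = binding_free_energy(p_avg, kt, n_trials=len(trials), name=name)
    per_trial_dg = [binding_free_energy(P, kt, name=name).delta_g for P in p_trials]

    records = []
    checkpoints = trials[0].checkpoints
    if checkpoints:
        final = checkpoints[-1][1]
        for step, P in checkpoints:
            rec = convergence_error(P, final)
            records.append((step, rec.l_value))
            logger.info("stage=converge preset=%s tau=%d L_vs_final=%.3e",
                        name, step, rec.l_value)

    window = WindowSpec(center=tuple(config.window.get("center", (4.5, 4.5, 4.5))),
                        half_width=config.window.get("half_width", 0.25))
    traj = Trajectory.concatenate([r.trajectory for r in trials])
    snaps = select_snapshots(traj, window)
    avg = average_structure(snaps, window=window)
    pitch = inter_pair_pitch(base_pair_centers(avg))
    logger.info("stage=structure preset=%s window_snapshots=%d pitch12=%.3f pitch23=%.3f",
                name, avg.n_snapshots, pitch.pitch_12, pitch.pitch_23)

    report = {
        "preset": name,
        "n_trials": len(trials),
        "single_trial": len(trials) == 1,
        "delta_g": binding.delta_g,
        "g_bound": binding.g_bound,
        "g_unbound": binding.g_unbound,
        "delta_g_per_trial": per_trial_dg,
        "ddg": None if reference is None else pairing_penalty(binding, reference),
        "convergence": [{"tau": s, "L_vs_final": l} for s, l in records],
        "pitch_12": pitch.pitch_12,
        "pitch_23": pitch.pitch_23,
        "window_snapshots": avg.n_snapshots,
        "skewed_particles": int(avg.skew_flags.sum()),
        "discarded_samples": int(sum(r.state.discarded for r in trials)),
    }
    artifacts = {"p_avg": p_avg, "g": g, "reductions": reductions,
                 "binding": binding, "structure": avg, "trials": trials}
    return report, artifacts


def pipeline_run(config: RunConfig, out_dir=None, dry_run: bool = False) -> dict:
    """Run the full analysis for every configured preset.

    Returns ``{"manifest": ..., "reports": [...]}``; when ``out_dir`` is
    given, also writes report.jsonl, summary.tsv, per-preset OpenDX grids,
    CV series and average-structure PDBs there.
    """
    manifest = make_manifest(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
    if dry_run:
        logger.info("stage=dry-run config_hash=%s presets=%s",
                    manifest.config_hash, ",".join(config.presets))
        return {"manifest": manifest, "reports": []}

    grid = GridSpec(**config.grid)
    presets = list(config.presets)
    if config.reference not in presets:
        logger.info("stage=setup note=reference_added reference=%s", config.reference)
        presets.insert(0, config.reference)

    results = {}
    for name in presets:
        t0 = time.perf_counter()
        logger.info("stage=preset-start preset=%s", name)
        spec, trials = _run_preset(name, config, grid)
        results[name] = (spec, trials)
        logger.info("stage=preset-end preset=%s wall_s=%.1f", name,
                    time.perf_counter() - t0)

    ref_spec, ref_trials = results[config.reference]
    ref_report, ref_art = _preset_report(config.reference, ref_spec, ref_trials, config)
    reference_binding = ref_art["binding"]
    ref_report["ddg"] = 0.0

    reports = []
    for name in presets:
        if name == config.reference:
            reports.append((ref_report, ref_art))
            continue
        spec, trials = results[name]
        reports.append(_preset_report(name, spec, trials, config,
                                      reference=reference_binding))

    if out is not None:
        with open(out / "report.jsonl", "w") as fh:
            for rep, _ in reports:
                fh.write(json.dumps(rep, sort_keys=True) + "\n")
        rows = ["preset\tdelta_g\tddg\tpitch_12\tpitch_23"]
        for rep, _ in reports:
            rows.append("\t".join([
                rep["preset"], repr(rep["delta_g"]),
                repr(rep["ddg"]), repr(rep["pitch_12"]), repr(rep["pitch_23"]),
            ]))
        (out / "summary.tsv").write_text("\n".join(rows) + "\n")
        for rep, art in reports:
            tag = rep["preset"].replace("Ψ", "psi")
            write_opendx(out / f"G_{tag}.dx",
                         np.nan_to_num(art["g"].values, nan=9999.0), grid)
            write_cv_series(out / f"cv_{tag}.tsv", art["trials"][0].cv_series)
            write_structure_pdb(out / f"avg_{tag}.pdb", art["structure"])

    return {"manifest": manifest, "reports": [rep for rep, _ in reports],
            "artifacts": {rep["preset"]: art for rep, art in reports}}
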