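"""Reporter-expression quantification and its link to pairing penalties.

Quantification rule for the fluorescence reporter assay: live, iRFP-positive
cells are gated; the per-cell GFP/iRFP ratio's median is the construct's
translation efficiency, expressed as percent of the Kozak-AUG control.  A
synthetic cytometry generator (log-normal intensities, programmed median
ratios, a configurable dead/iRFP-negative fraction) provides test data; the
real assay's values are wet-lab measurements and are not reproduced here.

The linkage stage regresses (log or linear) relative initiation frequency on
the pairing penalty DeltaDelta_G.  On a Boltzmann-consistent table
f = exp(-DeltaDelta_G / kT) the log regression recovers slope -1/kT with
r = -1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

CELL_COLUMNS = ["cell_id", "gfp", "irfp", "live"]


@dataclass(frozen=True)
class CorrelationResult:
    """OLS fit of transformed initiation frequency against DeltaDelta_G."""

    slope: float
    intercept: float
    r: float
    n: int
    transform: str

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r out of range")


def gate_cells(cells: pd.DataFrame, irfp_threshold: float) -> pd.DataFrame:
    """Keep live cells with iRFP strictly above the threshold."""
    if irfp_threshold < 0:
        raise ValueError("iRFP threshold must be >= 0")
    if (cells["gfp"] < 0).any() or (cells["irfp"] < 0).any():
        raise ValueError("intensities must be non-negative")
    gated = cells[cells["live"].astype(bool) & (cells["irfp"] > irfp_threshold)]
    if len(gated) == 0:
        raise ValueError(
            f"gate is empty: {len(cells)} cells in, {int(cells['live'].sum())} live, "
            f"0 above iRFP threshold {irfp_threshold}"
        )
    return gated


def translation_efficiency(gated: pd.DataFrame, control_gated: pd.DataFrame) -> float:
    """Median per-cell GFP/iRFP ratio as percent of the control construct."""
    for name, df in (("sample", gated), ("control", control_gated)):
        if len(df) == 0:
            raise ValueError(f"{name} subset is empty")
        if (df["irfp"] <= 0).any():
            raise ValueError(f"{name} subset contains non-positive iRFP after gating")
    ratio = (gated["gfp"] / gated["irfp"]).median()
    control = (control_gated["gfp"] / control_gated["irfp"]).median()
    if control <= 0:
        raise ValueError("control median ratio is non-positive")
    return 100.0 * float(ratio) / float(control)


def simulate_cytometry(
    efficiencies: dict[str, float],
    n: int = 10_000,
    seed: int = 0,
    intensity_cv: float = 0.5,
    channel_cv: float = 0.2,
    dead_fraction: float = 0.05,
    irfp_negative_fraction: float = 0.05,
    irfp_median: float = 1000.0,
) -> pd.DataFrame:
    """Generate a synthetic cell table, one block of ``n`` cells per construct.

    GFP and iRFP intensities are log-normal with a shared per-cell size
    factor: total per-channel log spread is ``intensity_cv``, of which
    ``channel_cv`` is channel-specific (the rest is common to both channels
    and cancels in the ratio, as cell-to-cell size variation does in a real
    cytometer).  Each construct's median GFP/iRFP ratio equals its programmed
    efficiency (log-normal noise has median 1).  A ``dead_fraction`` of cells
    is flagged dead and an ``irfp_negative_fraction`` gets near-zero iRFP, so
    realistic gating is exercised.  Deterministic for a given seed.
    """
    if any(e < 0 for e in efficiencies.values()):
        raise ValueError("programmed efficiencies must be >= 0")
    if channel_cv > intensity_cv:
        raise ValueError("channel_cv cannot exceed the total intensity_cv")
    common_cv = float(np.sqrt(intensity_cv**2 - channel_cv**2))
    rng = np.random.default_rng(seed)
    frames = []
    for construct, eff in efficiencies.items():
        size = rng.lognormal(0.0, common_cv, size=n)
        irfp = irfp_median * size * rng.lognormal(0.0, channel_cv, size=n)
        gfp = eff * irfp_median * size * rng.lognormal(0.0, channel_cv, size=n)
        live = rng.random(n) >= dead_fraction
        negative = rng.random(n) < irfp_negative_fraction
        irfp = np.where(negative, rng.uniform(0.0, 1.0, size=n), irfp)
        frames.append(pd.DataFrame({
            "construct": construct,
            "cell_id": [f"{construct}-{i}" for i in range(n)],
            "gfp": gfp,
            "irfp": irfp,
            "live": live,
        }))
    return pd.concat(frames, ignore_index=True)


def correlate_penalty_expression(
    table: pd.DataFrame,
    transform: str = "log",
    frequency_column: str = "frequency_percent",
    ddg_column: str = "ddg",
) -> CorrelationResult:
    """OLS of (log) relative initiation frequency on DeltaDelta_G.

    ``transform="log"`` (default) regresses ln(frequency) so that a
    Boltzmann-consistent table yields slope -1/kT; ``"linear"`` regresses the
    frequency itself.  Frequencies may be percentages or fractions — the
    slope is unaffected under log, only the intercept shifts.
    """
    if transform not in ("log", "linear"):
        raise ValueError("transform must be 'log' or 'linear'")
    rows = table.dropna(subset=[frequency_column, ddg_column])
    if len(rows) < 3:
        raise ValueError(f"need at least 3 rows with both fields, got {len(rows)}")
    x = rows[ddg_column].to_numpy(dtype=float)
    y = rows[frequency_column].to_numpy(dtype=float)
    if transform == "log":
        bad = rows[y <= 0]
        if len(bad):
            raise ValueError(
                "log transform requires positive frequencies; offending rows: "
                f"{bad.index.tolist()}"
            )
        y = np.log(y)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("degenerate table: response or penalty is constant")
    fit = scipy.stats.linregress(x, y)
    return CorrelationResult(slope=float(fit.slope), intercept=float(fit.intercept),
                             r=float(fit.rvalue), n=len(rows), transform=transform)


def load_expression_table(path=None) -> pd.DataFrame:
    """Load a codon -> relative-expression TSV (default: the shipped fixture).

    The shipped table is synthetic (see :func:`synthetic_expression_table`),
    not measured reporter data.
    """
    if path is None:
        from importlib.resources import files

        path = files("codonpmf").joinpath("data/synthetic_expression.tsv")
    return pd.read_csv(path, sep="\t", comment="#")


def synthetic_expression_table(
    names: list[str] | None = None,
    kt_eff: float = 2.577,
    subdivisions: int = 24,
) -> pd.DataFrame:
    """Synthetic codon -> relative-expression table (percent of AUG).

    Built to be Boltzmann-consistent with the shipped presets' oracle pairing
    penalties at an effective temperature ``kt_eff`` (kJ/mol):
    frequency = 100 * exp(-DeltaDelta_G / kT_eff).  This is a synthetic
    fixture standing in for undeposited reporter measurements; it preserves
    the penalty/frequency ordering by construction.
    """
    from .oracle import boltzmann_oracle
    from .pmf import pairing_penalty
    from .system import load_preset

    if names is None:
        names = ["AUG", "CUG", "GUG", "UUG", "ACG", "AUU", "CΨG", "GΨG", "mCUG"]
    ref = boltzmann_oracle(load_preset("AUG"), check=False,
                           subdivisions=subdivisions).binding
    rows = []
    for name in names:
        binding = boltzmann_oracle(load_preset(name), check=False,
                                   subdivisions=subdivisions).binding
        ddg = pairing_penalty(binding, ref)
        rows.append({
            "codon": name,
            "ddg": ddg,
            "frequency_percent": 100.0 * float(np.exp(-ddg / kt_eff)),
        })
    return pd.DataFrame(rows)
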