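"""Static figures: 2D free-energy surfaces and the penalty-vs-frequency scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .expression import CorrelationResult
from .pmf import Reduced2D


def plot_surface(surface: Reduced2D, path) -> None:
    """Filled-contour plot of a 2D free-energy surface (kJ/mol)."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    c = surface.grid.centers
    im = ax.pcolormesh(c, c, surface.g.T, shading="nearest", cmap="viridis")
    i, j = surface.axes
    ax.set_xlabel(f"d{i} (Å)")
    ax.set_ylabel(f"d{j} (Å)")
    fig.colorbar(im, ax=ax, label="G (kJ/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_penalty_scatter(table, fit: CorrelationResult | None, path,
                         frequency_column: str = "frequency_percent",
                         ddg_column: str = "ddg") -> None:
    """Pairing penalty vs relative initiation frequency, with the OLS fit."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    x = table[ddg_column].to_numpy(dtype=float)
    y = table[frequency_column].to_numpy(dtype=float)
    ax.scatter(x, y, color="tab:orange")
    for _, row in table.iterrows():
        ax.annotate(str(row.get("codon", "")), (row[ddg_column], row[frequency_column]),
                    fontsize=8, xytext=(3, 3), textcoords="offset points")
    if fit is not None:
        xs = np.linspace(x.min(), x.max(), 50)
        if fit.transform == "log":
            ax.plot(xs, np.exp(fit.intercept + fit.slope * xs), "k--", lw=1)
        else:
            ax.plot(xs, fit.intercept + fit.slope * xs, "k--", lw=1)
    ax.set_yscale("log")
    ax.set_xlabel("ΔΔG (kJ/mol)")
    ax.set_ylabel("initiation frequency (% of AUG)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
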