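"""Tornado and CEAC plots (optional outputs of the CLI)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .uncertainty import PsaResult, TornadoTable  # noqa: E402


def plot_tornado(tt: TornadoTable, path: str | Path) -> None:
    """Horizontal-bar tornado diagram, widest ICER range on top."""
    frame = tt.table.iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(frame) + 1.5))
    left = frame[["icer_low", "icer_high"]].min(axis=1)
    width = (frame[["icer_low", "icer_high"]].max(axis=1) - left).clip(lower=0)
    ax.barh(frame["parameter"], width, left=left, color="#4878d0")
    ax.axvline(tt.base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_xlabel("ICER (SGD per QALY)")
    ax.set_title(f"One-way sensitivity: {tt.candidate} vs {tt.reference}")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(psa: PsaResult, path: str | Path) -> None:
    """Acceptability curves, one panel per compliance scenario."""
    n = len(psa.surfaces)
    fig, axes = plt.subplots(1, n, figsize=(5 * n, 4), sharey=True, squeeze=False)
    for ax, surf in zip(axes[0], psa.surfaces):
        for name in surf.probability.columns:
            ax.plot(surf.wtp_grid, surf.probability[name], label=name)
        ax.set_title(surf.scenario)
        ax.set_xlabel("Willingness to pay (SGD per QALY)")
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].set_ylabel("Probability cost-effective")
    axes[0][-1].legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
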