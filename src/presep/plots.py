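"""Optional matplotlib figures for evaluation outputs.

Requires the ``plot`` extra (matplotlib); everything here consumes the
machine-readable objects the evaluation functions already return, so plots
are strictly derived views.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as e:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (install presep[plot])") from e
    return plt


def plot_roc(fpr, tpr, auc: float, path: str) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", label="random")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ri_coverage(curve: pd.DataFrame, path: str) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["ri_threshold"], 100 * curve["fraction"], "o-", label="% of proteins with RI ≥ t")
    ax.plot(curve["ri_threshold"], 100 * curve["accuracy"], "s-", label="accuracy among them (%)")
    ax.set_xlabel("Reliability index threshold t")
    ax.set_ylabel("Percent")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep_heatmap(sweep: pd.DataFrame, mode: str, path: str) -> None:
    plt = _plt()
    sub = sweep[sweep["mode"] == mode]
    pivot = sub.pivot(index="lam", columns="w", values="mcc").sort_index()
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower",
                   extent=(min(pivot.columns), max(pivot.columns),
                           min(pivot.index), max(pivot.index)))
    fig.colorbar(im, ax=ax, label="MCC")
    ax.set_xlabel("weight factor w")
    ax.set_ylabel("correlation rank λ")
    ax.set_title(f"Type {mode}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_terminal_scan(scan: pd.DataFrame, path: str) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for terminal, marker in (("N", "o"), ("C", "s")):
        sub = scan[scan["terminal"] == terminal].sort_values("k")
        ax.plot(sub["k"], sub["mcc"], marker + "-", label=f"{terminal}-terminal")
    ax.set_xlabel("window length k (residues)")
    ax.set_ylabel("MCC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
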