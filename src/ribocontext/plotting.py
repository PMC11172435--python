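"""Figure rendering for pipeline output directories.

All figures are rendered from the TSV outputs (not from in-memory state),
so a plotting failure can never corrupt the tabular results.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NUCS = ["A", "C", "G", "U"]


def plot_pwm(pwm_path, out_path) -> bool:
    """Bar chart of per-position nucleotide weights (PWM logo analogue)."""
    df = pd.read_csv(pwm_path, sep="\t")
    if len(df) == 0:
        logger.warning("plot_pwm: empty input %s", pwm_path)
        return False
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(3)
    width = 0.2
    for k, nuc in enumerate(_NUCS):
        ax.bar(x + (k - 1.5) * width, df[nuc], width, label=nuc)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xticks(x, [f"position {i + 1}" for i in range(3)])
    ax.set_ylabel("weight  log2(f_obs / f_exp)")
    ax.set_title("Codon nucleotide preferences")
    ax.legend(title="nucleotide")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return True


def plot_context_comparisons(comparisons_path, out_path) -> bool:
    """Paired bars of mean density with (w) vs without (wo) +1 GNN per codon."""
    df = pd.read_csv(comparisons_path, sep="\t")
    df = df[df["flag"].isna() | (df["flag"] == "")]
    if len(df) == 0:
        logger.warning("plot_context_comparisons: nothing to plot in %s", comparisons_path)
        return False
    df = df.sort_values("asite_codon_type").reset_index(drop=True)
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(df)), 4))
    ax.bar(x - 0.2, df["mean_with"], 0.4, label="w +1 GNN")
    ax.bar(x + 0.2, df["mean_without"], 0.4, label="wo +1 GNN")
    sig = df["p_two_tailed"] < 0.01
    for xi, (s, top) in enumerate(zip(sig, df[["mean_with", "mean_without"]].max(axis=1))):
        if s:
            ax.text(xi, top * 1.02, "*", ha="center")
    ax.set_xticks(x, df["asite_codon_type"], rotation=90, fontsize=7)
    ax.axhline(1.0, color="black", lw=0.8, ls=":")
    ax.set_ylabel("normalized ribosome density")
    ax.set_title(f"A-site codon densities ({df['rfp_class'].iloc[0]})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return True


def plot_class_summary(summary_path, out_path) -> bool:
    """Grouped bars of mean percent elevation per codon class and RFP class."""
    df = pd.read_csv(summary_path, sep="\t")
    if len(df) == 0:
        logger.warning("plot_class_summary: empty input %s", summary_path)
        return False
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(x - 0.2, df["mean_elev_21nt"], 0.4, label="21-nt RFPs")
    ax.bar(x + 0.2, df["mean_elev_28nt"], 0.4, label="28-nt RFPs")
    ax.set_xticks(x, df["group"], rotation=30)
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_ylabel("% density elevation with +1 GNN")
    ax.set_title("Elevation by codon class")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return True


def render_figures(run_dir) -> list[Path]:
    """Render every figure whose input TSV exists in a run directory."""
    run_dir = Path(run_dir)
    made: list[Path] = []
    jobs = [
        ("pwm_all.tsv", "fig_pwm.png", plot_pwm),
        ("pwm_conditional.tsv", "fig_pwm_conditional.png", plot_pwm),
    ]
    for cls in ("28nt", "21nt"):
        jobs.append(
            (f"comparisons_{cls}.tsv", f"fig_context_{cls}.png", plot_context_comparisons)
        )
    jobs.append(("class_summary.tsv", "fig_classes.png", plot_class_summary))
    for src, dst, fn in jobs:
        src_path = run_dir / src
        if not src_path.exists():
            continue
        try:
            if fn(src_path, run_dir / dst):
                made.append(run_dir / dst)
        except Exception:  # noqa: BLE001 - plotting must not kill the run
            logger.exception("figure %s failed", dst)
    return made
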