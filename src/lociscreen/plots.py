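"""Figure analogues: step-2 forest plot and SNP-by-TSH interaction plot."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .interaction import InteractionResult, predict_at_tsh_levels
from .mediation import MediationResult

__all__ = ["plot_step2_forest", "plot_interaction"]


def plot_step2_forest(
    results: Sequence[MediationResult],
    rsid: str,
    path: Optional[str] = None,
):
    """Forest plot of trait-adjusted SNP effects (b2 with 95% CI) for one
    variant, outliers highlighted in red against the unadjusted effect."""
    rows = [r for r in results if r.rsid == rsid]
    if not rows:
        raise ValueError(f"no mediation results for {rsid}")
    rows = sorted(rows, key=lambda r: r.b2)
    y = np.arange(len(rows))
    b2 = np.array([r.b2 for r in rows])
    se2 = np.array([r.se2 for r in rows])
    colors = ["red" if r.outlier_flag else "grey" for r in rows]

    fig, ax = plt.subplots(figsize=(6, max(3, 0.18 * len(rows) + 1)))
    ax.errorbar(b2, y, xerr=1.96 * se2, fmt="none", ecolor=colors, alpha=0.7)
    ax.scatter(b2, y, c=colors, s=12, zorder=3)
    ax.axvline(rows[0].b1, color="steelblue", ls="--", lw=1, label="unadjusted effect (b1)")
    ax.axvline(0.0, color="black", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels([r.trait_name for r in rows], fontsize=6)
    ax.set_xlabel("SNP effect on ln(eGFRcrea) after trait adjustment (b2)")
    ax.set_title(f"Step-2 mediation screen, {rsid}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_interaction(
    fit: InteractionResult,
    path: Optional[str] = None,
):
    """Predicted per-allele regression lines at low/average/high TSH.

    Lines show the SNP slope at TSH one SD below, at, and above the mean,
    with delta-method 95% confidence bands.
    """
    pred = predict_at_tsh_levels(fit)
    dose = np.linspace(0, 2, 50)
    labels = ["low TSH (mean - SD)", "average TSH (mean)", "high TSH (mean + SD)"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for (_, row), label in zip(pred.iterrows(), labels):
        line = row["snp_slope"] * dose
        ax.plot(dose, line, label=f"{label}: slope={row['snp_slope']:.4f}")
        ax.fill_between(
            dose, row["ci_low"] * dose, row["ci_high"] * dose, alpha=0.15
        )
    ax.set_xlabel(f"{fit.rsid} effect-allele dosage")
    ax.set_ylabel("predicted ln(eGFRcrea), centered")
    ax.set_title(f"SNP x TSH interaction (p = {fit.p_interaction:.3g})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
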