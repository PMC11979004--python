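"""Dot-whisker plots of session-wise EMMs and effect-size trajectories."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_session_contrasts"]


def plot_session_contrasts(contrasts: pd.DataFrame, response: str = "d'",
                           out: str | None = None):
    """Two panels: per-session group EMMs and Cohen's d with 95% CIs."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    s = contrasts["stim_session"]
    ax1.errorbar(s - 0.1, contrasts["emm_sham"], fmt="o", color="firebrick",
                 label="sham")
    ax1.errorbar(s + 0.1, contrasts["emm_active"], fmt="o", color="steelblue",
                 label="active")
    ax1.set_xlabel("stimulation session")
    ax1.set_ylabel(f"EMM {response}")
    ax1.legend(frameon=False)

    yerr = [contrasts["cohens_d"] - contrasts["d_ci_low"],
            contrasts["d_ci_high"] - contrasts["cohens_d"]]
    ax2.errorbar(s, contrasts["cohens_d"], yerr=yerr, fmt="o", color="black")
    ax2.axhline(0, lw=0.8, color="grey")
    for cut in (0.2, 0.5, 0.8):
        ax2.axhline(cut, lw=0.5, ls=":", color="grey")
        ax2.axhline(-cut, lw=0.5, ls=":", color="grey")
    ax2.set_xlabel("stimulation session")
    ax2.set_ylabel("Cohen's d (95% CI)")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
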