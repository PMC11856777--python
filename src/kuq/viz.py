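"""Optional figure output: KU density of the ID test split with the
percentile threshold, overlaid with the OoD samples' KU values."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy.stats import gaussian_kde  # noqa: E402

from .ood_eval import KuReport  # noqa: E402

__all__ = ["plot_ku_report"]


def plot_ku_report(report: KuReport, path: str | Path) -> None:
    """Kernel-density plot of the transformed test KU, the threshold line, and
    one dot row per OoD batch (undetected samples fall left of the line)."""
    test_ku = np.asarray(report.test_ku)
    fig, ax = plt.subplots(figsize=(6, 3.2))
    if np.ptp(test_ku) > 0:
        grid = np.linspace(test_ku.min() - 0.5, test_ku.max() + 1.5, 400)
        ax.plot(grid, gaussian_kde(test_ku)(grid), color="tab:orange",
                label="p(test KU)")
    ax.axvline(report.threshold, color="black",
               label=f"{report.percentile:.0f}th pct threshold")
    for i, (name, ku) in enumerate(sorted(report.ood_ku.items())):
        ku = np.asarray(ku)
        jitter = -0.02 * (i + 1) * np.ones_like(ku)
        ax.plot(ku, jitter, ".", ms=3, alpha=0.5,
                label=f"{name} OoD ({report.undetected_pct[name]:.1f}% undetected)")
    label = "log(10σ)" if report.variant == "toy" else "log(10σ+1)"
    ax.set_xlabel(f"knowledge uncertainty, {label}")
    ax.set_ylabel("density")
    ax.set_title(f"{report.experiment_id} — {report.estimator}")
    ax.legend(fontsize=8, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
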