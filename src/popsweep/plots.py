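"""Optional quick-look plots (requires matplotlib).

Small diagnostic figures: ZHp/ZFst window distributions for a scan and a
PC1/PC2 scatter coloured by population.  Imported lazily so the core
pipeline has no plotting dependency.
"""

from __future__ import annotations

import pandas as pd

from .structure import PcaResult


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_z_distributions(windows: pd.DataFrame, path) -> None:
    """Histograms of ZHp and ZFst over all retained windows."""
    plt = _plt()
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].hist(windows["zhp"].dropna(), bins=40, color="steelblue")
    axes[0].set_xlabel("ZHp")
    axes[1].hist(windows["zfst"].dropna(), bins=40, color="firebrick")
    axes[1].set_xlabel("ZFst")
    for ax in axes:
        ax.set_ylabel("windows")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(result: PcaResult, populations: list[str], path) -> None:
    """PC1 vs PC2 scatter, one colour per population."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    pops = sorted(set(populations))
    for pop in pops:
        idx = [i for i, p in enumerate(populations) if p == pop]
        ax.scatter(result.coordinates[idx, 0], result.coordinates[idx, 1],
                   label=pop, s=30)
    ax.set_xlabel(f"PC1 ({result.variance_explained[0]:.2f}%)")
    ax.set_ylabel(f"PC2 ({result.variance_explained[1]:.2f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
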