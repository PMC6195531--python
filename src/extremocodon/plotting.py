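"""Minimal plotting helpers for the abundance, ranking and data-point
results. Styling is deliberately plain; these are working plots, not
publication figures."""

from __future__ import annotations

from .abundance import AbundanceResult, DataPointSeries, RankTable


def _axes(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(max(4, 0.25 * 30), 3))
    return ax


def plot_relative_abundance(result: AbundanceResult, ax=None):
    """Bar chart of beta_rel per significant codon; positive contributors
    up, negative down."""
    ax = _axes(ax)
    colors = ["tab:green" if b > 0 else "tab:blue" for b in result.beta_rel]
    ax.bar(result.codons, result.beta_rel, color=colors)
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_ylabel("relative abundance")
    ax.set_title(result.dataset_label)
    ax.tick_params(axis="x", rotation=90)
    return ax


def plot_ranks(table: RankTable, ax=None):
    """1-9 rank per significant codon."""
    ax = _axes(ax)
    ax.bar(table.codons, table.rank, color="tab:purple")
    ax.set_ylim(0, 9.5)
    ax.set_ylabel("rank (1-9)")
    ax.set_title(table.dataset_label)
    ax.tick_params(axis="x", rotation=90)
    return ax


def plot_datapoints(series: DataPointSeries, ax=None):
    """Normalized per-pair scores of one codon for both classes."""
    ax = _axes(ax)
    x = range(len(series.pair_ids))
    ax.scatter(x, series.values_e, s=12, color="tab:green", label="extremophile")
    ax.scatter(x, series.values_ne, s=12, color="tab:blue", label="counterpart")
    ax.set_ylim(-0.05, 1.05)
    ax.set_xlabel("pair")
    ax.set_ylabel("normalized score")
    ax.set_title(f"{series.codon} ({series.dataset_label})")
    ax.legend(frameon=False, fontsize=8)
    return ax
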