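"""Plotting helpers (optional; requires matplotlib)."""

from __future__ import annotations

from .enrichment import EnrichmentResult

__all__ = ["plot_null_distribution"]


def plot_null_distribution(result: EnrichmentResult, ax=None, bins: int = 40):
    """Histogram of the null medians with the observed statistic marked.

    The arrow style follows the convention of resampling-test figures: the
    observed median density sits on the x-axis against the null histogram,
    annotated with both one-sided empirical p-values.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(result.null_medians, bins=bins, color="0.75", edgecolor="0.4")
    ax.axvline(result.m_obs, color="crimson", lw=2)
    ax.annotate(
        f"M_obs = {result.m_obs:.3g}\n"
        f"p_left = {result.p_left:.3g}, p_right = {result.p_right:.3g}",
        xy=(result.m_obs, ax.get_ylim()[1] * 0.95),
        xytext=(5, -5),
        textcoords="offset points",
        va="top",
        fontsize=8,
    )
    ax.set_xlabel("null median site density (sites/kb)")
    ax.set_ylabel("replicates")
    ax.set_title(f"{result.mirna_name} x {result.set_label} (B = {result.B})")
    return ax
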