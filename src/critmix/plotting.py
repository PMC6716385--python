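"""Boxplot-style summaries of two-session inconsistency proportions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .consistency import ConsistencyReport


def plot_inconsistency(report: ConsistencyReport, block_map: dict[str, str]):
    """Participant-wise and item-wise inconsistency proportions per block.

    Returns a matplotlib Figure with two panels of boxplots, one box per
    category, grouped and shaded by block.
    """
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    blocks = sorted(set(block_map.values()))
    shade = {b: c for b, c in zip(blocks, ("white", "0.8", "0.6", "0.4"))}

    for ax, (frame, unit) in zip(
        axes,
        ((report.per_participant_category, "participants"),
         (report.per_item, "items")),
    ):
        cats = sorted(frame["category"].unique(), key=lambda c: (block_map[c], c))
        data = [frame.loc[frame["category"] == c, "proportion"] for c in cats]
        boxes = ax.boxplot(data, labels=cats, patch_artist=True)
        for patch, cat in zip(boxes["boxes"], cats):
            patch.set_facecolor(shade.get(block_map[cat], "white"))
        ax.set_title(f"inconsistency across {unit}")
        ax.set_ylabel("proportion inconsistent")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    return fig
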