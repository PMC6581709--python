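"""Distortion maps and confusion-matrix heatmaps.

The distortion map draws the hand outline with one arrow per stimulation
site, originating at the site (thick black circle) and ending at the
center of the perceived locations; the arrow length therefore corresponds
to the offset and a semitransparent circle around the endpoint to the
spread.  Sites are colored yellow (distal) to blue (proximal).

The confusion heatmap shows row percentages (stimulated site on the rows,
discretized perceived site on the columns) in grayscale, with grid lines
after sites 4, 8, 12, 16 and 20 delimiting the digits and the palm.

Arrows are drawn as straight segments even though the offset metric is
geodesic; ``curved_arrows=True`` draws the realizing geodesic path
instead.  SVG output is deterministic for fixed inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Circle, Polygon as MplPolygon

from .geodesic import geodesic_path
from .hand_template import HandTemplate
from .metrics import AssessmentSummary, ConfusionMatrix

_DIGIT_BOUNDARIES = (4, 8, 12, 16, 20)  # grid lines after these site ids


def _deterministic_rc():
    return matplotlib.rc_context({"svg.hashsalt": "handloc"})


def _save(fig, path: str | Path) -> None:
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)


def _rank_colors(template: HandTemplate) -> dict[int, tuple]:
    ranks = [s.distal_rank for s in template.sites]
    span = max(ranks) or 1
    cmap = plt.get_cmap("viridis_r")  # yellow (distal) -> blue/violet (proximal)
    return {s.site_id: cmap(s.distal_rank / span) for s in template.sites}


def render_distortion_map(
    summary: AssessmentSummary,
    template: HandTemplate,
    path: str | Path,
    show_spread_circles: bool = True,
    curved_arrows: bool = False,
) -> None:
    """Render the per-site offset/spread distortion map to SVG or PNG.

    Arrow endpoints are the response centers stored in the summary; no
    metric is recomputed here.  Spread circles are drawn with the radius in
    template units implied by the summary's spread values.
    """
    colors = _rank_colors(template)
    # template units per reported cm (summary may be normalized)
    units_per_reported_cm = template.units_per_cm
    with _deterministic_rc():
        fig, ax = plt.subplots(figsize=(5, 7))
        ax.add_patch(
            MplPolygon(
                np.asarray(template.outline), closed=True, fill=False, lw=1.2, ec="black"
            )
        )
        for outcome in summary.per_site:
            site = template.site(outcome.site_id)
            ax.add_patch(
                Circle(site.position, 3.0, fc=colors[site.site_id], ec="black", lw=1.6, zorder=3)
            )
            if not outcome.defined:
                continue
            center = outcome.center
            if show_spread_circles:
                ax.add_patch(
                    Circle(
                        center,
                        outcome.spread_cm * units_per_reported_cm,
                        fc=colors[site.site_id],
                        alpha=0.25,
                        ec="none",
                        zorder=1,
                    )
                )
            if curved_arrows:
                wp = np.asarray(geodesic_path(template, site.position, center).waypoints)
                ax.plot(wp[:, 0], wp[:, 1], color="black", lw=1.0, zorder=2)
                tail = wp[-2]
            else:
                tail = np.asarray(site.position)
            ax.annotate(
                "",
                xy=center,
                xytext=tuple(tail),
                arrowprops={"arrowstyle": "->", "color": "black", "lw": 1.0},
                zorder=2,
            )
        ax.set_aspect("equal")
        ax.set_axis_off()
        _save(fig, path)


def render_confusion_heatmap(
    cm: ConfusionMatrix,
    template: Optional[HandTemplate] = None,
    path: str | Path = "confusion.svg",
    annotate_row_n: bool = False,
) -> None:
    """Render the 24x24 row-percentage confusion matrix as a heatmap."""
    with _deterministic_rc():
        fig, ax = plt.subplots(figsize=(6.5, 6))
        data = np.ma.masked_invalid(cm.matrix)
        im = ax.imshow(
            data, cmap="Greys", vmin=0, vmax=100, origin="upper", interpolation="nearest"
        )
        for b in _DIGIT_BOUNDARIES:
            ax.axhline(b - 0.5, color="tab:red", lw=0.8)
            ax.axvline(b - 0.5, color="tab:red", lw=0.8)
        ticks = np.arange(24)
        ax.set_xticks(ticks, [str(i + 1) for i in ticks], fontsize=6)
        ax.set_yticks(ticks, [str(i + 1) for i in ticks], fontsize=6)
        ax.set_xlabel("discretized perceived site")
        ax.set_ylabel("stimulated site")
        if annotate_row_n:
            for i, n in enumerate(cm.row_n):
                ax.text(23.8, i, str(int(n)), fontsize=5, va="center", ha="left")
        fig.colorbar(im, ax=ax, label="% of responses", shrink=0.8)
        _save(fig, path)
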