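"""Radar-chart rendering of criterion scores.

One chart shows, per session, a coloured mean polygon over the seven
criterion axes plus a translucent band between the session's extreme
values; the dashed ring at 0 marks the reference population.  The fill
colour encodes the session's speed z-score through a diverging colormap
clipped to the radial limits, so slow sessions read red and fast ones
green regardless of the polygon's shape.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib import colors  # noqa: E402

from .exceptions import GaitError
from .scoring import CRITERIA_ORDER, SessionSummary

from dataclasses import dataclass, field  # noqa: E402

# stable SVG output (no timestamps, reproducible ids)
plt.rcParams["svg.hashsalt"] = "semiogram"

SPEED_CMAP = "RdYlGn"


@dataclass
class RenderSpec:
    """Layout of the radar chart."""

    criteria: tuple = CRITERIA_ORDER
    r_min: float = -4.0
    r_max: float = 2.0
    cmap: str = SPEED_CMAP
    title: str | None = None

    def __post_init__(self) -> None:
        if self.r_min >= self.r_max:
            raise GaitError("radial limits must be ordered (r_min < r_max)")

    def speed_color(self, speed_z: float):
        norm = colors.Normalize(vmin=self.r_min, vmax=self.r_max, clip=True)
        return matplotlib.colormaps[self.cmap](norm(speed_z))


def _close(values: np.ndarray) -> np.ndarray:
    return np.concatenate([values, values[:1]])


def render(
    sessions: list,
    spec: RenderSpec | None = None,
    out: str | None = None,
    ax=None,
):
    """Draw the radar chart for one or more :class:`SessionSummary`.

    Scores below ``r_min`` are clipped to the chart edge and the session is
    flagged in the legend.  Writes SVG and/or PNG depending on the ``out``
    extension (no extension: both).  Returns the matplotlib figure.
    """
    spec = spec or RenderSpec()
    if not sessions:
        raise GaitError("render needs at least one session")
    k = len(spec.criteria)
    angles = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)

    if ax is None:
        fig, ax = plt.subplots(
            figsize=(6.5, 6.0), subplot_kw={"projection": "polar"}
        )
    else:
        fig = ax.figure
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    ax.set_xticks(angles)
    ax.set_xticklabels([c.capitalize() for c in spec.criteria])
    ax.set_ylim(spec.r_min, spec.r_max)
    ax.set_rlabel_position(180.0 / k)

    # dashed normative ring at z = 0
    ring = np.linspace(0, 2 * np.pi, 181)
    ax.plot(ring, np.zeros_like(ring), "k--", linewidth=1.4, zorder=3)

    for sess in sessions:
        if not isinstance(sess, SessionSummary):
            raise GaitError("sessions must be SessionSummary objects")
        mean = np.array([sess.mean.criteria[c] for c in spec.criteria])
        low = np.array([sess.low[c] for c in spec.criteria])
        high = np.array([sess.high[c] for c in spec.criteria])
        clipped = bool((mean < spec.r_min).any() or (low < spec.r_min).any())
        mean_c = np.clip(mean, spec.r_min, spec.r_max)
        low_c = np.clip(low, spec.r_min, spec.r_max)
        high_c = np.clip(high, spec.r_min, spec.r_max)
        color = spec.speed_color(sess.mean.speed_z)
        label = sess.label + (" (clipped)" if clipped else "")
        ax.plot(_close(angles), _close(mean_c), color=color, linewidth=2.0,
                label=label, zorder=4)
        ax.fill_between(_close(angles), _close(low_c), _close(high_c),
                        color=color, alpha=0.25, zorder=2)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=9)
    if spec.title:
        ax.set_title(spec.title, pad=24)

    if out is not None:
        _save(fig, out)
    return fig


def _save(fig, out: str) -> None:
    meta_svg = {"Date": None}
    if out.endswith(".svg"):
        fig.savefig(out, bbox_inches="tight", metadata=meta_svg)
    elif out.endswith(".png"):
        fig.savefig(out, bbox_inches="tight", dpi=150)
    else:
        fig.savefig(out + ".svg", bbox_inches="tight", metadata=meta_svg)
        fig.savefig(out + ".png", bbox_inches="tight", dpi=150)
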