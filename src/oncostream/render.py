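"""Snapshot rendering: ellipse glyphs coloured by nematic sign.

Cells travelling with the nematic mean direction are drawn blue, cells
travelling against it red — the convention used to visualise streams.
3D states are drawn as axis-projected ellipse glyphs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import EllipseCollection

from .model import CellConfiguration, ModelParams
from .stats import color_by_nematic

_BLUE = "#2166ac"
_RED = "#b2182b"


def render_snapshot(config: CellConfiguration, params: ModelParams,
                    ax=None, title: str | None = None,
                    projection_axes=(0, 1)):
    """Draw every cell as an ellipse with semi-axes (a, b) along its heading.

    For 3D states the positions and headings are projected onto the two
    ``projection_axes``; glyph angles follow the projected heading.
    Returns the matplotlib Axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    i0, i1 = projection_axes
    xy = config.positions[:, [i0, i1]]
    w = config.orientations[:, [i0, i1]]
    angles = np.degrees(np.arctan2(w[:, 1], w[:, 0]))
    signs = color_by_nematic(config.orientations)
    colors = np.where(signs > 0, _BLUE, _RED)
    n = config.n_cells
    coll = EllipseCollection(
        widths=np.full(n, 2 * params.a), heights=np.full(n, 2 * params.b),
        angles=angles,
        units="xy", offsets=xy, transOffset=ax.transData,
        facecolors=colors, edgecolors="none", alpha=0.8,
    )
    ax.add_collection(coll)
    ax.set_xlim(0, params.L)
    ax.set_ylim(0, params.L)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    if title is None:
        title = f"t = {config.time:g} h, N = {config.n_cells}"
    ax.set_title(title)
    return ax


def save_frames(trajectory, out_dir, prefix: str = "frame", dpi: int = 120):
    """Write one numbered PNG per recorded snapshot; returns the paths.

    Video encoding is left to external tooling (e.g. ffmpeg over the
    numbered frames).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, cfg in enumerate(trajectory.states):
        fig, ax = plt.subplots(figsize=(6, 6))
        render_snapshot(cfg, trajectory.params, ax=ax)
        path = out_dir / f"{prefix}_{k:05d}.png"
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        paths.append(path)
    return paths
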