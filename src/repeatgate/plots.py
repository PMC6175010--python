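"""Histogram and repeat-content visualizations, each with a TSV twin.

Every plot writes the numeric table behind it next to the image file
(same stem, ``.tsv`` suffix); tests and downstream tooling assert on the
TSVs, never on pixels.  Default image format is SVG (deterministic text).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from matplotlib.colors import ListedColormap  # noqa: E402

from .alleles import AlleleCall, CountHistogram  # noqa: E402
from .io import write_tsv  # noqa: E402
from .repeats import OTHER, RepeatComposition, track_rle  # noqa: E402

log = logging.getLogger("repeatgate")

# background, primary unit (red), first secondary (blue), other (gray)
_CONTENT_COLORS = ListedColormap(["#ffffff", "#c0392b", "#2980b9", "#95a5a6"])


def _twin_path(path) -> Path:
    return Path(path).with_suffix(".tsv")


def render_histogram(histogram: CountHistogram, call: AlleleCall | None,
                     path) -> Path | None:
    """Bar plot of read support per repeat count, called alleles marked.

    Returns the image path, or ``None`` (with a warning) for an empty
    histogram.  The underlying table is written as ``<stem>.tsv``.
    """
    if not histogram.bins:
        log.warning("empty histogram for %s/%s: no plot written",
                    histogram.locus, histogram.unit)
        return None
    path = Path(path)
    frame = histogram.as_frame()
    write_tsv(frame, _twin_path(path))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(frame["repeat_count"], frame["n_reads"], color="#34495e", width=0.8)
    if call is not None:
        for allele in sorted(set(call.alleles)):
            ax.axvline(allele, color="#c0392b", linestyle="--", linewidth=1)
            ax.annotate(f"{allele}x", (allele, frame["n_reads"].max()),
                        ha="center", va="bottom", color="#c0392b")
    ax.set_xlabel(f"{histogram.unit} repeat count")
    ax.set_ylabel("CCS reads")
    ax.set_title(f"{histogram.locus}: {histogram.unit} repeat distribution")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def render_content_plot(compositions: Sequence[RepeatComposition], path,
                        primary_unit: str | None = None,
                        secondary_unit: str | None = None) -> Path:
    """Repeat-content plot: one row per read, one cell per unit window.

    Rows are sorted by track length, descending (longest reads on top);
    primary-unit windows are red, the first secondary unit blue, anything
    else gray.  The run-length-encoded tracks are written as the TSV twin.
    Unit roles are inferred from window label frequency when not given.
    """
    if not compositions:
        raise ValueError("render_content_plot requires at least one composition")
    path = Path(path)
    if primary_unit is None:
        tally: dict[str, int] = {}
        for comp in compositions:
            for label in comp.unit_track:
                if label != OTHER:
                    tally[label] = tally.get(label, 0) + 1
        ranked = sorted(tally, key=lambda u: -tally[u])
        primary_unit = ranked[0] if ranked else ""
        if secondary_unit is None and len(ranked) > 1:
            secondary_unit = ranked[1]

    order = sorted(range(len(compositions)),
                   key=lambda i: -len(compositions[i].unit_track))
    ncols = max(len(c.unit_track) for c in compositions)
    grid = np.zeros((len(compositions), max(ncols, 1)), dtype=np.int8)
    for row, i in enumerate(order):
        for col, label in enumerate(compositions[i].unit_track):
            if label == primary_unit:
                grid[row, col] = 1
            elif secondary_unit is not None and label == secondary_unit:
                grid[row, col] = 2
            else:
                grid[row, col] = 3

    twin = pd.DataFrame(
        {"row": range(len(order)),
         "read_index": order,
         "track_length": [len(compositions[i].unit_track) for i in order],
         "unit_track": [track_rle(compositions[i].unit_track) for i in order]})
    write_tsv(twin, _twin_path(path))

    fig, ax = plt.subplots(figsize=(8, max(2, 0.08 * len(order))))
    ax.imshow(grid, cmap=_CONTENT_COLORS, vmin=0, vmax=3, aspect="auto",
              interpolation="none")
    ax.set_xlabel("repeat unit position")
    ax.set_ylabel("CCS reads")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
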