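"""Region-occupancy matrices and Ward clustering for heatmap displays.

Each window becomes one row of a signed occupancy matrix: +1 where a
c1>c2 region covers the position, -1 for c2>c1, 0 for filler or
untested positions.  Rows are clustered with Euclidean distances and
Ward's criterion so that windows with similar region layouts group
together, the display used to organise genome-wide results into
interpretable pattern classes.  All logic operates on the matrix; the
heatmap renderer is a thin optional layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .density import GenomicWindow
from .filtering import RegionOfChange

__all__ = ["OccupancyMatrix", "occupancy_matrix", "ward_cluster", "plot_heatmap"]


@dataclass
class OccupancyMatrix:
    """Windows x position-bins matrix with entries in {-1, 0, +1}."""

    values: np.ndarray
    window_ids: list[str]
    mode: str  # "absolute" or "end_relative"


def _region_offsets(w: GenomicWindow, r: RegionOfChange) -> tuple[int, int]:
    if r.off_start is not None:
        return r.off_start, r.off_end
    if w.strand == "-":
        return w.end - r.end, w.end - r.start
    return r.start - w.start, r.end - w.start


def occupancy_matrix(
    windows: Sequence[GenomicWindow],
    regions: Mapping[str, Sequence[RegionOfChange]],
    mode: str = "absolute",
    bins: int | None = None,
    only_significant: bool = True,
    alpha: float = 0.01,
) -> OccupancyMatrix:
    """Binned signed occupancy of regions over windows, 5'->3'.

    Bins receive the majority label (+1/-1 by covered length, ties 0) of
    the regions overlapping them.  "absolute" mode bins window offsets
    directly (default one bin per 10 bp of the longest window);
    "end_relative" mode splits each window at its midpoint and scales the
    5' half into the left half of the bins and the 3' half into the right
    half, anchoring variable-length windows at both ends (default 200
    bins).  With ``only_significant``, regions lacking an adjusted
    p-value <= alpha are ignored.
    """
    if mode not in ("absolute", "end_relative"):
        raise ValueError(f"unknown mode {mode!r}")
    if bins is None:
        bins = max(1, max(w.length for w in windows) // 10) if mode == "absolute" else 200
    out = np.zeros((len(windows), bins), dtype=np.int8)
    for row, w in enumerate(windows):
        cover_pos = np.zeros(bins)
        cover_neg = np.zeros(bins)
        for r in regions.get(w.id, ()):
            if only_significant and (r.padj is None or r.padj > alpha):
                continue
            sign = 1 if r.direction == "c1>c2" else -1
            off_s, off_e = _region_offsets(w, r)
            if mode == "absolute":
                b0 = off_s / w.length * bins
                b1 = off_e / w.length * bins
                spans = [(b0, b1)]
            else:
                half = w.length / 2
                nb = bins / 2
                spans = []
                lo, hi = min(off_s, half), min(off_e, half)
                if hi > lo:
                    spans.append((lo / half * nb, hi / half * nb))
                lo, hi = max(off_s, half), max(off_e, half)
                if hi > lo:
                    spans.append((nb + (lo - half) / half * nb, nb + (hi - half) / half * nb))
            for b0, b1 in spans:
                ib0, ib1 = int(np.floor(b0)), int(np.ceil(b1))
                for b in range(max(0, ib0), min(bins, ib1)):
                    frac = min(b1, b + 1) - max(b0, b)
                    if frac <= 0:
                        continue
                    (cover_pos if sign > 0 else cover_neg)[b] += frac
        out[row] = np.sign(cover_pos - cover_neg)
    return OccupancyMatrix(out, [w.id for w in windows], mode)


def ward_cluster(matrix: OccupancyMatrix, k: int) -> np.ndarray:
    """Cut a Euclidean/Ward dendrogram of the rows into ``k`` clusters."""
    n = len(matrix.window_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    if n == 1:
        return np.array([1])
    Z = linkage(matrix.values.astype(float), method="ward", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust")


def ward_heights(matrix: OccupancyMatrix) -> np.ndarray:
    """Dendrogram merge heights (ascending), an aid for choosing k."""
    Z = linkage(matrix.values.astype(float), method="ward", metric="euclidean")
    return Z[:, 2]


def plot_heatmap(matrix: OccupancyMatrix, labels: np.ndarray | None = None, path: str | None = None):
    """Render the occupancy matrix (red = c1>c2, blue = c2>c1, white = none)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    vals = matrix.values
    order = np.arange(len(matrix.window_ids))
    if labels is not None:
        order = np.argsort(labels, kind="stable")
        vals = vals[order]
    fig, ax = plt.subplots(figsize=(8, max(2, len(order) * 0.02)))
    ax.imshow(vals, aspect="auto", interpolation="nearest",
              cmap=ListedColormap(["#2166ac", "#ffffff", "#b2182b"]), vmin=-1, vmax=1)
    ax.set_xlabel("window position (bins, 5'->3')")
    ax.set_ylabel("windows")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
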