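"""Topographic 3D EEG tensors.

The channel axis of a 2-D EEG array ``(N, T)`` is rearranged onto a square
``W x W`` scalp grid, giving a ``(W, W, T)`` tensor whose rows run anterior
to posterior and whose columns run left to right; grid cells without an
electrode stay exactly zero.  ``T`` may be time samples or PSD bins — the
mapping is agnostic.

Packaged mappings (shipped as CSVs with columns ``channel,row,col`` so users
can override them):

* ``64ch-1020`` — a 64-electrode 10-20/10-10 layout on a 9 x 9 grid;
* ``22ch-bciiv2a`` — the 22-electrode four-class benchmark montage on a
  7 x 7 grid (its central row holds seven electrodes, so a 5-wide grid
  cannot place it injectively).

The 90-degree rotation used by the dual-branch network maps cell ``(r, c)``
to ``(c, W-1-r)``: the left-hemisphere column becomes the anterior row.  A
channel at (0, 0) therefore moves to (0, W-1).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .containers import TrialSet

__all__ = ["GridMapping", "standard_mapping", "load_mapping_csv", "to_3d",
           "gather_2d", "rotate90", "trials_to_tensors"]

MONTAGES = {"64ch-1020": "grid_64ch_1020.csv",
            "22ch-bciiv2a": "grid_22ch_bciiv2a.csv"}


@dataclass
class GridMapping:
    """Injective channel -> (row, col) placement on a W x W grid."""

    placements: dict[str, tuple[int, int]]
    W: int

    def __post_init__(self) -> None:
        cells = list(self.placements.values())
        if len(set(cells)) != len(cells):
            raise ValueError("placements must be injective (one channel per cell)")
        for r, c in cells:
            if not (0 <= r < self.W and 0 <= c < self.W):
                raise ValueError(f"cell ({r}, {c}) outside the {self.W}x{self.W} grid")

    @property
    def channels(self) -> list[str]:
        return list(self.placements)

    def __len__(self) -> int:
        return len(self.placements)


def load_mapping_csv(path, W: int | None = None) -> GridMapping:
    """Read a ``channel,row,col`` CSV; W defaults to 1 + the largest index."""
    placements: dict[str, tuple[int, int]] = {}
    with open(path, newline="") as f:
        for rec in csv.DictReader(f):
            placements[rec["channel"]] = (int(rec["row"]), int(rec["col"]))
    if W is None:
        W = 1 + max(max(r, c) for r, c in placements.values())
    return GridMapping(placements, W)


def standard_mapping(montage: str) -> GridMapping:
    """One of the packaged montage grids (see module docstring)."""
    if montage not in MONTAGES:
        raise ValueError(f"unknown montage {montage!r}; supported: "
                         f"{sorted(MONTAGES)}")
    ref = resources.files("mi3d.data").joinpath(MONTAGES[montage])
    with resources.as_file(ref) as path:
        W = 9 if montage == "64ch-1020" else 7
        return load_mapping_csv(Path(path), W=W)


def to_3d(data2d: np.ndarray, mapping: GridMapping,
          channel_names: list[str] | None = None) -> np.ndarray:
    """Scatter an (N, T) array onto the (W, W, T) grid; empty cells are zero."""
    data2d = np.asarray(data2d, dtype=float)
    names = channel_names if channel_names is not None else mapping.channels
    if data2d.shape[0] != len(names):
        raise ValueError(f"{data2d.shape[0]} rows for {len(names)} channel names")
    missing = [n for n in names if n not in mapping.placements]
    if missing:
        raise ValueError(f"channels not in the mapping: {missing[:5]}")
    W = mapping.W
    out = np.zeros((W, W, data2d.shape[1]))
    for i, name in enumerate(names):
        r, c = mapping.placements[name]
        out[r, c] = data2d[i]
    return out


def gather_2d(tensor: np.ndarray, mapping: GridMapping,
              channel_names: list[str] | None = None) -> np.ndarray:
    """Inverse of :func:`to_3d`: collect channel rows back from their cells."""
    names = channel_names if channel_names is not None else mapping.channels
    return np.stack([tensor[mapping.placements[n][0], mapping.placements[n][1]]
                     for n in names])


def rotate90(tensor: np.ndarray,
             mapping: GridMapping | None = None):
    """Rotate the spatial plane by 90 degrees; the T axis is untouched.

    Cell ``(r, c)`` moves to ``(c, W-1-r)``.  With a mapping supplied, the
    rotated mapping is returned alongside the tensor so round trips stay
    consistent.
    """
    if tensor.shape[0] != tensor.shape[1]:
        raise ValueError("spatial plane must be square")
    W = tensor.shape[0]
    out = np.zeros_like(tensor)
    for r in range(W):
        for c in range(W):
            out[c, W - 1 - r] = tensor[r, c]
    if mapping is None:
        return out
    rotated = GridMapping({n: (c, W - 1 - r)
                           for n, (r, c) in mapping.placements.items()}, W)
    return out, rotated


def trials_to_tensors(ts: TrialSet, mapping: GridMapping) -> np.ndarray:
    """Stack per-trial (W, W, T) tensors into (n_trials, W, W, T)."""
    return np.stack([to_3d(X, mapping, list(ts.channel_names))
                     for X in ts.trials])
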