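"""Synthetic Elekta-like sensor layout.

A TRIUX-style system carries 102 sensor sites, each holding one magnetometer
and an orthogonal pair of planar gradiometers (306 channels in total).  For
sensor-space cluster statistics the helmet is flattened onto a 2D grid; here
the flattening is an 11-column x 10-row rectangle with the four corner pairs
left empty (110 cells, 102 occupied), which is all the downstream statistics
require of the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

N_SITES = 102
GRID_ROWS = 10
GRID_COLS = 11
# corner cells left unoccupied so that 10 * 11 - 8 = 102
_UNUSED_CELLS = frozenset(
    {(0, 0), (0, 1), (0, GRID_COLS - 1), (0, GRID_COLS - 2),
     (GRID_ROWS - 1, 0), (GRID_ROWS - 1, 1),
     (GRID_ROWS - 1, GRID_COLS - 1), (GRID_ROWS - 1, GRID_COLS - 2)}
)

ChannelKind = Literal["planar_grad", "magnetometer"]


@dataclass(frozen=True)
class ChannelInfo:
    """One MEG channel: a planar gradiometer (fT/cm) or magnetometer (fT)."""

    name: str
    kind: ChannelKind
    site: int
    pair_index: int | None  # channel index of the planar partner, None for mags
    pos2d: tuple[int, int]  # (row, col) cell in the flattened layout


def site_cells() -> list[tuple[int, int]]:
    """Grid cells occupied by sensor sites, row-major, one per site."""
    cells = [
        (r, c)
        for r in range(GRID_ROWS)
        for c in range(GRID_COLS)
        if (r, c) not in _UNUSED_CELLS
    ]
    assert len(cells) == N_SITES
    return cells


def make_channels() -> list[ChannelInfo]:
    """Full 306-channel list: per site, two planar gradiometers then one
    magnetometer, sites in row-major grid order."""
    channels: list[ChannelInfo] = []
    for site, cell in enumerate(site_cells()):
        base = 3 * site
        channels.append(
            ChannelInfo(f"GRAD{site:03d}A", "planar_grad", site, base + 1, cell)
        )
        channels.append(
            ChannelInfo(f"GRAD{site:03d}B", "planar_grad", site, base, cell)
        )
        channels.append(
            ChannelInfo(f"MAG{site:03d}", "magnetometer", site, None, cell)
        )
    return channels


def site_grid() -> np.ndarray:
    """(rows, cols) int array mapping each layout cell to its site index,
    -1 for structurally empty cells."""
    grid = np.full((GRID_ROWS, GRID_COLS), -1, dtype=int)
    for site, (r, c) in enumerate(site_cells()):
        grid[r, c] = site
    return grid


def occupied_mask() -> np.ndarray:
    """Boolean (rows, cols) mask of cells that hold a sensor site."""
    return site_grid() >= 0


def auditory_sites() -> np.ndarray:
    """Site indices of the two temporal patches used as the synthetic
    auditory-response generators (3 x 3 sites on each side of the helmet)."""
    grid = site_grid()
    rows = slice(4, 7)
    left = grid[rows, 1:4].ravel()
    right = grid[rows, GRID_COLS - 4:GRID_COLS - 1].ravel()
    sites = np.concatenate([left, right])
    return sites[sites >= 0]


def channel_indices(channels: list[ChannelInfo], kind: ChannelKind) -> np.ndarray:
    return np.array([i for i, ch in enumerate(channels) if ch.kind == kind])
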