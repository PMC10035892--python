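"""Readers, writers, masks and the deterministic fixture battery.

Patterns travel in two interchangeable formats: a plain text grid (header
"width height [depth]" then one R/Y/. character per site, row-major) and a
raster (PNG/TIFF) in which pure red marks mutants, pure yellow wild-type and
everything else background — a stand-in for the colour conventions of
mutation-specific in-situ staining.  Raster classification is
nearest-reference-colour within a configurable tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .patterns import (EMPTY, RED, YELLOW, ClassGrid, class_ratio,
                       generate_centred, generate_clusters, generate_column)

__all__ = [
    "ColourMap",
    "RegionMask",
    "read_pattern",
    "write_pattern",
    "read_text_grid",
    "write_text_grid",
    "extract_subregion",
    "make_fixtures",
]

_CHAR = {EMPTY: ".", YELLOW: "Y", RED: "R"}
_LABEL = {v: k for k, v in _CHAR.items()}
_TEXT_SUFFIXES = {".txt", ".grid", ".tsv"}


@dataclass
class ColourMap:
    """Reference colours for raster classification.

    A pixel is assigned the class of the nearest reference colour if its
    squared RGB distance is within ``tolerance**2``; otherwise EMPTY.
    """

    red: tuple = (255, 0, 0)
    yellow: tuple = (255, 255, 0)
    tolerance: float = 60.0

    def __post_init__(self) -> None:
        if tuple(self.red) == tuple(self.yellow):
            raise ValueError("reference colours must be distinct")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class RegionMask:
    """Boolean mask delineating one locally connected tumour sub-region."""

    mask: np.ndarray
    note: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def write_text_grid(grid: ClassGrid, path) -> None:
    labels = grid.labels
    with open(path, "w") as fh:
        if labels.ndim == 2:
            fh.write(f"{grid.width} {grid.height}\n")
            planes = [labels]
        else:
            fh.write(f"{grid.width} {grid.height} {grid.depth}\n")
            planes = list(labels)
        for plane in planes:
            for row in plane:
                fh.write("".join(_CHAR[v] for v in row) + "\n")


def read_text_grid(path) -> ClassGrid:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) == 2:
            w, h = map(int, header)
            d = 1
        elif len(header) == 3:
            w, h, d = map(int, header)
        else:
            raise ValueError(f"bad text-grid header in {path}")
        rows = [line.rstrip("\n") for line in fh if line.strip()]
    if len(rows) != h * d:
        raise ValueError(f"expected {h * d} rows, found {len(rows)} in {path}")
    arr = np.array([[_LABEL[ch] for ch in row] for row in rows], dtype=np.int8)
    if arr.shape[1] != w:
        raise ValueError(f"row width mismatch in {path}")
    labels = arr if d == 1 else arr.reshape(d, h, w)
    return ClassGrid(labels)


def write_pattern(grid: ClassGrid, path, colour_map: ColourMap | None = None) -> None:
    """Write a pattern as text grid or raster depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        write_text_grid(grid, path)
        return
    if grid.labels.ndim != 2:
        raise ValueError("raster output supports 2-D grids only")
    cm = colour_map or ColourMap()
    rgb = np.zeros((grid.height, grid.width, 3), dtype=np.uint8)
    rgb[grid.labels == RED] = cm.red
    rgb[grid.labels == YELLOW] = cm.yellow
    Image.fromarray(rgb).save(path)


def read_pattern(path, colour_map: ColourMap | None = None) -> ClassGrid:
    """Read a text grid or raster into a ClassGrid.

    Raster pixels are matched to the nearest reference colour within the
    colour map's tolerance; unmatched pixels become EMPTY.
    """
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return read_text_grid(path)
    cm = colour_map or ColourMap()
    rgb = np.asarray(Image.open(path).convert("RGB"), dtype=np.int64)
    d_red = ((rgb - np.array(cm.red)) ** 2).sum(axis=-1)
    d_yel = ((rgb - np.array(cm.yellow)) ** 2).sum(axis=-1)
    tol2 = cm.tolerance ** 2
    labels = np.full(rgb.shape[:2], EMPTY, dtype=np.int8)
    labels[(d_red <= d_yel) & (d_red <= tol2)] = RED
    labels[(d_yel < d_red) & (d_yel <= tol2)] = YELLOW
    grid = ClassGrid(labels)
    if grid.n_red + grid.n_yellow == 0:
        raise ValueError(f"no coloured pixels recognised in {path}")
    return grid


def extract_subregion(grid: ClassGrid, mask: RegionMask) -> ClassGrid:
    """Blank everything outside the mask and crop to its bounding box."""
    if mask.mask.shape != grid.labels.shape:
        raise ValueError("mask dimensions must equal grid dimensions")
    if not mask.mask.any():
        raise ValueError("mask is empty")
    labels = np.where(mask.mask, grid.labels, EMPTY).astype(np.int8)
    idx = np.nonzero(mask.mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return ClassGrid(labels[sl])


def make_fixtures(out_dir, seed: int = 0) -> pd.DataFrame:
    """Write the deterministic fixture battery used by tests and docs.

    Produces toy rows, the 54x54 reference patterns (segregated /
    checkerboard / clusters / centred / column), three small simulated
    tumours and a mini inference library, plus a manifest TSV listing every
    pattern with its class ratio.
    """
    from .cmfpt import WalkConfig
    from .growth_sim import SimParams, simulate_tumour
    from .inference import build_library

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grids = {}
    grids["row_ryr.txt"] = ClassGrid(np.array([[RED, YELLOW, RED]], dtype=np.int8))
    grids["row_ry.txt"] = ClassGrid(np.array([[RED, YELLOW]], dtype=np.int8))
    grids["segregated_54.txt"] = generate_column(54, 54, 0.5)
    board = np.indices((54, 54)).sum(axis=0) % 2
    grids["checkerboard_54.txt"] = ClassGrid(
        np.where(board == 0, RED, YELLOW).astype(np.int8))
    grids["clusters_54.txt"] = generate_clusters(54, 54, 0.3, 3, seed=seed)
    grids["centred_54.txt"] = generate_centred(54, 54, 0.3)
    grids["column_54.txt"] = generate_column(54, 54, 0.3)
    for i, (s, q) in enumerate(((0.0, 0), (1.0, 5), (3.0, 0))):
        grid, _ = simulate_tumour(SimParams(
            s=s, n_mut=0.05, q=q, n_max=800, seed=seed + i))
        grids[f"tumour_s{s:g}_q{q}.txt"] = grid
    manifest = []
    for name, grid in grids.items():
        write_text_grid(grid, out_dir / name)
        manifest.append(dict(file=name, phi=class_ratio(grid),
                             width=grid.width, height=grid.height))
    build_library(
        s_grid=(0.0, 3.0), nmut_grid=(0.05, 0.5), q_grid=(0, 5),
        reps_per_combo=25, base_seed=seed, n_max=400,
        walk_config=WalkConfig(walks_per_start=100, null_reps=2),
        target_bins=400, out_path=str(out_dir / "mini_library.tsv"))
    mdf = pd.DataFrame(manifest)
    mdf.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return mdf
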