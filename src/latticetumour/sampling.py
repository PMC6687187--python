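"""Spatially defined cell subsets: punch/needle biopsies, whole tumour,
concentric-ring samples and single-cell draws.

A bulk sample is a set of adjacent live cells cut out of the final tumour;
for every mutation carried by at least one member the sample records the
cellular fraction (exact count / sample size — sequencing noise is applied
later) together with a clone annotation: truncal (carried by every live
cell of the whole tumour), subclone_founding (present in the first mutant
cell at the driver event), background (absent from the mutant subclone),
subclone (exclusive to the mutant), or shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import MUT, WT, TumourState

CLONE_LABELS = ("truncal", "subclone_founding", "background", "subclone", "shared")


class EmptyRegionError(ValueError):
    pass


@dataclass
class RegionSpec:
    """Geometry of a bulk sample on the lattice (0-based, closed on all sides)."""

    shape: str  # square | rectangle | whole | ring-arc
    anchor: tuple | None = None  # centre for squares, corner ignored
    width: int | None = None
    length: int | None = None
    thickness: int | None = None
    axis: int = 0
    ring_index: int | None = None
    direction: str | None = None

    def describe(self) -> str:
        if self.shape == "whole":
            return "whole tumour"
        if self.shape == "square":
            return f"square w={self.width} @ {self.anchor}"
        if self.shape == "rectangle":
            return (
                f"rectangle len={self.length} thick={self.thickness} "
                f"axis={self.axis} @ {self.anchor}"
            )
        return f"ring {self.ring_index}{self.direction or ''}"


@dataclass
class BulkSample:
    sample_id: str
    region: RegionSpec
    cell_ids: np.ndarray
    mutations: pd.DataFrame  # columns: id, n, clone

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _node_annotations(state: TumourState) -> np.ndarray:
    """Clone annotation per lineage node, cached on the state.

    Every mutation introduced at a node inherits the node's annotation.
    """
    cached = getattr(state, "_node_annotation_cache", None)
    if cached is not None and cached[0] == state.n_cells:
        return cached[1]
    _, _, clone, node, _ = state.as_arrays()
    tree = state.lineage
    n_all = tree.subtree_cell_counts(node)
    n_mut = tree.subtree_cell_counts(node[clone == MUT]) if (clone == MUT).any() else None
    total = state.n_cells
    ann = np.full(len(tree), -1, dtype=np.int8)
    driver_nodes = state.driver_path_nodes or frozenset()
    for v in range(len(tree)):
        if n_all[v] == total:
            ann[v] = 0  # truncal
        elif v in driver_nodes:
            ann[v] = 1  # subclone_founding
        elif n_mut is None or n_mut[v] == 0:
            ann[v] = 2  # background
        elif n_mut[v] == n_all[v]:
            ann[v] = 3  # subclone
        else:
            ann[v] = 4  # shared
    state._node_annotation_cache = (state.n_cells, ann)
    return ann


def cellular_fractions(state: TumourState, cell_ids: np.ndarray) -> pd.DataFrame:
    """Exact per-mutation cellular fractions among ``cell_ids``.

    Returns a frame with columns id, n (fraction in (0, 1]) and clone.
    """
    cell_ids = np.asarray(cell_ids)
    if len(cell_ids) == 0:
        raise EmptyRegionError("cannot compute fractions of an empty cell set")
    tree = state.lineage
    nodes = np.array([state.cells[int(c)].node for c in cell_ids], dtype=np.int64)
    counts = tree.subtree_cell_counts(nodes)
    ann = _node_annotations(state)
    ids, fracs, labels = [], [], []
    mut_n = tree.mut_n
    mut_start = tree.mut_start
    m = len(cell_ids)
    for v in np.nonzero(counts)[0]:
        k = mut_n[v]
        if not k:
            continue
        s = mut_start[v]
        ids.append(np.arange(s, s + k, dtype=np.int64))
        fracs.append(np.full(k, counts[v] / m))
        labels.append(np.full(k, ann[v], dtype=np.int8))
    if ids:
        ids = np.concatenate(ids)
        fracs = np.concatenate(fracs)
        labels = np.concatenate(labels)
    else:
        ids = np.empty(0, dtype=np.int64)
        fracs = np.empty(0)
        labels = np.empty(0, dtype=np.int8)
    return pd.DataFrame(
        {"id": ids, "n": fracs, "clone": np.asarray(CLONE_LABELS)[labels]}
    )


def _sample_from_mask(state: TumourState, mask: np.ndarray, sample_id: str,
                      region: RegionSpec) -> BulkSample:
    ids, _, _, _, _ = state.as_arrays()
    members = ids[mask]
    if len(members) == 0:
        raise EmptyRegionError(f"region {region.describe()} contains no live cell")
    return BulkSample(sample_id, region, members, cellular_fractions(state, members))


def punch_biopsy(state: TumourState, centre: tuple, width: int,
                 sample_id: str = "punch") -> BulkSample:
    """Square (cube in 3D) sample of side ``width`` centred at ``centre``."""
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    region = RegionSpec("square", anchor=tuple(centre), width=width)
    _, pos, _, _, _ = state.as_arrays()
    lo = np.asarray(centre) - (width - 1) // 2
    hi = np.asarray(centre) + width // 2
    mask = np.all((pos >= lo) & (pos <= hi), axis=1)
    return _sample_from_mask(state, mask, sample_id, region)


def needle_biopsy(state: TumourState, anchor: tuple, length: int,
                  thickness: int = 3, axis: int = 0,
                  sample_id: str = "needle") -> BulkSample:
    """Long thin axis-aligned rectangle: ``length`` along ``axis``, centred
    transversally on ``anchor``."""
    if length < 1 or thickness < 1:
        raise ValueError("length and thickness must be >= 1")
    region = RegionSpec(
        "rectangle", anchor=tuple(anchor), length=length, thickness=thickness, axis=axis
    )
    _, pos, _, _, _ = state.as_arrays()
    anchor = np.asarray(anchor)
    lo = anchor.copy()
    hi = anchor.copy()
    for ax in range(state.params.dims):
        if ax == axis:
            lo[ax] = anchor[ax] - (length - 1) // 2
            hi[ax] = anchor[ax] + length // 2
        else:
            lo[ax] = anchor[ax] - (thickness - 1) // 2
            hi[ax] = anchor[ax] + thickness // 2
    mask = np.all((pos >= lo) & (pos <= hi), axis=1)
    return _sample_from_mask(state, mask, sample_id, region)


def whole_tumour(state: TumourState, sample_id: str = "whole_tumour") -> BulkSample:
    """All live cells; truncal mutations have fraction exactly 1."""
    ids, _, _, _, _ = state.as_arrays()
    region = RegionSpec("whole")
    return BulkSample(sample_id, region, ids.copy(), cellular_fractions(state, ids))


def concentric_samples(state: TumourState, n_rings: int,
                       directions=("W", "E", "N", "S"),
                       metric: str = "chebyshev") -> list[BulkSample]:
    """Central sample C1 plus ring-arc samples at increasing radial distance.

    Rings are square annuli (Chebyshev metric, the lattice-consistent
    reading of concentric circles; Euclidean behind ``metric='euclidean'``)
    split into four directional arcs labelled W/E/N/S by the side on which
    the site lies.  Empty arcs are skipped.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    _, pos, _, _, _ = state.as_arrays()
    o = np.asarray(state.origin)
    delta = pos - o
    if metric == "euclidean":
        r = np.sqrt((delta**2).sum(axis=1))
        rmax = r.max()
    else:
        r = np.abs(delta).max(axis=1)
        rmax = state.R
    ring_w = max(rmax / n_rings, 1.0)
    out = []
    mask = r < ring_w
    if mask.any():
        out.append(
            _sample_from_mask(
                state, mask, "C1", RegionSpec("ring-arc", ring_index=1)
            )
        )
    dx = delta[:, 0]
    dy = delta[:, 1] if state.params.dims >= 2 else np.zeros_like(dx)
    side = {
        "E": (dx >= np.abs(dy)),
        "W": (-dx >= np.abs(dy)),
        "N": (dy > np.abs(dx)),
        "S": (-dy > np.abs(dx)),
    }
    for k in range(2, n_rings + 1):
        annulus = (r >= (k - 1) * ring_w) & (r < k * ring_w)
        for d in directions:
            mask = annulus & side[d]
            if not mask.any():
                continue
            region = RegionSpec("ring-arc", ring_index=k, direction=d)
            out.append(_sample_from_mask(state, mask, f"{k}{d}", region))
    return out


def default_multiregion_design(state: TumourState, n_punches: int = 6,
                               punch_width: int | None = None,
                               needle_thickness: int = 3) -> list[BulkSample]:
    """The reproducible default layout: ``n_punches`` punches at evenly
    spaced angles at half-radius, plus two orthogonal needle biopsies
    through the centre, plus the whole tumour."""
    R = max(state.R, 2)
    if punch_width is None:
        punch_width = max(3, int(round(R / 3)))
    o = np.asarray(state.origin[:2])
    samples = []
    for i in range(n_punches):
        theta = 2.0 * np.pi * i / n_punches
        c = o + np.round(0.5 * R * np.array([np.cos(theta), np.sin(theta)])).astype(int)
        centre = tuple(c) + state.origin[2:]
        samples.append(punch_biopsy(state, centre, punch_width, sample_id=f"punch_{i+1}"))
    length = int(2.2 * R)
    for j, axis in enumerate((0, 1)):
        samples.append(
            needle_biopsy(
                state,
                state.origin,
                length,
                thickness=needle_thickness,
                axis=axis,
                sample_id=f"needle_{n_punches + j + 1}",
            )
        )
    samples.append(whole_tumour(state))
    return samples


def sample_single_cells_random(state: TumourState, n: int, rng=None) -> np.ndarray:
    """Uniform sample of ``n`` live cell ids without replacement."""
    rng = rng or state.rng
    ids, _, _, _, _ = state.as_arrays()
    if n > len(ids):
        raise ValueError(f"requested {n} cells from a population of {len(ids)}")
    return np.sort(rng.choice(ids, size=n, replace=False))


def sample_single_cells_from_bulks(state: TumourState, bulks: list[BulkSample],
                                   n_per_bulk: int, rng=None) -> pd.DataFrame:
    """Uniform sample within each bulk; provenance tag retained.

    Returns a frame with columns cell_id and bulk (the bulk's sample_id).
    """
    rng = rng or state.rng
    rows = []
    for b in bulks:
        k = min(n_per_bulk, b.n_cells)
        chosen = rng.choice(b.cell_ids, size=k, replace=False)
        for c in np.sort(chosen):
            rows.append((int(c), b.sample_id))
    return pd.DataFrame(rows, columns=["cell_id", "bulk"])


def sample_manifest(samples: list[BulkSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "shape": s.region.shape,
                "anchor": "" if s.region.anchor is None else str(tuple(s.region.anchor)),
                "dims": s.region.width or s.region.length or "",
                "n_cells": s.n_cells,
            }
        )
    return pd.DataFrame(rows)
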