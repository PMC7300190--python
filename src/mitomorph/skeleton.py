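"""Skeletonization and branch/junction metrics of the binarized network.

Pixels of a unit-width 8-connected skeleton are classified by their
8-neighbor count: endpoints (< 2 neighbors), slab pixels (exactly 2) and
junction pixels (> 2).  A *branch* is a maximal slab path connecting two
anchors (endpoints or junctions); its length accumulates 1 per straight
step and √2 per diagonal step, times the pixel size.  Components without
any junction pixel are *individuals* (punctate or rod mitochondria, one
branch each); components with junctions are *networks*.  ``n_junctions``
reports raw junction pixels (the pixel-count definition); adjacent
junction pixels are additionally merged into junction *nodes* for branch
tracing, and the merged count is recorded alongside.

Z-stacks are analyzed on the max projection of the mask by default
(per-slice mode is available through the pipeline configuration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label as sk_label
from skimage.morphology import skeletonize as sk_skeletonize

from .core import BinaryMask

__all__ = ["SkeletonSummary", "skeletonize", "analyze_skeleton"]

# fixed neighbor scan order: N, NE, E, SE, S, SW, W, NW — deterministic tracing
_OFFSETS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


@dataclass
class SkeletonSummary:
    n_branches: int
    n_junctions: int
    n_junction_nodes: int
    n_individuals: int
    n_networks: int
    mean_branch_length_um: float
    mean_network_size: float
    footprint_um2: float
    branches: pd.DataFrame = field(repr=False, default=None)


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Topology-preserving thinning to a unit-width 8-connected skeleton."""
    pix = mask.pixels
    if pix.dtype != bool:
        raise ValueError("skeletonize requires a binary mask")
    if mask.is_stack:
        skel = np.stack([sk_skeletonize(s) for s in pix])
    else:
        skel = sk_skeletonize(pix)
    prov = dict(mask.provenance)
    prov["skeletonized"] = True
    return BinaryMask(skel, mask.pixel_size_um, provenance=prov)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=np.int8)
    k[1, 1] = 0
    return ndi.convolve(skel.astype(np.int8), k, mode="constant", cval=0)


def _step(a: tuple, b: tuple) -> float:
    return math.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0


def analyze_skeleton(
    skel: BinaryMask,
    calibration: float | None = None,
    footprint_um2: float = float("nan"),
) -> SkeletonSummary:
    """Branch/junction metrics of a unit-width skeleton (2-D).

    ``footprint_um2`` is the area of the pre-skeleton mask and is carried
    through to the summary (it cannot be recovered from the skeleton).
    """
    if skel.is_stack:
        raise ValueError("analyze_skeleton expects a 2D skeleton; project or select a slice")
    cal = skel.pixel_size_um if calibration is None else float(calibration)
    pix = skel.pixels
    if pix.dtype != bool:
        raise ValueError("skeleton must be binary")

    nn = _neighbor_counts(pix)
    junction_px = pix & (nn > 2)
    n_junctions = int(junction_px.sum())
    junction_nodes = sk_label(junction_px, connectivity=2)
    n_junction_nodes = int(junction_nodes.max())

    comp = sk_label(pix, connectivity=2)
    n_comp = int(comp.max())

    in_skel = pix
    node_of = junction_nodes  # 0 where not a junction pixel

    def neighbors(p):
        y, x = p
        for dy, dx in _OFFSETS:
            q = (y + dy, x + dx)
            if 0 <= q[0] < pix.shape[0] and 0 <= q[1] < pix.shape[1] and in_skel[q]:
                yield q

    rows = []
    n_individuals = n_networks = 0
    branches_per_network = []

    slices = ndi.find_objects(comp)
    for ci in range(1, n_comp + 1):
        sl = slices[ci - 1]
        ys, xs = np.nonzero(comp[sl] == ci)
        pts = [(int(y + sl[0].start), int(x + sl[1].start)) for y, x in zip(ys, xs)]
        pts.sort()
        comp_j = [p for p in pts if node_of[p] > 0]
        comp_e = [p for p in pts if nn[p] < 2]

        if not comp_j:
            # individual: exactly one branch (point, path or cycle)
            n_individuals += 1
            if len(pts) == 1:
                length = 0.0
            elif comp_e:
                start = comp_e[0]
                prev, cur, length = None, start, 0.0
                while True:
                    nxt = [q for q in neighbors(cur) if q != prev]
                    if not nxt:
                        break
                    prev, length, cur = cur, length + _step(cur, nxt[0]), nxt[0]
            else:  # pure cycle: closed-walk length
                start = pts[0]
                prev, cur, length = None, start, 0.0
                while True:
                    nxt = [q for q in neighbors(cur) if q != prev]
                    step_to = nxt[0]
                    length += _step(cur, step_to)
                    prev, cur = cur, step_to
                    if cur == start:
                        break
            rows.append((ci, "individual", length * cal))
            continue

        n_networks += 1
        visited: set = set()
        n_br = 0
        anchors = sorted(set(comp_j) | set(comp_e))
        anchor_set = set(anchors)
        for a in anchors:
            for b in neighbors(a):
                if b in anchor_set:
                    # direct anchor-anchor contact; skip within one junction node,
                    # count each contact pair once (scan order)
                    if node_of[a] > 0 and node_of[a] == node_of[b]:
                        continue
                    if a < b:
                        n_br += 1
                        rows.append((ci, "contact", _step(a, b) * cal))
                    continue
                if b in visited:
                    continue
                # walk along slab pixels until the next anchor
                visited.add(b)
                length = _step(a, b)
                prev, cur = a, b
                while cur not in anchor_set:
                    nxt = [q for q in neighbors(cur) if q != prev]
                    if not nxt:
                        break  # dead end (endpoint already consumed)
                    prev, cur = cur, nxt[0]
                    length += _step(prev, cur)
                    if cur not in anchor_set:
                        visited.add(cur)
                n_br += 1
                rows.append((ci, "branch", length * cal))
        branches_per_network.append(n_br)

    branch_df = pd.DataFrame(rows, columns=["component", "kind", "length_um"])
    n_branches = n_individuals + int(sum(branches_per_network))
    lengths = branch_df["length_um"].to_numpy()
    return SkeletonSummary(
        n_branches=n_branches,
        n_junctions=n_junctions,
        n_junction_nodes=n_junction_nodes,
        n_individuals=n_individuals,
        n_networks=n_networks,
        mean_branch_length_um=float(lengths.mean()) if len(lengths) else 0.0,
        mean_network_size=float(np.mean(branches_per_network)) if branches_per_network else 0.0,
        footprint_um2=footprint_um2,
        branches=branch_df,
    )
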