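"""Structured graded Q8 mesh of the axisymmetric tissue cylinder.

The r-z cross-section (radius ``r_C`` = height = 110 mm) is meshed with
``10*N x 5*N`` 8-node serendipity quadrilaterals.  Element widths follow
geometric progressions: radial spacing grows by the factor ``bias_radial``
away from the axis (bias 1.1 toward the center) and axial spacing grows by
``1/bias_axial`` away from the top surface (bias 0.8 toward the top), so
resolution concentrates under and beside the indenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MeshSpec", "Mesh", "build_mesh"]


@dataclass(frozen=True)
class MeshSpec:
    """Mesh refinement specification; ``N=3`` gives the production 30x15 mesh."""

    N: int = 3
    r_c: float = 110.0
    height: float = 110.0
    bias_radial: float = 1.1
    bias_axial: float = 0.8

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("refinement factor N must be >= 1")
        if self.bias_radial <= 0 or self.bias_axial <= 0:
            raise ValueError("biases must be positive")

    @property
    def n_radial(self) -> int:
        return 10 * self.N

    @property
    def n_axial(self) -> int:
        return 5 * self.N


@dataclass
class Mesh:
    spec: MeshSpec
    nodes: np.ndarray  # (n_nodes, 2) reference coordinates (R, Z), mm
    conn: np.ndarray  # (n_elems, 8) Q8 connectivity
    node_sets: dict = field(default_factory=dict)
    top_edges: np.ndarray | None = None  # (n_top, 3) edge node triples (l, m, r)
    r_breaks: np.ndarray | None = None  # element boundaries along r
    z_breaks: np.ndarray | None = None  # element boundaries along z
    node_index: np.ndarray | None = None  # (2nr+1, 2na+1) grid -> node id (-1 at holes)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.conn.shape[0]

    @property
    def top_edge_nodes(self) -> np.ndarray:
        """Top-surface node indices sorted by initial radius."""
        return self.node_sets["top"]


def _graded_breaks(total: float, n: int, ratio: float) -> np.ndarray:
    """n interval widths in geometric progression w_{i+1} = ratio * w_i."""
    if abs(ratio - 1.0) < 1e-12:
        w = np.full(n, total / n)
    else:
        w0 = total * (ratio - 1.0) / (ratio**n - 1.0)
        w = w0 * ratio ** np.arange(n)
    breaks = np.concatenate([[0.0], np.cumsum(w)])
    breaks[-1] = total
    return breaks


def build_mesh(spec: MeshSpec) -> Mesh:
    """Build the graded Q8 sector cross-section mesh with its node sets.

    The bias factors define the per-element width progression of the
    production mesh (``N=3``, 30x15 elements); other refinement levels
    subdivide the same spatial grading profile (per-element ratio
    ``bias**(3/N)``), so refining ``N`` adds resolution without moving the
    grading.
    """
    nr, na = spec.n_radial, spec.n_axial
    ratio_r = spec.bias_radial ** (30.0 / nr)
    ratio_a = spec.bias_axial ** (15.0 / na)
    # radial: fine at the axis, widths grow outward
    r_breaks = _graded_breaks(spec.r_c, nr, ratio_r)
    # axial (bottom z=0 .. top z=H): fine at the top; build from the top down
    h_from_top = np.diff(_graded_breaks(spec.height, na, 1.0 / ratio_a))
    z_breaks = spec.height - np.concatenate([[0.0], np.cumsum(h_from_top)])[::-1]
    z_breaks[0] = 0.0
    if np.any(np.diff(r_breaks) <= 0) or np.any(np.diff(z_breaks) <= 0):
        raise ValueError("bias produces inverted elements")

    # half-index grids (element boundaries at even indices, midsides at odd)
    r_half = np.empty(2 * nr + 1)
    r_half[0::2] = r_breaks
    r_half[1::2] = 0.5 * (r_breaks[:-1] + r_breaks[1:])
    z_half = np.empty(2 * na + 1)
    z_half[0::2] = z_breaks
    z_half[1::2] = 0.5 * (z_breaks[:-1] + z_breaks[1:])

    index = -np.ones((2 * nr + 1, 2 * na + 1), dtype=int)
    coords = []
    k = 0
    for j in range(2 * na + 1):
        for i in range(2 * nr + 1):
            if i % 2 == 1 and j % 2 == 1:
                continue  # Q8 has no interior center node
            index[i, j] = k
            coords.append((r_half[i], z_half[j]))
            k += 1
    nodes = np.asarray(coords)

    conn = np.empty((nr * na, 8), dtype=int)
    e = 0
    for j in range(na):
        for i in range(nr):
            i0, j0 = 2 * i, 2 * j
            conn[e] = [
                index[i0, j0],          # (-1,-1)
                index[i0 + 2, j0],      # (+1,-1)
                index[i0 + 2, j0 + 2],  # (+1,+1)
                index[i0, j0 + 2],      # (-1,+1)
                index[i0 + 1, j0],      # ( 0,-1)
                index[i0 + 2, j0 + 1],  # (+1, 0)
                index[i0 + 1, j0 + 2],  # ( 0,+1)
                index[i0, j0 + 1],      # (-1, 0)
            ]
            e += 1

    R, Z = nodes[:, 0], nodes[:, 1]
    axis = np.nonzero(np.abs(R) < 1e-12)[0]
    bottom = np.nonzero(np.abs(Z) < 1e-12)[0]
    top = np.nonzero(np.abs(Z - spec.height) < 1e-12)[0]
    top = top[np.argsort(R[top])]

    top_row = conn[(na - 1) * nr : na * nr]
    top_edges = top_row[:, [3, 6, 2]]  # (left, mid, right) on eta = +1

    return Mesh(
        spec=spec,
        nodes=nodes,
        conn=conn,
        node_sets={"axis": axis, "bottom": bottom, "top": top},
        top_edges=top_edges,
        r_breaks=r_breaks,
        z_breaks=z_breaks,
        node_index=index,
    )
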