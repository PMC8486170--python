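"""Spatial domains: 1D chains and hexagonal 2D patches, with the discrete
diffusion operator.

Diffusion on the lattice is the unnormalised graph Laplacian

    (L f)[i] = sum_{j ~ i} f[j]  -  deg(i) * f[i]

with unit site spacing, so a diffusion coefficient ``D`` enters the Euler
update as ``D * (L f)[i]`` and carries units lattice-length^2 / time.
Boundary sites simply have fewer neighbours, which makes the boundary
zero-flux (reflecting) — the natural condition for a closed Petri dish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Lattice",
    "build_lattice_1d",
    "build_lattice_hex",
    "graph_laplacian_apply",
    "nodes_within_distance",
]


@dataclass
class Lattice:
    """A spatial domain: node adjacency plus a planar embedding.

    Attributes
    ----------
    kind : {"chain_1d", "hex_2d"}
    neighbors : list of numpy index arrays, one per node
    positions : (n, 2) array of planar coordinates, unit nearest-neighbour
        spacing
    """

    kind: str
    neighbors: list
    positions: np.ndarray
    shape: tuple = ()
    _laplacian: sp.csr_array = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.neighbors)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    def laplacian_matrix(self) -> sp.csr_array:
        """Sparse A - D operator, cached after first use."""
        if self._laplacian is None:
            rows, cols = [], []
            for i, nb in enumerate(self.neighbors):
                rows.extend([i] * len(nb))
                cols.extend(nb)
            data = np.ones(len(rows))
            adj = sp.csr_array(
                (data, (rows, cols)), shape=(self.n_nodes, self.n_nodes)
            )
            deg = sp.dia_array(
                (self.degrees[None, :].astype(float), [0]),
                shape=(self.n_nodes, self.n_nodes),
            )
            self._laplacian = (adj - deg).tocsr()
        return self._laplacian

    def center_node(self) -> int:
        """Node nearest (Euclidean) to the centroid of the embedding.

        For an even-length chain this is the site at index ``n // 2``.
        """
        if self.kind == "chain_1d":
            return self.n_nodes // 2
        centroid = self.positions.mean(axis=0)
        d2 = np.sum((self.positions - centroid) ** 2, axis=1)
        return int(np.argmin(d2))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, nb in enumerate(self.neighbors):
            g.add_node(i, pos=tuple(self.positions[i]))
            g.add_edges_from((i, int(j)) for j in nb if j > i)
        return g

    def save(self, edges_path, positions_path) -> None:
        """Write an edge list and a node/x/y position table (TSV)."""
        with open(edges_path, "w") as fh:
            for i, nb in enumerate(self.neighbors):
                for j in nb:
                    if j > i:
                        fh.write(f"{i}\t{j}\n")
        pd.DataFrame(
            {
                "node": np.arange(self.n_nodes),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        ).to_csv(positions_path, sep="\t", index=False)


def _from_graph(g: nx.Graph, kind: str, shape: tuple) -> Lattice:
    n = g.number_of_nodes()
    neighbors = [np.array(sorted(g.neighbors(i)), dtype=np.intp) for i in range(n)]
    positions = np.array([g.nodes[i]["pos"] for i in range(n)], dtype=float)
    return Lattice(kind=kind, neighbors=neighbors, positions=positions, shape=shape)


def build_lattice_1d(n_sites: int) -> Lattice:
    """Chain of ``n_sites`` nodes at integer positions, unit spacing."""
    if n_sites < 3:
        raise ValueError(f"a 1D chain needs at least 3 sites, got {n_sites}")
    g = nx.path_graph(n_sites)
    for i in g.nodes:
        g.nodes[i]["pos"] = (float(i), 0.0)
    return _from_graph(g, "chain_1d", (n_sites,))


def build_lattice_hex(width: int, height: int) -> Lattice:
    """Hexagonal (triangular-tiling) patch of ``width * height`` sites.

    Axial indexing: node (q, r) sits at planar position
    ``(q + r/2, r*sqrt(3)/2)``, so every interior node has six neighbours
    all at unit distance.  The patch is a rhombus of width columns by
    height rows.
    """
    if width < 3 or height < 3:
        raise ValueError(
            f"hex patch needs width, height >= 3, got {width}x{height}"
        )
    idx = lambda q, r: r * width + q
    g = nx.Graph()
    for r in range(height):
        for q in range(width):
            g.add_node(idx(q, r), pos=(q + 0.5 * r, r * np.sqrt(3) / 2.0))
    # axial-coordinate neighbour offsets of a triangular tiling
    offsets = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1)]
    for r in range(height):
        for q in range(width):
            for dq, dr in offsets:
                q2, r2 = q + dq, r + dr
                if 0 <= q2 < width and 0 <= r2 < height:
                    g.add_edge(idx(q, r), idx(q2, r2))
    return _from_graph(g, "hex_2d", (width, height))


def graph_laplacian_apply(lattice: Lattice, field_values) -> np.ndarray:
    """Apply the zero-flux graph Laplacian to a per-node field."""
    f = np.asarray(field_values, dtype=float)
    if f.shape != (lattice.n_nodes,):
        raise ValueError(
            f"field has shape {f.shape}, lattice has {lattice.n_nodes} nodes"
        )
    return lattice.laplacian_matrix() @ f


def nodes_within_distance(lattice: Lattice, center: int, d: float) -> set:
    """All nodes within Euclidean distance ``d`` of ``center`` in the
    planar embedding (the center itself included)."""
    if not (0 <= center < lattice.n_nodes):
        raise ValueError(f"invalid center node {center}")
    if d < 0:
        raise ValueError("distance must be non-negative")
    delta = lattice.positions - lattice.positions[center]
    dist = np.hypot(delta[:, 0], delta[:, 1])
    return set(np.flatnonzero(dist <= d + 1e-12).tolist())
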