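"""Spatial computations on protein chains.

Covers the residue neighbourhood constructions the feature set depends on:

* Euclidean neighbour graph — residues whose minimum heavy-atom distance is
  within a radius (default 10 Å);
* Voronoi adjacency — residue pairs whose atoms share a Voronoi facet, with a
  dummy-point shell bounding the surface cells;
* Delaunay tetrahedra over one representative point per residue (Cα);
* per-residue atom/residue contact counts;
* side-chain geometric centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi, cKDTree

from .structures import Chain, Residue

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
NEIGHBOR_RADIUS = 10.0
CONTACT_CUTOFF = 5.0
SHELL_MARGIN = 15.0


class GeometryError(ValueError):
    """Raised for degenerate point configurations."""


@dataclass
class NeighborGraph:
    """Symmetric residue graph with minimum heavy-atom distances (Å)."""

    n: int
    radius: float
    edges: dict[int, dict[int, float]] = field(default_factory=dict)

    def neighbors(self, i: int) -> dict[int, float]:
        return self.edges.get(i, {})

    def degree(self, i: int) -> int:
        return len(self.edges.get(i, {}))

    def to_tsv(self) -> str:
        lines = ["residue_i\tresidue_j\tdistance"]
        for i in sorted(self.edges):
            for j, d in sorted(self.edges[i].items()):
                if i < j:
                    lines.append(f"{i}\t{j}\t{d:.4f}")
        return "\n".join(lines) + "\n"


@dataclass
class VoronoiAdjacency:
    """Residue pairs sharing ≥1 atom-level Voronoi facet.

    ``facet_counts`` records, per unordered residue pair, the number of
    atom pairs (one atom from each residue) whose Voronoi cells share a
    facet — the basis of the two Voronoi-contact site features.
    """

    n: int
    facet_counts: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(self.facet_counts)

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for a, b in self.facet_counts:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out

    def to_tsv(self) -> str:
        lines = ["residue_i\tresidue_j\tshared_facets"]
        for (a, b), c in sorted(self.facet_counts.items()):
            lines.append(f"{a}\t{b}\t{c}")
        return "\n".join(lines) + "\n"


def _atoms_by_residue(chain: Chain, heavy_only: bool):
    coords, owners = [], []
    for idx, res in enumerate(chain):
        kept = [a for a in res.atoms if a.is_heavy] if heavy_only else res.atoms
        if not kept:
            kept = res.atoms
        for atom in kept:
            coords.append(atom.position)
            owners.append(idx)
    return np.asarray(coords, float), np.asarray(owners, int)


def euclidean_neighbors(chain: Chain, radius: float = NEIGHBOR_RADIUS) -> NeighborGraph:
    """Residues r, n are neighbours iff r ≠ n and the minimum Euclidean
    distance between any heavy atoms of the two is ≤ ``radius`` (inclusive)."""
    if not chain:
        raise GeometryError("empty chain")
    coords, owners = _atoms_by_residue(chain, heavy_only=True)
    graph = NeighborGraph(n=len(chain), radius=radius)
    if len(chain) == 1:
        return graph
    tree = cKDTree(coords)
    best: dict[tuple[int, int], float] = {}
    for ai, aj in tree.query_pairs(radius):
        ri, rj = owners[ai], owners[aj]
        if ri == rj:
            continue
        if ri > rj:
            ri, rj = rj, ri
        d = float(np.linalg.norm(coords[ai] - coords[aj]))
        if d <= radius:
            key = (ri, rj)
            if d < best.get(key, np.inf):
                best[key] = d
    for (ri, rj), d in best.items():
        graph.edges.setdefault(ri, {})[rj] = d
        graph.edges.setdefault(rj, {})[ri] = d
    return graph


def sidechain_center(residue: Residue) -> np.ndarray:
    """Unweighted centroid of the side-chain heavy atoms; glycine and other
    side-chain-less residues fall back to Cα (then to the all-atom centroid)."""
    side = [a.position for a in residue.atoms
            if a.is_heavy and a.name not in BACKBONE_ATOMS]
    if side:
        return np.mean(side, axis=0)
    ca = residue.atom("CA")
    if ca is not None:
        return np.asarray(ca.position, float)
    return residue.coords().mean(axis=0)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def voronoi_adjacency(chain: Chain,
                      shell_points: int = 256,
                      shell_margin: float = SHELL_MARGIN,
                      jitter: float = 1e-6,
                      jitter_seed: int = 0) -> VoronoiAdjacency:
    """Voronoi adjacency between residues of a chain.

    Space is partitioned into Voronoi cells around individual atoms; two
    residues are adjacent when some atom of one and some atom of the other
    have cells sharing a facet.  To avoid spurious adjacencies through
    unbounded surface cells, a shell of dummy points is added on a sphere of
    radius (structure radius + ``shell_margin``); facets involving dummy
    points are discarded.  Exact duplicate coordinates are jittered by
    ``jitter`` Å with a fixed seed before tessellation.
    """
    coords, owners = _atoms_by_residue(chain, heavy_only=False)
    if len(coords) < 4:
        raise GeometryError(
            f"need ≥4 atoms for a 3D Voronoi tessellation, got {len(coords)}")
    rng = np.random.default_rng(jitter_seed)
    rounded = {}
    pts = coords.copy()
    for i, p in enumerate(pts):
        key = tuple(np.round(p, 6))
        if key in rounded:
            pts[i] = p + rng.normal(scale=jitter, size=3)
        else:
            rounded[key] = i

    center = pts.mean(axis=0)
    if np.linalg.matrix_rank(pts - center, tol=1e-8) < 3:
        raise GeometryError(
            "degenerate atom configuration: points are collinear or coplanar")
    radius = float(np.linalg.norm(pts - center, axis=1).max()) + shell_margin
    shell = center + radius * _fibonacci_sphere(shell_points)
    allpts = np.vstack([pts, shell])
    n_real = len(pts)

    try:
        vor = Voronoi(allpts)
    except QhullError as exc:
        raise GeometryError(
            f"degenerate atom configuration (coplanar/collinear/duplicate "
            f"points): {exc}") from exc

    adj = VoronoiAdjacency(n=len(chain))
    for a, b in vor.ridge_points:
        if a >= n_real or b >= n_real:
            continue
        ra, rb = int(owners[a]), int(owners[b])
        if ra == rb:
            continue
        key = (ra, rb) if ra < rb else (rb, ra)
        adj.facet_counts[key] = adj.facet_counts.get(key, 0) + 1
    return adj


def representative_points(chain: Chain) -> np.ndarray:
    """One representative 3D point per residue: Cα, falling back to the
    heavy-atom centroid when Cα is absent."""
    pts = []
    for res in chain:
        ca = res.atom("CA")
        pts.append(np.asarray(ca.position, float) if ca is not None
                   else res.coords(heavy_only=True).mean(axis=0))
    return np.asarray(pts, float)


def delaunay_tetrahedra(chain: Chain) -> list[tuple[int, int, int, int]]:
    """Simplices of the 3D Delaunay tessellation over residue representative
    points.  Fewer than 4 residues yields an empty list; degenerate
    (collinear/coplanar) configurations raise :class:`GeometryError`."""
    if len(chain) < 4:
        return []
    pts = representative_points(chain)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise GeometryError(
            f"degenerate residue configuration for Delaunay tessellation "
            f"(collinear or coplanar points): {exc}") from exc
    return [tuple(int(v) for v in simplex) for simplex in tri.simplices]


def contact_counts(chain: Chain,
                   contact_cutoff: float = CONTACT_CUTOFF
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (NC_a, NC_r) contact features.

    NC_a(r): number of atom–atom pairs between r and any *other* residue at
    distance ≤ cutoff, divided by the atom count of r.  NC_r(r): number of
    distinct other residues with ≥1 such contact, divided by the atom count.
    """
    if not chain:
        raise GeometryError("empty chain")
    coords, owners = _atoms_by_residue(chain, heavy_only=False)
    n = len(chain)
    atom_pair_counts = np.zeros(n)
    partner_sets: list[set[int]] = [set() for _ in range(n)]
    tree = cKDTree(coords)
    for ai, aj in tree.query_pairs(contact_cutoff):
        ri, rj = int(owners[ai]), int(owners[aj])
        if ri == rj:
            continue
        atom_pair_counts[ri] += 1
        atom_pair_counts[rj] += 1
        partner_sets[ri].add(rj)
        partner_sets[rj].add(ri)
    n_atoms = np.array([len(res.atoms) for res in chain], dtype=float)
    nc_a = atom_pair_counts / n_atoms
    nc_r = np.array([len(s) for s in partner_sets], dtype=float) / n_atoms
    return nc_a, nc_r
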