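"""Discrete size functions on vertex-filtered graphs.

A *size function* of a pair ``(M, phi)`` — a space and a real measuring
function on it — assigns to each point ``(x, y)`` of the half-plane
``x <= y`` the number of connected components of the sublevel set
``{phi <= y}`` that contain at least one point with ``phi <= x``.  In the
discrete setting the space is a finite graph and connectedness is graph
connectedness.  This is 0-dimensional persistent homology of the sublevel
filtration; a size function is fully encoded by a multiset of *proper
cornerpoints* ``(x, y)`` with ``x < y`` (birth/death of a merging
component) together with one *cornerline* abscissa per connected component
of the whole graph (that component's minimum ``phi``).

This module provides the fast union-find computation, evaluation of a
size function from its cornerpoint diagram, the bottleneck-type matching
distance between diagrams, and deliberately naive brute-force oracles for
both, used by the test suite as independent references.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

__all__ = [
    "SizeGraph",
    "SFDiagram",
    "compute_size_function",
    "evaluate_sf",
    "brute_force_sf",
    "matching_distance",
    "brute_force_matching",
    "prune_diagram",
    "diagram_to_json",
    "diagram_from_json",
    "EmptyDomainError",
]


class EmptyDomainError(ValueError):
    """Raised for operations on an empty graph or empty diagram."""


def _norm_edge(a, b):
    return (a, b) if repr(a) <= repr(b) else (b, a)


@dataclass
class SizeGraph:
    """A finite graph with one real (finite) value per vertex.

    Parameters
    ----------
    vertices : list
        Ordered list of hashable vertex ids.  The order breaks ties
        between equal ``phi`` values, making the sweep deterministic.
    edges : set of 2-tuples
        Unordered vertex-id pairs; self-loops are rejected.
    phi : dict
        Measuring-function value for every vertex; must be finite.
    """

    vertices: list
    edges: set = field(default_factory=set)
    phi: dict = field(default_factory=dict)

    def __post_init__(self):
        vset = set(self.vertices)
        if len(vset) != len(self.vertices):
            raise ValueError("duplicate vertex ids")
        norm = set()
        for e in self.edges:
            a, b = e
            if a == b:
                raise ValueError(f"self-loop at {a!r}")
            if a not in vset or b not in vset:
                raise ValueError(f"edge {e!r} references undeclared vertex")
            norm.add(_norm_edge(a, b))
        self.edges = norm
        for v in self.vertices:
            if v not in self.phi:
                raise ValueError(f"phi missing for vertex {v!r}")
            if not math.isfinite(self.phi[v]):
                raise ValueError(f"phi not finite at {v!r}")

    def __len__(self):
        return len(self.vertices)


@dataclass
class SFDiagram:
    """Cornerpoint representation of a discrete size function.

    ``proper`` is a multiset (list) of ``(x, y)`` pairs with ``x < y``;
    ``cornerlines`` holds one abscissa per connected component of the
    source graph.
    """

    proper: list
    cornerlines: list

    def __post_init__(self):
        for x, y in self.proper:
            if not (x < y):
                raise ValueError(f"cornerpoint ({x}, {y}) not strictly below-diagonal")

    def __eq__(self, other):
        if not isinstance(other, SFDiagram):
            return NotImplemented
        return sorted(self.proper) == sorted(other.proper) and sorted(
            self.cornerlines
        ) == sorted(other.cornerlines)


class _UnionFind:
    """Union-find tracking per-component birth (phi value, processing rank)."""

    def __init__(self):
        self.parent = {}
        self.birth = {}  # root -> (phi, rank)

    def make(self, v, phi, rank):
        self.parent[v] = v
        self.birth[v] = (phi, rank)

    def find(self, v):
        root = v
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[v] != root:
            self.parent[v], v = root, self.parent[v]
        return root

    def union_elder(self, a, b):
        """Merge the components of a and b; the elder (smaller birth) root
        survives.  Returns (survivor_root, dying_birth) or None if already
        joined."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return None
        if self.birth[ra] <= self.birth[rb]:
            elder, younger = ra, rb
        else:
            elder, younger = rb, ra
        dying = self.birth[younger]
        self.parent[younger] = elder
        return elder, dying


def compute_size_function(g: SizeGraph) -> SFDiagram:
    """Cornerpoint diagram of the size function of ``g`` via a sorted sweep.

    Vertices are processed in increasing ``phi`` (ties by declaration
    order); each local entry births a component, an edge becomes active at
    the larger ``phi`` of its endpoints, and when two components merge the
    younger dies, emitting a proper cornerpoint unless birth equals death
    (zero-persistence pairs are dropped).  Components that never die emit
    cornerlines at their birth level.
    """
    if len(g) == 0:
        raise EmptyDomainError("empty domain")
    order = {v: i for i, v in enumerate(g.vertices)}
    verts = sorted(g.vertices, key=lambda v: (g.phi[v], order[v]))
    uf = _UnionFind()
    for rank, v in enumerate(verts):
        uf.make(v, g.phi[v], rank)

    def edge_key(e):
        a, b = e
        return (
            max(g.phi[a], g.phi[b]),
            max(order[a], order[b]),
            min(order[a], order[b]),
        )

    proper = []
    for e in sorted(g.edges, key=edge_key):
        a, b = e
        y = max(g.phi[a], g.phi[b])
        merged = uf.union_elder(a, b)
        if merged is not None:
            _, (x, _) = merged
            if x < y:
                proper.append((x, y))
    roots = {uf.find(v) for v in g.vertices}
    cornerlines = [uf.birth[r][0] for r in roots]
    return SFDiagram(proper=sorted(proper), cornerlines=sorted(cornerlines))


def evaluate_sf(d: SFDiagram, x: float, y: float) -> int:
    """Value of the size function at ``(x, y)`` from its diagram.

    By the representation theorem this equals the number of proper
    cornerpoints ``(a, b)`` with ``a <= x < y < b`` plus the number of
    cornerlines with abscissa ``<= x``.
    """
    if x > y:
        raise ValueError("above diagonal")
    n = sum(1 for a, b in d.proper if a <= x and b > y)
    n += sum(1 for a in d.cornerlines if a <= x)
    return n


def brute_force_sf(g: SizeGraph, x: float, y: float) -> int:
    """Direct evaluation from the definition; test oracle only.

    Builds the subgraph induced by ``{phi <= y}`` and counts its connected
    components containing at least one vertex with ``phi <= x``.
    """
    if x > y:
        raise ValueError("above diagonal")
    sub = [v for v in g.vertices if g.phi[v] <= y]
    uf = _UnionFind()
    for i, v in enumerate(sub):
        uf.make(v, g.phi[v], i)
    keep = set(sub)
    for a, b in g.edges:
        if a in keep and b in keep:
            uf.union_elder(a, b)
    touched = {uf.find(v) for v in sub if g.phi[v] <= x}
    return len(touched)


# ---------------------------------------------------------------------------
# Matching distance
# ---------------------------------------------------------------------------

def _pair_cost(p, q):
    # Transporting p to q, or pushing both to the diagonal, whichever is
    # cheaper — the standard matching-distance ground cost for cornerpoints.
    return min(
        max(abs(p[0] - q[0]), abs(p[1] - q[1])),
        max((p[1] - p[0]) / 2.0, (q[1] - q[0]) / 2.0),
    )


def _diag_cost(p):
    return (p[1] - p[0]) / 2.0


_EXHAUSTIVE_LIMIT = 8


def _bottleneck_exhaustive(p1, p2):
    n1, n2 = len(p1), len(p2)
    m = n1 + n2
    if m == 0:
        return 0.0
    # Pad both sides with diagonal slots; every bijection of the padded
    # sets corresponds to an admissible partial matching.
    a = list(p1) + [None] * n2
    b = list(p2) + [None] * n1
    best = math.inf
    for perm in itertools.permutations(range(m)):
        worst = 0.0
        for i, j in enumerate(perm):
            p, q = a[i], b[j]
            if p is None and q is None:
                c = 0.0
            elif p is None:
                c = _diag_cost(q)
            elif q is None:
                c = _diag_cost(p)
            else:
                c = _pair_cost(p, q)
            if c > worst:
                worst = c
            if worst >= best:
                break
        if worst < best:
            best = worst
            if best == 0.0:
                break
    return best


def _bottleneck_feasible(cost, diag1, diag2, t):
    """Perfect matching of size n1+n2 in the threshold graph at level t?

    Side A = points of d1 then one diagonal slot per point of d2; side B =
    points of d2 then one diagonal slot per point of d1.  Diagonal slots
    are mutually connected at zero cost.
    """
    n1, n2 = len(diag1), len(diag2)
    rows, cols = [], []
    rr, cc = np.nonzero(cost <= t)
    rows.extend(rr.tolist())
    cols.extend(cc.tolist())
    for i in np.nonzero(diag1 <= t)[0]:
        rows.append(int(i))
        cols.append(n2 + int(i))
    for j in np.nonzero(diag2 <= t)[0]:
        rows.append(n1 + int(j))
        cols.append(int(j))
    for i in range(n2):
        for j in range(n1):
            rows.append(n1 + i)
            cols.append(n2 + j)
    m = n1 + n2
    graph = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(m, m)
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum()) == m


def _bottleneck(p1, p2):
    n1, n2 = len(p1), len(p2)
    if n1 + n2 == 0:
        return 0.0
    if n1 + n2 <= _EXHAUSTIVE_LIMIT:
        return _bottleneck_exhaustive(p1, p2)
    a1 = np.asarray(p1, dtype=float).reshape(n1, 2)
    a2 = np.asarray(p2, dtype=float).reshape(n2, 2)
    diag1 = (a1[:, 1] - a1[:, 0]) / 2.0
    diag2 = (a2[:, 1] - a2[:, 0]) / 2.0
    dx = np.abs(a1[:, None, 0] - a2[None, :, 0])
    dy = np.abs(a1[:, None, 1] - a2[None, :, 1])
    cost = np.minimum(
        np.maximum(dx, dy), np.maximum(diag1[:, None], diag2[None, :])
    )
    cands = np.unique(
        np.concatenate([cost.ravel(), diag1, diag2, [0.0]])
    )
    lo, hi = 0, len(cands) - 1
    if _bottleneck_feasible(cost, diag1, diag2, cands[lo]):
        return float(cands[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _bottleneck_feasible(cost, diag1, diag2, cands[mid]):
            hi = mid
        else:
            lo = mid
    return float(cands[hi])


def _cornerline_cost(c1, c2, penalty):
    if len(c1) != len(c2):
        return None  # signal: conceptually infinite, use the penalty cap
    if not c1:
        return 0.0
    s1, s2 = sorted(c1), sorted(c2)
    return max(abs(a - b) for a, b in zip(s1, s2))


def _joint_range(d1, d2):
    vals = list(d1.cornerlines) + list(d2.cornerlines)
    for x, y in d1.proper:
        vals.extend((x, y))
    for x, y in d2.proper:
        vals.extend((x, y))
    return max(vals) - min(vals) if vals else 0.0


def matching_distance(d1: SFDiagram, d2: SFDiagram, cornerline_penalty=None) -> float:
    """Bottleneck-type matching distance between two cornerpoint diagrams.

    Proper cornerpoints are matched bijectively with the diagonal available
    as a sink; the reported value is the minimax pair cost.  Cornerlines
    match only cornerlines, in sorted order; when the two diagrams have
    different numbers of cornerlines the distance is conceptually infinite
    and the configured ``cornerline_penalty`` cap is returned instead
    (default: the joint range of the two diagrams' coordinates).
    """
    if not d1.cornerlines or not d2.cornerlines:
        raise EmptyDomainError("empty diagram")
    cl = _cornerline_cost(d1.cornerlines, d2.cornerlines, cornerline_penalty)
    if cl is None:
        return float(
            cornerline_penalty
            if cornerline_penalty is not None
            else _joint_range(d1, d2)
        )
    return float(max(cl, _bottleneck(d1.proper, d2.proper)))


def brute_force_matching(d1: SFDiagram, d2: SFDiagram, cornerline_penalty=None) -> float:
    """Exhaustive matching distance; test oracle only (<= 8 proper points)."""
    if not d1.cornerlines or not d2.cornerlines:
        raise EmptyDomainError("empty diagram")
    if len(d1.proper) + len(d2.proper) > _EXHAUSTIVE_LIMIT:
        raise ValueError("oracle limit")
    cl = _cornerline_cost(d1.cornerlines, d2.cornerlines, cornerline_penalty)
    if cl is None:
        return float(
            cornerline_penalty
            if cornerline_penalty is not None
            else _joint_range(d1, d2)
        )
    return float(max(cl, _bottleneck_exhaustive(d1.proper, d2.proper)))


def prune_diagram(d: SFDiagram, min_persistence: float) -> SFDiagram:
    """Drop proper cornerpoints with persistence ``y - x <= min_persistence``.

    Pruning both diagrams at level eps perturbs the matching distance by at
    most ``eps / 2`` (each dropped point was within eps/2 of the diagonal).
    """
    return SFDiagram(
        proper=[(x, y) for x, y in d.proper if y - x > min_persistence],
        cornerlines=list(d.cornerlines),
    )


def diagram_to_json(d: SFDiagram) -> str:
    def f(v):
        return float(f"{v:.12g}")

    return json.dumps(
        {
            "proper": [[f(x), f(y)] for x, y in d.proper],
            "cornerlines": [f(a) for a in d.cornerlines],
        }
    )


def diagram_from_json(s: str) -> SFDiagram:
    obj = json.loads(s)
    return SFDiagram(
        proper=[(x, y) for x, y in obj["proper"]],
        cornerlines=list(obj["cornerlines"]),
    )
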