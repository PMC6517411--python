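"""Binary directed networks: enumeration, sampling, perturbation, statistics.

Networks here stand in for large-scale brain networks: nodes are brain
regions, directed edges are (binary) interactions between them.  The study
design needs three ensembles — every weakly-connected nonisomorphic digraph
on 3 and on 4 nodes, and a stratified random sample of 19-node digraphs
whose edge counts cover the feasible range approximately uniformly.

Conventions
-----------
* ``adjacency[i, j] == 1`` means node *i* receives an edge from node *j*,
  matching the coupling sums ``sum_j M[i, j] * f(state_j)`` used by the
  dynamics.
* "Connected" means weakly connected (the underlying undirected graph is
  connected); this is the criterion under which there are exactly 13
  three-node and 199 four-node classes.
* Self-loops are excluded everywhere: the models describe inter-regional
  interactions only.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "NetworkStats",
    "enumerate_digraphs",
    "are_isomorphic",
    "automorphism_orbits",
    "sample_random_digraphs",
    "remove_node",
    "network_stats",
    "network_id",
    "save_edge_list",
    "load_edge_list",
    "save_adjacency_csv",
    "load_adjacency_csv",
    "save_ensemble_manifest",
]


@dataclass(frozen=True)
class Network:
    """A simple binary digraph with stable node labels.

    Parameters
    ----------
    adjacency
        Square 0/1 matrix with zero diagonal; ``adjacency[i, j] == 1``
        iff node ``labels[i]`` receives an edge from node ``labels[j]``.
    labels
        Stable integer identifiers, preserved across node removal so that
        per-node results remain attributable after perturbation.
    """

    adjacency: np.ndarray
    labels: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.int8)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.trace(adj) != 0:
            raise ValueError("self-loops are not allowed (nonzero diagonal)")
        object.__setattr__(self, "adjacency", adj)
        labels = self.labels
        if labels is None:
            labels = tuple(range(adj.shape[0]))
        else:
            labels = tuple(int(x) for x in labels)
            if len(labels) != adj.shape[0] or len(set(labels)) != len(labels):
                raise ValueError("labels must be unique and match adjacency size")
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def is_weakly_connected(self) -> bool:
        if self.n_nodes == 1:
            return True
        return nx.is_weakly_connected(self.to_networkx())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        rows, cols = np.nonzero(self.adjacency)
        # adjacency[i, j] = 1 is an edge j -> i
        g.add_edges_from(
            (self.labels[j], self.labels[i]) for i, j in zip(rows, cols)
        )
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.adjacency, other.adjacency
        )

    def __hash__(self) -> int:
        return hash((self.labels, self.adjacency.tobytes()))


@dataclass(frozen=True)
class NetworkStats:
    """Degree summary used by the heterogeneity analysis."""

    n_edges: int
    outdegree_mean: float
    outdegree_sd: float
    normalized_sd: float
    total_degree: tuple[int, ...]


def network_id(net: Network) -> int:
    """Stable 31-bit identifier of a network's labelled adjacency.

    Used to derive per-cell simulation seeds; depends only on the adjacency
    bytes and the label tuple, never on object identity.
    """
    h = np.uint64(0x9E3779B97F4A7C15)
    data = net.adjacency.tobytes() + np.asarray(net.labels, dtype=np.int64).tobytes()
    for b in data:
        h = np.uint64((int(h) ^ b) * 0x100000001B3 % (1 << 64))
    return int(h) % (1 << 31)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

_MAX_ENUM_NODES = 5


def _offdiag_indices(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def _canonical_code(adj: np.ndarray) -> int:
    """Smallest integer encoding of the off-diagonal bits over all node
    relabelings; two digraphs share a code iff they are isomorphic."""
    n = adj.shape[0]
    idx = _offdiag_indices(n)
    best = None
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        code = 0
        for i, j in idx:
            code = (code << 1) | int(adj[p[i], p[j]])
        if best is None or code < best:
            best = code
    return best


def enumerate_digraphs(n_nodes: int) -> list[Network]:
    """All weakly-connected simple digraphs on ``n_nodes`` nodes, one
    representative per isomorphism class.

    Exhausts the ``2**(n(n-1))`` zero-diagonal binary matrices, deduplicates
    by exact canonical form (minimum over all node permutations), then keeps
    the weakly-connected classes.  Output order is deterministic: ascending
    edge count, then canonical code.

    There are 13 classes for ``n_nodes=3`` and 199 for ``n_nodes=4``.
    """
    if not 2 <= n_nodes <= _MAX_ENUM_NODES:
        raise ValueError(
            f"exhaustive enumeration supports 2..{_MAX_ENUM_NODES} nodes, "
            f"got {n_nodes}"
        )
    n = n_nodes
    idx = _offdiag_indices(n)
    m = len(idx)

    # All 2**m bit patterns as a (2**m, m) uint8 array, bit k of pattern b in
    # column k (MSB first so codes match _canonical_code's encoding order).
    patterns = np.arange(1 << m, dtype=np.uint32)
    bits = (patterns[:, None] >> np.arange(m - 1, -1, -1)[None, :]) & 1
    bits = bits.astype(np.uint8)

    pos = {ij: k for k, ij in enumerate(idx)}
    weights = 1 << np.arange(m - 1, -1, -1, dtype=np.uint64)

    # Canonical code = min over permutations of the permuted bit string.
    codes = np.full(1 << m, np.iinfo(np.uint64).max, dtype=np.uint64)
    for perm in itertools.permutations(range(n)):
        col_order = np.array([pos[(perm[i], perm[j])] for i, j in idx])
        permuted = bits[:, col_order].astype(np.uint64)
        codes = np.minimum(codes, permuted @ weights)

    reps: list[Network] = []
    for code in np.unique(codes):
        adj = np.zeros((n, n), dtype=np.int8)
        for k, (i, j) in enumerate(idx):
            adj[i, j] = (int(code) >> (m - 1 - k)) & 1
        net = Network(adj)
        if net.is_weakly_connected():
            reps.append(net)
    reps.sort(key=lambda g: (g.n_edges, _canonical_code(g.adjacency)))
    return reps


# ---------------------------------------------------------------------------
# Isomorphism
# ---------------------------------------------------------------------------

def _fingerprint(net: Network) -> tuple:
    """Cheap isomorphism invariant: sorted joint degree/neighbourhood data."""
    adj = net.adjacency
    out_deg = adj.sum(axis=0)
    in_deg = adj.sum(axis=1)
    # For each node, the sorted multiset of (in, out) degrees of the nodes it
    # receives from — a 1-step Weisfeiler-Lehman style refinement.
    nbr = tuple(
        tuple(
            sorted(
                (int(in_deg[j]), int(out_deg[j])) for j in np.nonzero(adj[i])[0]
            )
        )
        for i in range(net.n_nodes)
    )
    joint = tuple(
        sorted(zip((int(x) for x in in_deg), (int(x) for x in out_deg), nbr))
    )
    return (net.n_nodes, net.n_edges, joint)


def are_isomorphic(a: Network, b: Network) -> bool:
    """Exact digraph isomorphism test.

    Cheap degree/neighbourhood invariants prune obvious non-matches; the
    remaining cases go through an exact VF2 search.
    """
    if a.n_nodes != b.n_nodes:
        return False
    if _fingerprint(a) != _fingerprint(b):
        return False
    ga = nx.from_numpy_array(np.asarray(a.adjacency.T), create_using=nx.DiGraph)
    gb = nx.from_numpy_array(np.asarray(b.adjacency.T), create_using=nx.DiGraph)
    return nx.is_isomorphic(ga, gb)


def automorphism_orbits(net: Network) -> list[tuple[int, ...]]:
    """Partition the node labels into automorphism orbits.

    Nodes in the same orbit are exchangeable by a relabeling symmetry of the
    network, so any node-level quantity defined by the dynamics (such as NI)
    is exactly equal across an orbit.  Two nodes share an orbit iff the
    network with one node marked is isomorphic to the network with the other
    marked; cheap degree/neighbourhood invariants prune the candidate pairs,
    so rigid graphs (the generic case) cost nothing and even the complete
    digraph stays fast because a witness mapping is found immediately.
    """
    n = net.n_nodes
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    adj = net.adjacency
    out_deg = adj.sum(axis=0)
    in_deg = adj.sum(axis=1)
    invariant = [
        (
            int(in_deg[i]),
            int(out_deg[i]),
            tuple(sorted(
                (int(in_deg[j]), int(out_deg[j])) for j in np.nonzero(adj[i])[0]
            )),
        )
        for i in range(n)
    ]

    def marked_isomorphic(i: int, j: int) -> bool:
        gi = nx.from_numpy_array(np.asarray(adj.T), create_using=nx.DiGraph)
        gj = gi.copy()
        nx.set_node_attributes(gi, {k: (k == i) for k in range(n)}, "marked")
        nx.set_node_attributes(gj, {k: (k == j) for k in range(n)}, "marked")
        matcher = nx.algorithms.isomorphism.DiGraphMatcher(
            gi, gj, node_match=lambda a, b: a["marked"] == b["marked"]
        )
        return matcher.is_isomorphic()

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j) or invariant[i] != invariant[j]:
                continue
            if marked_isomorphic(i, j):
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [tuple(net.labels[i] for i in members) for members in groups.values()]


# ---------------------------------------------------------------------------
# Stratified random sampling
# ---------------------------------------------------------------------------

def sample_random_digraphs(
    n_nodes: int,
    n_networks: int,
    edge_range: tuple[int, int],
    seed: int,
    max_tries_per_network: int = 20_000,
) -> list[Network]:
    """Sample weakly-connected, pairwise-nonisomorphic digraphs with edge
    counts approximately uniform over ``edge_range``.

    The target edge count of network ``k`` is the stratum
    ``min + k * (max - min) / (n_networks - 1)`` (rounded), so the sample
    spans the range evenly by construction.  For each stratum, that many
    directed edges are placed uniformly at random among the ``n(n-1)``
    ordered pairs, rejecting draws that are disconnected or isomorphic to an
    already accepted network.

    Fully reproducible: same arguments, same networks.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    lo, hi = int(edge_range[0]), int(edge_range[1])
    max_edges = n_nodes * (n_nodes - 1)
    if lo < n_nodes - 1 or hi > max_edges or lo > hi:
        raise ValueError(
            f"edge_range {edge_range} infeasible for weakly-connected "
            f"{n_nodes}-node digraphs (need {n_nodes - 1} <= lo <= hi <= {max_edges})"
        )
    rng = np.random.default_rng(seed)
    pairs = np.asarray(_offdiag_indices(n_nodes))

    if n_networks == 1:
        targets = [int(round((lo + hi) / 2))] if lo != hi else [lo]
    else:
        targets = [
            int(round(lo + k * (hi - lo) / (n_networks - 1)))
            for k in range(n_networks)
        ]

    accepted: list[Network] = []
    fingerprints: dict[tuple, list[Network]] = {}
    for k, m in enumerate(targets):
        ok = False
        for _ in range(max_tries_per_network):
            chosen = rng.choice(len(pairs), size=m, replace=False)
            adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
            adj[pairs[chosen, 0], pairs[chosen, 1]] = 1
            net = Network(adj)
            if not net.is_weakly_connected():
                continue
            fp = _fingerprint(net)
            if any(are_isomorphic(net, other) for other in fingerprints.get(fp, [])):
                continue
            accepted.append(net)
            fingerprints.setdefault(fp, []).append(net)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not draw a fresh connected nonisomorphic digraph with "
                f"{m} edges (stratum {k}) within {max_tries_per_network} tries"
            )
    return accepted


# ---------------------------------------------------------------------------
# Perturbation and statistics
# ---------------------------------------------------------------------------

def remove_node(net: Network, node: int) -> Network:
    """Induced subnetwork after deleting one node (a model resection).

    The remaining labels are unchanged.  The result is allowed to be
    disconnected: the dynamics remain well defined on it.
    """
    if net.n_nodes < 2:
        raise ValueError("cannot remove a node from a 1-node network")
    if node not in net.labels:
        raise KeyError(f"no node labelled {node!r} in network")
    pos = net.labels.index(node)
    keep = [i for i in range(net.n_nodes) if i != pos]
    sub = net.adjacency[np.ix_(keep, keep)]
    labels = tuple(l for l in net.labels if l != node)
    return Network(sub, labels)


def network_stats(net: Network) -> NetworkStats:
    """Edge count and outdegree dispersion.

    ``normalized_sd`` is the population standard deviation of the outdegree
    sequence divided by its mean — the heterogeneity measure related to
    cross-model agreement of resection predictions.
    """
    adj = net.adjacency
    out_deg = adj.sum(axis=0).astype(float)
    in_deg = adj.sum(axis=1).astype(float)
    mean = float(out_deg.mean())
    sd = float(out_deg.std())  # population convention (divide by N)
    return NetworkStats(
        n_edges=int(adj.sum()),
        outdegree_mean=mean,
        outdegree_sd=sd,
        normalized_sd=sd / mean if mean > 0 else 0.0,
        total_degree=tuple(int(x) for x in (in_deg + out_deg)),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_edge_list(net: Network, path) -> None:
    """Write a TSV edge list (source, target), one directed edge per line."""
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={net.n_nodes} labels={','.join(map(str, net.labels))}\n")
        rows, cols = np.nonzero(net.adjacency)
        for i, j in zip(rows, cols):
            fh.write(f"{net.labels[j]}\t{net.labels[i]}\n")


def load_edge_list(path) -> Network:
    labels: list[int] | None = None
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("labels="):
                        labels = [int(x) for x in tok[len("labels="):].split(",")]
                continue
            s, t = line.split("\t")
            edges.append((int(s), int(t)))
    if labels is None:
        labels = sorted({x for e in edges for x in e})
    index = {l: k for k, l in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for s, t in edges:
        adj[index[t], index[s]] = 1
    return Network(adj, tuple(labels))


def save_adjacency_csv(net: Network, path) -> None:
    np.savetxt(path, net.adjacency, fmt="%d", delimiter=",")


def load_adjacency_csv(path) -> Network:
    adj = np.loadtxt(path, delimiter=",", dtype=np.int8)
    if adj.ndim == 0:
        adj = adj.reshape(1, 1)
    return Network(np.atleast_2d(adj))


def save_ensemble_manifest(nets: list[Network], path, seed: int | None = None) -> None:
    """JSON manifest describing an ensemble (ids, sizes, generation seed)."""
    records = [
        {
            "index": k,
            "network_id": network_id(net),
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
        }
        for k, net in enumerate(nets)
    ]
    with open(path, "w") as fh:
        json.dump({"seed": seed, "networks": records}, fh, indent=1)
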