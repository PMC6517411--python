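"""Cross-model agreement of node-removal predictions.

Two models agree on a network when they rank its nodes' ictogenicity (NI)
the same way.  Agreement is scored with a weighted Kendall rank
coefficient: over all unordered node pairs (i, j), a pair ranked in the
same order by both models adds ``|NI_i^A - NI_j^A| * |NI_i^B - NI_j^B|``
to the concordant mass P, a pair ranked oppositely adds the same weight to
the discordant mass Q, and

    tau = (P - Q) / (P + Q),   tau in [-1, 1].

The weighting makes disagreements between nearly-tied nodes (whose order is
dominated by simulation noise) count for little, while disagreements about
clearly separated nodes count heavily.

The ensemble analysis then relates agreement to NI heterogeneity: per-model
min-max normalised ``dNI`` spreads, equal-occupancy ``dNI`` bins of the
mean tau, and the Spearman correlation between outdegree dispersion and
``dNI``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ictogenicity import NIDistribution
from .networks import Network, network_stats

__all__ = [
    "WeightedKendallResult",
    "ComparisonResult",
    "weighted_kendall",
    "top_k_kendall",
    "pairwise_tau",
    "orbit_groups",
    "heterogeneity_analysis",
    "TIE_TOL",
]

# NI values closer than this are treated as exactly tied (zero weight).
TIE_TOL = 1e-12


@dataclass(frozen=True)
class WeightedKendallResult:
    tau: float
    concordant: float        # weighted mass P
    discordant: float        # weighted mass Q
    n_pairs: int             # unordered pairs considered (ties included)
    undefined: bool          # P + Q == 0: no rankable pair

    def __float__(self) -> float:
        return self.tau


def weighted_kendall(ni_a, ni_b, weighted: bool = True,
                     groups=None) -> WeightedKendallResult:
    """Weighted Kendall rank agreement of two per-node NI lists.

    Pairs tied (within ``TIE_TOL``) in either list carry zero weight and
    affect neither P nor Q.  ``groups`` (an integer group id per node) marks
    *structural* ties: pairs within a group — e.g. nodes in the same network
    automorphism orbit, whose true NI is exactly equal — also carry zero
    weight, so their noise-driven ordering cannot masquerade as agreement or
    disagreement.  With ``weighted=False`` every non-tied pair counts 1,
    which reproduces the classical Kendall tau-a whenever there are no
    ties.  When no pair is rankable (P + Q = 0) the result is flagged
    undefined and ``tau`` is NaN.
    """
    a = np.asarray(ni_a, dtype=float)
    b = np.asarray(ni_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("NI lists must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 nodes to rank")
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    iu = np.triu_indices(n, k=1)
    da, db = da[iu], db[iu]
    tied = (np.abs(da) <= TIE_TOL) | (np.abs(db) <= TIE_TOL)
    if groups is not None:
        g = np.asarray(groups)
        if g.shape != a.shape:
            raise ValueError("groups must assign one group id per node")
        tied |= (g[:, None] == g[None, :])[iu]
    w = np.where(tied, 0.0, np.abs(da * db) if weighted else 1.0)
    sign = np.sign(da) * np.sign(db)
    P = float(w[sign > 0].sum())
    Q = float(w[sign < 0].sum())
    if P + Q == 0.0:
        return WeightedKendallResult(float("nan"), P, Q, da.size, True)
    return WeightedKendallResult((P - Q) / (P + Q), P, Q, da.size, False)


def top_k_kendall(ni_a, ni_b, k: int, reference: str = "a",
                  weighted: bool = True) -> WeightedKendallResult:
    """Weighted Kendall tau restricted to the k most ictogenic nodes.

    "Most ictogenic" is judged by the ``reference`` list ("a" or "b"); with
    ties at the cut, earlier positions win (stable sort).
    """
    a = np.asarray(ni_a, dtype=float)
    b = np.asarray(ni_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("NI lists must be 1-D and of equal length")
    if k < 2:
        raise ValueError("need k >= 2 to rank a restriction")
    if k > a.size:
        raise ValueError(f"k={k} exceeds the number of nodes {a.size}")
    if reference not in ("a", "b"):
        raise ValueError("reference must be 'a' or 'b'")
    ref = a if reference == "a" else b
    top = np.argsort(-ref, kind="stable")[:k]
    return weighted_kendall(a[top], b[top], weighted=weighted)


def orbit_groups(net: Network) -> np.ndarray:
    """Group id per node (in label order) from the automorphism orbits."""
    from .networks import automorphism_orbits

    membership = {}
    for gid, orbit in enumerate(automorphism_orbits(net)):
        for label in orbit:
            membership[label] = gid
    return np.array([membership[label] for label in net.labels])


def pairwise_tau(dists_a: list[NIDistribution],
                 dists_b: list[NIDistribution],
                 networks: list[Network] | None = None) -> np.ndarray:
    """Per-network weighted tau between two aligned lists of NI results.

    When ``networks`` is supplied, node pairs in the same automorphism orbit
    are treated as structural ties (their true NI is equal by symmetry); a
    vertex-transitive network then has no rankable pair and yields NaN.
    """
    if len(dists_a) != len(dists_b):
        raise ValueError("NI lists cover different numbers of networks")
    if networks is not None and len(networks) != len(dists_a):
        raise ValueError("networks must align with the NI lists")
    taus = np.empty(len(dists_a))
    for k, (da, db) in enumerate(zip(dists_a, dists_b)):
        if da.labels != db.labels:
            raise ValueError(f"node labels differ at ensemble index {k}")
        groups = None
        if networks is not None:
            if networks[k].labels != da.labels:
                raise ValueError(f"network labels differ at ensemble index {k}")
            groups = orbit_groups(networks[k])
        taus[k] = weighted_kendall(da.ni, db.ni, groups=groups).tau
    return taus


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement summary for one ensemble and set of models."""

    pairs: tuple[tuple[str, str], ...]
    per_network: pd.DataFrame     # network, pair, tau
    mean_tau: dict[tuple[str, str], float]
    n_undefined: dict[tuple[str, str], int]
    binned: pd.DataFrame          # pair, reference, bin, tau_mean, tau_sem, ...
    spearman: dict[str, tuple[float, float]]   # model -> (rho, p-value)


def _equal_occupancy_bins(n: int, n_bins: int) -> list[np.ndarray]:
    """Index blocks of sizes differing by at most one; the remainder goes to
    the lowest bins."""
    q, r = divmod(n, n_bins)
    sizes = [q + 1] * r + [q] * (n_bins - r)
    edges = np.cumsum([0] + sizes)
    return [np.arange(edges[i], edges[i + 1]) for i in range(n_bins)]


def heterogeneity_analysis(ni_tables: dict[str, list[NIDistribution]],
                           networks: list[Network],
                           n_bins: int = 4,
                           norm_dni_min: float = 0.05,
                           ) -> tuple[pd.DataFrame, ComparisonResult]:
    """Relate cross-model agreement to NI heterogeneity over an ensemble.

    Parameters
    ----------
    ni_tables
        Model name -> NI results, one per network, in the same network order
        for every model.
    networks
        The ensemble, aligned with the NI lists (provides degree statistics).

    Returns the per-(network, model) heterogeneity table and a
    :class:`ComparisonResult` with ensemble mean tau per model pair, the
    tau-vs-dNI bin profile (equal-occupancy bins of the networks whose
    normalised dNI exceeds ``norm_dni_min``, binned separately with each
    model of the pair as reference), and the per-model Spearman correlation
    between outdegree dispersion and dNI.

    Networks whose tau is undefined (no rankable pair) are excluded from the
    averages and counted in ``n_undefined``.
    """
    models = list(ni_tables)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    n_networks = len(networks)
    for m in models:
        if len(ni_tables[m]) != n_networks:
            raise ValueError(f"model {m!r} has NI for {len(ni_tables[m])} "
                             f"networks, expected {n_networks}")

    stats_ = [network_stats(net) for net in networks]
    het_rows = []
    dni = {}
    dni_norm = {}
    for m in models:
        d = np.array([dist.delta_ni for dist in ni_tables[m]])
        span = d.max() - d.min()
        dn = (d - d.min()) / span if span > 0 else np.zeros_like(d)
        dni[m], dni_norm[m] = d, dn
        for k in range(n_networks):
            het_rows.append({
                "network": k,
                "network_id": ni_tables[m][k].network_id,
                "model": m,
                "delta_ni": d[k],
                "delta_ni_norm": dn[k],
                "n_edges": stats_[k].n_edges,
                "outdegree_norm_sd": stats_[k].normalized_sd,
            })
    het = pd.DataFrame(het_rows)

    pairs = [(models[i], models[j]) for i in range(len(models))
             for j in range(i + 1, len(models))]
    per_net_rows = []
    mean_tau = {}
    n_undef = {}
    taus = {}
    for pair in pairs:
        t = pairwise_tau(ni_tables[pair[0]], ni_tables[pair[1]],
                         networks=networks)
        taus[pair] = t
        defined = np.isfinite(t)
        mean_tau[pair] = float(t[defined].mean()) if defined.any() else float("nan")
        n_undef[pair] = int((~defined).sum())
        for k in range(n_networks):
            per_net_rows.append({"network": k, "pair": f"{pair[0]}|{pair[1]}",
                                 "tau": t[k]})
    per_network = pd.DataFrame(per_net_rows)

    bin_rows = []
    for pair in pairs:
        t = taus[pair]
        for ref in pair:
            keep = np.where((dni_norm[ref] > norm_dni_min) & np.isfinite(t))[0]
            if keep.size < n_bins:
                raise ValueError(
                    f"only {keep.size} networks pass the dNI filter for "
                    f"reference {ref!r}; cannot form {n_bins} bins"
                )
            order = keep[np.argsort(dni[ref][keep], kind="stable")]
            for b, idx in enumerate(_equal_occupancy_bins(order.size, n_bins)):
                members = order[idx]
                tv = t[members]
                bin_rows.append({
                    "pair": f"{pair[0]}|{pair[1]}",
                    "reference": ref,
                    "bin": b,
                    "tau_mean": float(tv.mean()),
                    "tau_sem": float(tv.std(ddof=1) / np.sqrt(tv.size))
                    if tv.size > 1 else float("nan"),
                    "dni_mean": float(dni[ref][members].mean()),
                    "n_networks": int(members.size),
                })
    binned = pd.DataFrame(bin_rows)

    spearman = {}
    for m in models:
        x = np.array([s.normalized_sd for s in stats_])
        rho, pval = stats.spearmanr(x, dni[m])
        spearman[m] = (float(rho), float(pval))

    return het, ComparisonResult(tuple(pairs), per_network, mean_tau,
                                 n_undef, binned, spearman)
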