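import numpy as np
import pytest
from scipy import stats as sps

from ictonet.comparison import (
    _equal_occupancy_bins,
    heterogeneity_analysis,
    top_k_kendall,
    weighted_kendall,
)
from ictonet.ictogenicity import NIDistribution
from ictonet.networks import Network, network_stats


def brute_force_weighted_tau(a, b, weighted=True):
    """Independent O(n^2) oracle: literal pair enumeration."""
    P = Q = 0.0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if abs(da) <= 1e-12 or abs(db) <= 1e-12:
                continue
            w = abs(da) * abs(db) if weighted else 1.0
            if (da > 0) == (db > 0):
                P += w
            else:
                Q += w
    if P + Q == 0:
        return float("nan"), P, Q
    return (P - Q) / (P + Q), P, Q


class TestWeightedKendall:
    def test_hand_worked_example(self):
        res = weighted_kendall([0.5, 0.3, 0.2], [0.5, 0.2, 0.3])
        assert res.concordant == pytest.approx(0.12)
        assert res.discordant == pytest.approx(0.01)
        assert res.tau == pytest.approx(11 / 13)

    def test_perfect_agreement_and_inversion(self):
        a = np.array([0.9, 0.5, 0.3, 0.1])
        assert weighted_kendall(a, a).tau == 1.0
        assert weighted_kendall(a, -a).tau == -1.0

    def test_undefined_when_one_list_constant(self):
        res = weighted_kendall([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.undefined
        assert np.isnan(res.tau)

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_kendall([1.0], [2.0])
        with pytest.raises(ValueError):
            weighted_kendall([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            if rng.random() < 0.3:   # inject ties
                a[rng.integers(n)] = a[rng.integers(n)]
            res = weighted_kendall(a, b)
            expected, P, Q = brute_force_weighted_tau(a, b)
            assert res.concordant == pytest.approx(P)
            assert res.discordant == pytest.approx(Q)
            if np.isnan(expected):
                assert res.undefined
            else:
                assert res.tau == pytest.approx(expected)

    def test_unweighted_equals_classical_tau_a(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            a = rng.permutation(n).astype(float)
            b = rng.permutation(n).astype(float)
            ours = weighted_kendall(a, b, weighted=False).tau
            ref = sps.kendalltau(a, b).statistic  # tau-b == tau-a without ties
            assert ours == pytest.approx(ref)

    def test_invariant_under_positive_affine_transforms(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        base = weighted_kendall(a, b).tau
        assert weighted_kendall(3.0 * a + 1.0, 0.5 * b - 2.0).tau == pytest.approx(base)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=9)
        b = rng.normal(size=9)
        assert weighted_kendall(a, b).tau == pytest.approx(weighted_kendall(b, a).tau)


class TestTopK:
    def test_full_k_equals_unrestricted(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=7)
        b = rng.normal(size=7)
        assert top_k_kendall(a, b, 7).tau == pytest.approx(weighted_kendall(a, b).tau)

    def test_agreeing_head(self):
        a = np.array([9.0, 8.0, 7.0, 6.0, 5.0, 0.1, 0.2])
        b = np.array([9.0, 8.5, 7.2, 6.1, 5.3, 0.3, 0.1])
        assert top_k_kendall(a, b, 5).tau == 1.0

    def test_restriction_can_raise_agreement(self):
        # head agrees, tail strongly disagrees
        a = np.array([10.0, 9.0, 8.0, 1.0, 2.0, 3.0])
        b = np.array([10.0, 9.0, 8.0, 3.0, 2.0, 1.0])
        assert top_k_kendall(a, b, 3).tau > weighted_kendall(a, b).tau

    def test_reference_selection(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([4.0, 3.0, 2.0, 1.0])
        ra = top_k_kendall(a, b, 2, reference="a")
        rb = top_k_kendall(a, b, 2, reference="b")
        assert ra.tau == rb.tau == -1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            top_k_kendall([1.0, 2.0], [1.0, 2.0], 1)
        with pytest.raises(ValueError):
            top_k_kendall([1.0, 2.0], [1.0, 2.0], 5)
        with pytest.raises(ValueError):
            top_k_kendall([1.0, 2.0], [1.0, 2.0], 2, reference="c")


class TestEqualOccupancyBins:
    @pytest.mark.parametrize("n, sizes", [(8, [2, 2, 2, 2]), (10, [3, 3, 2, 2]),
                                          (13, [4, 3, 3, 3]), (4, [1, 1, 1, 1])])
    def test_sizes(self, n, sizes):
        bins = _equal_occupancy_bins(n, 4)
        assert [len(b) for b in bins] == sizes
        assert np.concatenate(bins).tolist() == list(range(n))


def _synthetic_ensemble(n_networks=12, n_nodes=6, seed=0):
    """Networks with increasing outdegree dispersion plus NI tables whose
    heterogeneity follows that dispersion monotonically."""
    rng = np.random.default_rng(seed)
    networks, spreads = [], []
    k = 0
    while len(networks) < n_networks:
        adj = (rng.random((n_nodes, n_nodes)) < rng.uniform(0.2, 0.9)).astype(np.int8)
        np.fill_diagonal(adj, 0)
        net = Network(adj)
        if not net.is_weakly_connected():
            continue
        nsd = network_stats(net).normalized_sd
        if any(abs(nsd - s) < 1e-9 for s in spreads):
            continue   # strict monotonicity needs distinct dispersions
        networks.append(net)
        spreads.append(nsd)
        k += 1
    order = np.argsort(spreads)
    networks = [networks[i] for i in order]
    spreads = [spreads[i] for i in order]
    tables = {}
    for model in ("m1", "m2"):
        dists = []
        for j, net in enumerate(networks):
            # identical rankings across models; dNI grows with dispersion rank
            ni = np.linspace(0.0, 0.1 + 0.08 * j, n_nodes)
            dists.append(NIDistribution(model, j, net.labels, ni, 0.5,
                                        0.5 * (1 - ni)))
        tables[model] = dists
    return tables, networks


class TestHeterogeneityAnalysis:
    def test_identical_rankings_give_unit_tau_everywhere(self):
        tables, networks = _synthetic_ensemble()
        het, comp = heterogeneity_analysis(tables, networks)
        assert comp.mean_tau[("m1", "m2")] == pytest.approx(1.0)
        assert np.allclose(comp.binned["tau_mean"], 1.0)

    def test_monotone_spread_gives_unit_spearman(self):
        tables, networks = _synthetic_ensemble()
        _, comp = heterogeneity_analysis(tables, networks)
        for model in ("m1", "m2"):
            assert comp.spearman[model][0] == pytest.approx(1.0)

    def test_normalized_dni_spans_unit_interval(self):
        tables, networks = _synthetic_ensemble()
        het, _ = heterogeneity_analysis(tables, networks)
        for model in ("m1", "m2"):
            col = het[het["model"] == model]["delta_ni_norm"]
            assert col.min() == 0.0 and col.max() == 1.0

    def test_equal_bin_occupancy(self):
        tables, networks = _synthetic_ensemble()
        _, comp = heterogeneity_analysis(tables, networks)
        for (_, _), group in comp.binned.groupby(["pair", "reference"]):
            sizes = group["n_networks"].to_numpy()
            assert sizes.max() - sizes.min() <= 1

    def test_undefined_tau_excluded_and_counted(self):
        tables, networks = _synthetic_ensemble()
        # make one network unrankable in m1
        d = tables["m1"][5]
        tables["m1"][5] = NIDistribution(
            d.model, d.network_id, d.labels, np.zeros_like(d.ni),
            d.mean_bni_full, d.mean_bni_removed)
        _, comp = heterogeneity_analysis(tables, networks)
        assert comp.n_undefined[("m1", "m2")] == 1
        assert comp.mean_tau[("m1", "m2")] == pytest.approx(1.0)

    def test_too_few_survivors_is_an_error(self):
        tables, networks = _synthetic_ensemble(n_networks=5)
        # squash all spreads below the filter except one dominating network
        for model in tables:
            for j, d in enumerate(tables[model]):
                ni = np.full(len(d.ni), 0.2)
                if j == 4:
                    ni = np.linspace(0, 5.0, len(d.ni))
                tables[model][j] = NIDistribution(
                    d.model, d.network_id, d.labels, ni, 0.5, 0.5 * (1 - ni))
        with pytest.raises(ValueError, match="bins"):
            heterogeneity_analysis(tables, networks)

    def test_misaligned_inputs_rejected(self):
        tables, networks = _synthetic_ensemble()
        with pytest.raises(ValueError):
            heterogeneity_analysis({"m1": tables["m1"]}, networks)
        with pytest.raises(ValueError):
            heterogeneity_analysis(
                {"m1": tables["m1"], "m2": tables["m2"][:-1]}, networks)
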